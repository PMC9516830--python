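"""Delivery-ascertainment phenotyping from timestamped billing codes and EGA.

The algorithm demarcates pregnancy episodes by grouping delivery-relevant
events into backward 37-week windows anchored at the most recent unassigned
event, assigns each episode an outcome label from delivery-type diagnosis
codes and from the most recent estimated-gestational-age (EGA) observation,
resolves code/EGA disagreement by the priority postterm > term > preterm
(the oldest gestational classification wins), takes the most recent member
timestamp as the delivery date, and derives a conception date when an EGA
observation exists within three days of delivery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from gravida.simulate import (
    CESAREAN_CODES,
    DELIVERY_DX_CODES,
    DELIVERY_PX_CODES,
    INDUCED_CODES,
    MULTI_GEST_CODES,
    POSTTERM,
    PPROM_CODES,
    PRETERM,
    TERM,
    UNDETERMINED,
    VAGINAL_CODES,
)

logger = logging.getLogger(__name__)

#: Episode window length in days (< 37 completed weeks).
EPISODE_WINDOW_DAYS = 259

#: EGA observations documented up to this many days after a code-seeded
#: episode's anchor still attach to it (EGA near delivery is routinely
#: recorded a day or two after the delivery codes; a strict backward window
#: would split those observations into spurious one-event episodes).
EGA_ATTACH_GRACE_DAYS = 3

#: Consensus priority: the oldest gestational-age classification wins.
LABEL_PRIORITY = {POSTTERM: 3, TERM: 2, PRETERM: 1}

LABELS = (PRETERM, TERM, POSTTERM)


class DataError(ValueError):
    """Raised on physically impossible input values (e.g. negative EGA)."""


@dataclass(frozen=True)
class CodeEvent:
    """One timestamped billing code for one patient."""

    patient_id: str
    system: str  # DX or PX
    code: str
    day: int


@dataclass(frozen=True)
class AscertainmentCodeSets:
    """User-configurable code families used to ascertain delivery type/date.

    ``delivery_dx`` maps each delivery-type diagnosis code to its implied
    label (``preterm`` / ``term`` / ``postterm`` / ``unlabeled``); the other
    families are plain sets.
    """

    delivery_dx: Mapping[str, str] = field(default_factory=dict)
    delivery_px: frozenset = frozenset()
    multiple_gestation: frozenset = frozenset()
    induced_labor: frozenset = frozenset()
    cesarean: frozenset = frozenset()
    vaginal: frozenset = frozenset()
    pprom: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "delivery_dx", dict(self.delivery_dx))
        for name in ("delivery_px", "multiple_gestation", "induced_labor",
                     "cesarean", "vaginal", "pprom"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        bad = set(self.cesarean) & set(self.vaginal)
        if bad:
            raise ValueError(f"cesarean and vaginal code sets overlap: {sorted(bad)}")
        for code, label in self.delivery_dx.items():
            if label not in (*LABELS, "unlabeled"):
                raise ValueError(f"delivery_dx[{code!r}] has invalid label {label!r}")

    @property
    def all_codes(self) -> frozenset:
        """Every ascertainment code (excluded from prediction features)."""
        return frozenset(self.delivery_dx) | self.delivery_px | \
            self.multiple_gestation | self.induced_labor | self.cesarean | \
            self.vaginal | self.pprom

    @classmethod
    def default(cls) -> "AscertainmentCodeSets":
        """Code sets matching the synthetic generator's vocabulary."""
        dx = {c: lab for lab, codes in DELIVERY_DX_CODES.items() for c in codes}
        return cls(
            delivery_dx=dx,
            delivery_px=frozenset(DELIVERY_PX_CODES),
            multiple_gestation=frozenset(MULTI_GEST_CODES),
            induced_labor=frozenset(INDUCED_CODES),
            cesarean=frozenset(CESAREAN_CODES),
            vaginal=frozenset(VAGINAL_CODES),
            pprom=frozenset(PPROM_CODES),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AscertainmentCodeSets":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            delivery_dx=d.get("delivery_dx", {}),
            delivery_px=frozenset(d.get("delivery_px", [])),
            multiple_gestation=frozenset(d.get("multiple_gestation", [])),
            induced_labor=frozenset(d.get("induced_labor", [])),
            cesarean=frozenset(d.get("cesarean", [])),
            vaginal=frozenset(d.get("vaginal", [])),
            pprom=frozenset(d.get("pprom", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dict(
            delivery_dx=dict(self.delivery_dx),
            delivery_px=sorted(self.delivery_px),
            multiple_gestation=sorted(self.multiple_gestation),
            induced_labor=sorted(self.induced_labor),
            cesarean=sorted(self.cesarean),
            vaginal=sorted(self.vaginal),
            pprom=sorted(self.pprom),
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# core demarcation and labeling rules
# ---------------------------------------------------------------------------

def demarcate_episodes(days: Sequence[int]) -> np.ndarray:
    """Assign delivery-relevant event days to pregnancy episodes.

    Iterative rule: anchor at the latest unassigned day; all unassigned days
    in the half-open window ``(anchor - 259, anchor]`` join that episode;
    repeat until every day is assigned. Episodes are re-indexed oldest-first
    starting at 1. Returns an array of episode indices aligned with the
    input order; empty input yields an empty assignment.
    """
    days = np.asarray(days, dtype=np.int64)
    out = np.zeros(len(days), dtype=np.int64)
    unassigned = np.ones(len(days), dtype=bool)
    groups = []  # anchors, newest first
    while unassigned.any():
        anchor = days[unassigned].max()
        member = unassigned & (days > anchor - EPISODE_WINDOW_DAYS) & (days <= anchor)
        groups.append(member)
        unassigned &= ~member
    for newest_rank, member in enumerate(groups):
        out[member] = len(groups) - newest_rank  # oldest-first indices
    return out


def label_from_delivery_codes(
    codes: Iterable[str], code_sets: AscertainmentCodeSets
) -> str:
    """Outcome label implied by an episode's delivery-type diagnosis codes.

    Conflicting implied labels within an episode resolve by the consensus
    priority (postterm > term > preterm); no labeled code -> undetermined.
    """
    labels = {
        code_sets.delivery_dx.get(c, "unlabeled")
        for c in codes
        if c in code_sets.delivery_dx
    }
    labels &= set(LABELS)
    if not labels:
        return UNDETERMINED
    return max(labels, key=LABEL_PRIORITY.__getitem__)


def label_from_ega(observations: Sequence[tuple[int, float]]) -> str:
    """Outcome label from the most recent EGA observation of an episode.

    ``observations`` is a sequence of (day, ega_weeks). Bands: < 37 weeks
    preterm, [37, 42) term, >= 42 weeks postterm. Empty -> undetermined.
    """
    if len(observations) == 0:
        return UNDETERMINED
    day, ega = max(observations, key=lambda o: o[0])
    if ega < 0:
        raise DataError(f"negative EGA value {ega!r} at day {day!r}")
    if ega < 37.0:
        return PRETERM
    if ega < 42.0:
        return TERM
    return POSTTERM


def consensus_label(code_label: str, ega_label: str) -> str:
    """Resolve code- and EGA-based labels: oldest classification wins.

    Priority postterm > term > preterm; undetermined inputs are ignored, and
    two undetermined inputs yield undetermined.
    """
    cands = [l for l in (code_label, ega_label) if l in LABEL_PRIORITY]
    if not cands:
        return UNDETERMINED
    return max(cands, key=LABEL_PRIORITY.__getitem__)


def approximate_delivery_date(member_days: Sequence[int]) -> int:
    """Most recent timestamp across the episode's delivery-DX, delivery-PX,
    and EGA events approximates the delivery date."""
    if len(member_days) == 0:
        raise ValueError("episode has no member events")
    return int(np.max(member_days))


def derive_conception_date(
    delivery_day: int, ega_observations: Sequence[tuple[int, float]]
) -> int | None:
    """Conception = delivery minus EGA, using an EGA recorded within 3 days
    of delivery (closest observation; ties resolved to the latest).

    EGA weeks are converted to days with half-up rounding. Returns ``None``
    when no sufficiently close observation exists.
    """
    close = [
        (abs(day - delivery_day), -day, ega)
        for day, ega in ega_observations
        if abs(day - delivery_day) <= 3
    ]
    if not close:
        return None
    _, _, ega = min(close)
    return int(delivery_day - math.floor(ega * 7.0 + 0.5))


# ---------------------------------------------------------------------------
# cohort phenotyping
# ---------------------------------------------------------------------------

EPISODE_COLUMNS = [
    "patient_id", "episode_index", "delivery_day", "label", "label_source",
    "code_label", "ega_label", "conception_day", "multiple_gestation",
    "is_earliest", "n_delivery_dx", "n_delivery_px", "n_ega",
]


def _reject_malformed(df: pd.DataFrame, required: dict[str, str], name: str) -> pd.DataFrame:
    """Drop rows with missing/non-finite required fields, logging the count."""
    mask = np.ones(len(df), dtype=bool)
    for col in required:
        mask &= df[col].notna().to_numpy()
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed row(s)", name, n_bad)
    return df[mask]


def phenotype_cohort(
    code_events: pd.DataFrame,
    ega: pd.DataFrame | None,
    code_sets: AscertainmentCodeSets,
    *,
    labeler: str = "consensus",
) -> pd.DataFrame:
    """Run the full phenotyping algorithm over a cohort's event tables.

    Delivery-DX and delivery-PX events seed episodes jointly; EGA
    observations attach to the episode whose backward 37-week window
    (extended by a 3-day post-anchor grace) contains them, and otherwise
    seed episodes of their own. Each episode
    gets a label (per ``labeler``), an approximate delivery date, a
    conception date when derivable, and a multiple-gestation flag scoped to
    codes falling inside its window. Each patient's earliest episode is
    marked.

    Parameters
    ----------
    labeler : {"consensus", "codes_only", "ega_within_3d"}
        ``consensus`` (default) pools code- and EGA-based labels;
        ``codes_only`` ignores EGA labels; ``ega_within_3d`` is the simpler
        comparator that labels solely from an EGA recorded within 3 days of
        delivery.
    """
    if labeler not in ("consensus", "codes_only", "ega_within_3d"):
        raise ValueError(f"unknown labeler {labeler!r}")
    code_events = _reject_malformed(
        code_events, {"patient_id": "", "code": "", "day": ""}, "code_events"
    )
    if ega is None:
        ega = pd.DataFrame(columns=["patient_id", "day", "ega_weeks"])
    ega = _reject_malformed(ega, {"patient_id": "", "day": "", "ega_weeks": ""}, "ega")
    if (ega["ega_weeks"] < 0).any():
        raise DataError("negative EGA values present")

    dx_map = code_sets.delivery_dx
    is_dx = code_events["code"].isin(set(dx_map)).to_numpy()
    is_px = code_events["code"].isin(code_sets.delivery_px).to_numpy()
    is_multi = code_events["code"].isin(code_sets.multiple_gestation).to_numpy()
    deliv = code_events[is_dx | is_px]
    multi_events = code_events[is_multi]

    rows: list[dict] = []
    patients = set(deliv["patient_id"]) | set(ega["patient_id"])
    deliv_by_pat = dict(tuple(deliv.groupby("patient_id", sort=False)))
    ega_by_pat = dict(tuple(ega.groupby("patient_id", sort=False)))
    multi_by_pat = dict(tuple(multi_events.groupby("patient_id", sort=False)))

    for pat in sorted(patients):
        pdeliv = deliv_by_pat.get(pat)
        pega = ega_by_pat.get(pat)
        d_days = pdeliv["day"].to_numpy(np.int64) if pdeliv is not None else np.array([], np.int64)
        d_codes = pdeliv["code"].to_numpy(object) if pdeliv is not None else np.array([], object)
        d_isdx = np.isin(d_codes, list(dx_map)) if len(d_codes) else np.array([], bool)
        e_days = pega["day"].to_numpy(np.int64) if pega is not None else np.array([], np.int64)
        e_vals = pega["ega_weeks"].to_numpy(float) if pega is not None else np.array([], float)

        assign = demarcate_episodes(d_days)
        # window (anchor-259, anchor] per code-seeded episode
        anchors = {
            int(ep): int(d_days[assign == ep].max()) for ep in np.unique(assign) if ep > 0
        }
        # attach EGA observations to containing windows; leftovers seed episodes
        e_assign = np.zeros(len(e_days), dtype=np.int64)
        for i, day in enumerate(e_days):
            for ep, anchor in anchors.items():
                if anchor - EPISODE_WINDOW_DAYS < day <= anchor + EGA_ATTACH_GRACE_DAYS:
                    e_assign[i] = ep
                    break
        leftover = e_assign == 0
        if leftover.any():
            extra = demarcate_episodes(e_days[leftover])
            e_assign[leftover] = extra + (max(anchors) if anchors else 0)

        all_eps = sorted(set(anchors) | set(int(x) for x in np.unique(e_assign) if x > 0))
        # order episodes by delivery day and re-index oldest-first
        ep_delivery = {}
        for ep in all_eps:
            days = np.concatenate([d_days[assign == ep], e_days[e_assign == ep]])
            ep_delivery[ep] = approximate_delivery_date(days)
        order = sorted(all_eps, key=ep_delivery.__getitem__)

        m_days = (
            multi_by_pat[pat]["day"].to_numpy(np.int64)
            if pat in multi_by_pat
            else np.array([], np.int64)
        )
        for new_idx, ep in enumerate(order, start=1):
            delivery_day = ep_delivery[ep]
            ep_dx = d_codes[(assign == ep) & d_isdx]
            ep_obs = list(zip(e_days[e_assign == ep].tolist(), e_vals[e_assign == ep].tolist()))
            code_label = label_from_delivery_codes(ep_dx, code_sets)
            ega_label = label_from_ega(ep_obs)
            close_obs = [(d, v) for d, v in ep_obs if abs(d - delivery_day) <= 3]
            if labeler == "consensus":
                label = consensus_label(code_label, ega_label)
            elif labeler == "codes_only":
                label = code_label
            else:  # ega_within_3d comparator
                label = label_from_ega(close_obs)
            if code_label != UNDETERMINED and ega_label != UNDETERMINED:
                source = "consensus"
            elif code_label != UNDETERMINED:
                source = "codes"
            elif ega_label != UNDETERMINED:
                source = "ega"
            else:
                source = "none"
            in_window = (m_days > delivery_day - EPISODE_WINDOW_DAYS) & (m_days <= delivery_day)
            rows.append(
                dict(
                    patient_id=pat,
                    episode_index=new_idx,
                    delivery_day=delivery_day,
                    label=label,
                    label_source=source,
                    code_label=code_label,
                    ega_label=ega_label,
                    conception_day=derive_conception_date(delivery_day, ep_obs),
                    multiple_gestation=bool(in_window.any()),
                    is_earliest=new_idx == 1,
                    n_delivery_dx=int(((assign == ep) & d_isdx).sum()),
                    n_delivery_px=int(((assign == ep) & ~d_isdx).sum()),
                    n_ega=len(ep_obs),
                )
            )

    out = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    if len(out):
        out = out.sort_values(["patient_id", "episode_index"]).reset_index(drop=True)
        out["conception_day"] = out["conception_day"].astype("Float64")
    return out


def flag_multiple_gestation(
    episodes: pd.DataFrame, code_events: pd.DataFrame, code_sets: AscertainmentCodeSets
) -> pd.Series:
    """Re-derive the per-episode multiple-gestation flag from raw events.

    A code flags only the episode whose backward 37-week window contains it,
    so an earlier twin pregnancy does not exclude a later singleton one.
    """
    multi = code_events[code_events["code"].isin(code_sets.multiple_gestation)]
    by_pat = dict(tuple(multi.groupby("patient_id", sort=False)))
    flags = []
    for _, row in episodes.iterrows():
        m = by_pat.get(row["patient_id"])
        if m is None:
            flags.append(False)
            continue
        days = m["day"].to_numpy(np.int64)
        d = row["delivery_day"]
        flags.append(bool(((days > d - EPISODE_WINDOW_DAYS) & (days <= d)).any()))
    return pd.Series(flags, index=episodes.index, name="multiple_gestation")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Binary preterm-vs-not confusion counts with precision and recall."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return self.tp / (self.tp + self.fn)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        p = "n/a" if self.precision is None else f"{self.precision:.3f}"
        return (
            f"ValidationReport(tp={self.tp}, fp={self.fp}, fn={self.fn}, "
            f"tn={self.tn}, precision={p}, recall={self.recall:.3f})"
        )


def validate_against_gold(
    predicted: pd.Series, gold: pd.Series
) -> ValidationReport:
    """Compare predicted episode labels with gold labels, preterm vs not.

    Both series must share an index (e.g. patient id); a mismatch is an
    error rather than a silent intersection.
    """
    if set(predicted.index) != set(gold.index):
        raise ValueError("predicted and gold label indices differ")
    gold = gold.loc[predicted.index]
    pred_pos = (predicted == PRETERM).to_numpy()
    gold_pos = (gold == PRETERM).to_numpy()
    return ValidationReport(
        tp=int((pred_pos & gold_pos).sum()),
        fp=int((pred_pos & ~gold_pos).sum()),
        fn=int((~pred_pos & gold_pos).sum()),
        tn=int((~pred_pos & ~gold_pos).sum()),
    )
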