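"""Time-anchored cohorts and feature matrices for outcome prediction.

Feature rows are (patient, episode) pairs; every code-count cell derives
exclusively from events timestamped *strictly before* the row's anchor day,
and every code used to ascertain delivery type or date is dropped from the
column space entirely. Both guards protect against outcome leakage and are
asserted programmatically by :func:`check_leakage`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gravida.phenotype import AscertainmentCodeSets, EPISODE_WINDOW_DAYS, PRETERM, UNDETERMINED

logger = logging.getLogger(__name__)

ROW_KEYS = ["patient_id", "episode_index"]

RISK_FACTOR_NAMES = (
    "race_high_risk",
    "age_extreme",
    "nongestational_diabetes",
    "gestational_diabetes",
    "sickle_cell",
    "fetal_abnormalities",
    "prepregnancy_bmi_ge_35",
    "prepregnancy_hypertension",
    "gestational_hypertension",
    "preeclampsia",
    "eclampsia",
    "cervical_abnormalities",
)

HIGH_RISK_RACES = frozenset({"Black", "Asian", "Hispanic"})

#: Days in the "9 months before delivery" pre-pregnancy window.
PREPREGNANCY_WINDOW_DAYS = 270


@dataclass
class FeatureMatrix:
    """Deliveries-by-features design matrix with anchor metadata.

    Attributes
    ----------
    X : pandas.DataFrame
        Feature values indexed by (patient_id, episode_index); code columns
        hold non-negative integer counts.
    y : pandas.Series
        Binary outcome aligned to ``X`` (preterm = 1).
    anchors : pandas.Series
        Anchor day per row; no contributing event may be on or after it.
    excluded_codes : frozenset
        Manifest of ascertainment codes barred from the column space.
    """

    X: pd.DataFrame
    y: pd.Series
    anchors: pd.Series
    excluded_codes: frozenset = frozenset()

    def __post_init__(self):
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.anchors.index)):
            raise ValueError("X, y and anchors must share an index")
        bad = set(self.X.columns) & set(self.excluded_codes)
        if bad:
            raise ValueError(f"excluded codes present as columns: {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())

    def subset(self, index) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.loc[index], self.y.loc[index], self.anchors.loc[index], self.excluded_codes
        )

    def align_to(self, columns: Sequence[str]) -> "FeatureMatrix":
        """Re-featurize against another site's column vocabulary: unseen
        codes are dropped, missing codes zero-filled."""
        X = self.X.reindex(columns=list(columns), fill_value=0)
        return FeatureMatrix(X, self.y, self.anchors, self.excluded_codes)

    # -- sparse-triplet serialization -----------------------------------
    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stacked = self.X.stack()
        stacked = stacked[stacked != 0]
        trip = stacked.rename_axis(ROW_KEYS + ["feature"]).rename("value").reset_index()
        trip.to_csv(outdir / "features_triplets.csv", index=False)
        meta = pd.DataFrame(
            {"anchor_day": self.anchors, "outcome": self.y}
        ).reset_index()
        meta.to_csv(outdir / "rows.csv", index=False)
        pd.Series(sorted(self.X.columns), name="feature").to_csv(
            outdir / "columns.csv", index=False
        )
        pd.Series(sorted(self.excluded_codes), name="code").to_csv(
            outdir / "excluded_codes.csv", index=False
        )

    @classmethod
    def read_csv(cls, indir: str | Path) -> "FeatureMatrix":
        indir = Path(indir)
        meta = pd.read_csv(indir / "rows.csv").set_index(ROW_KEYS)
        cols = pd.read_csv(indir / "columns.csv")["feature"].tolist()
        trip = pd.read_csv(indir / "features_triplets.csv")
        X = (
            trip.pivot_table(
                index=ROW_KEYS, columns="feature", values="value", fill_value=0, aggfunc="sum"
            )
            .reindex(index=meta.index, columns=cols, fill_value=0)
        )
        excluded = pd.read_csv(indir / "excluded_codes.csv")
        return cls(
            X,
            meta["outcome"].rename("outcome"),
            meta["anchor_day"].rename("anchor_day"),
            frozenset(excluded["code"].tolist()) if len(excluded) else frozenset(),
        )


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """How to anchor and filter a prediction cohort."""

    anchor_kind: str  # "conception_plus_weeks" | "delivery_minus_days"
    offset: int  # weeks or days per anchor_kind
    require_conception: bool = True
    exclude_multiple_gestation: bool = True
    exclude_delivered_before_anchor: bool = True

    def __post_init__(self):
        if self.anchor_kind not in ("conception_plus_weeks", "delivery_minus_days"):
            raise ValueError(f"unknown anchor_kind {self.anchor_kind!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.anchor_kind == "conception_plus_weeks" and not self.require_conception:
            raise ValueError("conception anchors require require_conception=True")


def _labeled(episodes: pd.DataFrame) -> pd.DataFrame:
    return episodes[episodes["label"] != UNDETERMINED]


def build_gestational_cohort(
    episodes: pd.DataFrame,
    weeks: int,
    *,
    earliest_only: bool = True,
    exclude_multiple_gestation: bool = True,
) -> pd.DataFrame:
    """Cohort anchored at ``conception + 7 * weeks`` days of gestation.

    Keeps episodes with a derived conception date whose delivery did not
    precede the anchor (women already delivered are excluded at each time
    point). Returns episode rows with an ``anchor_day`` column.
    """
    if weeks < 0:
        raise ValueError("weeks must be >= 0")
    df = _labeled(episodes)
    if earliest_only:
        df = df[df["is_earliest"]]
    if exclude_multiple_gestation:
        df = df[~df["multiple_gestation"]]
    df = df[df["conception_day"].notna()].copy()
    df["anchor_day"] = (df["conception_day"].astype(np.int64) + 7 * weeks).astype(np.int64)
    df = df[df["delivery_day"] >= df["anchor_day"]]
    return df.reset_index(drop=True)


def build_predelivery_cohort(
    episodes: pd.DataFrame,
    days: int,
    *,
    earliest_only: bool = False,
    exclude_multiple_gestation: bool = True,
) -> pd.DataFrame:
    """Cohort anchored at ``delivery_day - days``; no conception needed."""
    if days < 0:
        raise ValueError("days must be >= 0")
    df = _labeled(episodes)
    if earliest_only:
        df = df[df["is_earliest"]]
    if exclude_multiple_gestation:
        df = df[~df["multiple_gestation"]]
    df = df.copy()
    df["anchor_day"] = (df["delivery_day"] - days).astype(np.int64)
    return df.reset_index(drop=True)


def downsample_to_match(
    cohorts: Sequence[pd.DataFrame], seed: int
) -> list[pd.DataFrame]:
    """Uniform seeded subsampling of each cohort to the smallest size.

    Used when comparing models across gestational time points so sample
    size is not a confounder.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to match")
    sizes = [len(c) for c in cohorts]
    if min(sizes) == 0:
        raise ValueError("cannot downsample an empty cohort")
    target = min(sizes)
    rng = np.random.default_rng(seed)
    out = []
    for c in cohorts:
        idx = np.sort(rng.choice(len(c), size=target, replace=False))
        out.append(c.iloc[idx].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def _row_index(cohort: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(cohort[ROW_KEYS])


def _pre_anchor_events(
    code_events: pd.DataFrame, cohort: pd.DataFrame, excluded: frozenset
) -> pd.DataFrame:
    """Per-row pre-anchor events (day strictly < anchor), excluded codes gone."""
    ev = code_events[~code_events["code"].isin(excluded)]
    merged = cohort[ROW_KEYS + ["anchor_day"]].merge(ev, on="patient_id", how="left")
    return merged[merged["day"] < merged["anchor_day"]]


def build_code_count_matrix(
    code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    code_sets: AscertainmentCodeSets | frozenset,
) -> FeatureMatrix:
    """Counts of each billing code strictly before the row's anchor day.

    Ascertainment codes are removed from the column space entirely; rows
    with no prior events get all-zero feature vectors (a woman with no
    billing history is encoded as zeros, not dropped).
    """
    excluded = (
        code_sets.all_codes if isinstance(code_sets, AscertainmentCodeSets) else frozenset(code_sets)
    )
    rows = _row_index(cohort)
    kept = _pre_anchor_events(code_events, cohort, excluded)
    if len(kept):
        counts = (
            kept.groupby(ROW_KEYS + ["code"], sort=True).size().rename("n").reset_index()
        )
        X = (
            counts.pivot_table(
                index=ROW_KEYS, columns="code", values="n", fill_value=0, aggfunc="sum"
            )
            .reindex(rows, fill_value=0)
            .astype(np.int64)
        )
        X = X[sorted(X.columns)]
    else:
        X = pd.DataFrame(index=rows)
    y = pd.Series(
        (cohort["label"] == PRETERM).astype(int).to_numpy(), index=rows, name="outcome"
    )
    anchors = pd.Series(cohort["anchor_day"].to_numpy(), index=rows, name="anchor_day")
    return FeatureMatrix(X, y, anchors, excluded)


def total_code_count_feature(
    code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    code_sets: AscertainmentCodeSets | frozenset,
) -> FeatureMatrix:
    """Single-column comparator: total pre-anchor code count per row.

    Probes whether sheer contact with the health system (utilization alone)
    predicts the outcome.
    """
    fm = build_code_count_matrix(code_events, cohort, code_sets)
    X = pd.DataFrame({"total_code_count": fm.X.sum(axis=1).astype(np.int64)}, index=fm.X.index)
    return FeatureMatrix(X, fm.y, fm.anchors, fm.excluded_codes)


def check_leakage(
    fm: FeatureMatrix, code_events: pd.DataFrame
) -> None:
    """Assert the two leakage guards on a built matrix.

    Raises ``AssertionError`` if an excluded code survives as a column or
    if any cell count exceeds the pre-anchor event count for its row.
    """
    assert not (set(fm.X.columns) & set(fm.excluded_codes)), "ascertainment code leaked into columns"
    ev = code_events.merge(
        pd.DataFrame({"anchor_day": fm.anchors}).reset_index(), on="patient_id"
    )
    pre = ev[ev["day"] < ev["anchor_day"]]
    pre_counts = pre.groupby(ROW_KEYS + ["code"]).size()
    cells = fm.X.stack()
    cells = cells[cells > 0]
    for (pat, epi, code), v in cells.items():
        assert v <= pre_counts.get((pat, epi, code), 0), (
            f"cell ({pat}, {epi}, {code}) = {v} exceeds pre-anchor event count"
        )


# ---------------------------------------------------------------------------
# risk factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskFactorProfile:
    """The 12 binary obstetric risk-factor indicators for one delivery."""

    flags: Mapping[str, int]

    def __post_init__(self):
        missing = set(RISK_FACTOR_NAMES) - set(self.flags)
        if missing:
            raise ValueError(f"missing risk-factor flags: {sorted(missing)}")
        object.__setattr__(self, "flags", {k: int(self.flags[k]) for k in RISK_FACTOR_NAMES})

    @property
    def count(self) -> int:
        return int(sum(self.flags.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.flags, name="risk_factor")


def default_risk_factor_codes() -> dict[str, frozenset]:
    """Map the code-ascertainable factors to the generator's code families."""
    from gravida.simulate import default_risk_factors

    return {
        f.name: frozenset(f.codes)
        for f in default_risk_factors()
        if f.name in RISK_FACTOR_NAMES
    }


def encode_risk_factors_cohort(
    demographics: pd.DataFrame,
    code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    factor_codes: Mapping[str, frozenset] | None = None,
    measurements: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Encode the 12 binary risk factors for every cohort row.

    Code-based factors are 1 iff at least one matching code occurs strictly
    before the delivery day. Age is extreme when > 34 or < 18 years. BMI and
    blood pressure use the pre-pregnancy value: the most recent measurement
    more than 9 months (270 days) before delivery when a ``measurements``
    table (patient_id, kind, day, value) is given, else the static
    demographics columns. Missing demographics yield 0 with a logged
    warning.
    """
    if factor_codes is None:
        factor_codes = default_risk_factor_codes()
    rows = _row_index(cohort)
    out = pd.DataFrame(0, index=rows, columns=list(RISK_FACTOR_NAMES), dtype=np.int64)

    # code-based factors: >= 1 matching code before delivery
    merged = cohort[ROW_KEYS + ["delivery_day"]].merge(code_events, on="patient_id")
    pre = merged[merged["day"] < merged["delivery_day"]]
    for name, codes in factor_codes.items():
        if name not in out.columns:
            continue
        hits = pre[pre["code"].isin(codes)]
        if len(hits):
            idx = pd.MultiIndex.from_frame(hits[ROW_KEYS].drop_duplicates())
            out.loc[out.index.isin(idx), name] = 1

    demo = demographics.set_index("patient_id")
    pat = cohort["patient_id"]
    missing = ~pat.isin(demo.index)
    if missing.any():
        logger.warning(
            "encode_risk_factors: %d row(s) missing demographics; factors set to 0",
            int(missing.sum()),
        )

    def _demo_col(col):
        return pat.map(demo[col]) if col in demo.columns else pd.Series(np.nan, index=pat.index)

    race = _demo_col("race")
    out["race_high_risk"] = race.isin(HIGH_RISK_RACES).astype(int).to_numpy()
    age = pd.to_numeric(_demo_col("age_at_first_delivery"), errors="coerce")
    out["age_extreme"] = (((age > 34) | (age < 18)).fillna(False)).astype(int).to_numpy()

    def _prepreg_value(kind: str, static_col: str) -> np.ndarray:
        if measurements is not None and (measurements["kind"] == kind).any():
            m = cohort[ROW_KEYS + ["delivery_day"]].merge(
                measurements[measurements["kind"] == kind], on="patient_id"
            )
            m = m[m["day"] < m["delivery_day"] - PREPREGNANCY_WINDOW_DAYS]
            latest = (
                m.sort_values("day").groupby(ROW_KEYS)["value"].last()
                if len(m)
                else pd.Series(dtype=float)
            )
            return latest.reindex(rows).to_numpy()
        return pd.to_numeric(_demo_col(static_col), errors="coerce").to_numpy()

    bmi = _prepreg_value("bmi", "prepregnancy_bmi")
    out["prepregnancy_bmi_ge_35"] = (np.nan_to_num(bmi, nan=0.0) >= 35).astype(int)
    sbp = _prepreg_value("sbp", "prepregnancy_sbp")
    dbp = _prepreg_value("dbp", "prepregnancy_dbp")
    bp_high = (np.nan_to_num(sbp, nan=0.0) > 120) | (np.nan_to_num(dbp, nan=0.0) > 80)
    # a code-based hypertension hit also counts; keep the max of the two routes
    out["prepregnancy_hypertension"] = np.maximum(
        out["prepregnancy_hypertension"].to_numpy(), bp_high.astype(int)
    )
    return out


def encode_risk_factors(
    demographics: pd.DataFrame,
    code_events: pd.DataFrame,
    episode: pd.Series | Mapping,
    factor_codes: Mapping[str, frozenset] | None = None,
    measurements: pd.DataFrame | None = None,
) -> RiskFactorProfile:
    """Risk-factor profile for a single phenotyped episode."""
    cohort = pd.DataFrame([
        {
            "patient_id": episode["patient_id"],
            "episode_index": episode["episode_index"],
            "delivery_day": episode["delivery_day"],
        }
    ])
    df = encode_risk_factors_cohort(
        demographics, code_events, cohort, factor_codes, measurements
    )
    return RiskFactorProfile(df.iloc[0].to_dict())


def risk_factor_matrix(
    demographics: pd.DataFrame,
    code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    factor_codes: Mapping[str, frozenset] | None = None,
) -> FeatureMatrix:
    """The 12 binary indicators packaged as a model-ready feature matrix."""
    X = encode_risk_factors_cohort(demographics, code_events, cohort, factor_codes)
    rows = _row_index(cohort)
    y = pd.Series((cohort["label"] == PRETERM).astype(int).to_numpy(), index=rows, name="outcome")
    anchor_col = "anchor_day" if "anchor_day" in cohort.columns else "delivery_day"
    anchors = pd.Series(cohort[anchor_col].to_numpy(), index=rows, name="anchor_day")
    return FeatureMatrix(X, y, anchors, frozenset())


# ---------------------------------------------------------------------------
# labs, PRS
# ---------------------------------------------------------------------------

def aggregate_labs(
    lab_events: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    sd_cutoff: float = 4.0,
    per_episode_outliers: bool = False,
) -> pd.DataFrame:
    """Per-(row, lab) summary of in-pregnancy measurements after outlier
    exclusion.

    Measurements within [conception_day, delivery_day] enter; values more
    than ``sd_cutoff`` standard deviations from the mean are excluded
    before summarizing. By default the mean/SD are computed per lab over
    the whole cohort's in-window values; ``per_episode_outliers=True``
    switches to per-episode statistics. Returns columns mean, median, min,
    max, n_used, n_excluded; a lab with zero in-window measurements for an
    episode is simply absent.
    """
    if cohort["conception_day"].isna().any():
        raise ValueError("aggregate_labs requires conception_day for every cohort row")
    win = cohort[ROW_KEYS + ["conception_day", "delivery_day"]].merge(
        lab_events, on="patient_id"
    )
    win = win[(win["day"] >= win["conception_day"]) & (win["day"] <= win["delivery_day"])]
    if not len(win):
        return pd.DataFrame(
            columns=ROW_KEYS + ["lab", "mean", "median", "min", "max", "n_used", "n_excluded"]
        )
    group_keys = ROW_KEYS + ["lab"] if per_episode_outliers else ["lab"]
    stats = win.groupby(group_keys)["value"].agg(["mean", "std"]).rename(
        columns={"mean": "_m", "std": "_s"}
    )
    win = win.join(stats, on=group_keys)
    sd = win["_s"].fillna(0.0)
    keep = (sd == 0) | ((win["value"] - win["_m"]).abs() <= sd_cutoff * sd)
    survivors = win[keep]
    out = (
        survivors.groupby(ROW_KEYS + ["lab"])["value"]
        .agg(["mean", "median", "min", "max", "count"])
        .rename(columns={"count": "n_used"})
    )
    raw = win.groupby(ROW_KEYS + ["lab"]).size().rename("n_raw")
    out = out.join(raw)
    out["n_excluded"] = (out["n_raw"] - out["n_used"]).astype(int)
    return out.drop(columns="n_raw").reset_index()


def lab_feature_matrix(summaries: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot lab summaries to wide ``{lab}_{stat}`` columns (NaN = missing)."""
    rows = _row_index(cohort)
    if not len(summaries):
        return pd.DataFrame(index=rows)
    wide = summaries.pivot_table(
        index=ROW_KEYS, columns="lab", values=["mean", "median", "min", "max"]
    )
    wide.columns = [f"{lab}_{stat}" for stat, lab in wide.columns]
    return wide.reindex(rows)


def additive_prs(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    p_threshold: float = 1.0,
) -> pd.Series:
    """Additive polygenic score: sum of dosage x effect size over variants
    with association p-value below ``p_threshold``.

    Variants in the weight table absent from the genotype matrix are
    skipped with a logged count.
    """
    sel = weights[weights["p_value"] < p_threshold]
    present = sel[sel["variant"].isin(genotypes.columns)]
    n_missing = len(sel) - len(present)
    if n_missing:
        logger.warning("additive_prs: %d weighted variant(s) missing from genotypes", n_missing)
    pid = genotypes["patient_id"]
    if not len(present):
        return pd.Series(0.0, index=pid.to_numpy(), name="prs")
    dos = genotypes[present["variant"].tolist()].to_numpy(dtype=float)
    score = dos @ present["effect_size"].to_numpy(dtype=float)
    return pd.Series(score, index=pid.to_numpy(), name="prs")


# ---------------------------------------------------------------------------
# clinical sub-cohorts
# ---------------------------------------------------------------------------

def identify_spontaneous(
    preterm_rows: pd.DataFrame,
    code_events: pd.DataFrame,
    code_sets: AscertainmentCodeSets,
) -> pd.Series:
    """Flag spontaneous preterm deliveries among preterm episode rows.

    Spontaneous = no medically-induced-labor, cesarean, or PPROM code in
    the episode (codes within the backward 37-week window, allowing up to
    10 days after delivery for delivery-attached coding). Rows must all be
    preterm; anything else violates the contract.
    """
    if (preterm_rows["label"] != PRETERM).any():
        raise ValueError("identify_spontaneous expects only preterm rows")
    excl_codes = code_sets.induced_labor | code_sets.cesarean | code_sets.pprom
    ev = code_events[code_events["code"].isin(excl_codes)]
    by_pat = dict(tuple(ev.groupby("patient_id", sort=False)))
    flags = []
    for _, row in preterm_rows.iterrows():
        e = by_pat.get(row["patient_id"])
        if e is None:
            flags.append(True)
            continue
        days = e["day"].to_numpy(np.int64)
        d = row["delivery_day"]
        hit = ((days > d - EPISODE_WINDOW_DAYS) & (days <= d + 10)).any()
        flags.append(not bool(hit))
    return pd.Series(flags, index=preterm_rows.index, name="spontaneous")


def build_recurrent_cohort(episodes: pd.DataFrame) -> pd.DataFrame:
    """Second deliveries of women whose first delivery was preterm.

    Rows are episode-2 records with a determined label; the outcome is the
    second delivery's label.
    """
    first = episodes[episodes["episode_index"] == 1]
    preterm_first = set(first.loc[first["label"] == PRETERM, "patient_id"])
    second = episodes[
        (episodes["episode_index"] == 2)
        & episodes["patient_id"].isin(preterm_first)
        & (episodes["label"] != UNDETERMINED)
    ]
    return second.reset_index(drop=True)


def classify_delivery_mode(
    episodes: pd.DataFrame,
    code_events: pd.DataFrame,
    code_sets: AscertainmentCodeSets,
    *,
    window_days: int = 10,
) -> pd.Series:
    """Cesarean vs vaginal by code families within 10 days of delivery.

    Both families present -> ``excluded``; neither -> ``unclassified``.
    """
    ces = code_events[code_events["code"].isin(code_sets.cesarean)]
    vag = code_events[code_events["code"].isin(code_sets.vaginal)]
    ces_by = dict(tuple(ces.groupby("patient_id", sort=False)))
    vag_by = dict(tuple(vag.groupby("patient_id", sort=False)))

    def _near(df, pat, day):
        e = df.get(pat)
        if e is None:
            return False
        return bool((np.abs(e["day"].to_numpy(np.int64) - day) <= window_days).any())

    out = []
    for _, row in episodes.iterrows():
        has_c = _near(ces_by, row["patient_id"], row["delivery_day"])
        has_v = _near(vag_by, row["patient_id"], row["delivery_day"])
        if has_c and has_v:
            out.append("excluded")
        elif has_c:
            out.append("cesarean")
        elif has_v:
            out.append("vaginal")
        else:
            out.append("unclassified")
    return pd.Series(out, index=episodes.index, name="delivery_mode")
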