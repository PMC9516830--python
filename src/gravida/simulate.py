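"""Seeded synthetic-EHR generator with known pregnancy ground truth.

Emulates the statistical structure a billing-code preterm-birth analysis
relies on: per-patient visit streams that emit diagnosis/procedure codes,
delivery-specific codes at an outcome-dependent delivery date, estimated
gestational age (EGA) observations near delivery with configurable
availability and error, binary clinical risk factors with logistic effects
on preterm probability, recurrence elevation for second pregnancies, and
mode-of-delivery / spontaneous-subtype labels.

Time is an integer day index from an arbitrary origin; gestational weeks are
days / 7 and all thresholds live in days (37 wk = 259 d, 42 wk = 294 d).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

PRETERM = "preterm"
TERM = "term"
POSTTERM = "postterm"
UNDETERMINED = "undetermined"

PRETERM_MAX_DAYS = 259  # < 37 completed weeks
POSTTERM_MIN_DAYS = 294  # >= 42 weeks

#: Default ascertainment vocabulary. Delivery-type diagnosis codes carry an
#: implied outcome label; procedure codes are unlabeled.
DELIVERY_DX_CODES: dict[str, tuple[str, ...]] = {
    PRETERM: ("DDX.PRE.1", "DDX.PRE.2"),
    TERM: ("DDX.TERM.1", "DDX.TERM.2"),
    POSTTERM: ("DDX.POST.1",),
}
DELIVERY_PX_CODES: tuple[str, ...] = ("DPX.DELIV.1", "DPX.DELIV.2")
MULTI_GEST_CODES: tuple[str, ...] = ("DDX.MULTI.1",)
CESAREAN_CODES: tuple[str, ...] = ("DPX.CSEC.1",)
VAGINAL_CODES: tuple[str, ...] = ("DPX.VAG.1",)
INDUCED_CODES: tuple[str, ...] = ("DDX.INDUCE.1",)
PPROM_CODES: tuple[str, ...] = ("DDX.PPROM.1",)

_PX_PREFIX = "DPX"

RACES = ("White", "Black", "Hispanic", "Asian", "Other")
RACE_PROBS = (0.60, 0.18, 0.11, 0.06, 0.05)


class ConfigurationError(ValueError):
    """Raised when a :class:`SimulationConfig` field is invalid."""


@dataclass(frozen=True)
class RiskFactor:
    """A binary clinical risk factor with a logistic effect on preterm odds.

    Parameters
    ----------
    name : str
        Factor identifier (e.g. ``"preeclampsia"``).
    prevalence : float
        Population prevalence in [0, 1]; factors are drawn independently
        Bernoulli(prevalence) per patient.
    log_odds : float
        Additive effect on the preterm log-odds when the factor is active.
    code_rate : float
        Per-visit Poisson rate of dedicated-code emission when active.
    codes : tuple of str
        Dedicated code identifiers, disjoint from all other vocabularies.
    gestational_only : bool
        If true, the condition manifests during pregnancy only: its codes
        are emitted at pregnancy visits but never at background
        (pre-conception) visits.
    """

    name: str
    prevalence: float
    log_odds: float
    code_rate: float = 0.6
    codes: tuple[str, ...] = ()
    gestational_only: bool = False

    def __post_init__(self):
        if not self.codes:
            object.__setattr__(
                self, "codes", tuple(f"RF.{self.name.upper()}.{i}" for i in (1, 2, 3))
            )


@dataclass(frozen=True)
class LabSpec:
    """A clinical lab with a healthy distribution and a risk-factor shift."""

    name: str
    mean: float
    sd: float
    shift_factor: str | None = None
    shift: float = 0.0
    per_pregnancy_rate: float = 3.0  # expected measurements per pregnancy


@dataclass(frozen=True)
class GenotypeSpec:
    """Synthetic genotype panel: dosages in {0,1,2} plus a weight table."""

    n_variants: int = 50
    n_causal: int = 5
    effect_sizes: tuple[float, ...] | None = None
    allele_freqs: tuple[float, ...] | None = None


_PROB_FIELDS = (
    "postterm_rate",
    "delivery_code_mislabel_rate",
    "ega_availability",
    "multiple_gestation_rate",
    "second_pregnancy_rate",
    "spontaneous_fraction",
    "cesarean_rate",
)
_NONNEG_FIELDS = (
    "term_length_sd",
    "visit_rate",
    "background_visit_rate",
    "noise_rate",
    "ega_error_sd",
    "site_shift",
)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Defaults are calibrated to the study conditions the downstream analysis
    assumes: ~13% preterm prevalence, mean term gestation ~39 weeks, ~7.6%
    multiple gestations, and visit-driven code accrual that grows with
    gestational age.
    """

    n_patients: int = 1000
    preterm_base_logit: float = -2.15
    risk_factors: list[RiskFactor] = field(default_factory=list)
    term_length_mean: float = 273.0
    term_length_sd: float = 8.0
    preterm_length_min: int = 175
    preterm_length_max: int = 259  # exclusive
    postterm_rate: float = 0.03
    visit_rate: float = 0.45  # visits per pregnancy week
    background_visit_rate: float = 0.06  # visits per week outside pregnancy
    noise_code_vocab_size: int = 300
    noise_rate: float = 2.0  # codes per visit
    delivery_code_mislabel_rate: float = 0.02
    ega_availability: float = 0.8
    ega_error_sd: float = 3.0  # days
    multiple_gestation_rate: float = 0.076
    recurrence_log_odds: float = 1.0
    second_pregnancy_rate: float = 0.3
    spontaneous_fraction: float = 0.45
    cesarean_rate: float = 0.25
    labs: list[LabSpec] = field(default_factory=list)
    genotypes: GenotypeSpec | None = None
    site_shift: float = 1.0
    site: str = "A"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v!r}")
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients!r}")
        if self.noise_code_vocab_size < 1:
            raise ConfigurationError(
                f"noise_code_vocab_size must be >= 1, got {self.noise_code_vocab_size!r}"
            )
        if not (0 < self.preterm_length_min < self.preterm_length_max):
            raise ConfigurationError(
                "preterm_length_min/max must satisfy 0 < min < max, got "
                f"({self.preterm_length_min!r}, {self.preterm_length_max!r})"
            )
        if self.preterm_length_max > PRETERM_MAX_DAYS:
            raise ConfigurationError(
                f"preterm_length_max must be <= {PRETERM_MAX_DAYS} days (37 weeks)"
            )
        for f in self.risk_factors:
            if not (0.0 <= f.prevalence <= 1.0):
                raise ConfigurationError(
                    f"risk_factors[{f.name}].prevalence must be in [0, 1]"
                )
            if f.code_rate < 0:
                raise ConfigurationError(f"risk_factors[{f.name}].code_rate must be >= 0")
        vocabs = [set(self.noise_vocabulary()), set(self.ascertainment_vocabulary())]
        vocabs += [set(f.codes) for f in self.risk_factors]
        total = sum(len(v) for v in vocabs)
        if len(set().union(*vocabs)) != total:
            raise ConfigurationError(
                "risk_factors/noise vocabularies overlap each other or the "
                "ascertainment codes; code families must be disjoint"
            )

    # -- vocabularies ----------------------------------------------------
    def noise_vocabulary(self) -> list[str]:
        return [f"NZ.{i:04d}" for i in range(self.noise_code_vocab_size)]

    @staticmethod
    def ascertainment_vocabulary() -> list[str]:
        out: list[str] = []
        for codes in DELIVERY_DX_CODES.values():
            out.extend(codes)
        out.extend(DELIVERY_PX_CODES)
        out.extend(MULTI_GEST_CODES)
        out.extend(CESAREAN_CODES)
        out.extend(VAGINAL_CODES)
        out.extend(INDUCED_CODES)
        out.extend(PPROM_CODES)
        return out

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["risk_factors"] = [
            RiskFactor(**{**rf, "codes": tuple(rf.get("codes") or ())})
            for rf in d.get("risk_factors", [])
        ]
        d["labs"] = [LabSpec(**lb) for lb in d.get("labs", [])]
        if d.get("genotypes") is not None:
            g = dict(d["genotypes"])
            for k in ("effect_sizes", "allele_freqs"):
                if g.get(k) is not None:
                    g[k] = tuple(g[k])
            d["genotypes"] = GenotypeSpec(**g)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# prevalence calibration
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def expected_preterm_prevalence(
    base_logit: float, factors: Sequence[RiskFactor], n_mc: int = 200_000, seed: int = 0
) -> float:
    """Closed-form first-pregnancy preterm prevalence under the mixture model.

    Enumerates all 2^k active-factor patterns when k <= 16; falls back to
    Monte Carlo beyond that.
    """
    k = len(factors)
    if k == 0:
        return float(_sigmoid(base_logit))
    if k <= 16:
        patterns = (np.arange(2**k)[:, None] >> np.arange(k)) & 1
        prev = np.array([f.prevalence for f in factors])
        eff = np.array([f.log_odds for f in factors])
        pattern_p = np.prod(np.where(patterns == 1, prev, 1 - prev), axis=1)
        return float(np.sum(pattern_p * _sigmoid(base_logit + patterns @ eff)))
    rng = np.random.default_rng(seed)
    prev = np.array([f.prevalence for f in factors])
    eff = np.array([f.log_odds for f in factors])
    draws = rng.random((n_mc, k)) < prev
    return float(np.mean(_sigmoid(base_logit + draws @ eff)))


def calibrate_base_logit(
    target_prevalence: float, factors: Sequence[RiskFactor]
) -> float:
    """Solve for the intercept giving the target marginal preterm prevalence."""
    from scipy.optimize import brentq

    if not (0 < target_prevalence < 1):
        raise ConfigurationError("target_prevalence must be in (0, 1)")
    f = lambda b: expected_preterm_prevalence(b, factors) - target_prevalence
    return float(brentq(f, -20.0, 20.0, xtol=1e-10))


def default_risk_factors() -> list[RiskFactor]:
    """Coded comorbidities with literature-scale preterm log-odds.

    The first nine are the code-ascertainable entries of the standard
    12-factor clinical risk profile; conditions that arise only in
    pregnancy are marked gestational-only (their codes cannot appear before
    conception). The last four are comorbidities that billing codes capture
    but the 12-factor profile does not — the informational margin of the
    full coding stream over a fixed risk-factor checklist.
    """
    spec = [
        # name, prevalence, log-odds, gestational_only
        ("nongestational_diabetes", 0.040, 0.7, False),
        ("gestational_diabetes", 0.070, 0.35, True),
        ("sickle_cell", 0.010, 1.1, False),
        ("fetal_abnormalities", 0.030, 1.0, True),
        ("prepregnancy_hypertension", 0.050, 0.7, False),
        ("gestational_hypertension", 0.060, 0.9, True),
        ("preeclampsia", 0.040, 1.4, True),
        ("eclampsia", 0.005, 1.6, True),
        ("cervical_abnormalities", 0.010, 1.25, False),
        ("prior_preterm_history", 0.080, 1.4, False),
        ("genitourinary_infection", 0.100, 0.7, False),
        ("anemia", 0.120, 0.5, False),
        ("substance_use", 0.050, 0.9, False),
    ]
    return [RiskFactor(name, p, b, gestational_only=g) for name, p, b, g in spec]


def default_labs() -> list[LabSpec]:
    return [
        LabSpec("hemoglobin", 12.5, 1.0, shift_factor="sickle_cell", shift=-1.5),
        LabSpec("glucose", 90.0, 12.0, shift_factor="gestational_diabetes", shift=25.0),
        LabSpec("crp", 3.0, 2.0, shift_factor="preeclampsia", shift=2.5),
    ]


def default_config(
    site: str = "A",
    n_patients: int = 1000,
    seed: int = 0,
    target_prevalence: float | None = None,
    **overrides,
) -> SimulationConfig:
    """Build the default study conditions for one site.

    Site ``"A"`` targets ~13% first-pregnancy preterm prevalence; site
    ``"B"`` targets ~6% with a 0.8x multiplicative shift on code-emission
    rates, emulating an independent health system sharing the vocabulary.
    """
    site = site.upper()
    if target_prevalence is None:
        target_prevalence = {"A": 0.13, "B": 0.06}.get(site, 0.13)
    factors = overrides.pop("risk_factors", default_risk_factors())
    base = calibrate_base_logit(target_prevalence, factors)
    kw = dict(
        n_patients=n_patients,
        preterm_base_logit=base,
        risk_factors=factors,
        labs=default_labs(),
        genotypes=GenotypeSpec(),
        site=site,
        site_shift=0.8 if site == "B" else 1.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pregnancy:
    index: int  # 1 = earliest
    conception_day: int
    gestational_length: int
    delivery_day: int
    outcome: str
    subtype: str  # spontaneous / induced / cesarean / pprom / n/a
    mode: str  # vaginal / cesarean
    multiple_gestation: bool


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one patient: active risk factors and pregnancies."""

    patient_id: str
    site: str
    risk_factors: frozenset[str]
    pregnancies: tuple[Pregnancy, ...]


def outcome_band(gestational_length: int) -> str:
    """Deterministic outcome from gestational length in days."""
    if gestational_length < PRETERM_MAX_DAYS:
        return PRETERM
    if gestational_length < POSTTERM_MIN_DAYS:
        return TERM
    return POSTTERM


def _draw_gestational_length(preterm: bool, config: SimulationConfig, rng) -> int:
    if preterm:
        return int(rng.integers(config.preterm_length_min, config.preterm_length_max))
    if rng.random() < config.postterm_rate:
        return int(rng.integers(POSTTERM_MIN_DAYS, POSTTERM_MIN_DAYS + 8))
    # truncated normal on [259, 294)
    while True:
        x = rng.normal(config.term_length_mean, config.term_length_sd)
        if PRETERM_MAX_DAYS <= x < POSTTERM_MIN_DAYS:
            return int(round(x))


def _draw_subtype_mode(outcome: str, config: SimulationConfig, rng) -> tuple[str, str]:
    if outcome == PRETERM:
        if rng.random() < config.spontaneous_fraction:
            subtype = "spontaneous"
        else:
            subtype = str(rng.choice(["induced", "cesarean", "pprom"]))
    else:
        subtype = "n/a"
    if subtype == "cesarean":
        mode = "cesarean"
    else:
        mode = "cesarean" if rng.random() < config.cesarean_rate else "vaginal"
    return subtype, mode


def sample_patient_truth(
    config: SimulationConfig, patient_index: int, rng: np.random.Generator
) -> SyntheticTruth:
    """Draw one patient's risk factors and pregnancy ground truth.

    Risk factors are independent Bernoulli(prevalence). Preterm probability
    for the first pregnancy is ``logistic(base_logit + sum of active
    effects)``; a second pregnancy (drawn with ``second_pregnancy_rate``)
    adds ``recurrence_log_odds`` when the first was preterm.
    """
    config.validate()
    active = frozenset(
        f.name for f in config.risk_factors if rng.random() < f.prevalence
    )
    logit = config.preterm_base_logit + sum(
        f.log_odds for f in config.risk_factors if f.name in active
    )
    pregnancies: list[Pregnancy] = []
    conception = int(rng.integers(400, 1500))
    prev_preterm = False
    n_pregs = 2 if rng.random() < config.second_pregnancy_rate else 1
    for idx in range(1, n_pregs + 1):
        lg = logit + (config.recurrence_log_odds if (idx == 2 and prev_preterm) else 0.0)
        preterm = rng.random() < _sigmoid(lg)
        length = _draw_gestational_length(bool(preterm), config, rng)
        outcome = outcome_band(length)
        subtype, mode = _draw_subtype_mode(outcome, config, rng)
        multi = rng.random() < config.multiple_gestation_rate
        delivery = conception + length
        pregnancies.append(
            Pregnancy(idx, conception, length, delivery, outcome, subtype, mode, multi)
        )
        prev_preterm = outcome == PRETERM
        # inter-pregnancy gap >= 60 days keeps 37-week demarcation identifiable
        conception = delivery + 60 + int(rng.integers(0, 300))
    return SyntheticTruth(
        patient_id=f"P{patient_index:06d}",
        site=config.site,
        risk_factors=active,
        pregnancies=tuple(pregnancies),
    )


def truth_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for p in t.pregnancies:
            rows.append(
                dict(
                    patient_id=t.patient_id,
                    pregnancy_index=p.index,
                    conception_day=p.conception_day,
                    gestational_length=p.gestational_length,
                    delivery_day=p.delivery_day,
                    outcome=p.outcome,
                    subtype=p.subtype,
                    mode=p.mode,
                    multiple_gestation=int(p.multiple_gestation),
                    risk_factors=";".join(sorted(t.risk_factors)),
                    site=t.site,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "pregnancy_index", "conception_day", "gestational_length",
            "delivery_day", "outcome", "subtype", "mode", "multiple_gestation",
            "risk_factors", "site",
        ],
    )


# ---------------------------------------------------------------------------
# event emission
# ---------------------------------------------------------------------------

def _system_of(code: str) -> str:
    return "PX" if code.startswith(_PX_PREFIX) else "DX"


def _code_frame(patient_ids, codes, days) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "code": codes,
            "day": np.asarray(days, dtype=np.int64),
        }
    )
    df["system"] = np.where(df["code"].str.startswith(_PX_PREFIX), "PX", "DX")
    return df[["patient_id", "system", "code", "day"]]


def _emit_visit_codes(
    pid: np.ndarray,  # patient id per visit slot
    days: np.ndarray,  # day per visit slot
    active_mask: dict[str, np.ndarray],  # factor -> bool per visit slot
    config: SimulationConfig,
    rng: np.random.Generator,
    parts: list[pd.DataFrame],
) -> None:
    """Emit noise and risk-factor codes for a batch of visits."""
    n = len(days)
    if n == 0:
        return
    shift = config.site_shift
    # noise codes
    counts = rng.poisson(config.noise_rate * shift, size=n)
    rep = np.repeat(np.arange(n), counts)
    if len(rep):
        vocab = np.array(config.noise_vocabulary())
        codes = vocab[rng.integers(0, len(vocab), size=len(rep))]
        parts.append(_code_frame(pid[rep], codes, days[rep]))
    # risk-factor codes
    for f in config.risk_factors:
        mask = active_mask[f.name]
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        counts = rng.poisson(f.code_rate * shift, size=len(idx))
        rep = idx[np.repeat(np.arange(len(idx)), counts)]
        if len(rep):
            fam = np.array(f.codes)
            codes = fam[rng.integers(0, len(fam), size=len(rep))]
            parts.append(_code_frame(pid[rep], codes, days[rep]))


def emit_events(
    truths: Sequence[SyntheticTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    rngs: dict[str, np.random.Generator] | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit all event tables for a collection of patient truths.

    Returns a dict with keys ``demographics``, ``code_events``, ``ega``,
    ``labs``, ``genotypes``, ``weights``. Vectorized across pregnancies so a
    cohort of tens of thousands simulates in seconds. Separate named random
    substreams (visits, codes, delivery, ega, labs, demographics, genotypes)
    keep features independent under config toggles.
    """
    if isinstance(truths, SyntheticTruth):
        truths = [truths]
    if rngs is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        keys = ("demo", "visits", "codes", "delivery", "ega", "labs", "geno")
        seeds = rng.integers(0, 2**31 - 1, size=len(keys))
        rngs = {k: np.random.default_rng(int(s)) for k, s in zip(keys, seeds)}

    # ---- pregnancy-level arrays
    pid, conc, deliv, length, outcome, subtype, mode, multi = [], [], [], [], [], [], [], []
    factor_active = {f.name: [] for f in config.risk_factors}
    first_conc: dict[str, int] = {}
    for t in truths:
        for p in t.pregnancies:
            pid.append(t.patient_id)
            conc.append(p.conception_day)
            deliv.append(p.delivery_day)
            length.append(p.gestational_length)
            outcome.append(p.outcome)
            subtype.append(p.subtype)
            mode.append(p.mode)
            multi.append(p.multiple_gestation)
            for name in factor_active:
                factor_active[name].append(name in t.risk_factors)
        if t.pregnancies:
            first_conc[t.patient_id] = t.pregnancies[0].conception_day
    pid = np.array(pid, dtype=object)
    conc = np.array(conc, dtype=np.int64)
    deliv = np.array(deliv, dtype=np.int64)
    length = np.array(length, dtype=np.int64)
    outcome = np.array(outcome, dtype=object)
    subtype = np.array(subtype, dtype=object)
    mode = np.array(mode, dtype=object)
    multi = np.array(multi, dtype=bool)
    factor_active = {k: np.array(v, dtype=bool) for k, v in factor_active.items()}
    n_preg = len(pid)

    parts: list[pd.DataFrame] = []

    # ---- pregnancy visit stream
    r = rngs["visits"]
    n_visits = r.poisson(config.visit_rate * length / 7.0) if n_preg else np.array([], int)
    vrep = np.repeat(np.arange(n_preg), n_visits)
    vdays = conc[vrep] + (r.random(len(vrep)) * length[vrep]).astype(np.int64)
    vactive = {k: v[vrep] for k, v in factor_active.items()}
    _emit_visit_codes(pid[vrep], vdays, vactive, config, rngs["codes"], parts)

    # ---- background (pre-first-conception) visit stream, 365-day window
    bg_pid = np.array(list(first_conc.keys()), dtype=object)
    bg_conc = np.array(list(first_conc.values()), dtype=np.int64)
    r = rngs["visits"]
    n_bg = r.poisson(config.background_visit_rate * 365 / 7.0, size=len(bg_pid))
    brep = np.repeat(np.arange(len(bg_pid)), n_bg)
    bdays = bg_conc[brep] - 1 - (r.random(len(brep)) * 364).astype(np.int64)
    pat_factor = {
        t.patient_id: t.risk_factors for t in truths
    }
    gestational_only = {f.name for f in config.risk_factors if f.gestational_only}
    bactive = {
        name: (
            np.zeros(len(brep), dtype=bool)
            if name in gestational_only
            else np.array([name in pat_factor[p] for p in bg_pid[brep]], dtype=bool)
        )
        for name in factor_active
    }
    _emit_visit_codes(bg_pid[brep], bdays, bactive, config, rngs["codes"], parts)

    # ---- delivery-day codes
    r = rngs["delivery"]
    if n_preg:
        labels = outcome.copy()
        flip = r.random(n_preg) < config.delivery_code_mislabel_rate
        all_labels = np.array([PRETERM, TERM, POSTTERM], dtype=object)
        for i in np.flatnonzero(flip):
            others = [l for l in all_labels if l != labels[i]]
            labels[i] = others[int(r.integers(0, len(others)))]
        dx_codes = np.array(
            [DELIVERY_DX_CODES[l][int(r.integers(0, len(DELIVERY_DX_CODES[l])))] for l in labels],
            dtype=object,
        )
        parts.append(_code_frame(pid, dx_codes, deliv))
        px = np.array(DELIVERY_PX_CODES, dtype=object)
        parts.append(_code_frame(pid, px[r.integers(0, len(px), size=n_preg)], deliv))
        # mode / subtype codes at the delivery day
        ces = mode == "cesarean"
        if ces.any():
            parts.append(_code_frame(pid[ces], np.repeat(CESAREAN_CODES[0], ces.sum()), deliv[ces]))
        vag = ~ces
        if vag.any():
            parts.append(_code_frame(pid[vag], np.repeat(VAGINAL_CODES[0], vag.sum()), deliv[vag]))
        ind = subtype == "induced"
        if ind.any():
            parts.append(_code_frame(pid[ind], np.repeat(INDUCED_CODES[0], ind.sum()), deliv[ind]))
        ppr = subtype == "pprom"
        if ppr.any():
            parts.append(_code_frame(pid[ppr], np.repeat(PPROM_CODES[0], ppr.sum()), deliv[ppr]))
        if multi.any():
            mdays = deliv[multi] - r.integers(0, 6, size=int(multi.sum()))
            parts.append(_code_frame(pid[multi], np.repeat(MULTI_GEST_CODES[0], int(multi.sum())), mdays))

    code_events = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=["patient_id", "system", "code", "day"])
    )
    code_events = code_events.sort_values(
        ["patient_id", "day", "code"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- EGA observations near delivery
    r = rngs["ega"]
    if n_preg:
        have = r.random(n_preg) < config.ega_availability
        offs = r.integers(0, 4, size=n_preg) * np.where(r.random(n_preg) < 0.5, -1, 1)
        obs_day = deliv + offs
        ega_weeks = length / 7.0 + r.normal(0.0, config.ega_error_sd, size=n_preg) / 7.0
        ega = pd.DataFrame(
            {
                "patient_id": pid[have],
                "day": obs_day[have].astype(np.int64),
                "ega_weeks": np.round(ega_weeks[have], 3),
            }
        )
    else:
        ega = pd.DataFrame(columns=["patient_id", "day", "ega_weeks"])
    ega = ega.sort_values(["patient_id", "day"], kind="mergesort").reset_index(drop=True)

    # ---- labs during pregnancy
    r = rngs["labs"]
    lab_parts = []
    for lab in config.labs:
        n_meas = r.poisson(lab.per_pregnancy_rate, size=n_preg) if n_preg else np.array([], int)
        rep = np.repeat(np.arange(n_preg), n_meas)
        if not len(rep):
            continue
        days = conc[rep] + (r.random(len(rep)) * length[rep]).astype(np.int64)
        mean = np.full(len(rep), lab.mean)
        if lab.shift_factor is not None and lab.shift_factor in factor_active:
            mean = mean + lab.shift * factor_active[lab.shift_factor][rep]
        vals = r.normal(mean, lab.sd)
        lab_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[rep],
                    "lab": lab.name,
                    "day": days,
                    "value": np.round(vals, 4),
                }
            )
        )
    labs = (
        pd.concat(lab_parts, ignore_index=True)
        if lab_parts
        else pd.DataFrame(columns=["patient_id", "lab", "day", "value"])
    )
    labs = labs.sort_values(["patient_id", "lab", "day"], kind="mergesort").reset_index(drop=True)

    # ---- demographics
    r = rngs["demo"]
    all_pids = [t.patient_id for t in truths]
    n_pat = len(all_pids)
    age = np.clip(r.normal(27.5, 6.0, size=n_pat), 14, 48)
    race = np.array(RACES, dtype=object)[
        r.choice(len(RACES), size=n_pat, p=np.array(RACE_PROBS))
    ]
    bmi = np.clip(r.normal(26.5, 5.5, size=n_pat), 15, 60)
    sbp = np.clip(r.normal(114.0, 12.0, size=n_pat), 80, 200)
    dbp = np.clip(r.normal(72.0, 9.0, size=n_pat), 40, 130)
    demographics = pd.DataFrame(
        {
            "patient_id": all_pids,
            "age_at_first_delivery": np.round(age, 1),
            "race": race,
            "prepregnancy_bmi": np.round(bmi, 1),
            "prepregnancy_sbp": np.round(sbp, 1),
            "prepregnancy_dbp": np.round(dbp, 1),
        }
    )

    # ---- genotypes
    r = rngs["geno"]
    if config.genotypes is not None and n_pat:
        g = config.genotypes
        if g.allele_freqs is not None:
            afs = np.asarray(g.allele_freqs, dtype=float)
        else:
            afs = r.uniform(0.1, 0.5, size=g.n_variants)
        if g.effect_sizes is not None:
            effects = np.asarray(g.effect_sizes, dtype=float)
        else:
            effects = np.zeros(g.n_variants)
            effects[: g.n_causal] = r.normal(0.0, 0.2, size=min(g.n_causal, g.n_variants))
        dosage = r.binomial(2, afs[None, :], size=(n_pat, len(afs)))
        variants = [f"rs{i:05d}" for i in range(len(afs))]
        genotypes = pd.DataFrame(dosage, columns=variants)
        genotypes.insert(0, "patient_id", all_pids)
        pvals = np.where(
            effects != 0.0,
            10.0 ** (-r.uniform(4, 8, size=len(afs))),
            r.uniform(0.05, 1.0, size=len(afs)),
        )
        weights = pd.DataFrame(
            {
                "variant": variants,
                "effect_size": np.round(effects, 6),
                "p_value": pvals,
                "allele_freq": np.round(afs, 4),
            }
        )
    else:
        genotypes = pd.DataFrame(columns=["patient_id"])
        weights = pd.DataFrame(columns=["variant", "effect_size", "p_value", "allele_freq"])

    return {
        "demographics": demographics,
        "code_events": code_events,
        "ega": ega,
        "labs": labs,
        "genotypes": genotypes,
        "weights": weights,
    }


# ---------------------------------------------------------------------------
# cohort-level API
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Event tables plus ground truth for one simulated site."""

    config: SimulationConfig
    demographics: pd.DataFrame
    code_events: pd.DataFrame
    ega: pd.DataFrame
    labs: pd.DataFrame
    genotypes: pd.DataFrame
    weights: pd.DataFrame
    truth: pd.DataFrame

    @property
    def site(self) -> str:
        return self.config.site

    _FILES = (
        "demographics", "code_events", "ega", "labs", "genotypes", "weights", "truth",
    )

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._FILES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")

    @classmethod
    def read_csv(cls, indir: str | Path) -> "SyntheticDataset":
        indir = Path(indir)
        frames = {name: pd.read_csv(indir / f"{name}.csv") for name in cls._FILES}
        config = SimulationConfig.from_yaml(indir / "config.yaml")
        return cls(config=config, **frames)


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full site: ground truth plus all event tables.

    Deterministic given ``config.seed``: identical configs yield
    byte-identical serialized tables.
    """
    master = np.random.SeedSequence(config.seed)
    truth_seed, emit_seed = master.spawn(2)
    truth_rng = np.random.default_rng(truth_seed)
    truths = [
        sample_patient_truth(config, i, truth_rng) for i in range(config.n_patients)
    ]
    emit_rng = np.random.default_rng(emit_seed)
    tables = emit_events(truths, config, emit_rng)
    return SyntheticDataset(config=config, truth=truth_frame(truths), **tables)


def simulate_multisite(
    config_a: SimulationConfig, config_b: SimulationConfig
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Simulate two sites sharing a code vocabulary (portability experiments).

    Site B carries its own prevalence target (via its intercept) and applies
    its ``site_shift`` to code-emission rates.
    """
    vocab_a = set(config_a.noise_vocabulary()).union(
        *[set(f.codes) for f in config_a.risk_factors] or [set()]
    )
    vocab_b = set(config_b.noise_vocabulary()).union(
        *[set(f.codes) for f in config_b.risk_factors] or [set()]
    )
    if vocab_a != vocab_b:
        raise ConfigurationError(
            "site configs must share the code vocabulary (risk-factor and noise codes)"
        )
    return simulate_cohort(config_a), simulate_cohort(config_b)
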