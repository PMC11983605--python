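"""Synthetic autoimmune-disorder cohort generator.

Emulates a cross-sectional clinical table of 13 predictors plus a categorical
disease label: demographics (age, gender, family history), vitals and routine
laboratory values (blood pressure, cholesterol, BMI, blood counts, hemoglobin,
platelets) and the inflammation work-up (CRP, ESR, symptom count).  The
disease mix defaults to the published prevalence of the eight diagnostic
groups (RA 25%, SLE 18%, MS 15%, T1D 12%, psoriasis 10%, IBD 8%, Sjögren 7%,
other 5%) with a 52/48 women/men split and ages uniform on 18–80.

Learnable signal is planted as class-conditional mean shifts on the four
biomarkers reported as most discriminative in this setting — CRP, ESR, white
blood cell count and symptom count — scaled by a single ``effect_size`` knob.
``effect_size = 0`` makes every predictor independent of the label, which the
test suite verifies by contingency-table chi-square.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

__all__ = [
    "DISEASES",
    "PREDICTORS",
    "CONTINUOUS",
    "CATEGORICAL",
    "CSV_NAMES",
    "HIGH_EFFECT_SIZE",
    "CohortSpec",
    "generate_cohort",
    "inject_missingness",
    "make_visits",
    "write_cohort_csv",
    "read_cohort_csv",
]

DISEASES: tuple[str, ...] = (
    "RA", "SLE", "MS", "T1D", "Psoriasis", "IBD", "Sjogren", "Other",
)

DEFAULT_CLASS_MIX: dict[str, float] = {
    "RA": 0.25, "SLE": 0.18, "MS": 0.15, "T1D": 0.12,
    "Psoriasis": 0.10, "IBD": 0.08, "Sjogren": 0.07, "Other": 0.05,
}

CONTINUOUS: tuple[str, ...] = (
    "age", "symptom_count", "blood_pressure", "cholesterol", "bmi",
    "wbc", "rbc", "hemoglobin", "platelets", "crp", "esr",
)
CATEGORICAL: tuple[str, ...] = ("gender", "family_history")
PREDICTORS: tuple[str, ...] = (
    "age", "gender", "family_history", "symptom_count", "blood_pressure",
    "cholesterol", "bmi", "wbc", "rbc", "hemoglobin", "platelets",
    "crp", "esr",
)
LABEL = "disease"

# Column header names used in the cohort CSV dialect.
CSV_NAMES: dict[str, str] = {
    "age": "Age",
    "gender": "Gender",
    "family_history": "Family history",
    "symptom_count": "Symptom count",
    "blood_pressure": "Blood pressure",
    "cholesterol": "Cholesterol level",
    "bmi": "Body mass index",
    "wbc": "White blood cell count",
    "rbc": "Red blood cell count",
    "hemoglobin": "Hemoglobin level",
    "platelets": "Platelet count",
    "crp": "C-reactive protein",
    "esr": "Erythrocyte sedimentation rate",
    "disease": "Disease",
}

# Physiological baselines: (mean, sd, lower, upper) for truncated normals.
_BASELINES: dict[str, tuple[float, float, float, float]] = {
    "blood_pressure": (125.0, 15.0, 80.0, 220.0),   # systolic, mmHg
    "cholesterol":    (195.0, 35.0, 100.0, 400.0),  # mg/dL
    "bmi":            (26.0, 4.5, 15.0, 50.0),      # kg/m^2
    "wbc":            (7000.0, 1800.0, 2000.0, 25000.0),   # cells/uL
    "rbc":            (4.8e6, 0.5e6, 3.0e6, 7.0e6),        # cells/uL
    "hemoglobin":     (13.8, 1.5, 7.0, 20.0),       # g/dL
    "platelets":      (260e3, 60e3, 50e3, 600e3),   # cells/uL
    "crp":            (8.0, 6.0, 0.0, 200.0),       # mg/L
    "esr":            (20.0, 12.0, 0.0, 150.0),     # mm/h
}

_SYMPTOM_BASE_RATE = 4.0  # Poisson mean symptom count in the reference class

# Per-class mean shifts, in units of each biomarker's population sd, applied
# as effect_size x signature.  Order: (crp, esr, wbc, symptom_count).
# "Other" is the unshifted reference profile.
SIGNATURES: dict[str, tuple[float, float, float, float]] = {
    "RA":        (1.2, 1.0, 0.3, 0.8),
    "SLE":       (0.8, 1.2, -0.4, 1.0),
    "MS":        (-0.3, 0.2, 0.6, 1.2),
    "T1D":       (0.1, -0.5, 1.1, 0.4),
    "Psoriasis": (0.6, -0.2, -0.8, 0.6),
    "IBD":       (1.0, 0.5, 0.9, -0.3),
    "Sjogren":   (-0.6, 0.8, -0.2, 0.2),
    "Other":     (0.0, 0.0, 0.0, 0.0),
}
_SIGNAL_FEATURES = ("crp", "esr", "wbc", "symptom_count")

# Class-conditional correlation patterns among the latent normals behind
# (crp, esr, wbc): inflammatory markers co-vary differently across diseases
# (e.g. tightly coupled CRP/ESR in RA).  Encoded as pairwise correlations of
# the latent Gaussian before truncation; blended toward these targets with
# weight min(effect_size / HIGH_EFFECT_SIZE, 1), so effect_size = 0 leaves
# every feature label-independent.  This is the inter-feature relationship
# structure the topology-refinement stage is designed to pick up.
CORRELATION_PATTERNS: dict[str, tuple[tuple[int, int, float], ...]] = {
    "RA":        ((0, 1, 0.85),),
    "SLE":       ((0, 1, -0.55), (1, 2, 0.60)),
    "MS":        ((0, 2, 0.80),),
    "T1D":       ((1, 2, -0.70),),
    "Psoriasis": ((0, 1, 0.50), (0, 2, -0.55)),
    "IBD":       ((0, 2, -0.80),),
    "Sjogren":   ((0, 1, -0.45), (1, 2, 0.75)),
    "Other":     (),
}

# Effect size of the documented high-signal regime: class-conditional mean
# shifts wide enough for ~95% separability and correlation contrasts at full
# strength.  The default (1.0) is a deliberately hard, overlapping mixture.
HIGH_EFFECT_SIZE = 3.5


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 10_000
    seed: int = 0
    class_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    gender_split: float = 0.52          # P(gender == "women")
    age_range: tuple[float, float] = (18.0, 80.0)
    effect_size: float = 1.0            # scales class-conditional mean shifts
    missing_rate: float = 0.0
    signatures: Mapping[str, Sequence[float]] = dataclasses.field(
        default_factory=lambda: dict(SIGNATURES)
    )
    correlation_patterns: Mapping[str, Sequence] = dataclasses.field(
        default_factory=lambda: dict(CORRELATION_PATTERNS)
    )

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        probs = np.array(list(self.class_mix.values()), dtype=float)
        if (probs < 0).any():
            raise ValueError("class_mix probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_mix must sum to 1 (got {probs.sum():.12f})"
            )
        if not 0.0 <= self.gender_split <= 1.0:
            raise ValueError("gender_split must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_mix"] = dict(self.class_mix)
        d["signatures"] = {k: list(v) for k, v in self.signatures.items()}
        d["correlation_patterns"] = {
            k: [list(t) for t in v] for k, v in self.correlation_patterns.items()
        }
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "signatures" in d:
            d["signatures"] = {k: tuple(v) for k, v in d["signatures"].items()}
        if "correlation_patterns" in d:
            d["correlation_patterns"] = {
                k: tuple(tuple(t) for t in v)
                for k, v in d["correlation_patterns"].items()
            }
        return cls(**d)


def _truncnorm_draw(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _class_correlation(pattern: Sequence, strength: float) -> np.ndarray:
    """Latent 3×3 correlation matrix for (crp, esr, wbc) in one class,
    blended between identity (strength 0) and the class pattern (1)."""
    R = np.eye(3)
    for i, j, rho in pattern:
        R[i, j] = R[j, i] = rho * strength
    return R


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table; identical spec gives a bitwise-identical table.

    Disease labels are i.i.d. from ``spec.class_mix``; the signal biomarkers
    are drawn from class-conditional truncated normals whose means are shifted
    by ``effect_size × signature × sd``; every other predictor is drawn from
    its label-independent baseline distribution.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.class_mix.keys())
    probs = np.array([spec.class_mix[c] for c in labels], dtype=float)
    y = rng.choice(len(labels), size=spec.n, p=probs)
    disease = np.array(labels, dtype=object)[y]

    cols: dict[str, np.ndarray] = {}
    lo, hi = spec.age_range
    cols["age"] = rng.uniform(lo, hi, size=spec.n)
    cols["gender"] = np.where(
        rng.random(spec.n) < spec.gender_split, "women", "men"
    ).astype(object)
    cols["family_history"] = np.where(
        rng.random(spec.n) < 0.30, "yes", "no"
    ).astype(object)

    sig = {c: np.asarray(spec.signatures.get(c, (0.0,) * 4), float)
           for c in labels}
    shift = np.stack([sig[labels[k]] for k in range(len(labels))])[y]
    # shift columns align with _SIGNAL_FEATURES

    # correlated inflammation markers: a per-class latent Gaussian with the
    # class correlation pattern, mapped through a Gaussian copula onto
    # truncated-normal marginals so the mean-shift contract stays exact
    corr_w = min(spec.effect_size / HIGH_EFFECT_SIZE, 1.0)
    latent = rng.standard_normal(size=(spec.n, 3))
    tri = ("crp", "esr", "wbc")
    for k, cname in enumerate(labels):
        m = y == k
        if not m.any():
            continue
        pattern = spec.correlation_patterns.get(cname, ())
        L = np.linalg.cholesky(_class_correlation(pattern, corr_w))
        latent[m] = latent[m] @ L.T
    u = norm.cdf(latent)
    for idx, feat in enumerate(tri):
        mean, sd, flo, fhi = _BASELINES[feat]
        mu = mean + spec.effect_size * shift[:, idx] * sd
        a, b = (flo - mu) / sd, (fhi - mu) / sd
        cols[feat] = truncnorm.ppf(
            np.clip(u[:, idx], 1e-12, 1 - 1e-12), a, b, loc=mu, scale=sd
        )

    for feat, (mean, sd, flo, fhi) in _BASELINES.items():
        if feat in tri:
            continue
        cols[feat] = _truncnorm_draw(rng, spec.n, mean, sd, flo, fhi)

    lam = _SYMPTOM_BASE_RATE + spec.effect_size * shift[:, 3] * np.sqrt(
        _SYMPTOM_BASE_RATE
    )
    cols["symptom_count"] = rng.poisson(np.clip(lam, 0.1, None)).astype(float)

    cols["disease"] = disease
    table = pd.DataFrame({c: cols[c] for c in PREDICTORS + (LABEL,)})
    if spec.missing_rate > 0:
        table = inject_missingness(table, spec.missing_rate, seed=spec.seed + 1)
    return table


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each predictor cell missing independently with probability ``rate``.

    Missingness is completely at random (MCAR); the disease label is never
    masked.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    out = table.copy()
    if rate == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in PREDICTORS:
        mask = rng.random(len(out)) < rate
        if col in CATEGORICAL:
            vals = out[col].astype(object)
            vals[mask] = np.nan
            out[col] = vals
        else:
            vals = out[col].to_numpy(dtype=float, copy=True)
            vals[mask] = np.nan
            out[col] = vals
    return out


def make_visits(
    table: pd.DataFrame, n_visits: int, seed: int, drift: float = 0.05
) -> pd.DataFrame:
    """Expand a cross-sectional cohort into per-patient visit sequences.

    Visit 1 is the baseline record; later visits add a seeded Gaussian random
    walk of relative step ``drift`` (fraction of each biomarker's population
    sd) to the continuous biomarkers.  The label is constant across visits.
    The source data are cross-sectional, so this longitudinal expansion is a
    modelling device for exercising the recurrent stage, not a reconstruction
    of real disease trajectories.
    """
    if n_visits < 1:
        raise ValueError(f"n_visits must be >= 1, got {n_visits}")
    rng = np.random.default_rng(seed)
    n = len(table)
    frames = []
    walk = {c: np.zeros(n) for c in _BASELINES}
    for v in range(1, n_visits + 1):
        frame = table.copy()
        frame.insert(0, "patient_id", np.arange(n))
        frame.insert(1, "visit", v)
        if v > 1 and drift > 0:
            for c, (_, sd, flo, fhi) in _BASELINES.items():
                walk[c] = walk[c] + rng.normal(0.0, drift * sd, size=n)
                frame[c] = np.clip(frame[c] + walk[c], flo, fhi)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "visit"], kind="stable").reset_index(
        drop=True
    )


def write_cohort_csv(table: pd.DataFrame, path_or_buf) -> None:
    """Write a cohort as UTF-8 CSV with clinical header names, blanks for NA."""
    out = table.rename(columns=CSV_NAMES)
    out.to_csv(path_or_buf, index=False, na_rep="")


def read_cohort_csv(path_or_buf) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    inv = {v: k for k, v in CSV_NAMES.items()}
    raw = pd.read_csv(path_or_buf)
    raw = raw.rename(columns=inv)
    missing = [c for c in PREDICTORS + (LABEL,) if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks expected columns: {missing}")
    return raw[list(PREDICTORS + (LABEL,))]


def cohort_to_csv_bytes(table: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_cohort_csv(table, buf)
    return buf.getvalue().encode("utf-8")
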