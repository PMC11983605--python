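"""Cohort preparation: imputation, scaling, encoding, splitting, SMOTE.

The pipeline follows the usual leak-free discipline: every statistic
(imputation values, min-max bounds, winsorization bounds, category levels) is
fitted on the training partition only and reused verbatim on validation and
test data.  Minority-class oversampling (SMOTE) runs after the split, on the
training partition only, so no synthetic point can leak into evaluation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import CATEGORICAL, CONTINUOUS, LABEL, PREDICTORS

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "PreprocessorState",
    "FeatureMatrix",
    "SplitIndices",
    "fit_preprocessor",
    "transform",
    "inverse_transform_continuous",
    "zscore_outliers",
    "stratified_split",
    "smote",
    "prepare_datasets",
]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    numeric_strategy: str = "mean"      # mean | median | knn
    knn_k: int = 5
    zscore_threshold: float = 3.0       # |z| beyond which values are winsorized
    winsorize: bool = True

    def __post_init__(self):
        if self.numeric_strategy not in ("mean", "median", "knn"):
            raise ValueError(f"unknown numeric_strategy {self.numeric_strategy!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclasses.dataclass
class PreprocessorState:
    """Everything fitted on the training partition."""

    config: PreprocessConfig
    impute: dict[str, object]               # feature -> value (or mode)
    mins: dict[str, float]
    maxs: dict[str, float]
    winsor_lo: dict[str, float]
    winsor_hi: dict[str, float]
    levels: dict[str, list[str]]            # categorical -> ordered levels
    class_names: list[str]                  # label code order
    knn_reference: pd.DataFrame | None = None  # train predictors (knn only)

    @property
    def feature_names(self) -> list[str]:
        names = list(CONTINUOUS)
        for cat in CATEGORICAL:
            names += [f"{cat}={lv}" for lv in self.levels[cat]]
        return names

    def column_groups(self) -> dict[str, slice]:
        """Map each source predictor to its slice of feature-matrix columns."""
        groups: dict[str, slice] = {}
        pos = 0
        for c in CONTINUOUS:
            groups[c] = slice(pos, pos + 1)
            pos += 1
        for cat in CATEGORICAL:
            w = len(self.levels[cat])
            groups[cat] = slice(pos, pos + w)
            pos += w
        return groups

    # JSON sidecar round trip -------------------------------------------------

    def to_json(self) -> str:
        d = {
            "config": dataclasses.asdict(self.config),
            "impute": self.impute,
            "mins": self.mins,
            "maxs": self.maxs,
            "winsor_lo": self.winsor_lo,
            "winsor_hi": self.winsor_hi,
            "levels": self.levels,
            "class_names": self.class_names,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "PreprocessorState":
        d = json.loads(s)
        return cls(
            config=PreprocessConfig(**d["config"]),
            impute=d["impute"],
            mins=d["mins"],
            maxs=d["maxs"],
            winsor_lo=d["winsor_lo"],
            winsor_hi=d["winsor_hi"],
            levels=d["levels"],
            class_names=d["class_names"],
        )


@dataclasses.dataclass
class FeatureMatrix:
    """Model-ready design matrix: scaled continuous block then one-hot blocks."""

    X: np.ndarray                 # (n, F) float64, continuous entries in [0,1]
    y: np.ndarray                 # (n,) int class codes
    feature_names: list[str]
    class_names: list[str]
    groups: dict[str, slice]      # source predictor -> column slice


@dataclasses.dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


# ---------------------------------------------------------------------------
# fitting & transforming
# ---------------------------------------------------------------------------

def fit_preprocessor(
    train: pd.DataFrame, config: PreprocessConfig | None = None
) -> PreprocessorState:
    """Fit imputation values, winsor bounds, min-max bounds and level maps.

    Raises if the table is empty or any feature has no observed training
    value, since no statistic could then be estimated.
    """
    config = config or PreprocessConfig()
    if len(train) == 0:
        raise ValueError("cannot fit preprocessor on an empty table")

    impute: dict[str, object] = {}
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    w_lo: dict[str, float] = {}
    w_hi: dict[str, float] = {}

    for c in CONTINUOUS:
        obs = pd.to_numeric(train[c], errors="coerce").dropna().to_numpy(float)
        if obs.size == 0:
            raise ValueError(f"feature {c!r} is entirely missing in training data")
        if config.numeric_strategy == "median":
            impute[c] = float(np.median(obs))
        else:  # mean fallback value also backs the knn path
            impute[c] = float(np.mean(obs))
        if config.winsorize and obs.size > 1 and np.std(obs) > 0:
            m, s = float(np.mean(obs)), float(np.std(obs))
            w_lo[c] = m - config.zscore_threshold * s
            w_hi[c] = m + config.zscore_threshold * s
        else:
            w_lo[c], w_hi[c] = -np.inf, np.inf
        clipped = np.clip(obs, w_lo[c], w_hi[c])
        mins[c] = float(np.min(clipped))
        maxs[c] = float(np.max(clipped))

    levels: dict[str, list[str]] = {}
    for cat in CATEGORICAL:
        obs = train[cat].dropna()
        obs = obs[obs.astype(str) != "nan"]
        if len(obs) == 0:
            raise ValueError(f"feature {cat!r} is entirely missing in training data")
        levels[cat] = sorted(obs.astype(str).unique())
        impute[cat] = str(obs.mode().sort_values().iloc[0])

    class_names = sorted(train[LABEL].astype(str).unique())
    ref = train[list(PREDICTORS)].copy() if config.numeric_strategy == "knn" else None
    return PreprocessorState(
        config=config, impute=impute, mins=mins, maxs=maxs,
        winsor_lo=w_lo, winsor_hi=w_hi, levels=levels,
        class_names=class_names, knn_reference=ref,
    )


def _knn_impute_column(
    state: PreprocessorState, table: pd.DataFrame, col: str, vals: np.ndarray
) -> np.ndarray:
    """Fill missing entries of one continuous column from the k nearest
    complete training rows, Euclidean distance on min-max-scaled continuous
    features observed in both rows."""
    ref = state.knn_reference
    other = [c for c in CONTINUOUS if c != col]

    def scaled(frame: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(frame), len(other)))
        for j, c in enumerate(other):
            x = pd.to_numeric(frame[c], errors="coerce").to_numpy(float)
            rng_ = state.maxs[c] - state.mins[c]
            if rng_ == 0:
                out[:, j] = np.where(np.isnan(x), np.nan, 0.0)
            else:
                out[:, j] = (x - state.mins[c]) / rng_
        return out

    ref_y = pd.to_numeric(ref[col], errors="coerce").to_numpy(float)
    donors = ~np.isnan(ref_y) & ~np.isnan(scaled(ref)).any(axis=1)
    if donors.sum() == 0:
        return np.where(np.isnan(vals), state.impute[col], vals)
    ref_X = scaled(ref)[donors]
    nn = NearestNeighbors(n_neighbors=min(state.config.knn_k, donors.sum()))
    nn.fit(ref_X)
    out = vals.copy()
    qmask = np.isnan(vals)
    q = scaled(table)[qmask]
    # queries with missing covariates fall back to the mean value
    ok = ~np.isnan(q).any(axis=1)
    filled = np.full(qmask.sum(), float(state.impute[col]))
    if ok.any():
        _, idx = nn.kneighbors(q[ok])
        filled[ok] = ref_y[donors][idx].mean(axis=1)
    out[qmask] = filled
    return out


def transform(state: PreprocessorState, table: pd.DataFrame) -> FeatureMatrix:
    """Impute, winsorize, min-max scale and one-hot encode a cohort table.

    Continuous values are clipped into [0, 1] after scaling so unseen
    out-of-range values cannot escape the training range; a categorical level
    unseen at fit time produces an all-zero indicator block with a warning.
    """
    missing_cols = [c for c in PREDICTORS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks predictor columns: {missing_cols}")
    n = len(table)
    blocks: list[np.ndarray] = []

    for c in CONTINUOUS:
        vals = pd.to_numeric(table[c], errors="coerce").to_numpy(float)
        if state.config.numeric_strategy == "knn" and np.isnan(vals).any():
            vals = _knn_impute_column(state, table, c, vals)
        vals = np.where(np.isnan(vals), float(state.impute[c]), vals)
        vals = np.clip(vals, state.winsor_lo[c], state.winsor_hi[c])
        rng_ = state.maxs[c] - state.mins[c]
        if rng_ == 0:
            scaled = np.zeros(n)  # constant training feature maps to 0
        else:
            scaled = np.clip((vals - state.mins[c]) / rng_, 0.0, 1.0)
        blocks.append(scaled[:, None])

    for cat in CATEGORICAL:
        raw = table[cat].astype(object).to_numpy()
        raw = np.array(
            [state.impute[cat] if (x is np.nan or pd.isna(x)) else str(x)
             for x in raw], dtype=object,
        )
        lv = state.levels[cat]
        block = np.zeros((n, len(lv)))
        lv_index = {v: i for i, v in enumerate(lv)}
        unseen = 0
        for i, v in enumerate(raw):
            j = lv_index.get(v)
            if j is None:
                unseen += 1
            else:
                block[i, j] = 1.0
        if unseen:
            logger.warning(
                "%d rows carry unseen %r categories; encoded as all-zero block",
                unseen, cat,
            )
        blocks.append(block)

    X = np.hstack(blocks)
    if LABEL in table.columns:
        code = {c: i for i, c in enumerate(state.class_names)}
        try:
            y = np.array([code[str(v)] for v in table[LABEL]], dtype=int)
        except KeyError as e:
            raise ValueError(f"unknown disease label {e.args[0]!r}") from None
    else:
        y = np.full(n, -1, dtype=int)
    return FeatureMatrix(
        X=X, y=y, feature_names=state.feature_names,
        class_names=list(state.class_names), groups=state.column_groups(),
    )


def inverse_transform_continuous(
    state: PreprocessorState, feature: str, scaled: np.ndarray
) -> np.ndarray:
    """Undo min-max scaling for one continuous feature (in-range values)."""
    rng_ = state.maxs[feature] - state.mins[feature]
    return np.asarray(scaled) * rng_ + state.mins[feature]


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def zscore_outliers(
    values: np.ndarray, threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag |z| > threshold entries and clamp them to mean ± threshold·sd.

    Returns (mask, winsorized).  A zero-variance vector has no outliers and
    is returned unchanged.  NaNs are ignored (never flagged, never altered).
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    mask = np.zeros(x.shape, dtype=bool)
    if obs.size < 2:
        return mask, x.copy()
    m, s = float(np.mean(obs)), float(np.std(obs))
    if s == 0:
        return mask, x.copy()
    with np.errstate(invalid="ignore"):
        mask = np.abs(x - m) / s > threshold
    mask &= ~np.isnan(x)
    out = x.copy()
    out[mask] = np.clip(x[mask], m - threshold * s, m + threshold * s)
    return mask, out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    labels: Sequence, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitIndices:
    """Stratified train/validation/test partition by largest-remainder rounding.

    Within every class, members are shuffled with the given seed and counts
    are allocated to the three partitions by largest remainder (ties broken
    toward the earlier partition), so each partition's per-class count is
    within one sample of exact proportionality.  Classes with fewer than 3
    members go entirely to training (with a warning).
    """
    fr = np.asarray(fractions, dtype=float)
    if (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in sorted(pd.unique(y), key=str):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        m = idx.size
        if m < 3:
            warnings.warn(
                f"class {cls!r} has {m} member(s); assigned entirely to training"
            )
            parts[0].extend(idx.tolist())
            continue
        quota = fr * m
        counts = np.floor(quota).astype(int)
        rem = quota - counts
        # largest remainder; ties toward the earlier partition
        order = np.lexsort((np.arange(3), -rem))
        for j in order[: m - counts.sum()]:
            counts[j] += 1
        stops = np.cumsum(counts)
        parts[0].extend(idx[: stops[0]].tolist())
        parts[1].extend(idx[stops[0]: stops[1]].tolist())
        parts[2].extend(idx[stops[1]: stops[2]].tolist())
    return SplitIndices(
        train=np.sort(np.array(parts[0], dtype=int)),
        validation=np.sort(np.array(parts[1], dtype=int)),
        test=np.sort(np.array(parts[2], dtype=int)),
        fractions=tuple(fractions), seed=seed,
    )


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to the majority-class count.

    Each synthetic row is x + λ(x_nn − x) with λ ~ U[0, 1], x a minority-class
    row and x_nn one of its k nearest same-class neighbours (Euclidean).
    Original rows are returned unchanged, followed by the synthetic rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_X: list[np.ndarray] = [X]
    new_y: list[np.ndarray] = [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has a single member; SMOTE needs >= 2 "
                "(lower k or merge classes)"
            )
        rows = X[y == cls]
        kk = min(k, cnt - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(rows)
        _, nbr = nn.kneighbors(rows)  # col 0 is the point itself
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, kk + 1, size=need)
        lam = rng.random(need)[:, None]
        x0 = rows[base]
        x1 = rows[nbr[base, pick]]
        new_X.append(x0 + lam * (x1 - x0))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# end-to-end data preparation
# ---------------------------------------------------------------------------

def prepare_datasets(
    cohort: pd.DataFrame,
    seed: int = 0,
    config: PreprocessConfig | None = None,
    apply_smote: bool = True,
    smote_k: int = 5,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, PreprocessorState]:
    """Stratified 80/10/10 split, train-only fitting, transform, train SMOTE.

    Returns (train, validation, test, state); only the training partition is
    rebalanced.
    """
    split = stratified_split(cohort[LABEL].to_numpy(), seed=seed)
    train_tab = cohort.iloc[split.train]
    state = fit_preprocessor(train_tab, config)
    fm_train = transform(state, train_tab)
    fm_val = transform(state, cohort.iloc[split.validation])
    fm_test = transform(state, cohort.iloc[split.test])
    if apply_smote:
        counts = np.bincount(fm_train.y, minlength=len(state.class_names))
        k = min(smote_k, max(int(counts[counts > 0].min()) - 1, 1))
        fm_train = FeatureMatrix(
            *smote(fm_train.X, fm_train.y, k=k, seed=seed),
            feature_names=fm_train.feature_names,
            class_names=fm_train.class_names,
            groups=fm_train.groups,
        )
    return fm_train, fm_val, fm_test, state
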