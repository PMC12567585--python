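"""SNAP-IV scoring, T-score labelling, and clinical feature preparation.

The SNAP-IV questionnaire has 26 items rated 0-3, ordered as inattention
(items 1-9), hyperactivity/impulsivity (items 10-18) and oppositional defiant
behaviours (items 19-26). The total score is standardised within the cohort
(Z-score), rescaled to a T-score T = 10 Z + 50, and subjects with T >= 55 are
labelled positive. Labels are defined on the full cohort — they are a property
of each participant relative to the study sample — while feature
standardisation uses training-fold statistics only, to avoid leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnapIvResponse", "SnapIvScores", "ClinicalRecord", "CohortTable",
    "score_snapiv", "t_score", "label_adhd", "impute_missing",
    "standardise_features", "build_cohort_table",
    "DEFAULT_FEATURE_COLUMNS", "SNAP_ITEM_COLUMNS", "T_SCORE_THRESHOLD",
]

N_ITEMS = 26
_INATTENTION = slice(0, 9)
_HYPERACTIVITY = slice(9, 18)
_OPPOSITIONAL = slice(18, 26)

T_SCORE_THRESHOLD = 55.0

SNAP_ITEM_COLUMNS = [f"snap_{i:02d}" for i in range(1, N_ITEMS + 1)]

#: Columns entering the tabular feature vector. All SNAP-IV-derived scores
#: (total *and* subscales) are deliberately excluded by default: the binary
#: label is a deterministic threshold on the total, and the subscales sum to
#: the total, so either would leak the label into the features. Pass an
#: explicit ``feature_columns`` list (e.g. adding "inattention",
#: "hyperactivity", "oppositional") to opt in, understanding the leakage.
DEFAULT_FEATURE_COLUMNS = [
    "sex", "age", "bmi", "grade", "health_state", "diet_state",
    "parental_education",
]


@dataclass
class SnapIvResponse:
    items: np.ndarray

    def __post_init__(self):
        items = np.asarray(self.items)
        if items.shape != (N_ITEMS,):
            raise ValueError(f"SNAP-IV needs exactly {N_ITEMS} items, got shape {items.shape}")
        for i, v in enumerate(items):
            if not (float(v).is_integer() and 0 <= v <= 3):
                raise ValueError(f"item {i + 1} rating {v!r} outside {{0, 1, 2, 3}}")
        self.items = items.astype(np.int64)


@dataclass
class SnapIvScores:
    inattention: int
    hyperactivity: int
    oppositional: int
    total: int


@dataclass
class ClinicalRecord:
    subject_id: str
    sex: int          # male = 0, female = 1
    age: float        # years
    bmi: float        # kg/m^2
    grade: int
    health_state: int         # 1-3 ordinal
    diet_state: int           # 1-3 ordinal
    parental_education: int   # 1-3 ordinal
    snap: SnapIvResponse


@dataclass
class CohortTable:
    """Scored, labelled and standardised cohort ready for modelling."""

    frame: pd.DataFrame                 # one row per subject, scored columns
    t_scores: np.ndarray
    labels: np.ndarray
    feature_matrix: np.ndarray = None
    feature_columns: list = field(default_factory=list)
    feature_means: np.ndarray = None
    feature_stds: np.ndarray = None

    @property
    def subject_ids(self):
        return self.frame["subject_id"].to_numpy()


def score_snapiv(resp: SnapIvResponse) -> SnapIvScores:
    """Subscale sums over the three item blocks; total = sum of all 26 items."""
    items = resp.items
    return SnapIvScores(
        inattention=int(items[_INATTENTION].sum()),
        hyperactivity=int(items[_HYPERACTIVITY].sum()),
        oppositional=int(items[_OPPOSITIONAL].sum()),
        total=int(items.sum()),
    )


def t_score(totals, ddof: int = 1) -> np.ndarray:
    """Cohort-standardised T-scores: T = 10 Z + 50 with Z from sample mean/sd.

    ``ddof=1`` (sample standard deviation, denominator n-1) is the default;
    set ``ddof=0`` for the population convention.
    """
    totals = np.asarray(totals, dtype=np.float64)
    if totals.ndim != 1 or len(totals) < 2:
        raise ValueError("need at least 2 subjects to standardise totals")
    sd = totals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate cohort: all totals identical (zero standard deviation)")
    z = (totals - totals.mean()) / sd
    return 10.0 * z + 50.0


def label_adhd(t_scores) -> np.ndarray:
    """Binary label: 1 iff T >= 55 (threshold inclusive)."""
    t_scores = np.asarray(t_scores, dtype=np.float64)
    if not np.all(np.isfinite(t_scores)):
        raise ValueError("non-finite T-score")
    return (t_scores >= T_SCORE_THRESHOLD).astype(np.int64)


def impute_missing(frame: pd.DataFrame, categorical_columns=None) -> pd.DataFrame:
    """Fill numeric gaps with the column mean, categorical gaps with the mode.

    Mode ties resolve to the lowest encoded category (logged). A fully missing
    column cannot be imputed and raises.
    """
    frame = frame.copy()
    if categorical_columns is None:
        categorical_columns = ["sex", "grade", "health_state", "diet_state",
                               "parental_education"] + SNAP_ITEM_COLUMNS
    for col in frame.columns:
        if col == "subject_id" or not frame[col].isna().any():
            continue
        observed = frame[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        if col in categorical_columns:
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            if len(top) > 1:
                logger.info("mode tie in %r among %s; using lowest category", col, sorted(top))
            fill = min(top)
        else:
            fill = observed.mean()
        frame[col] = frame[col].fillna(fill)
    return frame


def standardise_features(frame: pd.DataFrame, train_ids, feature_columns=None):
    """Z-score feature columns using *training-subject* statistics only.

    Returns ``(matrix, kept_columns, means, stds)`` where the matrix covers all
    subjects in `frame` order. Zero-variance training columns carry no
    information for the model and are dropped with a warning.
    """
    if feature_columns is None:
        feature_columns = DEFAULT_FEATURE_COLUMNS
    train_ids = set(train_ids)
    if not train_ids:
        raise ValueError("training subject set is empty")
    train_mask = frame["subject_id"].isin(train_ids).to_numpy()
    if not train_mask.any():
        raise ValueError("no rows match the training subject ids")
    X = frame[list(feature_columns)].to_numpy(dtype=np.float64)
    mu = X[train_mask].mean(axis=0)
    sd = X[train_mask].std(axis=0, ddof=1) if train_mask.sum() > 1 else np.zeros(X.shape[1])
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(feature_columns, keep) if not k]
        warnings.warn(f"dropping zero-variance training columns: {dropped}")
    kept_cols = [c for c, k in zip(feature_columns, keep) if k]
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, kept_cols, mu[keep], sd[keep]


def build_cohort_table(frame: pd.DataFrame, train_ids=None, feature_columns=None,
                       ddof: int = 1) -> CohortTable:
    """Impute, score, label and (optionally) standardise a raw clinical table.

    `frame` needs a ``subject_id`` column, the demographic columns and the 26
    ``snap_01..snap_26`` item columns. Labels are computed on the full cohort;
    the feature matrix is standardised with training statistics when
    ``train_ids`` is given (defaults to all subjects, e.g. for exploration).
    """
    missing = [c for c in ["subject_id", *SNAP_ITEM_COLUMNS] if c not in frame.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    frame = impute_missing(frame)
    items = frame[SNAP_ITEM_COLUMNS].to_numpy()
    scores = [score_snapiv(SnapIvResponse(items=row)) for row in np.rint(items).astype(int)]
    frame = frame.copy()
    frame["inattention"] = [s.inattention for s in scores]
    frame["hyperactivity"] = [s.hyperactivity for s in scores]
    frame["oppositional"] = [s.oppositional for s in scores]
    frame["snap_total"] = [s.total for s in scores]
    t = t_score(frame["snap_total"].to_numpy(), ddof=ddof)
    labels = label_adhd(t)
    frame["t_score"] = t
    frame["label"] = labels
    table = CohortTable(frame=frame, t_scores=t, labels=labels)
    if train_ids is None:
        train_ids = frame["subject_id"].tolist()
    Z, cols, mu, sd = standardise_features(frame, train_ids, feature_columns)
    table.feature_matrix = Z
    table.feature_columns = cols
    table.feature_means = mu
    table.feature_stds = sd
    return table
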