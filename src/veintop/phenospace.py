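"""Statistical comparison and classification in fingerprint space.

Networks are compared by the two-sample Kolmogorov–Smirnov statistic D_KS
between their nesting-ratio distributions — a rank-based distance that is
insensitive to network size.  Specimen/species identification uses Linear
Discriminant Analysis on standardized fingerprints with stratified k-fold
cross-validation; standardization statistics are fit on the training folds
only so no information leaks into the held-out fold.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import GEOMETRY_COLUMNS, METRIC_COLUMNS, TOPOLOGY_COLUMNS

logger = logging.getLogger(__name__)

FEATURE_SETS = {
    "geometry": GEOMETRY_COLUMNS,
    "geometry+topology": GEOMETRY_COLUMNS + TOPOLOGY_COLUMNS,
    "topology": TOPOLOGY_COLUMNS,
}


# ---------------------------------------------------------------------------
# KS network distance and retrieval
# ---------------------------------------------------------------------------

def ks_distance(sample_1: Sequence[float], sample_2: Sequence[float]) -> float:
    """sup_x |ECDF1(x) - ECDF2(x)| between two nesting-ratio samples."""
    a, b = np.asarray(sample_1, float), np.asarray(sample_2, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance requires nonempty samples")
    return float(stats.ks_2samp(a, b).statistic)


def nearest_neighbors(
    target_id: str,
    ratio_samples_by_id: dict[str, Sequence[float]],
    k: int = 2,
) -> list[tuple[str, float]]:
    """The k ids whose nesting-ratio distributions are closest to the target
    in D_KS, ranked ascending (ties by id)."""
    if target_id not in ratio_samples_by_id:
        raise KeyError(f"unknown target {target_id!r}")
    others = {i: s for i, s in ratio_samples_by_id.items() if i != target_id}
    if k > len(others):
        raise ValueError(f"k={k} exceeds the {len(others)} available specimens")
    target = ratio_samples_by_id[target_id]
    ranked = sorted(((ks_distance(target, s), i) for i, s in others.items()))
    return [(i, d) for d, i in ranked[:k]]


# ---------------------------------------------------------------------------
# Fingerprint tables
# ---------------------------------------------------------------------------

def load_fingerprint_table(path: str) -> pd.DataFrame:
    """Load a fingerprint table (CSV, or ODS when an odf engine is available).

    Expected columns: ``specimen_id``, ``species`` plus the 8 metrics."""
    path = str(path)
    if path.endswith(".ods"):
        try:
            table = pd.read_excel(path, engine="odf")
        except ImportError as err:
            raise ImportError(
                "reading ODS requires the 'odfpy' package; convert the table "
                "to CSV (same columns) and load that instead"
            ) from err
    else:
        table = pd.read_csv(path)
    return table


def validate_table(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"fingerprint table missing columns {missing}")
    if table[columns].isna().any().any():
        raise ValueError("fingerprint table contains missing values in used columns")


# ---------------------------------------------------------------------------
# PCA of fingerprints
# ---------------------------------------------------------------------------

def pca_fingerprints(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Explained-variance fractions and loadings of the standardized
    fingerprint matrix (equivalently, of its correlation matrix).

    Returns ``(fractions, loadings)`` with one loadings row per component.
    """
    columns = columns or METRIC_COLUMNS
    validate_table(table, columns)
    X = table[columns].to_numpy(float)
    if X.shape[0] < len(columns) + 1:
        raise ValueError("need more rows than metrics for a meaningful PCA")
    sd = X.std(axis=0)
    for c, s in zip(columns, sd):
        if s == 0:
            raise ValueError(f"column {c!r} is constant; drop it before PCA")
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=len(columns)).fit(Z)
    loadings = pd.DataFrame(
        pca.components_,
        index=[f"PC{i + 1}" for i in range(len(columns))],
        columns=columns,
    )
    return pca.explained_variance_ratio_, loadings


# ---------------------------------------------------------------------------
# LDA identification
# ---------------------------------------------------------------------------

def _label_column(table: pd.DataFrame, label: str) -> str:
    if label in table.columns:
        return label
    alias = {"specimen": "specimen_id", "species": "species"}
    col = alias.get(label, label)
    if col not in table.columns:
        raise ValueError(f"no label column for {label!r}")
    return col


def lda_cv(
    table: pd.DataFrame,
    label: str = "specimen",
    feature_set: str = "geometry+topology",
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold accuracies of LDA identification under stratified k-fold CV.

    Classes with fewer rows than folds are dropped (with a warning) so each
    fold sees every class; features are standardized with train-fold
    statistics inside the pipeline.
    """
    columns = FEATURE_SETS[feature_set]
    validate_table(table, columns)
    col = _label_column(table, label)
    y_all = table[col].astype(str)
    counts = y_all.value_counts()
    keep = counts[counts >= folds].index
    dropped = len(counts) - len(keep)
    if dropped:
        logger.warning("dropping %d classes with fewer than %d rows", dropped, folds)
    sub = table[y_all.isin(keep)]
    y = sub[col].astype(str).to_numpy()
    if len(set(y)) < 2:
        raise ValueError("classification requires at least two usable classes")
    X = sub[columns].to_numpy(float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
        clf.fit(X[train], y[train])
        accs.append(float((clf.predict(X[test]) == y[test]).mean()))
    return np.array(accs)


def pairwise_lda(
    table: pd.DataFrame,
    label: str = "specimen",
    feature_set: str = "geometry+topology",
    folds: int = 10,
    seed: int = 0,
    return_matrix: bool = False,
):
    """Mean accuracy of two-class LDA over every unordered pair of labels —
    the probability of correctly attributing a fragment to one of two leaves."""
    col = _label_column(table, label)
    y_all = table[col].astype(str)
    counts = y_all.value_counts()
    classes = sorted(counts[counts >= folds].index)
    if len(classes) < 2:
        raise ValueError("need at least two classes with enough rows")
    result = pd.DataFrame(np.nan, index=classes, columns=classes)
    accs = []
    for a, b in combinations(classes, 2):
        pair = table[y_all.isin([a, b])]
        acc = float(lda_cv(pair, label, feature_set, folds, seed).mean())
        result.loc[a, b] = result.loc[b, a] = acc
        accs.append(acc)
    mean = float(np.mean(accs))
    return (mean, result) if return_matrix else mean


def welch_t(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch–Satterthwaite df, and the
    two-sided p value."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t requires at least two values per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
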