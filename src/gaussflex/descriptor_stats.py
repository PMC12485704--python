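"""Descriptor normalization, PCA, structural clustering and composition summaries.

Descriptor matrices are scaled to unit variance per component (no centering
in the network input path; PCA centers internally).  The two leading
principal components are clustered with k-means (k = 4 by default) and each
cluster is summarized by its dominant-secondary-structure and flexibility
composition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SkPCA

from .dynamics import FLEXIBLE
from .errors import DataError, JoinError, ParameterError
from .structure_io import SecondaryStructureAnnotation

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Unit-variance scaled descriptor matrix with its fitted scaler."""

    ids: list
    X: np.ndarray
    scaler: np.ndarray  # per-column standard deviations used for scaling

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if len(self.ids) != self.X.shape[0]:
            raise ParameterError("ids and matrix row count mismatch")


def normalize_features(
    X, ids=None, mode: str = "fit", scaler=None
) -> FeatureMatrix:
    """Scale each column to unit variance (division by its sd, no centering).

    ``mode="fit"`` estimates per-column standard deviations; ``mode="apply"``
    reuses a previously fitted ``scaler``.  Zero-variance columns are left
    unscaled with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError(f"feature matrix must be 2-D, got shape {X.shape}")
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise DataError(f"non-finite feature value at row {r}, column {c}")
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    if mode == "fit":
        if X.shape[0] < 2:
            raise ParameterError("fitting the scaler needs >= 2 rows")
        sd = X.std(axis=0, ddof=0)
        zero = sd == 0.0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} constant column(s) left unscaled: "
                f"{np.nonzero(zero)[0].tolist()}",
                stacklevel=2,
            )
            sd = np.where(zero, 1.0, sd)
    elif mode == "apply":
        if scaler is None:
            raise ParameterError("mode='apply' requires a fitted scaler")
        sd = np.asarray(scaler, dtype=float)
        if sd.shape != (X.shape[1],):
            raise ParameterError("scaler length does not match column count")
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return FeatureMatrix(ids=list(ids), X=X / sd, scaler=sd)


@dataclass
class PCAResult:
    """Scores, orthonormal loadings and explained-variance ratios."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(Xn: FeatureMatrix, k: int) -> PCAResult:
    """Centered SVD-based PCA of the scaled feature matrix.

    Column signs are fixed by making each loading's largest-magnitude entry
    positive, so the decomposition is deterministic.
    """
    X = np.asarray(getattr(Xn, "X", Xn), dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ParameterError(f"k={k} out of range for matrix {X.shape}")
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # (p, k)
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        mean=model.mean_.copy(),
    )


@dataclass
class ClusterAssignment:
    """Cluster labels in 1..k, renumbered by descending cluster size."""

    ids: list
    labels: np.ndarray
    k: int
    seed: int
    algorithm: str = "kmeans"

    def as_dict(self) -> dict:
        return {i: int(l) for i, l in zip(self.ids, self.labels)}


def cluster_scores(
    pca_result: PCAResult, ids=None, k: int = 4, seed: int = 0
) -> ClusterAssignment:
    """k-means on the first two PC scores, 10 restarts, labels 1..k by size.

    Renumbering by descending cluster size (ties by original k-means label)
    makes the labeling deterministic given the data and seed.
    """
    scores = pca_result.scores[:, : min(2, pca_result.scores.shape[1])]
    n = scores.shape[0]
    if n < k:
        raise ParameterError(f"cannot form {k} clusters from {n} points")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if k == 1:
        return ClusterAssignment(ids=list(ids), labels=np.ones(n, dtype=int), k=1, seed=seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(scores)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")  # largest first
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return ClusterAssignment(
        ids=list(ids), labels=remap[raw], k=k, seed=seed
    )


def majority_secondary_structure(ann: SecondaryStructureAnnotation) -> str:
    """Dominant secondary-structure class by residue count.

    Ties are broken by the fixed priority helix > sheet > coil.
    """
    counts = {"helix": 0, "sheet": 0, "coil": 0}
    for c in ann.classes:
        counts[c] += 1
    best = max(counts, key=lambda c: (counts[c], -["helix", "sheet", "coil"].index(c)))
    tied = [c for c, v in counts.items() if v == counts[best]]
    if len(tied) > 1:
        logger.info("secondary-structure tie %s resolved to %s", tied, best)
    return best


def cluster_composition(
    assign: ClusterAssignment,
    dominant: dict,
    labels: dict,
    rmsf_values: dict | None = None,
) -> pd.DataFrame:
    """Per-cluster composition: dominant-class fractions, flexible fraction, median RMSF.

    ``dominant`` maps id -> {helix, sheet, coil}; ``labels`` maps id ->
    flexibility label.  Fractions sum to 1 per cluster per facet.
    """
    ids = set(assign.ids)
    for name, mapping in (("dominant", dominant), ("labels", labels)):
        missing = sorted(ids - set(mapping))[:10]
        if missing:
            raise JoinError(f"{name} map lacks ids {missing}")
    if not ids:
        raise JoinError("empty id set")
    rows = []
    members = {}
    for pid, cl in zip(assign.ids, assign.labels):
        members.setdefault(int(cl), []).append(pid)
    for cl in sorted(members):
        group = members[cl]
        n = len(group)
        row = {"cluster": cl, "n": n}
        for ss in ("helix", "sheet", "coil"):
            row[f"frac_{ss}"] = sum(dominant[p] == ss for p in group) / n
        row["frac_flexible"] = sum(labels[p] == FLEXIBLE for p in group) / n
        row["frac_non_flexible"] = 1.0 - row["frac_flexible"]
        if rmsf_values is not None:
            row["median_rmsf"] = float(np.median([rmsf_values[p] for p in group]))
        rows.append(row)
    return pd.DataFrame(rows)
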