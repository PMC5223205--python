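"""Transforms, dissimilarities and ordinations shared by the pipelines.

The hydrology pipeline ordinates standardized cycle x metric tables with PCA;
the assemblage pipeline ordinates square-root transformed CPUE through
Bray-Curtis dissimilarity and principal coordinates (PCoA), and
Hellinger-transformed functional-group tables through centred PCA.  Axis
retention uses the broken-stick null expectation, with a largest-drop scree
elbow reported alongside.

Both ordinations use a deterministic sign convention (the largest-magnitude
loading — or coordinate, for PCoA — on each axis is positive) so repeated
runs agree across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "OrdinationResult",
    "sqrt_transform",
    "hellinger_transform",
    "bray_curtis",
    "pca",
    "pcoa",
    "broken_stick",
    "broken_stick_thresholds",
    "scree_elbow",
    "retain_axes",
]


@dataclass
class OrdinationResult:
    """Scores, loadings (PCA only) and eigenvalue spectrum of an ordination."""

    scores: pd.DataFrame                 # objects x axes
    eigenvalues: np.ndarray              # descending
    proportion_explained: np.ndarray
    loadings: pd.DataFrame | None = None  # variables x axes (PCA)
    negative_eigenvalue_share: float = 0.0  # |sum of negatives| / sum |all| (PCoA)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _as_array(matrix) -> tuple[np.ndarray, list, list]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def sqrt_transform(matrix):
    """Elementwise square root, damping the influence of abundant species."""
    arr, _, _ = _as_array(matrix)
    if (arr < 0).any():
        raise ValueError("sqrt transform requires non-negative entries")
    out = np.sqrt(arr)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def hellinger_transform(matrix):
    """Square root of row-relative abundances.

    Rows are objects (cycles), columns species or groups.  Every nonzero row
    of the result has unit sum of squares, which makes Euclidean-based
    ordination appropriate for composition data.  All-zero rows map to
    all-zero rows with a warning.
    """
    arr, _, _ = _as_array(matrix)
    if (arr < 0).any():
        raise ValueError("Hellinger transform requires non-negative entries")
    row_sums = arr.sum(axis=1, keepdims=True)
    zero_rows = row_sums[:, 0] == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero rows left at zero",
                      stacklevel=2)
    safe = np.where(row_sums == 0, 1.0, row_sums)
    out = np.sqrt(arr / safe)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), in [0, 1].

    A pair of all-zero rows is assigned distance 0 with a warning (no shared
    or unshared abundance to compare).
    """
    arr, index, _ = _as_array(matrix)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    zero_rows = arr.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(arr, metric="braycurtis"))
    if np.isnan(dm).any():
        warnings.warn("distance between all-zero rows set to 0", stacklevel=2)
        dm = np.nan_to_num(dm, nan=0.0)
    if zero_rows.any() and not np.isnan(dm).any():
        pass  # scipy already yielded NaN handled above; nothing else to do
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=index, columns=index)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(matrix, center: bool = True, scale: bool = False) -> OrdinationResult:
    """Principal components analysis via singular value decomposition.

    Eigenvalues are the variances (n-1 denominator) of the scores, sorted
    descending.  ``scale=True`` divides each column by its sample standard
    deviation; a constant column is then dropped with a warning.  The sign of
    each axis is fixed so its largest-magnitude loading is positive.
    """
    arr, index, columns = _as_array(matrix)
    n, p = arr.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 objects and 2 variables")
    X = arr - arr.mean(axis=0) if center else arr.astype(float).copy()
    kept = list(range(p))
    if scale:
        sd = arr.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            dropped = [columns[j] for j in np.flatnonzero(const)]
            warnings.warn(f"dropping constant columns under scale=True: {dropped}",
                          stacklevel=2)
            kept = [j for j in range(p) if not const[j]]
            X = X[:, kept]
            sd = sd[kept]
        X = X / sd
    cols = [columns[j] for j in kept]

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    V = _fix_signs(Vt.T)
    scores = X @ V
    total = eigenvalues.sum()
    prop = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    axes = [f"PC{i + 1}" for i in range(len(eigenvalues))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=index, columns=axes),
        eigenvalues=eigenvalues,
        proportion_explained=prop,
        loadings=pd.DataFrame(V, index=cols, columns=axes),
    )


def pcoa(dissimilarity) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-centres -D^2/2, eigendecomposes, and returns coordinates
    eigenvector * sqrt(eigenvalue) for the positive eigenvalues.  Negative
    eigenvalues (possible for non-Euclidean dissimilarities like Bray-Curtis)
    are reported through ``negative_eigenvalue_share``; no Lingoes/Cailliez
    correction is applied.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        index = list(dissimilarity.index)
        D = dissimilarity.to_numpy(dtype=float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        index = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    pos = eigval > tol
    neg_sum = float(-eigval[eigval < -tol].sum())
    abs_total = float(np.abs(eigval).sum())
    coords = _fix_signs(eigvec[:, pos]) * np.sqrt(eigval[pos])
    pos_eig = eigval[pos]
    total = pos_eig.sum() + neg_sum
    prop = pos_eig / total if total > 0 else np.zeros_like(pos_eig)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(coords, index=index, columns=axes),
        eigenvalues=pos_eig,
        proportion_explained=prop,
        negative_eigenvalue_share=neg_sum / abs_total if abs_total > 0 else 0.0,
    )


def broken_stick_thresholds(p: int) -> np.ndarray:
    """Broken-stick expected proportions b_k = (1/p) * sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading axes whose variance share beats the broken stick.

    Axes are retained while their proportion of total variance exceeds the
    broken-stick expectation; retention stops at the first failure.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if (ev < -1e-12).any():
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be sorted descending")
    total = ev.sum()
    if total <= 0:
        return 0
    props = ev / total
    thresholds = broken_stick_thresholds(len(ev))
    k = 0
    for prop, b in zip(props, thresholds):
        if prop > b:
            k += 1
        else:
            break
    return k


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Scree criterion: retain axes up to the largest successive eigenvalue drop."""
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 2:
        return len(ev)
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops)) + 1


def retain_axes(eigenvalues: np.ndarray) -> int:
    """Axes to keep for interpretation: broken stick, falling back to the scree
    elbow only when the broken stick retains none (they adjudicate jointly in
    practice; the broken stick takes precedence when they disagree)."""
    bs = broken_stick(eigenvalues)
    return bs if bs > 0 else min(scree_elbow(eigenvalues), 1)
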