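"""Correlation, adjacency, topological-overlap and dissimilarity matrices.

The network is built feature-by-feature from standardized abundance data:
pairwise correlation -> soft-thresholded adjacency (``|r|^beta`` for the
unsigned default) -> topological overlap (direct link plus shared-neighbor
weight) -> dissimilarity ``1 - overlap`` for hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .data import ScaledMatrix
from .errors import InputError

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "DissimilarityMatrix",
    "correlation_matrix",
    "adjacency",
    "topological_overlap",
    "dissimilarity",
    "soft_threshold_diagnostic",
]

_SYM_TOL = 1e-10


def _validate_square(values: np.ndarray, feature_ids: list[str], what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(feature_ids)
    if values.shape != (n, n):
        raise InputError(f"{what} must be {n}x{n} to match its feature ids")
    if not np.all(np.isfinite(values)):
        raise InputError(f"{what} contains non-finite entries")
    if np.abs(values - values.T).max(initial=0.0) > _SYM_TOL:
        raise InputError(f"{what} is not symmetric")
    return values


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    feature_ids: list[str]
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = _validate_square(self.values, self.feature_ids, "correlation matrix")
        if np.any(self.values < -1 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise InputError("correlation entries must lie in [-1, 1]")
        if np.abs(np.diag(self.values) - 1).max(initial=0.0) > 1e-9:
            raise InputError("correlation diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    feature_ids: list[str]
    power: float = 6.0
    sign_mode: str = "unsigned"

    def __post_init__(self) -> None:
        self.values = _validate_square(self.values, self.feature_ids, "adjacency matrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise InputError("adjacency entries must lie in [0, 1]")
        if np.abs(np.diag(self.values) - 1).max(initial=0.0) > 1e-9:
            raise InputError("adjacency diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class TOMMatrix:
    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _validate_square(self.values, self.feature_ids, "TOM matrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise InputError("TOM entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _validate_square(self.values, self.feature_ids, "dissimilarity matrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise InputError("dissimilarity entries must lie in [0, 1]")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-9:
            raise InputError("dissimilarity diagonal must be 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


def correlation_matrix(x: ScaledMatrix, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise feature correlation (Pearson default, Spearman optional).

    Exact symmetry is enforced by averaging with the transpose; entries are
    clipped to [-1, 1] and the diagonal set to 1.  Constant features must be
    removed beforehand (their correlation is undefined).
    """
    if x.n_samples < 3:
        raise InputError("correlation needs at least 3 samples")
    sd = x.values.std(axis=0, ddof=1)
    const = np.where(sd <= 1e-12)[0]
    if const.size:
        raise InputError(
            f"constant feature {x.feature_ids[const[0]]!r}: correlation undefined; "
            "drop constant features first (ScaledMatrix.drop_constant)"
        )
    if method == "pearson":
        c = np.corrcoef(x.values, rowvar=False)
    elif method == "spearman":
        c, _ = sp_stats.spearmanr(x.values)
        c = np.atleast_2d(c)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    c = (c + c.T) / 2.0
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(values=c, feature_ids=list(x.feature_ids), method=method)


def adjacency(
    c: CorrelationMatrix, power: float = 6.0, sign_mode: str = "unsigned"
) -> AdjacencyMatrix:
    """Soft-threshold correlations into connection strengths in [0, 1].

    unsigned: ``a_ij = |r_ij|**power``; signed: ``a_ij = ((1 + r_ij)/2)**power``.
    The diagonal is set to 1.
    """
    if power <= 0:
        raise InputError(f"soft-threshold power must be positive, got {power}")
    if sign_mode == "unsigned":
        a = np.abs(c.values) ** power
    elif sign_mode == "signed":
        a = ((1.0 + c.values) / 2.0) ** power
    else:
        raise InputError(f"sign_mode must be 'unsigned' or 'signed', got {sign_mode!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(
        values=a, feature_ids=list(c.feature_ids), power=power, sign_mode=sign_mode
    )


def topological_overlap(a: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: direct link weight plus shared-neighbor weight.

    For i != j::

        omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with ``l_ij = sum_{u != i,j} a_iu * a_uj`` and node connectivity
    ``k_i = sum_{u != i} a_iu``; the diagonal is 1.
    """
    av = a.values
    n = av.shape[0]
    k = av.sum(axis=0) - np.diag(av)  # off-diagonal row sums
    # l_ij over u != i, j: subtract the u = i and u = j terms (diag of a is 1)
    l = av @ av - av * np.diag(av)[:, None] - av * np.diag(av)[None, :]
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - av
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + av) / denom
    omega[denom <= 0] = 0.0
    omega = (omega + omega.T) / 2.0
    np.clip(omega, 0.0, 1.0, out=omega)
    np.fill_diagonal(omega, 1.0)
    return TOMMatrix(values=omega, feature_ids=list(a.feature_ids))


def dissimilarity(t: TOMMatrix) -> DissimilarityMatrix:
    """Elementwise ``1 - omega``, diagonal forced to 0."""
    d = 1.0 - t.values
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return DissimilarityMatrix(values=d, feature_ids=list(t.feature_ids))


def soft_threshold_diagnostic(
    c: CorrelationMatrix,
    powers: list[float] | None = None,
    sign_mode: str = "unsigned",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Report-only scale-free fit diagnostic over a power sweep.

    For each power, computes node connectivities and the R^2 of the
    log-log regression of the binned connectivity distribution.  This is a
    diagnostic table; it is never used to choose the power automatically.
    """
    if powers is None:
        powers = [1, 2, 3, 4, 5, 6, 7, 8, 10, 12]
    rows = []
    for p in powers:
        a = adjacency(c, power=float(p), sign_mode=sign_mode)
        k = a.values.sum(axis=0) - 1.0
        rows.append(
            {
                "power": float(p),
                "scale_free_r2": _scale_free_r2(k, n_bins=n_bins),
                "mean_k": float(k.mean()),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return float("nan")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    centers, freqs = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.any():
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(freqs))
    if x.size < 3 or np.allclose(x, x[0]):
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
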