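"""Comparison methods: PCA with loading screening and a batch-learning SOM.

PCA summarizes samples; the SOM places *features* (metabolites) on a 2-D
lattice so that similar expression profiles land in the same or adjacent
cells, and supports +/- 1 standard-deviation heat-map contrasts between a
sample and the population mean (or between two samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ScaledMatrix
from .errors import InputError

__all__ = [
    "PCAResult",
    "SOMGrid",
    "CellComparison",
    "pca",
    "top_loadings",
    "blsom_fit",
    "blsom_compare",
]

CATEGORIES = ("strong-down", "weak-down", "neutral", "weak-up", "strong-up")


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # features x components
    variance_explained: np.ndarray    # fractions, non-increasing

    def __post_init__(self) -> None:
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise InputError("variance fractions must be non-increasing")
        if self.variance_explained.sum() > 1 + 1e-9:
            raise InputError("variance fractions must sum to <= 1")


def pca(x: ScaledMatrix, n_components: int | None = None) -> PCAResult:
    """SVD principal component analysis of the column-centered matrix.

    Sign convention: within each component, the largest-magnitude loading is
    made positive (first index on ties), so results are deterministic.
    """
    if x.n_samples < 2 or x.n_features < 2:
        raise InputError("PCA needs at least 2 samples and 2 features")
    centered = x.values - x.values.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise InputError("degenerate all-zero matrix")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    fractions = s**2 / total
    k = len(s) if n_components is None else min(n_components, len(s))
    # deterministic sign: largest |loading| positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=list(x.sample_ids), columns=comp_names
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=list(x.feature_ids), columns=comp_names
    )
    return PCAResult(scores=scores, loadings=loadings, variance_explained=fractions[:k])


def top_loadings(
    p: PCAResult,
    component: str | int,
    pos_threshold: float,
    neg_threshold: float,
) -> dict[str, str]:
    """Features loading above ``pos_threshold`` ("+") or below
    ``neg_threshold`` ("-") on a component."""
    if isinstance(component, int):
        component = f"PC{component}"
    if component not in p.loadings.columns:
        raise InputError(f"unknown component {component!r}")
    col = p.loadings[component]
    out: dict[str, str] = {}
    for feat, v in col.items():
        if v > pos_threshold:
            out[feat] = "+"
        elif v < neg_threshold:
            out[feat] = "-"
    return out


@dataclass
class SOMGrid:
    rows: int
    cols: int
    references: np.ndarray            # (rows * cols, n_samples)
    assignment: dict[str, tuple[int, int]]
    sample_ids: list[str] = field(default_factory=list)

    def cell_members(self) -> dict[tuple[int, int], list[str]]:
        out: dict[tuple[int, int], list[str]] = {}
        for f, cell in self.assignment.items():
            out.setdefault(cell, []).append(f)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Cell -> comma-joined member list (mirrors a lattice figure)."""
        grid = [["" for _ in range(self.cols)] for _ in range(self.rows)]
        for (r, c), members in self.cell_members().items():
            grid[r][c] = ",".join(members)
        return pd.DataFrame(grid)


def _default_side(n_features: int) -> int:
    return max(2, math.ceil(math.sqrt(5.0 * math.sqrt(n_features))))


def blsom_fit(
    x: ScaledMatrix,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 100,
    seed: int = 0,
) -> SOMGrid:
    """Batch-learning SOM over feature expression profiles.

    Each feature is a vector over samples.  Reference vectors are
    initialized on the plane spanned by the feature cloud's first two
    principal axes; each epoch assigns all features to their nearest
    reference (Euclidean) and replaces every reference by the Gaussian
    neighborhood-weighted mean of the assigned features.  The neighborhood
    radius shrinks linearly to zero, so the final epochs behave like
    k-means on the lattice.  Batch updates make the result independent of
    feature order; ``seed`` only breaks exact assignment ties.
    """
    n_feat = x.n_features
    if n_feat < 2:
        raise InputError("SOM needs at least 2 features")
    if rows is None:
        rows = _default_side(n_feat)
    if cols is None:
        cols = _default_side(n_feat)
    if rows * cols < 2:
        raise InputError("lattice must have at least 2 cells")
    if rows * cols > 4 * n_feat:
        import warnings

        warnings.warn(
            f"lattice has {rows * cols} cells for only {n_feat} features",
            stacklevel=2,
        )

    feats = x.values.T  # (n_features, n_samples)
    mean = feats.mean(axis=0)
    centered = feats - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic axis orientation (sample space, so permutation-invariant)
    for c in range(min(2, vt.shape[0])):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
    sd = s / math.sqrt(max(n_feat - 1, 1))
    axis1 = vt[0] * (sd[0] if len(sd) > 0 else 1.0)
    axis2 = vt[1] * (sd[1] if len(sd) > 1 else 0.0)
    r_coords = np.linspace(-2, 2, rows) if rows > 1 else np.zeros(1)
    c_coords = np.linspace(-2, 2, cols) if cols > 1 else np.zeros(1)
    refs = (
        mean[None, None, :]
        + r_coords[:, None, None] * axis1[None, None, :]
        + c_coords[None, :, None] * axis2[None, None, :]
    ).reshape(rows * cols, -1)

    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    lattice_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)
    r0 = max(rows, cols) / 2.0

    rng = np.random.default_rng(seed)
    tie_jitter = rng.uniform(0, 1e-12, size=rows * cols)

    bmu = np.zeros(n_feat, dtype=int)
    for t in range(epochs):
        radius = r0 * (1.0 - t / max(epochs - 1, 1))
        d2 = ((feats[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2 + tie_jitter[None, :], axis=1)
        if radius > 1e-9:
            h = np.exp(-lattice_d2 / (2.0 * radius**2))  # (cells, cells)
        else:
            h = np.eye(rows * cols)
        w = h[:, bmu]  # (cells, n_features)
        denom = w.sum(axis=1)
        upd = w @ feats
        nonzero = denom > 0
        refs[nonzero] = upd[nonzero] / denom[nonzero, None]

    assignment = {
        f: (int(b // cols), int(b % cols)) for f, b in zip(x.feature_ids, bmu)
    }
    return SOMGrid(
        rows=rows,
        cols=cols,
        references=refs,
        assignment=assignment,
        sample_ids=list(x.sample_ids),
    )


@dataclass
class CellComparison:
    categories: pd.DataFrame          # rows x cols of category strings
    empty_cells: list[tuple[int, int]]
    left: str
    right: str


def blsom_compare(
    g: SOMGrid,
    x: ScaledMatrix,
    left: str = "mean",
    right: str = "mean",
) -> CellComparison:
    """Categorize each lattice cell for a left-minus-right contrast.

    ``left``/``right`` are sample ids or the string ``"mean"`` (population
    mean profile).  Per metabolite the contrast is compared against that
    metabolite's population standard deviation; the cell reports the
    category of its largest-magnitude member contrast: beyond +1 SD ->
    strong-up, within (0, +1 SD] -> weak-up, and symmetrically down.  Cells
    with no members are neutral and flagged.
    """
    frame = x.to_frame()

    def profile(which: str) -> pd.Series:
        if which == "mean":
            return frame.mean(axis=0)
        if which not in frame.index:
            raise InputError(f"unknown sample {which!r}")
        return frame.loc[which]

    lv, rv = profile(left), profile(right)
    sd = frame.std(axis=0, ddof=1)
    contrast = (lv - rv).to_numpy()
    sd_arr = sd.to_numpy()
    feat_index = {f: i for i, f in enumerate(frame.columns)}

    members = g.cell_members()
    cats = [["neutral" for _ in range(g.cols)] for _ in range(g.rows)]
    empty: list[tuple[int, int]] = []
    for r in range(g.rows):
        for c in range(g.cols):
            cell = (r, c)
            if cell not in members or not members[cell]:
                empty.append(cell)
                continue
            idx = [feat_index[f] for f in members[cell]]
            deltas = contrast[idx]
            scales = np.where(sd_arr[idx] > 0, sd_arr[idx], 1.0)
            rel = deltas / scales
            j = int(np.argmax(np.abs(rel)))
            v = rel[j]
            if abs(v) < 1e-12:
                cats[r][c] = "neutral"
            elif v > 1:
                cats[r][c] = "strong-up"
            elif v > 0:
                cats[r][c] = "weak-up"
            elif v < -1:
                cats[r][c] = "strong-down"
            else:
                cats[r][c] = "weak-down"
    return CellComparison(
        categories=pd.DataFrame(cats),
        empty_cells=empty,
        left=left,
        right=right,
    )
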