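"""Fundamental weighted-network statistics at node and module level.

Node level: connectivity k (sum of off-diagonal connection strengths),
scaled connectivity K = k / max(k), maximum adjacency ratio MAR, and the
weighted clustering coefficient C.  Module level: density, centralization
and heterogeneity of the module's induced subnetwork.

All statistics are computed on the adjacency matrix by default.  Node
statistics use the full network; module statistics use induced submatrices.
Both scopes are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .modules import GREY, ModuleAssignment
from .network import AdjacencyMatrix, TOMMatrix

__all__ = [
    "ModuleStats",
    "node_connectivity",
    "scaled_connectivity",
    "max_adjacency_ratio",
    "clustering_coefficient",
    "node_stats_table",
    "module_stats",
    "module_stats_table",
]


def _offdiag(a: AdjacencyMatrix | TOMMatrix | np.ndarray) -> np.ndarray:
    values = a.values if hasattr(a, "values") else np.asarray(a, dtype=float)
    out = values.copy()
    np.fill_diagonal(out, 0.0)
    return out


def node_connectivity(a: AdjacencyMatrix | TOMMatrix) -> np.ndarray:
    """k_i = sum of off-diagonal connection strengths of node i."""
    return _offdiag(a).sum(axis=1)


def scaled_connectivity(k: np.ndarray) -> np.ndarray:
    """K_i = k_i / max(k); the most connected node gets K = 1."""
    k = np.asarray(k, dtype=float)
    kmax = k.max(initial=0.0)
    if kmax <= 0:
        raise InputError("scaled connectivity undefined: all connectivities are 0")
    return k / kmax


def max_adjacency_ratio(a: AdjacencyMatrix | TOMMatrix) -> np.ndarray:
    """MAR_i = sum_j a_ij^2 / sum_j a_ij (off-diagonal sums).

    High for few strong connections, low for many weak ones; NaN for
    isolated nodes (k = 0).
    """
    off = _offdiag(a)
    k = off.sum(axis=1)
    num = (off**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mar = np.where(k > 0, num / np.where(k > 0, k, 1.0), np.nan)
    return mar


def clustering_coefficient(a: AdjacencyMatrix | TOMMatrix) -> np.ndarray:
    """Weighted clustering coefficient.

    C_i = sum_{j != i} sum_{q != i,j} a_ij a_jq a_qi / (k_i^2 - sum_j a_ij^2),
    defined as 0 where the denominator vanishes.
    """
    off = _offdiag(a)
    k = off.sum(axis=1)
    tri = np.diag(off @ off @ off)  # closed weighted triangles through i
    denom = k**2 - (off**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def node_stats_table(
    a: AdjacencyMatrix | TOMMatrix,
    assign: ModuleAssignment | None = None,
    scope: str = "network",
) -> pd.DataFrame:
    """Per-feature k, K, C and MAR.

    ``scope="network"`` (default) evaluates every statistic on the full
    matrix; ``scope="module"`` evaluates each node's statistics on its
    module's induced submatrix (grey nodes get NaN).
    """
    ids = list(a.feature_ids)
    module_col = (
        [assign.labels.get(f, GREY) for f in ids] if assign is not None else [GREY] * len(ids)
    )
    if scope == "network":
        k = node_connectivity(a)
        table = pd.DataFrame(
            {
                "module": module_col,
                "k": k,
                "K": scaled_connectivity(k),
                "C": clustering_coefficient(a),
                "MAR": max_adjacency_ratio(a),
            },
            index=ids,
        )
    elif scope == "module":
        if assign is None:
            raise InputError("scope='module' requires a module assignment")
        table = pd.DataFrame(
            np.nan, index=ids, columns=["k", "K", "C", "MAR"]
        )
        table.insert(0, "module", module_col)
        idx = {f: i for i, f in enumerate(ids)}
        for m in assign.module_names:
            members = assign.members(m)
            sel = [idx[f] for f in members]
            sub = a.values[np.ix_(sel, sel)]
            sub_adj = _offdiag(sub)
            k = sub_adj.sum(axis=1)
            table.loc[members, "k"] = k
            table.loc[members, "K"] = k / k.max() if k.max() > 0 else np.nan
            # reuse the vectorized forms on the submatrix
            tri = np.diag(sub_adj @ sub_adj @ sub_adj)
            denom = k**2 - (sub_adj**2).sum(axis=1)
            table.loc[members, "C"] = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
            table.loc[members, "MAR"] = np.where(k > 0, (sub_adj**2).sum(axis=1) / np.where(k > 0, k, 1.0), np.nan)
    else:
        raise InputError(f"scope must be 'network' or 'module', got {scope!r}")
    table.index.name = "feature"
    return table


@dataclass
class ModuleStats:
    module: str
    node_count: int
    density: float
    centralization: float | None  # None when undefined (n = 2)
    heterogeneity: float


def module_stats(
    a: AdjacencyMatrix | TOMMatrix, assign: ModuleAssignment, module: str
) -> ModuleStats:
    """Density, centralization and heterogeneity of a module's subnetwork.

    density = sum_{i != j} a_ij / (n (n - 1));
    centralization = (n / (n - 2)) * (max(k) / (n - 1) - density) for n > 2;
    heterogeneity = sqrt(mean(k^2) / mean(k)^2 - 1) (population CV of k).
    All from the module's induced submatrix.
    """
    members = assign.members(module)
    n = len(members)
    if n < 2:
        raise InputError(f"module {module!r} has {n} member(s); need >= 2")
    idx = {f: i for i, f in enumerate(a.feature_ids)}
    sel = [idx[f] for f in members]
    sub = _offdiag(a.values[np.ix_(sel, sel)])
    k = sub.sum(axis=1)
    density = float(sub.sum() / (n * (n - 1)))
    if n > 2:
        centralization = float((n / (n - 2)) * (k.max() / (n - 1) - density))
    else:
        centralization = None
    mean_k = k.mean()
    if mean_k > 0:
        heterogeneity = float(np.sqrt(max((k**2).mean() / mean_k**2 - 1.0, 0.0)))
    else:
        heterogeneity = 0.0
    return ModuleStats(
        module=module,
        node_count=n,
        density=density,
        centralization=centralization,
        heterogeneity=heterogeneity,
    )


def module_stats_table(
    a: AdjacencyMatrix | TOMMatrix, assign: ModuleAssignment
) -> pd.DataFrame:
    rows = []
    for m in assign.module_names:
        s = module_stats(a, assign, m)
        rows.append(
            {
                "module": s.module,
                "node_count": s.node_count,
                "density": s.density,
                "centralization": np.nan if s.centralization is None else s.centralization,
                "heterogeneity": s.heterogeneity,
            }
        )
    return pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["node_count", "density", "centralization", "heterogeneity"]
    )
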