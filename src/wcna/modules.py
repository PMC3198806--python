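"""Hierarchical clustering of the dissimilarity matrix and module cutting.

Features are clustered by average-linkage agglomeration of the TOM
dissimilarity; a static cut of the dendrogram yields clusters, clusters
smaller than ``min_module_size`` are relabeled "grey" (unassigned), and the
surviving modules are renamed along a conventional color sequence in
descending size order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError
from .network import DissimilarityMatrix, TOMMatrix

__all__ = [
    "GREY",
    "COLOR_SEQUENCE",
    "Dendrogram",
    "ModuleAssignment",
    "hierarchical_cluster",
    "cut_modules",
    "assign_colors",
]

GREY = "grey"

# conventional module palette, ordered; applied by descending module size
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage encoding."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise InputError(
                f"linkage must have {n - 1} merges for {n} leaves"
            )

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.heights.max()) if len(self.heights) else 0.0

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage,
            columns=["left", "right", "height", "size"],
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                name = self.leaf_ids[node.id].replace(" ", "_")
                return f"{name}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


@dataclass
class ModuleAssignment:
    """Feature -> module label map; the reserved label "grey" = unassigned."""

    labels: dict[str, str]
    min_module_size: int = 2

    def __post_init__(self) -> None:
        if not self.labels:
            raise InputError("empty module assignment")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def module_names(self) -> list[str]:
        """Non-grey module labels in descending size order (first-feature tiebreak)."""
        order: dict[str, int] = {}
        sizes: dict[str, int] = {}
        for i, (f, lab) in enumerate(self.labels.items()):
            if lab == GREY:
                continue
            sizes[lab] = sizes.get(lab, 0) + 1
            order.setdefault(lab, i)
        return sorted(sizes, key=lambda m: (-sizes[m], order[m]))

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, module: str) -> list[str]:
        return [f for f, lab in self.labels.items() if lab == module]

    def size(self, module: str) -> int:
        return len(self.members(module))

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="module")

    def write_tsv(self, path: str | Path) -> None:
        self.to_series().rename_axis("feature").to_csv(path, sep="\t")


def hierarchical_cluster(
    d: DissimilarityMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of the feature dissimilarity matrix.

    Ties are resolved deterministically by scipy's ordering (lowest cluster
    index first).
    """
    n = len(d.feature_ids)
    if n < 2:
        raise InputError("clustering needs at least 2 features")
    condensed = squareform(d.values, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage=z, leaf_ids=list(d.feature_ids))


def cut_modules(
    dend: Dendrogram,
    cut_height: float | None = None,
    min_module_size: int = 3,
    method: str = "static",
    tom: TOMMatrix | None = None,
    reassign_threshold: float = 0.15,
) -> ModuleAssignment:
    """Cut the dendrogram at a fixed height into modules.

    Clusters of size < ``min_module_size`` are relabeled grey.  With
    ``method="hybrid"`` grey features are subsequently assigned to the
    module with the highest mean topological overlap, provided that mean
    exceeds ``reassign_threshold`` (requires ``tom``).

    Default cut height is 0.95 x the maximum merge height.
    """
    if min_module_size < 2:
        raise InputError("min_module_size must be >= 2")
    if cut_height is None:
        cut_height = 0.95 * dend.max_height
    if not 0 < cut_height <= dend.max_height + 1e-12:
        raise InputError(
            f"cut height {cut_height} outside (0, max merge height "
            f"{dend.max_height}]"
        )
    flat = hierarchy.fcluster(dend.linkage, t=cut_height, criterion="distance")
    labels: dict[str, str] = {}
    counts: dict[int, int] = {}
    for c in flat:
        counts[int(c)] = counts.get(int(c), 0) + 1
    # stable module numbering by first appearance
    renum: dict[int, int] = {}
    for c in flat:
        if counts[int(c)] >= min_module_size and int(c) not in renum:
            renum[int(c)] = len(renum) + 1
    for f, c in zip(dend.leaf_ids, flat):
        if counts[int(c)] >= min_module_size:
            labels[f] = f"module_{renum[int(c)]}"
        else:
            labels[f] = GREY

    if method == "hybrid":
        if tom is None:
            raise InputError("hybrid cut requires the TOM matrix")
        labels = _reassign_by_tom(labels, tom, reassign_threshold)
    elif method != "static":
        raise InputError(f"unknown cut method {method!r}")

    return ModuleAssignment(labels=labels, min_module_size=min_module_size)


def _reassign_by_tom(
    labels: dict[str, str], tom: TOMMatrix, threshold: float
) -> dict[str, str]:
    idx = {f: i for i, f in enumerate(tom.feature_ids)}
    modules = sorted({lab for lab in labels.values() if lab != GREY})
    if not modules:
        return labels
    out = dict(labels)
    for f, lab in labels.items():
        if lab != GREY:
            continue
        best, best_mean = None, -np.inf
        for m in modules:
            members = [g for g, l2 in labels.items() if l2 == m]
            mean_tom = float(
                np.mean([tom.values[idx[f], idx[g]] for g in members])
            )
            if mean_tom > best_mean:
                best, best_mean = m, mean_tom
        if best is not None and best_mean >= threshold:
            out[f] = best
    return out


def assign_colors(
    assign: ModuleAssignment, palette: list[str] | None = None
) -> ModuleAssignment:
    """Rename modules along the color sequence by descending size.

    Ties are broken by first-feature order.  Grey is preserved.  A custom
    palette may be supplied (e.g. to match an existing figure's labels).
    """
    palette = palette or COLOR_SEQUENCE
    names = assign.module_names
    if len(names) > len(palette):
        raise InputError(
            f"{len(names)} modules but only {len(palette)} palette colors"
        )
    mapping = {m: palette[i] for i, m in enumerate(names)}
    mapping[GREY] = GREY
    return ModuleAssignment(
        labels={f: mapping[lab] for f, lab in assign.labels.items()},
        min_module_size=assign.min_module_size,
    )
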