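"""Module eigenmetabolites and their association with categorical traits.

The eigenmetabolite of a module is the first left singular vector of the
module's samples x members submatrix of the standardized data — the
module's typical expression pattern across samples.  Association with a
categorical factor uses one-way fixed-effects ANOVA at a Bonferroni-adjusted
threshold (0.05 / number of detected modules), with pairwise Welch t-tests
feeding a compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .data import ScaledMatrix, TraitTable
from .errors import InputError
from .modules import GREY, ModuleAssignment

__all__ = [
    "Eigenmetabolite",
    "AnovaResult",
    "eigenmetabolite",
    "eigenmetabolite_table",
    "module_trait_anova",
    "compact_letter_display",
]


@dataclass
class Eigenmetabolite:
    module: str
    sample_ids: list[str]
    scores: np.ndarray            # unit-norm sample-length vector
    variance_explained: float     # first singular value^2 / total
    orientation: int              # +1 or -1, sign applied to the raw SVD vector
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise InputError("eigenmetabolite scores must be sample-length")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise InputError("variance_explained must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.module)


@dataclass
class AnovaResult:
    module: str
    factor: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    alpha_adjusted: float
    level_stats: pd.DataFrame     # index = level, columns = [n, mean, se]
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def eigenmetabolite(
    x: ScaledMatrix, assign: ModuleAssignment, module: str
) -> Eigenmetabolite:
    """First principal-component sample profile of a module.

    The score vector is the first left singular vector of the module
    submatrix (unit norm), sign-oriented so that its correlation with the
    module's mean sample profile is non-negative; if that correlation is
    exactly zero the member with the largest absolute loading is made to
    load positively.  ``variance_explained`` is the first squared singular
    value over the total.
    """
    members = assign.members(module)
    if len(members) < 2:
        raise InputError(
            f"module {module!r} has {len(members)} member(s); need >= 2"
        )
    idx = {f: i for i, f in enumerate(x.feature_ids)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise InputError(f"module members absent from data: {missing}")
    sub = x.values[:, [idx[m] for m in members]]
    if np.allclose(sub, 0.0):
        raise InputError(f"module {module!r} submatrix is all zero")

    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    scores = u[:, 0]
    total = float(np.sum(s**2))
    var_explained = float(s[0] ** 2 / total) if total > 0 else 0.0

    mean_profile = sub.mean(axis=1)
    c = float(scores @ mean_profile)
    if c < 0:
        sign = -1
    elif c > 0:
        sign = 1
    else:  # orient by the largest-|loading| member
        j = int(np.argmax(np.abs(vt[0])))
        sign = 1 if vt[0, j] >= 0 else -1
    return Eigenmetabolite(
        module=module,
        sample_ids=list(x.sample_ids),
        scores=sign * scores,
        variance_explained=var_explained,
        orientation=sign,
        member_ids=members,
    )


def eigenmetabolite_table(
    x: ScaledMatrix, assign: ModuleAssignment
) -> pd.DataFrame:
    """Samples x modules table of eigenmetabolite scores (grey excluded)."""
    cols = {}
    for m in assign.module_names:
        cols[m] = eigenmetabolite(x, assign, m).to_series()
    if not cols:
        return pd.DataFrame(index=list(x.sample_ids))
    return pd.DataFrame(cols)


def module_trait_anova(
    e: Eigenmetabolite,
    traits: TraitTable,
    factor: str,
    n_modules: int,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way fixed-effects ANOVA of eigenmetabolite scores on a factor.

    The family-wise ``alpha`` is Bonferroni-divided by the number of
    detected modules.  Per-level letters come from a compact letter display
    over pairwise Welch t-tests at the adjusted threshold.
    """
    if n_modules < 1:
        raise InputError("n_modules must be >= 1")
    traits.check_samples(e.sample_ids)
    levels = traits.levels(factor).loc[e.sample_ids]
    groups: dict[str, np.ndarray] = {}
    for lev in pd.unique(levels):
        groups[str(lev)] = e.scores[(levels == lev).to_numpy()]
    if len(groups) < 2:
        raise InputError(f"factor {factor!r} has fewer than 2 levels")
    for lev, vals in groups.items():
        if vals.size < 2:
            raise InputError(
                f"level {lev!r} of factor {factor!r} has fewer than 2 samples"
            )

    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    k = len(arrays)
    n = grand.size
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        f_stat = np.inf if ss_between > 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    if f_stat == 0.0:
        p = 1.0
    elif np.isinf(f_stat):
        p = 0.0
    else:
        p = float(sp_stats.f.sf(f_stat, df_b, df_w))

    alpha_adj = alpha / n_modules
    pairwise: dict[tuple[str, str], float] = {}
    for a_lev, b_lev in itertools.combinations(groups, 2):
        va, vb = groups[a_lev], groups[b_lev]
        if np.var(va) == 0 and np.var(vb) == 0:
            pw = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            pw = float(sp_stats.ttest_ind(va, vb, equal_var=False).pvalue)
        pairwise[(a_lev, b_lev)] = pw
    letters = compact_letter_display(pairwise, alpha_adj, levels=list(groups))

    stats = pd.DataFrame(
        {
            "n": [groups[lev].size for lev in groups],
            "mean": [float(groups[lev].mean()) for lev in groups],
            "se": [
                float(groups[lev].std(ddof=1) / np.sqrt(groups[lev].size))
                for lev in groups
            ],
        },
        index=list(groups),
    )
    return AnovaResult(
        module=e.module,
        factor=factor,
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=df_b,
        df_within=df_w,
        alpha_adjusted=alpha_adj,
        level_stats=stats,
        pairwise_p=pairwise,
        letters=letters,
    )


def compact_letter_display(
    pairwise_p: dict[tuple[str, str], float],
    alpha: float,
    levels: list[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels connected only by non-significant pairs may share a letter;
    levels in a significant pair never share any letter.  Letter sets that
    become subsets of another are absorbed, keeping the letter count
    minimal for this class of algorithm.
    """
    if levels is None:
        seen: list[str] = []
        for a, b in pairwise_p:
            for lev in (a, b):
                if lev not in seen:
                    seen.append(lev)
        levels = seen
    order = {lev: i for i, lev in enumerate(levels)}

    sets: list[set[str]] = [set(levels)]
    for (a, b), p in sorted(pairwise_p.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])):
        if p >= alpha:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # drop empties and duplicates, absorb proper subsets
        new_sets = [s for s in new_sets if s]
        unique: list[set[str]] = []
        for s in new_sets:
            if s not in unique:
                unique.append(s)
        sets = [s for s in unique if not any(s < t for t in unique)]

    sets.sort(key=lambda s: min(order[lev] for lev in s))
    letters = {lev: "" for lev in levels}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i) if i < 26 else f"z{i}"
        for lev in sorted(s, key=lambda l: order[l]):
            letters[lev] += ch
    return letters
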