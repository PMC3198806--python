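"""Synthetic abundance data with planted correlation blocks and group effects.

Emulates a 6-genotype x 10-replicate design with 46 features: three
correlated blocks of sizes 13/12/6 plus 15 independent background features.
Each block is driven by one latent factor per sample scaled to give the
requested within-block pairwise correlation; categorical group effects are
added as mean shifts in standard-deviation units.  The single-factor
construction guarantees a positive-definite implied covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AbundanceMatrix, TraitTable
from .errors import InputError
from .modules import GREY, ModuleAssignment

__all__ = [
    "SyntheticSpec",
    "DEFAULT_GROUPS",
    "default_effect_map",
    "default_trait_map",
    "generate",
]

DEFAULT_GROUPS = ["AC", "AC_rin", "AC_tg_rin", "NC", "NC_rin", "NC_F1"]

# genotype -> (genetic background, ripeness class)
_TRAITS = {
    "AC": ("AC", "full"),
    "AC_rin": ("AC", "none"),
    "AC_tg_rin": ("AC", "partial"),
    "NC": ("NC", "full"),
    "NC_rin": ("NC", "none"),
    "NC_F1": ("NC", "partial"),
}


def default_trait_map(groups: list[str]) -> dict[str, tuple[str, str]]:
    return {g: _TRAITS.get(g, (g, "full")) for g in groups}


def default_effect_map(effect: float = 1.5) -> dict[int, dict[str, float]]:
    """Group mean shifts (SD units) per block, mirroring the study pattern:
    blocks 0 and 1 elevated in fully-ripe genotypes, block 1 additionally
    shifted by genetic background, block 2 elevated in the NC parents but
    not the NC hybrid."""
    return {
        0: {"AC": effect, "NC": effect},
        1: {"AC": effect, "NC": effect + effect, "NC_rin": effect, "NC_F1": effect},
        2: {"NC": effect, "NC_rin": effect},
    }


@dataclass
class SyntheticSpec:
    n_samples_per_group: int = 10
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    block_sizes: list[int] = field(default_factory=lambda: [13, 12, 6])
    n_background: int = 15
    rho_within: float = 0.8
    effect_map: dict[int, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise InputError("need at least 2 samples per group")
        if not self.groups:
            raise InputError("need at least one group")
        if not 0.0 <= self.rho_within < 1.0:
            raise InputError("rho_within must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be positive")
        if any(b < 1 for b in self.block_sizes):
            raise InputError("block sizes must be positive")
        for b in self.effect_map:
            if not 0 <= b < len(self.block_sizes):
                raise InputError(f"effect_map refers to unknown block {b}")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.groups)

    @property
    def n_features(self) -> int:
        return sum(self.block_sizes) + self.n_background


def generate(
    spec: SyntheticSpec,
) -> tuple[AbundanceMatrix, TraitTable, ModuleAssignment]:
    """Draw one dataset; returns (abundances, traits, true module labels).

    Deterministic for a fixed spec (including seed).  Output concentrations
    are affinely shifted onto a positive scale; autoscaling removes the
    shift exactly, so downstream analysis is unaffected.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    p = spec.n_features

    group_of_sample = np.repeat(np.arange(len(spec.groups)), spec.n_samples_per_group)
    sample_ids = [
        f"{spec.groups[g]}_{i + 1:02d}"
        for g in range(len(spec.groups))
        for i in range(spec.n_samples_per_group)
    ]

    raw = np.empty((n, p))
    feature_ids: list[str] = []
    truth: dict[str, str] = {}
    col = 0
    sq_rho = np.sqrt(spec.rho_within)
    sq_noise = np.sqrt(1.0 - spec.rho_within)
    for b, size in enumerate(spec.block_sizes):
        latent = rng.standard_normal(n)
        shifts = spec.effect_map.get(b, {})
        shift_vec = np.array(
            [shifts.get(spec.groups[g], 0.0) for g in group_of_sample]
        )
        for j in range(size):
            eps = rng.standard_normal(n)
            raw[:, col] = sq_rho * latent + sq_noise * eps + shift_vec
            fid = f"block{b + 1}_f{j + 1:02d}"
            feature_ids.append(fid)
            truth[fid] = f"block_{b + 1}"
            col += 1
    for j in range(spec.n_background):
        raw[:, col] = rng.standard_normal(n)
        fid = f"bg_f{j + 1:02d}"
        feature_ids.append(fid)
        truth[fid] = GREY
        col += 1

    max_shift = max(
        (abs(v) for shifts in spec.effect_map.values() for v in shifts.values()),
        default=0.0,
    )
    offset = 10.0 * spec.noise_sd * (1.0 + max_shift)
    values = offset + spec.noise_sd * raw
    values = np.maximum(values, 0.0)  # guard vs. extreme tails

    abundance = AbundanceMatrix(
        sample_ids=sample_ids, feature_ids=feature_ids, values=values
    )
    trait_map = default_trait_map(spec.groups)
    factors = pd.DataFrame(
        {
            "genotype": [spec.groups[g] for g in group_of_sample],
            "background": [trait_map[spec.groups[g]][0] for g in group_of_sample],
            "ripeness": [trait_map[spec.groups[g]][1] for g in group_of_sample],
        },
        index=sample_ids,
    )
    traits = TraitTable(sample_ids=sample_ids, factors=factors)
    assignment = ModuleAssignment(labels=truth)
    return abundance, traits, assignment
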