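"""End-to-end pipeline: autoscale -> network -> modules -> eigen/ANOVA -> stats.

``run_pipeline`` executes every stage with the configured parameters and
writes all tables, exports, a log and a machine-readable manifest to the
output directory.  Any stage failure is re-raised as ``PipelineError``
naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .data import (
    AbundanceMatrix,
    TraitTable,
    autoscale,
    read_abundance_table,
    read_trait_table,
)
from .eigen import eigenmetabolite, eigenmetabolite_table, module_trait_anova
from .errors import InputError, PipelineError
from .export import export_edge_list, write_matrix_tsv
from .modules import assign_colors, cut_modules, hierarchical_cluster
from .netstats import module_stats_table, node_stats_table
from .network import adjacency, correlation_matrix, dissimilarity, topological_overlap

log = logging.getLogger("wcna")


@dataclass
class RunConfig:
    """All pipeline knobs; defaults reproduce the study's stated settings."""

    abundance_path: str | None = None
    trait_path: str | None = None
    out_dir: str = "wcna_out"
    power: float = 6.0
    sign_mode: str = "unsigned"
    correlation_method: str = "pearson"
    cut_height: float | None = None       # default: 0.95 x max merge height
    min_module_size: int = 3
    cut_method: str = "static"
    linkage: str = "average"
    factors: list[str] = field(default_factory=list)
    alpha: float = 0.05
    edge_threshold: float = 0.10
    edge_source: str = "tom"              # "tom" or "adjacency"
    stats_scope: str = "network"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise InputError("power must be positive")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.edge_threshold < 0:
            raise InputError("edge threshold must be >= 0")
        if self.min_module_size < 2:
            raise InputError("min_module_size must be >= 2")
        if self.edge_source not in ("tom", "adjacency"):
            raise InputError("edge_source must be 'tom' or 'adjacency'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(
    cfg: RunConfig,
    abundance: AbundanceMatrix | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Run every stage and write outputs; returns a result bundle.

    Inputs can be passed directly (for in-process use) or read from the
    configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    results: dict = {"config": cfg}

    def stage(name, fn):
        log.info("stage: %s", name)
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    if abundance is None:
        if cfg.abundance_path is None:
            raise PipelineError("read_abundance", InputError("no abundance table given"))
        abundance = stage("read_abundance", lambda: read_abundance_table(cfg.abundance_path))
    if traits is None and cfg.trait_path is not None:
        traits = stage("read_traits", lambda: read_trait_table(cfg.trait_path))
    if cfg.factors and traits is None:
        raise PipelineError(
            "read_traits",
            InputError("ANOVA on factors requested but no trait table was provided"),
        )

    scaled = stage("autoscale", lambda: autoscale(abundance))
    if scaled.constant_features:
        log.warning("constant features excluded: %s", scaled.constant_features)
        scaled = scaled.drop_constant()
    corr = stage("correlation", lambda: correlation_matrix(scaled, method=cfg.correlation_method))
    adj = stage("adjacency", lambda: adjacency(corr, power=cfg.power, sign_mode=cfg.sign_mode))
    tom = stage("tom", lambda: topological_overlap(adj))
    diss = stage("dissimilarity", lambda: dissimilarity(tom))
    dend = stage("clustering", lambda: hierarchical_cluster(diss, linkage=cfg.linkage))
    raw_assign = stage(
        "cut_modules",
        lambda: cut_modules(
            dend,
            cut_height=cfg.cut_height,
            min_module_size=cfg.min_module_size,
            method=cfg.cut_method,
            tom=tom if cfg.cut_method == "hybrid" else None,
        ),
    )
    assign = stage("assign_colors", lambda: assign_colors(raw_assign))
    results.update(
        scaled=scaled, correlation=corr, adjacency=adj, tom=tom,
        dissimilarity=diss, dendrogram=dend, assignment=assign,
    )
    log.info(
        "modules: %s (grey: %d)",
        {m: assign.size(m) for m in assign.module_names},
        assign.size("grey"),
    )

    eigen_frame = stage("eigenmetabolites", lambda: eigenmetabolite_table(scaled, assign))
    results["eigenmetabolites"] = eigen_frame

    anovas = []
    if traits is not None and cfg.factors:
        n_mod = assign.n_modules
        for factor in cfg.factors:
            for m in assign.module_names:
                e = eigenmetabolite(scaled, assign, m)
                res = stage(
                    f"anova[{factor},{m}]",
                    lambda e=e, factor=factor: module_trait_anova(
                        e, traits, factor, n_modules=n_mod, alpha=cfg.alpha
                    ),
                )
                anovas.append(res)
    results["anova"] = anovas

    node_stats = stage(
        "node_stats", lambda: node_stats_table(adj, assign, scope=cfg.stats_scope)
    )
    mod_stats = stage("module_stats", lambda: module_stats_table(adj, assign))
    results["node_stats"] = node_stats
    results["module_stats"] = mod_stats

    stage("exports", lambda: _write_outputs(out, cfg, results))
    stage("manifest", lambda: _write_manifest(out, cfg, results))
    return results


def _write_outputs(out: Path, cfg: RunConfig, results: dict) -> None:
    scaled = results["scaled"]
    assign = results["assignment"]
    write_matrix_tsv(results["adjacency"], out / "adjacency.tsv")
    write_matrix_tsv(results["tom"], out / "tom.tsv")
    results["dendrogram"].write_newick(out / "dendrogram.nwk")
    results["dendrogram"].to_merge_table().to_csv(out / "merges.tsv", sep="\t", index=False)
    assign.write_tsv(out / "modules.tsv")
    results["eigenmetabolites"].rename_axis("sample_id").to_csv(
        out / "eigenmetabolites.tsv", sep="\t", float_format="%.17g"
    )
    results["node_stats"].to_csv(out / "node_stats.tsv", sep="\t", float_format="%.6g")
    results["module_stats"].to_csv(out / "module_stats.tsv", sep="\t", float_format="%.6g")
    if results["anova"]:
        rows = []
        for r in results["anova"]:
            letters = ";".join(f"{lev}:{let}" for lev, let in r.letters.items())
            rows.append(
                {
                    "module": r.module, "factor": r.factor, "F": r.f_statistic,
                    "p": r.p_value, "df_between": r.df_between,
                    "df_within": r.df_within, "alpha_adjusted": r.alpha_adjusted,
                    "significant": r.significant, "letters": letters,
                }
            )
        pd.DataFrame(rows).to_csv(out / "anova.tsv", sep="\t", index=False, float_format="%.6g")
    source = results["tom"] if cfg.edge_source == "tom" else results["adjacency"]
    for fmt, name in (("tsv", "edges.tsv"), ("sif", "edges.sif"), ("graphml", "edges.graphml")):
        export_edge_list(source, out / name, threshold=cfg.edge_threshold, fmt=fmt, assign=assign)


def _write_manifest(out: Path, cfg: RunConfig, results: dict) -> None:
    assign = results["assignment"]
    manifest = {
        "tool": "wcna",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "modules": {m: assign.size(m) for m in assign.module_names},
        "n_grey": assign.size("grey"),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
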