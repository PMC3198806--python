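# wcna

Weighted correlation network analysis for metabolite profiling data.

`wcna` builds weighted correlation networks from samples × metabolites
concentration tables (e.g. NMR-profiled metabolomes): soft-thresholded
adjacency, topological overlap (TOM), hierarchical module detection with
color labels, per-module eigenmetabolites with categorical-trait ANOVA
(Bonferroni-adjusted, compact letter display), and the fundamental network
statistics — connectivity, scaled connectivity, maximum adjacency ratio,
clustering coefficient, module density/centralization/heterogeneity.

It also ships the two common baselines for comparison — PCA with loading
screening and a batch-learning self-organizing map (BL-SOM) with ±1-SD
heat-map contrasts — plus fixed-width spectral binning of 1D NMR spectra
into fingerprint feature tables, a synthetic-data generator with planted
correlation blocks and group effects, and Cytoscape-friendly exports
(edge-list TSV, SIF, GraphML, Newick dendrograms).

## Quick start (library)

```python
import wcna

m = wcna.read_abundance_table("abundance.tsv")        # samples x features
scaled = wcna.autoscale(m).drop_constant()            # per-feature z-scores
corr = wcna.correlation_matrix(scaled)                # Pearson
adj = wcna.adjacency(corr, power=6, sign_mode="unsigned")
tom = wcna.topological_overlap(adj)
dend = wcna.hierarchical_cluster(wcna.dissimilarity(tom))
assign = wcna.assign_colors(wcna.cut_modules(dend, min_module_size=3))

eigen = wcna.eigenmetabolite(scaled, assign, "turquoise")
traits = wcna.read_trait_table("traits.tsv")
res = wcna.module_trait_anova(eigen, traits, "genotype",
                              n_modules=assign.n_modules)
print(res.f_statistic, res.p_value, res.letters)
```

## CLI

```sh
# generate a synthetic 6-genotype x 10-replicate dataset (46 features,
# planted blocks of 13/12/6 + 15 background features)
wcna simulate --out-dir sim --seed 1

# full pipeline: network -> modules -> eigenmetabolite ANOVA -> stats -> exports
wcna build --abundance sim/abundance.tsv --traits sim/traits.tsv \
     --factor genotype --out-dir run

# individual pieces
wcna stats  --abundance sim/abundance.tsv --out node_stats.tsv
wcna pca    --abundance sim/abundance.tsv --out-dir pca
wcna som    --abundance sim/abundance.tsv --out-dir som --compare-left AC_01
wcna export --abundance sim/abundance.tsv --out edges.tsv --threshold 0.10
```

`build` writes adjacency/TOM matrices, a Newick dendrogram, module
assignments, eigenmetabolite and ANOVA tables, node/module statistics,
edge lists (TSV/SIF/GraphML, edges below the threshold omitted) and a
machine-readable `manifest.json` recording every parameter and version.
Options can also come from a flat TOML file (`--config`), with flags taking
precedence. Exit codes: 0 ok, 1 input error, 2 internal error.

Defaults follow the published workflow this package reproduces: autoscaled
data, Pearson correlation, unsigned network at power 6, average-linkage
clustering of the TOM dissimilarity, static cut at 0.95 × the maximum merge
height with minimum module size 3, and a 0.10 edge-export threshold.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests,
brute-force (triple-loop) oracles for every network statistic, and
`tests/test_acceptance.py` covering planted-module recovery and the
type-I/power calibration of the eigenmetabolite ANOVA.

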