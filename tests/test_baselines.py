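import numpy as np
import pytest

import wcna
from wcna.baselines import blsom_compare, blsom_fit, pca, top_loadings
from wcna.errors import InputError


def scaled_from(values, feature_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    return wcna.ScaledMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(values.shape[0])],
        feature_ids=feature_ids or [f"f{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestPCA:
    def test_rank_one_full_variance(self):
        base = np.array([1.0, -2.0, 3.0, 0.0])
        x = scaled_from(np.column_stack([base, 2 * base, -base]))
        p = pca(x)
        assert p.variance_explained[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        x = scaled_from(rng.normal(size=(10, 4)))
        p = pca(x)
        assert p.variance_explained.sum() == pytest.approx(1.0)

    def test_known_covariance_eigenvalues(self, rng):
        # covariance [[2,1],[1,2]] has eigenvalues 3 and 1 -> fractions 3/4, 1/4
        n = 200_000
        z = rng.normal(size=(n, 2))
        chol = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        x = scaled_from(z @ chol.T)
        p = pca(x)
        np.testing.assert_allclose(p.variance_explained, [0.75, 0.25], atol=0.01)

    def test_reconstruction(self, rng):
        x = scaled_from(rng.normal(size=(8, 5)))
        p = pca(x)
        centered = x.values - x.values.mean(axis=0)
        recon = p.scores.to_numpy() @ p.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-9)

    def test_orthonormal_loadings(self, rng):
        x = scaled_from(rng.normal(size=(12, 6)))
        p = pca(x)
        l = p.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-9)

    def test_deterministic_sign(self, rng):
        x = scaled_from(rng.normal(size=(10, 4)))
        p = pca(x)
        for col in p.loadings.columns:
            v = p.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_degenerate_matrix_errors(self):
        x = scaled_from(np.ones((4, 3)))
        with pytest.raises(InputError):
            pca(x)


class TestTopLoadings:
    def make_result(self, loadings):
        import pandas as pd

        features = [f"feature{i + 1}" for i in range(len(loadings))]
        return wcna.baselines.PCAResult(
            scores=pd.DataFrame(np.zeros((2, 1)), columns=["PC1"]),
            loadings=pd.DataFrame({"PC1": loadings}, index=features),
            variance_explained=np.array([1.0]),
        )

    def test_direct_filter(self):
        p = self.make_result([0.25, 0.05, -0.15])
        hits = top_loadings(p, "PC1", 0.20, -0.10)
        assert hits == {"feature1": "+", "feature3": "-"}

    def test_all_zero_empty(self):
        p = self.make_result([0.0, 0.0])
        assert top_loadings(p, "PC1", 0.20, -0.10) == {}

    def test_zero_thresholds_select_all_nonzero(self):
        p = self.make_result([0.1, -0.1, 0.2])
        hits = top_loadings(p, 1, 0.0, 0.0)
        assert len(hits) == 3


def two_cluster_data(rng, n_samples=10, sep=8.0):
    c1 = rng.normal(size=n_samples)
    c2 = rng.normal(size=n_samples) + sep
    cols, ids = [], []
    for j in range(4):
        cols.append(c1 + 0.05 * rng.normal(size=n_samples))
        ids.append(f"a{j}")
    for j in range(4):
        cols.append(c2 + 0.05 * rng.normal(size=n_samples))
        ids.append(f"b{j}")
    return scaled_from(np.column_stack(cols), feature_ids=ids)


class TestBLSOM:
    def test_identical_profiles_share_cell(self, rng):
        base = rng.normal(size=8)
        x = scaled_from(
            np.column_stack([base, base, rng.normal(size=8)]),
            feature_ids=["twin1", "twin2", "other"],
        )
        g = blsom_fit(x, rows=2, cols=2, epochs=30, seed=0)
        assert g.assignment["twin1"] == g.assignment["twin2"]

    def test_deterministic_rerun(self, rng):
        x = scaled_from(rng.normal(size=(10, 12)))
        g1 = blsom_fit(x, rows=3, cols=3, epochs=40, seed=5)
        g2 = blsom_fit(x, rows=3, cols=3, epochs=40, seed=5)
        assert g1.assignment == g2.assignment
        np.testing.assert_array_equal(g1.references, g2.references)

    def test_two_clusters_on_1x2_grid(self, rng):
        x = two_cluster_data(rng)
        g = blsom_fit(x, rows=1, cols=2, epochs=50, seed=0)
        cells_a = {g.assignment[f] for f in x.feature_ids if f.startswith("a")}
        cells_b = {g.assignment[f] for f in x.feature_ids if f.startswith("b")}
        assert len(cells_a) == 1 and len(cells_b) == 1
        assert cells_a != cells_b

    def test_feature_order_invariance(self, rng):
        x = scaled_from(rng.normal(size=(8, 10)))
        perm = rng.permutation(10)
        x_perm = scaled_from(
            x.values[:, perm], feature_ids=[x.feature_ids[j] for j in perm]
        )
        g1 = blsom_fit(x, rows=3, cols=3, epochs=30, seed=0)
        g2 = blsom_fit(x_perm, rows=3, cols=3, epochs=30, seed=0)
        assert g1.assignment == g2.assignment

    def test_block_topology_preserved(self):
        # planted blocks land in the same or adjacent cells most of the time
        from wcna.simulate import SyntheticSpec, generate

        ok = total = 0
        for seed in range(10):
            spec = SyntheticSpec(seed=seed)
            ab, _, truth = generate(spec)
            x = wcna.autoscale(ab)
            g = blsom_fit(x, rows=4, cols=4, epochs=40, seed=seed)
            for block in ("block_1", "block_2", "block_3"):
                feats = [f for f, lab in truth.labels.items() if lab == block]
                cells = [g.assignment[f] for f in feats]
                r0 = np.median([c[0] for c in cells])
                c0 = np.median([c[1] for c in cells])
                for r, c in cells:
                    total += 1
                    if abs(r - r0) <= 1 and abs(c - c0) <= 1:
                        ok += 1
        assert ok / total >= 0.9

    def test_oversized_lattice_warns(self, rng):
        x = scaled_from(rng.normal(size=(6, 3)))
        with pytest.warns(UserWarning, match="cells"):
            blsom_fit(x, rows=5, cols=5, epochs=5, seed=0)


class TestBLSOMCompare:
    def fit(self, rng):
        x = two_cluster_data(rng)
        g = blsom_fit(x, rows=2, cols=2, epochs=30, seed=0)
        return g, x

    def test_mean_vs_mean_all_neutral(self, rng):
        g, x = self.fit(rng)
        comp = blsom_compare(g, x, left="mean", right="mean")
        occupied = comp.categories.to_numpy().ravel()
        assert set(occupied) <= {"neutral"}

    def test_strong_and_weak_categories(self):
        ids = [f"s{i}" for i in range(9)]
        base = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8])  # sd ~ 2.74
        sd = base.std(ddof=1)
        vals = np.column_stack([base, base[::-1]])
        x = scaled_from(vals, feature_ids=["up", "down"], sample_ids=ids)
        x = wcna.autoscale(x)
        g = blsom_fit(x, rows=1, cols=2, epochs=20, seed=0)
        # find the sample whose 'up' value exceeds mean + 1 sd
        frame = x.to_frame()
        strong_sample = frame["up"].idxmax()
        comp = blsom_compare(g, x, left=strong_sample, right="mean")
        cell = g.assignment["up"]
        assert comp.categories.iloc[cell[0], cell[1]] == "strong-up"
        weak_sample = frame["up"][(frame["up"] > 0) & (frame["up"] < frame["up"].std(ddof=1))].index[0]
        comp_w = blsom_compare(g, x, left=weak_sample, right="mean")
        assert comp_w.categories.iloc[cell[0], cell[1]].endswith("-up")

    def test_antisymmetry(self, rng):
        g, x = self.fit(rng)
        a = blsom_compare(g, x, left="s0", right="s1").categories.to_numpy()
        b = blsom_compare(g, x, left="s1", right="s0").categories.to_numpy()
        flip = {
            "strong-up": "strong-down",
            "weak-up": "weak-down",
            "neutral": "neutral",
            "weak-down": "weak-up",
            "strong-down": "strong-up",
        }
        assert (np.vectorize(flip.get)(a) == b).all()

    def test_unknown_sample_errors(self, rng):
        g, x = self.fit(rng)
        with pytest.raises(InputError, match="nope"):
            blsom_compare(g, x, left="nope", right="mean")

    def test_empty_cell_flagged_neutral(self, rng):
        base = rng.normal(size=6)
        x = scaled_from(
            np.column_stack([base, base]), feature_ids=["t1", "t2"]
        )
        g = blsom_fit(x, rows=2, cols=2, epochs=10, seed=0)
        comp = blsom_compare(g, x, left="s0", right="mean")
        assert comp.empty_cells  # twins share one cell, so others are empty
        for r, c in comp.empty_cells:
            assert comp.categories.iloc[r, c] == "neutral"
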