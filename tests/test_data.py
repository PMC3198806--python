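import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import wcna
from wcna.data import bin_spectrum, read_spectra
from wcna.errors import InputError


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestAbundanceIO:
    def test_identity_round_trip_values(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "id\tf1\tf2\ns1\t1\t2\ns2\t3\t4\n")
        m = wcna.read_abundance_table(p)
        assert m.sample_ids == ["s1", "s2"]
        assert m.feature_ids == ["f1", "f2"]
        np.testing.assert_array_equal(m.values, [[1, 2], [3, 4]])

    def test_write_read_round_trip(self, tmp_path, small_abundance):
        out = tmp_path / "m.tsv"
        wcna.write_abundance_table(small_abundance, out)
        back = wcna.read_abundance_table(out)
        assert back.sample_ids == small_abundance.sample_ids
        assert back.feature_ids == small_abundance.feature_ids
        np.testing.assert_allclose(back.values, small_abundance.values, rtol=0, atol=0)

    def test_csv_delimiter_inferred(self, tmp_path):
        p = write_tsv(tmp_path / "t.csv", "id,f1,f2\ns1,1,2\ns2,3,4\n")
        m = wcna.read_abundance_table(p)
        assert m.values[1, 1] == 4

    def test_na_cell_locates_error(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "id\tf1\tf2\ns1\t1\tNA\ns2\t3\t4\n")
        with pytest.raises(InputError, match=r"s1.*f2|f2.*s1"):
            wcna.read_abundance_table(p)

    def test_duplicate_sample_id_named(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "id\tf1\ns1\t1\ns1\t2\n")
        with pytest.raises(InputError, match="s1"):
            wcna.read_abundance_table(p)

    def test_duplicate_feature_id_named(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "id\tf1\tf1\ns1\t1\t2\n")
        with pytest.raises(InputError, match="f1"):
            wcna.read_abundance_table(p)

    def test_empty_table_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "")
        with pytest.raises(InputError, match="empty"):
            wcna.read_abundance_table(p)

    def test_negative_value_rejected(self):
        with pytest.raises(InputError, match="negative"):
            wcna.AbundanceMatrix(["s1"], ["f1"], np.array([[-1.0]]))


class TestTraitIO:
    def test_six_level_factor(self, tmp_path):
        lines = ["id\tgenotype"]
        for g in range(6):
            for r in range(10):
                lines.append(f"s{g}_{r}\tG{g}")
        p = write_tsv(tmp_path / "tr.tsv", "\n".join(lines) + "\n")
        t = wcna.read_trait_table(p)
        levels = t.levels("genotype")
        assert levels.nunique() == 6
        assert (levels.value_counts() == 10).all()

    def test_single_sample_valid(self, tmp_path):
        p = write_tsv(tmp_path / "tr.tsv", "id\tgenotype\ns1\tA\n")
        t = wcna.read_trait_table(p)
        assert t.sample_ids == ["s1"]

    def test_empty_factor_cell_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "tr.tsv", "id\tgenotype\ns1\tA\ns2\t\n")
        with pytest.raises(InputError, match="s2"):
            wcna.read_trait_table(p)

    def test_missing_sample_listed(self, tmp_path):
        p = write_tsv(tmp_path / "tr.tsv", "id\tgenotype\ns1\tA\ns2\tB\n")
        t = wcna.read_trait_table(p)
        with pytest.raises(InputError, match="s3"):
            t.check_samples(["s1", "s3"])

    def test_round_trip(self, tmp_path):
        p = write_tsv(tmp_path / "tr.tsv", "id\tg\tb\ns1\tA\tx\ns2\tB\ty\n")
        t = wcna.read_trait_table(p)
        out = tmp_path / "tr2.tsv"
        wcna.write_trait_table(t, out)
        t2 = wcna.read_trait_table(out)
        pd.testing.assert_frame_equal(t.factors, t2.factors)


class TestAutoscale:
    def test_hand_example(self):
        m = wcna.AbundanceMatrix(["a", "b", "c"], ["f"], np.array([[1.0], [2.0], [3.0]]))
        s = wcna.autoscale(m)
        np.testing.assert_allclose(s.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_flagged_zero(self):
        m = wcna.AbundanceMatrix(
            ["a", "b", "c"], ["f", "g"], np.array([[5.0, 1], [5.0, 2], [5.0, 3]])
        )
        s = wcna.autoscale(m)
        np.testing.assert_array_equal(s.values[:, 0], 0.0)
        assert s.constant_features == ["f"]

    def test_output_mean_zero_sd_one(self, small_abundance):
        s = wcna.autoscale(small_abundance)
        np.testing.assert_allclose(s.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(s.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_single_sample_errors(self):
        m = wcna.AbundanceMatrix(["a"], ["f"], np.array([[1.0]]))
        with pytest.raises(InputError, match="2 samples"):
            wcna.autoscale(m)

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(
            np.float64,
            (5, 3),
            elements=st.floats(0.1, 100.0, allow_nan=False),
        )
    )
    def test_idempotent(self, values):
        m = wcna.ScaledMatrix(
            sample_ids=[f"s{i}" for i in range(5)],
            feature_ids=["a", "b", "c"],
            values=values,
        )
        s1 = wcna.autoscale(m)
        s2 = wcna.autoscale(s1)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)


def flat_spectrum(lo=0.0, hi=11.0, step=0.005, value=1.0):
    ppm = np.arange(lo, hi, step)
    return wcna.SpectrumSet(
        ppm=ppm, intensities=np.full((1, ppm.size), value), sample_ids=["s1"]
    )


class TestBinSpectrum:
    def test_fingerprint_bin_count_450(self):
        s = flat_spectrum()
        m = bin_spectrum(s, lo=0.5, hi=10.0, width=0.02, exclusions=[(4.5, 5.0)])
        assert m.n_features == 450

    def test_no_exclusion_count_475(self):
        s = flat_spectrum()
        m = bin_spectrum(s, lo=0.5, hi=10.0, width=0.02)
        assert m.n_features == 475

    def test_flat_unit_spectrum_mean_agg(self):
        s = flat_spectrum()
        m = bin_spectrum(s, lo=0.5, hi=10.0, width=0.02, agg="mean")
        np.testing.assert_allclose(m.values, 1.0)

    def test_excluded_peak_contributes_nowhere(self):
        ppm = np.arange(0.5, 10.0, 0.005)
        inten = np.where(np.abs(ppm - 4.7) < 0.01, 100.0, 0.0)[None, :]
        s = wcna.SpectrumSet(ppm=ppm, intensities=inten, sample_ids=["s1"])
        m = bin_spectrum(s, lo=0.5, hi=10.0, width=0.02, exclusions=[(4.5, 5.0)])
        assert m.values.max() == 0.0

    def test_feature_named_by_center(self):
        s = flat_spectrum()
        m = bin_spectrum(s, lo=0.5, hi=0.54, width=0.02)
        assert m.feature_ids == ["ppm_0.51", "ppm_0.53"]

    def test_bad_parameters(self):
        s = flat_spectrum()
        with pytest.raises(InputError):
            bin_spectrum(s, lo=5, hi=1, width=0.02)
        with pytest.raises(InputError):
            bin_spectrum(s, lo=0.5, hi=10, width=-1)
        with pytest.raises(InputError):
            bin_spectrum(s, lo=0.5, hi=10, width=0.02, exclusions=[(0.0, 0.4)])

    def test_full_exclusion_errors(self):
        s = flat_spectrum()
        with pytest.raises(InputError, match="no bins"):
            bin_spectrum(s, lo=1.0, hi=2.0, width=0.1, exclusions=[(1.0, 2.0)])


def test_read_spectra_two_column(tmp_path):
    for sid in ("a", "b"):
        (tmp_path / f"{sid}.tsv").write_text(
            "".join(f"{x:.3f}\t{1.0 if sid == 'a' else 2.0}\n" for x in np.arange(0.5, 2.0, 0.01))
        )
    s = read_spectra([tmp_path / "a.tsv", tmp_path / "b.tsv"])
    assert s.sample_ids == ["a", "b"]
    assert s.intensities.shape[0] == 2
    np.testing.assert_allclose(s.intensities[1], 2.0)


def test_spectrum_axis_must_be_monotone():
    with pytest.raises(InputError, match="monotone"):
        wcna.SpectrumSet(
            ppm=np.array([1.0, 3.0, 2.0]),
            intensities=np.zeros((1, 3)),
            sample_ids=["s"],
        )
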