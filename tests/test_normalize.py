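"""Normalization chain: size factors, FPKM, VST, batch removal, rescaling."""

import numpy as np
import pandas as pd
import pytest

from imglia import (
    CountMatrix,
    fpkm,
    normalize_counts,
    remove_batch_effect,
    rescale_unit_interval,
    size_factors_median_of_ratios,
    vst_transform,
)


def _matrix(values, genes=None, samples=None, cell_types=None, studies=None):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "cell_type": cell_types or ["monocyte"] * len(samples),
            "study": studies or ["a"] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix([[5, 5], [9, 9], [2, 2]])
        assert np.allclose(size_factors_median_of_ratios(m), 1.0)

    def test_doubled_column_hand_arithmetic(self):
        m = _matrix([[10, 20], [20, 40], [30, 60]])
        f = size_factors_median_of_ratios(m)
        assert f.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], abs=1e-5)

    def test_permutation_equivariance(self):
        m = _matrix([[10, 25, 3], [7, 2, 9], [14, 30, 21]])
        f = size_factors_median_of_ratios(m)
        perm = ["s2", "s0", "s1"]
        f_perm = size_factors_median_of_ratios(m.subset_samples(perm))
        assert np.allclose(f.loc[perm].to_numpy(), f_perm.to_numpy())

    def test_no_reference_gene_errors(self):
        m = _matrix([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="total-count"):
            size_factors_median_of_ratios(m)

    def test_renormalization_fixed_point(self, default_study):
        """Dividing by the factors then re-estimating gives factors ≈ 1."""
        m = default_study.counts
        f = size_factors_median_of_ratios(m)
        scaled = (m.counts / f).round().astype(int)
        m2 = CountMatrix(scaled, m.sample_meta)
        f2 = size_factors_median_of_ratios(m2)
        assert np.allclose(f2.to_numpy(), 1.0, atol=0.05)


class TestNormalizeCounts:
    def test_unit_factors_identity(self, toy_counts):
        f = pd.Series(1.0, index=toy_counts.sample_ids)
        norm = normalize_counts(toy_counts, f)
        assert np.allclose(norm.values.to_numpy(), toy_counts.counts.to_numpy())
        assert norm.transform_log[0]["name"] == "size_factor"

    def test_division_arithmetic(self):
        m = _matrix([[20]])
        norm = normalize_counts(m, pd.Series({"s0": 2.0}))
        assert norm.values.iloc[0, 0] == 10.0

    def test_proportional_columns_equalized(self):
        m = _matrix([[10, 20], [20, 40], [30, 60]])
        norm = normalize_counts(m, size_factors_median_of_ratios(m))
        sums = norm.values.sum(axis=0)
        assert sums.iloc[0] == pytest.approx(sums.iloc[1])

    def test_missing_factor_errors(self, toy_counts):
        with pytest.raises(ValueError, match="size factor"):
            normalize_counts(toy_counts, pd.Series({"m1": 1.0}))


class TestFpkm:
    def test_formula_arithmetic(self):
        m = _matrix([[10], [999990]], genes=["GA", "FILL"])
        lengths = pd.Series({"GA": 1000.0, "FILL": 500.0})
        out = fpkm(m, lengths)
        # column total is 1e6, so FPKM = 10 * 1e9 / (1000 * 1e6) = 10
        assert out.values.loc["GA", "s0"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        m = _matrix([[0], [100]])
        out = fpkm(m, pd.Series({"G0": 100.0, "G1": 200.0}))
        assert out.values.loc["G0", "s0"] == 0.0

    def test_depth_invariance(self):
        lengths = pd.Series({"G0": 100.0, "G1": 300.0})
        a = fpkm(_matrix([[10], [30]]), lengths)
        b = fpkm(_matrix([[20], [60]]), lengths)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_length_weighted_sum_identity(self, default_study):
        """Σ_g FPKM[g,s] * length[g] = 1e9 for every sample."""
        m = default_study.counts
        rng = np.random.default_rng(0)
        lengths = pd.Series(
            rng.integers(200, 5000, size=len(m.gene_ids)).astype(float),
            index=m.gene_ids,
        )
        out = fpkm(m, lengths)
        weighted = out.values.mul(lengths, axis=0).sum(axis=0)
        assert np.allclose(weighted.to_numpy(), 1e9)

    def test_missing_length_errors(self, toy_counts):
        with pytest.raises(ValueError, match="GC"):
            fpkm(toy_counts, pd.Series({"GA": 100.0, "GB": 100.0}))


class TestVst:
    def _vst_scalar(self, x, alpha):
        m = _matrix([[int(x)], [1]], genes=["G", "REF"])
        f = pd.Series({"s0": 1.0})
        return vst_transform(m, alpha, f=f).values.loc["G", "s0"]

    def test_monotone_in_counts(self):
        for alpha in (0.05, 0.5, 2.0):
            vals = [self._vst_scalar(x, alpha) for x in (0, 1, 5, 50, 5000)]
            assert np.all(np.diff(vals) > 0)

    def test_log2_slope_at_large_counts(self):
        # doubling a large count must add one VST unit (log2 asymptote)
        alpha = 0.1
        gap = self._vst_scalar(2e6, alpha) - self._vst_scalar(1e6, alpha)
        assert gap == pytest.approx(1.0, abs=1e-3)

    def test_rank_preservation_within_sample(self, default_study):
        m = default_study.counts
        f = size_factors_median_of_ratios(m)
        out = vst_transform(m, 0.1, f=f)
        norm = m.counts / f
        for s in m.sample_ids[:3]:
            assert (
                norm[s].rank(method="average").corr(out.values[s].rank(method="average"))
                == pytest.approx(1.0)
            )

    def test_nonpositive_dispersion_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="dispersion"):
            vst_transform(toy_counts, 0.0)


class TestRemoveBatchEffect:
    def _normalized(self, values, studies, cell_types=None):
        from imglia import NormalizedMatrix

        values = np.asarray(values, dtype=float)
        samples = [f"s{i}" for i in range(values.shape[1])]
        meta = pd.DataFrame(
            {
                "cell_type": cell_types or ["monocyte"] * len(samples),
                "study": studies,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        return NormalizedMatrix(
            pd.DataFrame(values, index=[f"G{i}" for i in range(values.shape[0])], columns=samples),
            meta,
            [{"name": "test"}],
        )

    def test_single_batch_identity(self):
        norm = self._normalized([[1, 2, 3]], ["a", "a", "a"])
        out = remove_batch_effect(norm)
        assert np.allclose(out.values.to_numpy(), norm.values.to_numpy())

    def test_constant_shift_removed(self):
        """Two batches offset by +5 per gene: post-removal means agree < 1e-9."""
        base = np.array([[1.0, 2.0, 1.5, 2.5]])
        shifted = base + np.array([[0, 0, 5, 5]])
        norm = self._normalized(shifted, ["a", "a", "b", "b"])
        out = remove_batch_effect(norm)
        vals = out.values.to_numpy()[0]
        assert abs(vals[:2].mean() - vals[2:].mean()) < 1e-9

    def test_grand_mean_preserved(self, default_study):
        m = default_study.counts
        norm = vst_transform(m, 0.1)
        identity = m.sample_meta["cell_type"].map(
            {
                "monocyte": "mono",
                "ref_monocyte": "mono",
                "iMac": "mac",
                "iMG": "mg",
                "ref_microglia": "mg",
            }
        )
        out = remove_batch_effect(norm, keep=identity)
        before = norm.values.mean(axis=1)
        after = out.values.mean(axis=1)
        assert np.abs(before - after).max() < 1e-9

    def test_condition_effect_survives(self):
        """Planted condition log2FC of 2 recoverable after batch removal."""
        rng = np.random.default_rng(0)
        n = 40
        cond = np.array(["x"] * (n // 2) + ["y"] * (n // 2))
        batch = np.tile(["a", "b"], n // 2)
        vals = rng.normal(5.0, 0.3, size=(50, n))
        vals[:, cond == "y"] += 2.0
        vals[:, batch == "b"] += 1.5
        norm = self._normalized(vals, list(batch), cell_types=list(cond))
        out = remove_batch_effect(norm, keep=pd.Series(cond, index=norm.sample_ids))
        est = out.values.loc[:, cond == "y"].mean(axis=1) - out.values.loc[
            :, cond == "x"
        ].mean(axis=1)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 2.0) < 2 * se + 0.05

    def test_confounded_design_errors(self):
        norm = self._normalized(
            [[1.0, 2.0, 3.0, 4.0]], ["a", "a", "b", "b"], ["x", "x", "y", "y"]
        )
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effect(norm, keep=norm.sample_meta["cell_type"])


class TestRescale:
    def _normalized(self, values):
        m = _matrix(np.zeros_like(values, dtype=int))
        norm = normalize_counts(m, pd.Series(1.0, index=m.sample_ids))
        return norm.with_transform(
            pd.DataFrame(values, index=norm.gene_ids, columns=norm.sample_ids), "test"
        )

    def test_affine_arithmetic(self):
        out = rescale_unit_interval(self._normalized([[2.0, 4.0, 6.0]]))
        assert np.allclose(out.values.to_numpy()[0], [0.0, 0.5, 1.0])

    def test_constant_gene_maps_to_zero(self):
        out = rescale_unit_interval(self._normalized([[3.0, 3.0, 3.0]]))
        assert np.allclose(out.values.to_numpy()[0], 0.0)

    def test_idempotent_on_rescaled(self):
        once = rescale_unit_interval(self._normalized([[2.0, 4.0, 6.0], [1.0, 9.0, 5.0]]))
        twice = rescale_unit_interval(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())
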