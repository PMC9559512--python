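"""CPM, filtering, normalization and batch-adjustment contracts."""

import numpy as np
import pandas as pd
import pytest

from rewirenet.preprocess import (
    adjust_batch,
    compute_cpm,
    filter_low_expressed,
    normalize,
    run_preprocess,
)


def _mat(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


class TestCpm:
    def test_equal_split_single_sample(self):
        cpm = compute_cpm(_mat([[1], [1]]))
        assert cpm.iloc[:, 0].tolist() == [500000.0, 500000.0]

    def test_boundary_zero_count(self):
        cpm = compute_cpm(_mat([[0], [10]]))
        assert cpm.iloc[:, 0].tolist() == [0.0, 1000000.0]

    def test_column_sums_are_one_million(self):
        cpm = compute_cpm(_mat([[2, 0], [3, 5], [5, 5]]))
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_zero_library_names_sample(self):
        with pytest.raises(ValueError, match="S1"):
            compute_cpm(_mat([[1, 0], [1, 0]]))


class TestFilter:
    def test_kept_and_removed_extremes(self):
        cpm = _mat([[1.0] * 4, [0.0] * 4], genes=["hi", "zero"])
        assert filter_low_expressed(cpm) == ["hi"]

    def test_tie_at_half_of_samples_is_kept(self):
        cpm = _mat([[0.6, 0.6, 0.1, 0.1]], genes=["g"])
        assert filter_low_expressed(cpm, min_cpm=0.5, min_fraction=0.5) == ["g"]

    def test_min_cpm_zero_keeps_everything(self, toy_counts):
        counts, _ = toy_counts
        cpm = compute_cpm(counts)
        assert filter_low_expressed(cpm, min_cpm=0.0) == list(counts.index)

    def test_order_preserved(self):
        cpm = _mat([[5.0] * 4, [0.0] * 4, [9.0] * 4], genes=["b", "x", "a"])
        assert filter_low_expressed(cpm) == ["b", "a"]


class TestNormalize:
    def test_log_cpm_zero_count_maps_to_zero(self):
        norm = normalize(_mat([[0, 3], [10, 5]]), method="log_cpm")
        assert norm.iloc[0, 0] == 0.0

    @pytest.mark.parametrize("method", ["log_cpm", "vst_like"])
    def test_monotone_within_sample(self, method, rng):
        counts = _mat(rng.integers(1, 2000, size=(50, 8)))
        norm = normalize(counts, method=method)
        for s in counts.columns:
            order = counts[s].argsort(kind="mergesort").to_numpy()
            diffs = np.diff(norm[s].to_numpy()[order])
            ties = np.diff(counts[s].to_numpy()[order]) == 0
            assert (diffs[~ties] > 0).all()

    def test_vst_flattens_mean_variance_trend(self, rng):
        # NB draws spanning a wide mean range; VST should decouple SD from mean
        mu = np.exp2(rng.uniform(3, 11, size=50))[:, None] * np.ones((1, 200))
        nb_n = 1 / 0.1
        counts = _mat(rng.negative_binomial(nb_n, nb_n / (nb_n + mu)))

        def sd_vs_mean_slope(norm):
            m = norm.mean(axis=1).to_numpy()
            s = norm.std(axis=1).to_numpy()
            return np.polyfit(m, s, 1)[0]

        slope_vst = sd_vs_mean_slope(normalize(counts, "vst_like"))
        slope_log = sd_vs_mean_slope(normalize(counts, "log_cpm"))
        assert abs(slope_vst) < 0.3 * abs(slope_log)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(_mat([[0, 0], [5, 4]]))


class TestAdjustBatch:
    def _samples(self, classes, batches):
        return pd.DataFrame(
            {"sample": [f"S{i}" for i in range(len(classes))],
             "class": classes, "batch": batches}
        )

    def test_exact_removal_of_pure_batch_offset(self):
        # zero-mean offsets: sum-to-zero coding keeps the grand mean untouched,
        # so the batch component is removed exactly
        classes = ["P", "P", "NP", "NP"] * 2
        batches = ["B1", "B2"] * 4
        delta = np.array([1.0 if c == "P" else 0.0 for c in classes])
        offset = np.array([-1.25 if b == "B1" else 1.25 for b in batches])
        base = np.outer(np.arange(1, 6), np.ones(8))
        data = _mat(base + delta + offset)
        clean = _mat(base + delta)
        out = adjust_batch(data, self._samples(classes, batches))
        assert np.allclose(out.to_numpy(), clean.to_numpy(), atol=1e-10)

    def test_uneven_offset_removed_up_to_constant(self):
        classes = ["P", "P", "NP", "NP"] * 2
        batches = ["B1", "B2"] * 4
        delta = np.array([1.0 if c == "P" else 0.0 for c in classes])
        offset = np.array([0.0 if b == "B1" else 2.5 for b in batches])
        base = np.outer(np.arange(1, 6), np.ones(8))
        out = adjust_batch(_mat(base + delta + offset), self._samples(classes, batches))
        resid = out.to_numpy() - (base + delta)
        assert np.allclose(resid, resid[0, 0], atol=1e-10)  # constant shift only
        # class contrast preserved exactly
        p = np.array(classes) == "P"
        contrast = out.to_numpy()[:, p].mean(axis=1) - out.to_numpy()[:, ~p].mean(axis=1)
        assert np.allclose(contrast, 1.0, atol=1e-10)

    def test_single_batch_is_identity_with_warning(self):
        data = _mat(np.arange(12.0).reshape(3, 4))
        samples = self._samples(["P", "P", "NP", "NP"], ["B1"] * 4)
        with pytest.warns(UserWarning, match="single batch"):
            out = adjust_batch(data, samples)
        assert np.allclose(out.to_numpy(), data.to_numpy())

    def test_refit_batch_coefficient_is_null(self, rng):
        n = 40
        classes = ["P"] * 20 + ["NP"] * 20
        batches = (["B1", "B2"] * 20)[:n]
        y = rng.standard_normal((500, n)) + np.where(np.array(batches) == "B2", 1.0, 0.0)
        data = _mat(y)
        samples = self._samples(classes, batches)
        out = adjust_batch(data, samples)
        # refit: any remaining batch effect should be numerically zero
        b = np.array(batches) == "B2"
        cls = np.array(classes) == "P"
        design = np.column_stack([np.ones(n), cls, np.where(b, 1.0, -1.0)])
        coef, *_ = np.linalg.lstsq(design, out.to_numpy().T, rcond=None)
        assert np.abs(coef[2]).max() < 1e-8

    def test_idempotent(self, rng):
        classes = ["P", "NP"] * 6
        batches = ["B1"] * 6 + ["B2"] * 6
        data = _mat(rng.standard_normal((30, 12)))
        samples = self._samples(classes, batches)
        once = adjust_batch(data, samples)
        twice = adjust_batch(once, samples)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_confounded_batch_rejected(self):
        data = _mat(np.arange(12.0).reshape(3, 4))
        samples = self._samples(["P", "P", "NP", "NP"], ["B1", "B1", "B2", "B2"])
        with pytest.raises(ValueError, match="confounded"):
            adjust_batch(data, samples)


def test_run_preprocess_preserves_order_and_is_finite(toy_counts):
    counts, meta = toy_counts
    norm = run_preprocess(counts, meta)
    assert np.isfinite(norm.to_numpy()).all()
    kept = [g for g in counts.index if g in set(norm.index)]
    assert list(norm.index) == kept
    assert list(norm.columns) == list(counts.columns)
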