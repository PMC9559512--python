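"""Supervised tier: splitting, information gain, MCC, evaluation, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewirenet.features import (
    ModelReport,
    SplitSpec,
    bootstrap_632plus_weight,
    evaluate,
    extract_biomarkers,
    information_gain,
    make_classifier,
    mcc,
    rank_features,
    select_best_models,
    split_train_test,
)
from tests.conftest import information_gain_bruteforce


def _samples(n_p, n_np):
    return pd.DataFrame(
        {
            "sample": [f"P{i}" for i in range(n_p)] + [f"N{i}" for i in range(n_np)],
            "class": ["P"] * n_p + ["NP"] * n_np,
            "batch": "B1",
        }
    )


class TestSplit:
    def test_paper_design_rounding(self):
        train, test = split_train_test(_samples(25, 18), SplitSpec(seed=0))
        labels = lambda ids: [i[0] for i in ids]
        assert labels(train).count("P") == 17 and labels(train).count("N") == 12
        assert labels(test).count("P") == 8 and labels(test).count("N") == 6
        assert sorted(train + test) == sorted(_samples(25, 18)["sample"])

    def test_half_split_even_classes(self):
        train, test = split_train_test(_samples(4, 4), SplitSpec(train_fraction=0.5, seed=1))
        assert len(train) == 4 and len(test) == 4

    def test_determinism_and_seed_sensitivity(self):
        s = _samples(10, 10)
        a = split_train_test(s, SplitSpec(seed=5))
        b = split_train_test(s, SplitSpec(seed=5))
        c = split_train_test(s, SplitSpec(seed=6))
        assert a == b and a != c

    def test_per_class_override(self):
        train, _ = split_train_test(
            _samples(25, 18), SplitSpec(seed=0, per_class_train={"P": 18, "NP": 12})
        )
        assert sum(i.startswith("P") for i in train) == 18

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_samples(1, 5), SplitSpec(seed=0))


class TestInformationGain:
    def test_constant_vector_is_zero(self):
        assert information_gain(np.ones(6), np.array(["A", "B"] * 3)) == 0.0

    def test_perfect_split_of_balanced_classes_is_one_bit(self):
        x = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1.0])
        y = np.array(["A"] * 6 + ["B"] * 6)
        x = np.sort(x)
        assert information_gain(x, y) == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self, rng):
        y4 = np.array(["A", "A", "B", "A"])
        assert information_gain(np.array([1.0, 2, 3, 4]), y4, mdl_gate=False) == (
            pytest.approx(information_gain_bruteforce(np.array([1.0, 2, 3, 4]), y4))
        )
        for _ in range(25):
            x = rng.standard_normal(20)
            y = rng.choice(["A", "B"], size=20)
            if len(set(y)) < 2:
                continue
            assert information_gain(x, y, mdl_gate=False) == pytest.approx(
                information_gain_bruteforce(x, y), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(18)
        y = rng.choice(["P", "NP"], size=18)
        base = information_gain(x, y)
        assert information_gain(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert information_gain(3 * x + 7, y) == pytest.approx(base, abs=1e-12)

    def test_mdl_gate_suppresses_noise_splits(self, rng):
        y = np.array(["P"] * 18 + ["NP"] * 12)
        gains = [information_gain(rng.standard_normal(30), y) for _ in range(200)]
        assert np.mean(np.array(gains) > 0.01) < 0.15


class TestRankFeatures:
    def test_dominant_planted_marker_ranks_first(self, rng):
        samples = _samples(15, 15)
        y = np.array([1.0] * 15 + [0.0] * 15)
        data = rng.standard_normal((50, 30)) * 0.5
        data[7] += 3.0 * y  # log2fc 3 at sigma 0.5
        norm = pd.DataFrame(data, index=[f"G{i:02d}" for i in range(50)],
                            columns=samples["sample"])
        ranked = rank_features(norm, samples)
        assert ranked[0].gene_id == "G07"
        assert ranked[0].rank == 1
        assert [rf.rank for rf in ranked] == list(range(1, len(ranked) + 1))

    def test_impossible_threshold_raises(self, rng):
        samples = _samples(5, 5)
        norm = pd.DataFrame(rng.standard_normal((10, 10)),
                            index=[f"G{i}" for i in range(10)],
                            columns=samples["sample"])
        with pytest.raises(ValueError, match="ig_threshold"):
            rank_features(norm, samples, ig_threshold=np.inf)


class TestMcc:
    @pytest.mark.parametrize(
        "conf,expected",
        [((5, 5, 0, 0), 1.0), ((0, 0, 5, 5), -1.0), ((5, 3, 1, 2), 13 / np.sqrt(840))],
    )
    def test_reference_values(self, conf, expected):
        assert mcc(*conf) == pytest.approx(expected, abs=1e-5)

    def test_zero_denominator_factor_gives_zero(self):
        assert mcc(0, 5, 0, 5) == 0.0

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_class_swap_symmetry(self, conf):
        tp, tn, fp, fn = conf
        if tp + tn + fp + fn == 0:
            return
        assert mcc(tp, tn, fp, fn) == pytest.approx(mcc(tn, tp, fn, fp))


class TestEvaluate:
    def _separable(self, rng, n=30):
        y = np.array(["P"] * (n // 2) + ["NP"] * (n - n // 2))
        X = rng.standard_normal((n, 3)) * 0.1
        X[y == "P"] += 10.0  # two tight clusters separated on every feature
        return X, y

    @pytest.mark.parametrize("scheme", ["cv10", "loocv", "holdout", "repeated_holdout",
                                        "bootstrap", "bootstrap_632plus"])
    def test_perfectly_separable_scores_perfect(self, rng, scheme):
        X, y = self._separable(rng)
        m = evaluate(make_classifier("knn"), X, y, scheme, seed=0)
        assert m["MCC"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(1.0)

    def test_632plus_weight_limit(self):
        assert bootstrap_632plus_weight(0.2, 0.2, 0.5) == pytest.approx(0.632)
        # fully overfit: R = 1 -> w = 1
        assert bootstrap_632plus_weight(0.0, 0.5, 0.5) == pytest.approx(1.0)

    def test_632plus_null_calibration(self, rng):
        """With labels independent of features the 0.632+ error sits near the
        no-information rate gamma."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((30, 5))
            y = np.array(["P"] * 15 + ["NP"] * 15)
            r.shuffle(y)
            m = evaluate(make_classifier("knn"), X, y, "bootstrap_632plus", seed=seed)
            diffs.append(abs((1.0 - m["accuracy"]) - 0.5))
        assert np.mean(diffs) < 0.15


class TestSelection:
    def _report(self, name, avg, sd, genes):
        # six scheme entries engineered to a target mean/sd of MCC
        vals = avg + np.array([sd, -sd, sd, -sd, sd, -sd])
        schemes = {f"s{i}": {"MCC": float(v)} for i, v in enumerate(vals)}
        return ModelReport(name, "MCC", list(genes), schemes)

    def test_single_report_returned(self):
        r = self._report("knn", 0.8, 0.01, ["a"])
        assert select_best_models([r]) == [r]

    def test_sd_filter_beats_higher_mean(self):
        good = self._report("knn", 0.9, 0.04, ["a"])
        unstable = self._report("knn", 0.95, 0.2, ["b"])
        assert select_best_models([good, unstable]) == [good]

    def test_matches_bruteforce_sort_filter(self, rng):
        reports = [
            self._report(f"clf{i}", rng.uniform(0, 1), rng.uniform(0, 0.2),
                         [f"g{j}" for j in range(rng.integers(1, 5))])
            for i in range(20)
        ]
        got = select_best_models(reports, top_n=5, sd_max=0.1)
        ok = [r for r in reports if r.mcc_sd < 0.1]
        expected = sorted(ok, key=lambda r: (-r.avg_mcc, len(r.selected_gene_ids),
                                             r.classifier_name))[:5]
        assert got == expected

    def test_all_filtered_returns_flagged_best(self):
        r1 = self._report("knn", 0.9, 0.3, ["a"])
        r2 = self._report("knn", 0.5, 0.3, ["b"])
        with pytest.warns(UserWarning, match="stability"):
            out = select_best_models([r1, r2])
        assert out == [r1] and out[0].sd_filter_failed

    def test_extract_biomarkers_union_order(self):
        a = self._report("knn", 0.9, 0.0, ["a", "b"])
        b = self._report("knn", 0.8, 0.0, ["b", "c"])
        assert extract_biomarkers([a, b]) == ["a", "b", "c"]
        disjoint = self._report("knn", 0.7, 0.0, ["c"])
        assert extract_biomarkers([a, disjoint]) == ["a", "b", "c"]


def test_stratified_folds_preserve_class_ratio(rng):
    from sklearn.model_selection import StratifiedKFold

    y = np.array(["P"] * 18 + ["NP"] * 12)
    X = rng.standard_normal((30, 2))
    for _, te in StratifiedKFold(n_splits=10, shuffle=True, random_state=0).split(X, y):
        n_p = (y[te] == "P").sum()
        assert abs(n_p - 0.6 * len(te)) <= 1
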