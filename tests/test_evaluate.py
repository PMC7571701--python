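import math

import numpy as np
import pandas as pd
import pytest

from mscrepair import (
    Dataset,
    SynthConfig,
    TrainConfig,
    confidence_filtered_r2,
    correlation_screen,
    flag_anomalies,
    generate,
    knn_baseline,
    loocv,
    mean_baseline,
    r_squared,
    standard_deviations_out,
)
from mscrepair.evaluation import CVResult


def two_pass_r2(pred, actual):
    """Independent oracle: explicit two-pass sums."""
    mean = sum(actual) / len(actual)
    ss_res = sum((p - a) ** 2 for p, a in zip(pred, actual))
    ss_tot = sum((a - mean) ** 2 for a in actual)
    return 1.0 - ss_res / ss_tot


class TestRSquared:
    def test_perfect_fit_is_one(self):
        y = np.array([0.2, 0.5, 0.9])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([0.2, 0.5, 0.9])
        pred = np.full(3, y.mean())
        assert r_squared(pred, y) == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_example(self):
        actual = np.array([0.2, 0.4, 0.6])
        pred = np.array([0.3, 0.4, 0.5])
        assert r_squared(pred, actual) == pytest.approx(0.75)

    def test_matches_two_pass_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            actual = rng.normal(size=n)
            if np.ptp(actual) == 0:
                continue
            pred = rng.normal(size=n)
            assert r_squared(pred, actual) == pytest.approx(
                two_pass_r2(pred, actual), abs=1e-12
            )

    def test_constant_actual_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.array([0.1, 0.2]), np.array([0.5, 0.5]))


class TestStandardDeviationsOut:
    @pytest.mark.parametrize("pred, actl, std, expected", [
        (0.5, 0.5, 0.1, 0.0),
        (0.8, 0.6, 0.1, 2.0),    # overprediction is positive
        (0.5, 0.7, 0.2, -1.0),   # underprediction boundary
    ])
    def test_sign_convention(self, pred, actl, std, expected):
        assert standard_deviations_out(pred, actl, std) == pytest.approx(expected)

    def test_zero_std_with_mismatch_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            standard_deviations_out(0.5, 0.6, 0.0)
        assert standard_deviations_out(0.5, 0.5, 0.0) == 0.0


def make_cv(z_values, stds=None, actual=None, pred=None):
    n = len(z_values)
    table = pd.DataFrame({
        "entry": range(n),
        "actual": actual if actual is not None else np.linspace(0.2, 0.8, n),
        "pred": pred if pred is not None else np.linspace(0.25, 0.75, n),
        "std": stds if stds is not None else np.full(n, 0.1),
        "z": z_values,
    })
    r2 = r_squared(table["pred"].to_numpy(), table["actual"].to_numpy())
    return CVResult(table, r2, n)


class TestAnomalies:
    def test_all_within_one_sd_is_empty(self):
        assert len(flag_anomalies(make_cv([0.5, -0.9, 0.2]))) == 0

    def test_filter_and_ordering(self):
        out = flag_anomalies(make_cv([2.1, -0.5, -1.3]))
        assert len(out) == 2
        assert out.iloc[0]["z"] == 2.1 and out.iloc[0]["direction"] == "overpredicted"
        assert out.iloc[1]["z"] == -1.3

    def test_threshold_zero_flags_every_nonzero(self):
        out = flag_anomalies(make_cv([0.4, -0.2, 1.5]), threshold=0)
        assert len(out) == 3

    def test_count_matches_direct_scan(self, rng):
        z = rng.normal(scale=1.5, size=40)
        out = flag_anomalies(make_cv(z))
        assert len(out) == int((np.abs(z) > 1).sum())

    def test_most_extreme_first_on_each_side(self, rng):
        z = [1.2, 2.9, -1.1, -2.3, 0.1]
        out = flag_anomalies(make_cv(z))
        over = out[out["direction"] == "overpredicted"]["z"].tolist()
        under = out[out["direction"] == "underpredicted"]["z"].tolist()
        assert over == sorted(over, reverse=True)
        assert under == sorted(under)


class TestConfidenceFiltering:
    def test_full_fraction_equals_overall_r2_bitwise(self, rng):
        cv = make_cv(rng.normal(size=12), stds=rng.uniform(0.05, 0.3, 12),
                     actual=rng.uniform(0, 1, 12), pred=rng.uniform(0, 1, 12))
        assert confidence_filtered_r2(cv, 1.0) == cv.r2

    def test_dropping_worst_uncertainty_entry_helps(self):
        # hand-built: the noisiest entry carries the dominant error
        cv = make_cv([0, 0, 0, 0], stds=[0.05, 0.06, 0.07, 0.5],
                     actual=[0.2, 0.4, 0.6, 0.9], pred=[0.21, 0.39, 0.61, 0.4])
        assert confidence_filtered_r2(cv, 0.75) > cv.r2

    def test_ties_broken_by_original_order(self):
        cv = make_cv([0] * 4, stds=[0.1, 0.1, 0.1, 0.1],
                     actual=[0.2, 0.4, 0.6, 0.8], pred=[0.2, 0.4, 0.6, 0.0])
        # keeping 3 of 4 must retain the first three rows
        v = confidence_filtered_r2(cv, 0.75)
        assert v == pytest.approx(r_squared(np.array([0.2, 0.4, 0.6]),
                                            np.array([0.2, 0.4, 0.6])))

    def test_degenerate_subset_rejected(self):
        cv = make_cv([0, 0, 0], stds=[0.1, 0.2, 0.3],
                     actual=[0.5, 0.5, 0.9], pred=[0.4, 0.5, 0.8])
        with pytest.raises(ValueError, match="0.3"):
            confidence_filtered_r2(cv, 0.3)


class TestCorrelationScreen:
    def test_exact_linear_pair(self):
        vals = np.column_stack([[1, 2, 3], [2, 4, 6], [0.1, 0.2, 0.3]])
        ds = Dataset(vals, np.ones((3, 3), bool), ["a", "b", "repair_score"])
        pear, spear, max_off = correlation_screen(ds)
        assert pear.loc["a", "b"] == pytest.approx(1.0)
        assert spear.loc["a", "b"] == pytest.approx(1.0)
        assert pear.loc["a", "a"] == 1.0
        assert max_off == pytest.approx(1.0)

    def test_hand_ranked_spearman(self):
        vals = np.column_stack([[1, 2, 3], [1, 4, 2], [0.1, 0.2, 0.3]])
        ds = Dataset(vals, np.ones((3, 3), bool), ["a", "b", "repair_score"])
        _pear, spear, _ = correlation_screen(ds)
        assert spear.loc["a", "b"] == pytest.approx(0.5)

    def test_sparse_pair_flagged_not_computable(self):
        vals = np.array([[1.0, 2.0, 0.1], [2.0, np.nan, 0.2],
                         [3.0, np.nan, 0.3], [4.0, np.nan, 0.4]])
        ds = Dataset(vals, ~np.isnan(vals), ["a", "b", "repair_score"])
        pear, _spear, max_off = correlation_screen(ds)
        assert math.isnan(pear.loc["a", "b"])
        assert math.isnan(max_off)  # nothing computable -> no max


class TestBaselines:
    def test_knn_matches_exhaustive_distance_oracle(self, rng):
        for seed in range(3):
            ds, _ = generate(SynthConfig(n=12, outcome="tanh", noise_sd=0.05,
                                         seed=seed))
            cv = knn_baseline(ds, k=3)
            for row in cv.table.itertuples():
                i = int(row.entry)
                dists = []
                for j in range(ds.n_entries):
                    if j == i:
                        continue
                    d = math.sqrt(sum(
                        (ds.values[i, c] - ds.values[j, c]) ** 2
                        for c in range(ds.width - 1)
                    ))
                    dists.append((d, j))
                dists.sort()
                expected = np.mean([ds.values[j, -1] for _d, j in dists[:3]])
                assert row.pred == pytest.approx(expected, abs=1e-12)

    def test_knn_nearest_duplicate(self):
        vals = np.array([[0.1, 0.2, 0.9], [0.1, 0.2, 0.8], [0.9, 0.9, 0.1],
                         [0.5, 0.5, 0.5]])
        ds = Dataset(vals, np.ones((4, 3), bool), ["a", "b", "repair_score"])
        cv = knn_baseline(ds, k=1)
        assert cv.table.set_index("entry").loc[0, "pred"] == pytest.approx(0.8)

    def test_knn_k_too_large(self, tiny_dataset):
        with pytest.raises(ValueError):
            knn_baseline(tiny_dataset, k=5)

    def test_mean_baseline_r2_never_positive(self, rng):
        for seed in range(20):
            ds, _ = generate(SynthConfig(n=10, outcome="tanh", noise_sd=0.1,
                                         seed=seed))
            assert mean_baseline(ds).r2 <= 0.0 + 1e-12


@pytest.fixture(scope="module")
def small_cv():
    ds, _ = generate(SynthConfig(n=12, outcome="tanh", noise_sd=0.05, seed=4))
    cfg = TrainConfig(hidden=2, walk_steps=40, descent_steps=40,
                      sample_steps=30, seed=0)
    return ds, cfg, loocv(ds, cfg, n_members=4, base_seed=3)


class TestLoocvStructure:
    def test_one_row_per_known_outcome(self, small_cv):
        ds, _cfg, cv = small_cv
        assert len(cv.table) == int(ds.mask[:, -1].sum())

    def test_shuffling_entries_changes_no_prediction(self, small_cv):
        ds, cfg, cv = small_cv
        perm = np.random.default_rng(1).permutation(ds.n_entries)
        cv2 = loocv(ds.subset_rows(perm), cfg, n_members=4, base_seed=3)
        a = cv.table.sort_values("actual").reset_index(drop=True)
        b = cv2.table.sort_values("actual").reset_index(drop=True)
        np.testing.assert_array_equal(a["pred"].to_numpy(), b["pred"].to_numpy())
        np.testing.assert_array_equal(a["std"].to_numpy(), b["std"].to_numpy())

    def test_confidence_filter_full_fraction_identity(self, small_cv):
        _ds, _cfg, cv = small_cv
        assert confidence_filtered_r2(cv, 1.0) == cv.r2
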