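"""Window features, KDE entropy and the nested cross-validation protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from limbuse.data_model import ImuRecording, ValidationError
from limbuse.ml import (FEATURE_NAMES, FEATURE_SUBSETS, build_window_table,
                        entropy_kde, extract_features, gini_importances,
                        reduced_model_eval, train_eval_inter,
                        train_eval_intra)

RATE = 50.0
FAST_GRID = [{"n_estimators": n} for n in (25, 50)]


def oracle_features(window, bandwidth=0.2):
    """Formula-by-formula recomputation with plain Python loops."""
    k = len(window)
    norms = [math.sqrt(sum(v * v for v in row)) for row in window]

    def mean(xs):
        return sum(xs) / len(xs)

    def var(xs):
        m = mean(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    def kde_entropy(xs):
        logs = []
        for xi in xs:
            p = mean([math.exp(-0.5 * ((xi - xj) / bandwidth) ** 2)
                      / (math.sqrt(2 * math.pi) * bandwidth) for xj in xs])
            logs.append(math.log(p))
        return -mean(logs)

    cols = [[window[i][a] for i in range(k)] for a in range(3)]
    return [mean(cols[0]), mean(cols[1]), mean(cols[2]),
            var(cols[0]), var(cols[1]), var(cols[2]),
            mean(norms), var(norms), min(norms), max(norms),
            kde_entropy(norms)]


def make_table(n=120, sep=3.0, seed=0, flip=0.0):
    """Two-class feature table: classes separated along mean_ax by `sep` sd."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n):
        label = i % 2
        pitch = rng.normal(0.0, 10.0) if label else rng.normal(-sep * 10.0, 10.0)
        g = np.array([np.sin(np.radians(pitch)), 0.1,
                      np.cos(np.radians(pitch))])
        w = np.tile(g, (12, 1)) + rng.normal(0, 0.02, (12, 3))
        rows.append(extract_features(w))
        labels.append(label)
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    labels = np.array(labels)
    if flip:
        swap = rng.random(n) < flip
        labels = np.where(swap, 1 - labels, labels)
    table["label"] = labels
    return table


class TestEntropy:
    def test_point_mass_matches_closed_form(self):
        h = entropy_kde([0.7, 0.7, 0.7, 0.7])
        expected = -math.log(1.0 / (math.sqrt(2 * math.pi) * 0.2))
        assert h == pytest.approx(expected, abs=1e-12)

    def test_spread_exceeds_clustered(self):
        rng = np.random.default_rng(0)
        spread = entropy_kde(rng.normal(0, 1.0, 50))
        clustered = entropy_kde(rng.normal(0, 0.05, 50))
        assert spread > clustered

    def test_permutation_invariant(self):
        x = [0.1, 0.9, 0.4, 0.6]
        assert entropy_kde(x) == pytest.approx(entropy_kde(x[::-1]), abs=1e-14)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValidationError):
            entropy_kde([1.0])


class TestFeatures:
    def test_constant_window(self):
        w = np.tile([0.0, 0.0, 1.0], (12, 1))
        f = dict(zip(FEATURE_NAMES, extract_features(w)))
        assert f["mean_ax"] == 0 and f["mean_az"] == 1
        assert f["var_ax"] == f["var_norm"] == 0
        assert f["mean_norm"] == f["min_norm"] == f["max_norm"] == 1

    def test_exactly_eleven_features(self):
        rng = np.random.default_rng(1)
        assert len(extract_features(rng.normal(0, 1, (12, 3)))) == 11

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.normal(0, 0.5, (12, 3))
            np.testing.assert_allclose(extract_features(w),
                                       oracle_features(w.tolist()),
                                       atol=1e-10, rtol=0)

    def test_too_small_window_rejected(self):
        with pytest.raises(ValidationError):
            extract_features(np.zeros((1, 3)))


class TestWindowTable:
    def _recording(self, n):
        rng = np.random.default_rng(0)
        return ImuRecording(np.arange(n) / RATE,
                            rng.normal(0, 0.1, (n, 3)) + [0, 0, 1],
                            np.zeros((n, 3)), nominal_rate=RATE)

    def test_ten_seconds_gives_forty_rows(self):
        rec = self._recording(500)
        table = build_window_table(rec, np.ones(500, dtype=int), 0.25)
        assert len(table) == 40

    def test_constant_gt_gives_constant_labels(self):
        rec = self._recording(500)
        table = build_window_table(rec, np.ones(500, dtype=int), 0.25)
        assert (table["label"] == 1).all()

    def test_label_is_centre_sample_not_majority(self):
        rec = self._recording(25)  # two 0.25 s windows (12 + 13 samples)
        gt = np.zeros(25, dtype=int)
        gt[7:12] = 1  # majority of window 0 tail is 1, but centre (idx 6) is 0
        table = build_window_table(rec, gt, 0.25)
        assert table["label"].iloc[0] == 0
        gt2 = np.zeros(25, dtype=int)
        gt2[6] = 1  # only the centre sample is 1
        table2 = build_window_table(rec, gt2, 0.25)
        assert table2["label"].iloc[0] == 1

    def test_gt_grid_mismatch_rejected(self):
        rec = self._recording(100)
        with pytest.raises(ValidationError):
            build_window_table(rec, np.ones(99, dtype=int))

    def test_optional_gyro_features(self):
        from limbuse.ml import GYRO_FEATURE_NAMES
        rec = self._recording(500)
        plain = build_window_table(rec, np.ones(500, dtype=int))
        assert not set(GYRO_FEATURE_NAMES) & set(plain.columns)
        table = build_window_table(rec, np.ones(500, dtype=int),
                                   include_gyro=True)
        assert set(GYRO_FEATURE_NAMES) <= set(table.columns)
        # zero-gyro recording: gyro means and variances identically 0
        np.testing.assert_array_equal(
            table[GYRO_FEATURE_NAMES].to_numpy(), 0.0)


class TestIntraSubject:
    def test_separable_table_high_youden(self):
        table = make_table(n=150, sep=6.0, seed=1)
        grids = {"rf": FAST_GRID,
                 "svm": [{"C": 1.0, "gamma": g} for g in (0.01, 0.1)],
                 "mlp": None}
        for model in ("rf", "svm", "mlp"):
            res = train_eval_intra(table, model=model, folds=5, iterations=1,
                                   seed=0, grid=grids[model])
            assert np.mean([r.youden for r in res]) > 0.9, model

    def test_permuted_labels_near_zero_youden(self):
        rng = np.random.default_rng(3)
        table = make_table(n=200, sep=3.0, seed=2)
        table["label"] = rng.permutation(table["label"].to_numpy())
        res = train_eval_intra(table, model="rf", folds=5, iterations=2,
                               seed=0, grid=[{"n_estimators": 25}])
        assert abs(np.mean([r.youden for r in res])) < 0.15

    def test_identical_seed_identical_results(self):
        table = make_table(n=100, seed=4)
        r1 = train_eval_intra(table, "rf", folds=3, iterations=1, seed=9,
                              grid=FAST_GRID)
        r2 = train_eval_intra(table, "rf", folds=3, iterations=1, seed=9,
                              grid=FAST_GRID)
        for a, b in zip(r1, r2):
            assert a.youden == b.youden and a.params == b.params
            np.testing.assert_array_equal(a.test_indices, b.test_indices)

    def test_single_class_table_rejected(self):
        table = make_table(n=40, seed=5)
        table["label"] = 1
        with pytest.raises(ValidationError, match="class"):
            train_eval_intra(table, "rf")

    def test_result_count_is_iterations_times_folds(self):
        table = make_table(n=100, seed=6)
        res = train_eval_intra(table, "rf", folds=4, iterations=2, seed=0,
                               grid=[{"n_estimators": 10}])
        assert len(res) == 8


class TestInterSubject:
    def _tables(self, n_subj, seed=0, invert=None):
        tables = {}
        for s in range(n_subj):
            t = make_table(n=80, sep=3.0, seed=seed + s)
            if invert == s:
                t["label"] = 1 - t["label"]
            tables[f"s{s}"] = t
        return tables

    def test_one_result_per_subject(self):
        res = train_eval_inter(self._tables(4), "rf", seed=0,
                               grid=[{"n_estimators": 25}])
        assert sorted(r.fold for r in res) == ["s0", "s1", "s2", "s3"]

    def test_homogeneous_population_matches_intra(self):
        tables = self._tables(4, seed=10)
        inter = train_eval_inter(tables, "rf", seed=0, grid=FAST_GRID)
        intra = train_eval_intra(tables["s0"], "rf", folds=5, iterations=1,
                                 seed=0, grid=FAST_GRID)
        gap = abs(np.mean([r.youden for r in inter])
                  - np.mean([r.youden for r in intra]))
        assert gap < 0.15

    def test_inverted_subject_scores_negative(self):
        res = train_eval_inter(self._tables(4, seed=20, invert=2), "rf",
                               seed=0, grid=[{"n_estimators": 25}])
        by_subj = {r.fold: r.youden for r in res}
        assert by_subj["s2"] < 0
        assert by_subj["s0"] > 0.5 and by_subj["s1"] > 0.5

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValidationError):
            train_eval_inter(self._tables(2), "rf")


class TestGiniAndReducedModels:
    def test_importances_sum_to_one_descending(self):
        table = make_table(n=150, seed=7)
        rf = RandomForestClassifier(n_estimators=50, random_state=0)
        rf.fit(table[FEATURE_NAMES], table["label"])
        ranked = gini_importances(rf)
        total = sum(v for _, v in ranked)
        assert total == pytest.approx(1.0, abs=1e-9)
        vals = [v for _, v in ranked]
        assert vals == sorted(vals, reverse=True)

    def test_planted_signal_ranks_mean_ax_first(self):
        table = make_table(n=200, sep=4.0, seed=8)
        rf = RandomForestClassifier(n_estimators=100, random_state=0)
        rf.fit(table[FEATURE_NAMES], table["label"])
        assert gini_importances(rf)[0][0] == "mean_ax"

    def test_pure_noise_importances_stay_flat(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (100, 11)),
                             columns=FEATURE_NAMES)
            y = rng.integers(0, 2, 100)
            rf = RandomForestClassifier(n_estimators=50, random_state=seed)
            rf.fit(X, y)
            imp = rf.feature_importances_
            if imp.max() > 3 * imp.mean():
                hits += 1
        assert hits == 0

    def test_unfitted_forest_rejected(self):
        with pytest.raises(ValidationError):
            gini_importances(RandomForestClassifier())

    def test_full_subset_reproduces_train_eval_bitwise(self):
        table = make_table(n=100, seed=9)
        full = reduced_model_eval(table, {"full": FEATURE_SUBSETS["full"]},
                                  folds=3, iterations=1, seed=3,
                                  grid=[{"n_estimators": 25}])["full"]
        direct = train_eval_intra(table, "rf", folds=3, iterations=1, seed=3,
                                  grid=[{"n_estimators": 25}])
        for a, b in zip(full, direct):
            assert a.youden == b.youden

    def test_canonical_subset_sizes(self):
        assert [len(v) for v in FEATURE_SUBSETS.values()] == [1, 3, 6, 11]

    def test_pitch_only_signal_single_feature_suffices(self):
        table = make_table(n=200, sep=4.0, seed=12)
        out = reduced_model_eval(table, {"mean_ax": ["mean_ax"],
                                         "full": FEATURE_SUBSETS["full"]},
                                 folds=5, iterations=1, seed=0,
                                 grid=[{"n_estimators": 50}])
        y1 = np.mean([r.youden for r in out["mean_ax"]])
        y11 = np.mean([r.youden for r in out["full"]])
        assert abs(y1 - y11) < 0.1

    def test_unknown_subset_feature_rejected(self):
        with pytest.raises(ValidationError):
            reduced_model_eval(make_table(50), {"bad": ["not_a_feature"]})


class TestNestedCvIntegrity:
    def test_selection_never_touches_outer_test_rows(self):
        table = make_table(n=120, seed=13)
        res = train_eval_intra(table, "rf", folds=4, iterations=2, seed=0,
                               grid=FAST_GRID)
        for r in res:
            assert len(r.selection_indices) > 0
            assert not set(r.selection_indices) & set(r.test_indices)

    def test_inter_subject_selection_stays_off_held_out_subject(self):
        tables = {f"s{i}": make_table(60, seed=30 + i) for i in range(3)}
        res = train_eval_inter(tables, "rf", seed=0, grid=FAST_GRID)
        for r in res:
            assert not set(r.selection_indices) & set(r.test_indices)
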