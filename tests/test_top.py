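import numpy as np
import pandas as pd
import pytest

import pantop
from pantop.io import write_model
from pantop.top import (
    _fit_l1,
    lambda_max,
    make_ratio_set,
    prepare_collection,
)

from conftest import dyadic, make_array_dataset


class TestRatioSet:
    @pytest.mark.parametrize("p", [2, 5, 50])
    def test_pair_count(self, p):
        rs = make_ratio_set([f"g{i}" for i in range(p)])
        assert rs.q == p * (p - 1) // 2

    def test_fifty_gene_panel_gives_1225_ratios(self):
        assert make_ratio_set([f"g{i}" for i in range(50)]).q == 1225

    def test_pairs_sorted_without_self_pairs(self):
        rs = make_ratio_set(list("abcd"))
        assert rs.pairs == sorted(rs.pairs)
        assert all(l < m for l, m in rs.pairs)


class TestLogRatioMatrix:
    def test_pair_column_is_difference(self):
        M = pd.DataFrame([[3.0, 1.0], [1.0, 4.0]], index=["a", "b"], columns=["s1", "s2"])
        Z = pantop.build_log_ratio_matrix(M, make_ratio_set(["a", "b"]))
        np.testing.assert_array_equal(Z, [[2.0], [-3.0]])

    def test_missing_panel_gene_is_error(self):
        M = pd.DataFrame([[1.0]], index=["a"], columns=["s"])
        with pytest.raises(KeyError, match="b"):
            pantop.build_log_ratio_matrix(M, make_ratio_set(["a", "b"]))

    def test_per_sample_shift_cancels_bit_identically(self):
        rng = np.random.default_rng(0)
        M = dyadic(rng, (10, 6))
        offs = dyadic(rng, 6, scale=8.0)
        frame = pd.DataFrame(M, index=[f"g{i}" for i in range(10)],
                             columns=[f"s{j}" for j in range(6)])
        rs = make_ratio_set(list(frame.index))
        Z1 = pantop.build_log_ratio_matrix(frame, rs)
        Z2 = pantop.build_log_ratio_matrix(frame + offs, rs)
        assert np.array_equal(Z1, Z2)


class TestRatioFoldChanges:
    def test_identical_groups_give_zero(self):
        Z = np.array([[1.0, 2.0], [3.0, -1.0], [1.0, 2.0], [3.0, -1.0]])
        x = pantop.ratio_fold_changes(Z, np.array([0, 0, 1, 1]))
        np.testing.assert_array_equal(x, [0.0, 0.0])

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        Z[y == 1, 1] = Z[y == 0, 1] + 0.75
        x = pantop.ratio_fold_changes(Z, y)
        assert x[1] == pytest.approx(0.75, abs=1e-12)

    def test_antisymmetry_under_pair_swap(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(10, 4))
        y = np.repeat([0, 1], 5)
        np.testing.assert_allclose(
            pantop.ratio_fold_changes(-Z, y), -pantop.ratio_fold_changes(Z, y)
        )

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="classes"):
            pantop.ratio_fold_changes(np.ones((3, 2)), np.zeros(3))


class TestFeatureWeights:
    def test_equal_sizes_reduce_to_plain_mean(self):
        x = np.array([[1.0, 3.0], [0.0, 2.0]])
        st = pantop.feature_weights(x, [25, 25])
        np.testing.assert_allclose(st.weighted_mean, x.mean(axis=1))

    def test_zero_mean_gives_zero_weight(self):
        st = pantop.feature_weights(np.array([[1.0, -1.0], [1.0, 1.0]]), [10, 10])
        assert st.t_stat[0] == 0.0 and st.feature_weights[0] == 0.0

    def test_fudge_is_linear_interpolation_quantile(self):
        # equal weights, rows (0, 2*sqrt(v)) have weighted variance exactly v
        x = np.array([[0.0, 2 * np.sqrt(v)] for v in range(1, 11)])
        st = pantop.feature_weights(x, [30, 30])
        np.testing.assert_allclose(st.weighted_var, np.arange(1, 11), atol=1e-12)
        assert st.fudge == pytest.approx(9.1, abs=1e-12)

    def test_weighted_mean_hand_example(self):
        st = pantop.feature_weights(np.array([[1.0, 2.0]]), [10, 40])
        assert st.weighted_mean[0] == pytest.approx(1.2, abs=1e-12)

    def test_nonpositive_sample_size_error(self):
        with pytest.raises(ValueError, match="positive"):
            pantop.feature_weights(np.ones((2, 2)), [10, 0])

    def test_single_dataset_degenerates_to_fold_change(self):
        st = pantop.feature_weights(np.array([[0.5], [-2.0]]), [20])
        np.testing.assert_allclose(st.t_stat, [0.5, -2.0])
        np.testing.assert_allclose(st.feature_weights, np.sqrt([0.5, 2.0]))


def _tiny_dataset(dataset_id, organ, n=4, seed=0):
    rng = np.random.default_rng(seed)
    return make_array_dataset(
        rng.normal(6, 1, size=(3, n)), [0, 1] * (n // 2), dataset_id, organ
    )


class TestOrganWeights:
    def test_sixteen_datasets_weight_half(self):
        coll = pantop.DatasetCollection(
            [_tiny_dataset(f"k{i}", "kidney", seed=i) for i in range(16)]
        )
        ow = pantop.organ_sample_weights(coll)
        assert ow.organ_weight["kidney"] == pytest.approx(0.5, abs=1e-15)

    def test_single_dataset_weight_one(self):
        coll = pantop.DatasetCollection([_tiny_dataset("h1", "heart")])
        assert pantop.organ_sample_weights(coll).organ_weight["heart"] == 1.0

    def test_equal_counts_equal_weights(self):
        coll = pantop.DatasetCollection(
            [_tiny_dataset("k1", "kidney"), _tiny_dataset("h1", "heart")]
        )
        ow = pantop.organ_sample_weights(coll)
        stacked = np.concatenate(list(ow.sample_weights.values()))
        assert np.unique(stacked).size == 1


class TestWeightedLasso:
    def test_huge_penalty_gives_weighted_prevalence_intercept(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(40, 6))
        y = rng.binomial(1, 0.5, 40)
        y[:2] = [0, 1]
        w_s = rng.uniform(0.5, 2.0, 40)
        b0, beta, _ = pantop.fit_weighted_lasso(
            Z, y, np.ones(6), w_s, lam=1e4, loss="logistic"
        )
        assert np.count_nonzero(beta) == 0
        prev = np.sum(w_s * y) / w_s.sum()
        assert b0 == pytest.approx(np.log(prev / (1 - prev)), abs=1e-6)

    def test_unpenalized_single_column_matches_wls(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=30)
        y = rng.binomial(1, 0.5, 30).astype(float)
        y[:2] = [0, 1]
        w = rng.uniform(0.5, 2.0, 30)
        b0, beta, _ = pantop.fit_weighted_lasso(
            z[:, None], y.astype(int), np.ones(1), w, lam=0.0, loss="squared"
        )
        zc = z - np.sum(w * z) / w.sum()
        yc = y - np.sum(w * y) / w.sum()
        slope = np.sum(w * zc * yc) / np.sum(w * zc * zc)
        assert beta[0] == pytest.approx(slope, abs=1e-8)

    def test_zero_weight_columns_excluded(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 3))
        y = np.repeat([0, 1], 15)
        Z[:, 0] = y * 10.0  # hugely predictive but weight 0
        w_f = np.array([0.0, 1.0, 1.0])
        _, beta, _ = pantop.fit_weighted_lasso(Z, y, w_f, np.ones(30), lam=0.1)
        assert beta[0] == 0.0

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="feature weights"):
            pantop.fit_weighted_lasso(
                np.ones((4, 2)), np.array([0, 1, 0, 1]), np.zeros(2), np.ones(4), lam=1.0
            )

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single class"):
            pantop.fit_weighted_lasso(
                np.ones((4, 2)), np.zeros(4), np.ones(2), np.ones(4), lam=1.0
            )

    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(50, 8))
        y = rng.binomial(1, 0.4, 50)
        y[:2] = [0, 1]
        for loss in ("logistic", "squared"):
            lmax = lambda_max(Z, y, np.ones(50), loss)
            b0, beta = _fit_l1(Z, y, np.ones(50), lmax * 1.001, loss, seed=0)
            assert np.count_nonzero(beta) == 0

    def test_penalty_path_sparsity_monotone(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(60, 15))
        beta_true = np.zeros(15)
        beta_true[:4] = [2.0, -1.5, 1.0, 0.5]
        y = (Z @ beta_true + rng.normal(size=60) > 0).astype(int)
        lmax = lambda_max(Z, y, np.ones(60), "logistic")
        counts = []
        for lam in np.geomspace(lmax, lmax * 1e-3, 12):
            _, beta = _fit_l1(Z, y, np.ones(60), lam, "logistic", seed=0)
            counts.append(int(np.sum(np.abs(beta) > 1e-10)))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSelection:
    def test_top_one_gene_is_minimum_combined_p(self, small_collection):
        coll, _ = small_collection
        top1 = pantop.select_top_genes(coll, n=1)
        top5 = pantop.select_top_genes(coll, n=5)
        assert top1[0] == top5[0]
        assert len(top1) == 1

    def test_gene_absent_from_one_dataset_excluded(self):
        rng = np.random.default_rng(8)
        M1 = rng.normal(6, 1, size=(6, 20))
        y = np.repeat([0, 1], 10)
        M1[0, y == 1] += 10.0  # enormous effect for gene g0
        d1 = make_array_dataset(M1, y, "d1", "kidney")
        # second dataset lacks g0 entirely
        M2 = rng.normal(6, 1, size=(5, 20))
        d2 = make_array_dataset(
            M2, y, "d2", "heart", genes=[f"g{i}" for i in range(1, 6)]
        )
        panel = pantop.select_top_genes(pantop.DatasetCollection([d1, d2]), n=3)
        assert "g0" not in panel

    def test_planted_shared_signal_recovered(self, small_collection):
        coll, truth = small_collection
        panel = pantop.select_top_genes(coll, n=50)
        recall = len(set(panel) & set(truth.shared_genes)) / len(truth.shared_genes)
        assert recall >= 0.8

    def test_fixed_panel_preserved_and_filtered(self, small_collection):
        coll, _ = small_collection
        genes = coll.gene_intersection()
        panel = [genes[3], genes[1], genes[3], "NOT_A_GENE", genes[0]]
        with pytest.warns(UserWarning, match="missing"):
            kept = pantop.select_fixed_panel(coll, panel)
        assert kept == [genes[3], genes[1], genes[0]]

    def test_fixed_panel_fully_absent_error(self, small_collection):
        coll, _ = small_collection
        with pytest.raises(ValueError, match="present"):
            pantop.select_fixed_panel(coll, ["NOPE1", "NOPE2"])


class TestTrainPredict:
    def test_same_seed_byte_identical_model(self, small_collection, fast_config, tmp_path):
        coll, _ = small_collection
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model(pantop.train_top(coll, fast_config), p1)
        write_model(pantop.train_top(coll, fast_config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_dataset_collection_trains(self):
        rng = np.random.default_rng(9)
        M = rng.normal(6, 1, size=(40, 30))
        y = np.repeat([0, 1], 15)
        M[:5, y == 1] += 2.0
        ds = make_array_dataset(M, y, "only", "kidney")
        model = pantop.train_top(
            pantop.DatasetCollection([ds]),
            pantop.TOPConfig(n_features=6, loss="squared", n_lambda=10, cv_folds=3),
        )
        assert model.ratio_set.q == 15

    def test_zero_coefficients_predict_constant(self, small_collection):
        coll, _ = small_collection
        model = pantop.train_top(
            coll, pantop.TOPConfig(n_features=6, loss="logistic", lam=1e4)
        )
        assert model.n_nonzero == 0
        prep = pantop.prepare_dataset(coll.datasets[0], for_training=False)
        pred = pantop.predict_risk(model, prep.frame())
        assert np.allclose(pred["logit_score"], model.beta0)

    def test_prediction_shift_invariance_bit_identical(self, small_collection, fast_config):
        coll, _ = small_collection
        model = pantop.train_top(coll, fast_config)
        rng = np.random.default_rng(10)
        M = pd.DataFrame(
            dyadic(rng, (len(model.ratio_set.panel), 8)),
            index=model.ratio_set.panel,
            columns=[f"s{j}" for j in range(8)],
        )
        offs = dyadic(rng, 8, scale=8.0)
        s1 = pantop.predict_risk(model, M)["logit_score"].to_numpy()
        s2 = pantop.predict_risk(model, M + offs)["logit_score"].to_numpy()
        assert np.array_equal(s1, s2)

    def test_probability_monotone_in_score(self, small_collection, fast_config):
        coll, _ = small_collection
        model = pantop.train_top(
            coll, pantop.TOPConfig(n_features=8, loss="logistic", n_lambda=10)
        )
        prep = pantop.prepare_dataset(coll.datasets[0], for_training=False)
        pred = pantop.predict_risk(model, prep.frame()).sort_values("logit_score")
        assert pred["probability"].is_monotonic_increasing

    def test_pair_swap_with_negated_coefficient_equivalent(self, small_collection, fast_config):
        coll, _ = small_collection
        model = pantop.train_top(coll, fast_config)
        j = int(np.flatnonzero(model.beta)[0])
        swapped = pantop.TOPModel.from_dict(model.to_dict())
        l, m = swapped.ratio_set.pairs[j]
        swapped.ratio_set.pairs[j] = (m, l)
        swapped.beta[j] = -swapped.beta[j]
        prep = pantop.prepare_dataset(coll.datasets[0], for_training=False)
        np.testing.assert_array_equal(
            pantop.predict_risk(model, prep.frame())["logit_score"],
            pantop.predict_risk(swapped, prep.frame())["logit_score"],
        )

    def test_balanced_equals_naive_with_equal_representation(self):
        rng = np.random.default_rng(11)
        datasets = []
        for organ in ("kidney", "heart"):
            for rep in range(2):
                M = rng.normal(6, 1, size=(30, 24))
                y = np.tile([0, 1], 12)
                M[:4, y == 1] += 1.5
                datasets.append(
                    make_array_dataset(M, y, f"{organ}{rep}", organ)
                )
        coll = pantop.DatasetCollection(datasets)
        kwargs = dict(n_features=6, loss="squared", lam=2.0)
        balanced = pantop.train_top(coll, pantop.TOPConfig(**kwargs))
        naive = pantop.train_top(
            coll, pantop.TOPConfig(organ_weighting="naive", **kwargs)
        )
        np.testing.assert_allclose(balanced.beta, naive.beta, atol=1e-6)
        assert balanced.beta0 == pytest.approx(naive.beta0, abs=1e-6)

    def test_selected_ratios_touch_planted_genes_across_seeds(self):
        hits = 0
        for seed in range(10):
            spec = pantop.SyntheticSpec(
                organs={"kidney": 2, "heart": 1},
                n_genes=300,
                n_samples_range=(30, 30),
                organ_specific={"kidney": (5, 1.0), "heart": (5, 1.0)},
            )
            coll, truth = pantop.generate_collection(spec, seed=100 + seed)
            model = pantop.train_top(
                coll, pantop.TOPConfig(n_features=8, loss="squared", n_lambda=10)
            )
            planted = truth.planted_all()
            touched = {
                model.ratio_set.panel[i]
                for j in np.flatnonzero(model.beta)
                for i in model.ratio_set.pairs[j]
            }
            hits += bool(touched & planted)
        assert hits >= 9
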