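import dataclasses

import numpy as np
import pytest

from ersnet.ensemble import (
    EnsembleModel,
    assign_folds,
    convergence_analysis,
    crossvalidate,
    ensemble_predict,
    evaluate,
    load_ensemble,
    member_predictions,
    save_ensemble,
    train_ensemble,
)
from ersnet.model import ModelConfig, SecretionRecord, predict, train_model


class TestEnsembleTraining:
    def test_single_member_equals_its_model(self, small_records, tiny_config, random_tails):
        ens = train_ensemble(small_records, n_models=1, config=tiny_config, base_seed=5)
        solo = train_model(small_records, tiny_config.replace(seed=5))
        tails = random_tails(10)
        means, sds = ensemble_predict(ens, tails)
        assert np.allclose(means, predict(solo, tails))
        assert np.allclose(sds, 0.0)

    def test_member_seeds_are_base_plus_index(self, small_records, tiny_config):
        ens = train_ensemble(small_records, n_models=3, config=tiny_config, base_seed=10)
        assert [m.config.seed for m in ens.members] == [10, 11, 12]

    def test_retraining_reproduces_parameters(self, small_records, tiny_config):
        e1 = train_ensemble(small_records, n_models=4, config=tiny_config, base_seed=0)
        e2 = train_ensemble(small_records, n_models=4, config=tiny_config, base_seed=0)
        for m1, m2 in zip(e1.members, e2.members):
            for k in m1.params:
                assert np.array_equal(m1.params[k], m2.params[k])

    def test_mean_is_average_of_member_predictions(self, small_records, tiny_config,
                                                   random_tails):
        """Brute-force recomputation oracle: predict members independently."""
        ens = train_ensemble(small_records, n_models=5, config=tiny_config, base_seed=2)
        tails = random_tails(12)
        means, sds = ensemble_predict(ens, tails)
        stacked = np.stack([predict(m, tails) for m in ens.members])
        assert np.allclose(means, stacked.mean(axis=0))
        assert np.allclose(sds, stacked.std(axis=0))
        assert (means >= 0).all()

    def test_hand_mean_of_two_members(self, small_records, tiny_config, random_tails):
        ens = train_ensemble(small_records, n_models=2, config=tiny_config, base_seed=3)
        tails = random_tails(5)
        p = member_predictions(ens, tails)
        means, _ = ensemble_predict(ens, tails)
        assert means[0] == pytest.approx((p[0, 0] + p[1, 0]) / 2)

    def test_copies_of_one_model_have_zero_sd(self, small_records, tiny_config,
                                              random_tails):
        m = train_model(small_records, tiny_config)
        ens = EnsembleModel(members=[m, m, m], base_seed=0)
        _, sds = ensemble_predict(ens, random_tails(8))
        assert np.allclose(sds, 0.0)

    def test_ensemble_mse_not_worse_than_median_member(self):
        """Averaging members reduces held-out error: the ensemble's MSE is at
        most the median member's MSE on a synthetic split."""
        from ersnet.simulate import default_ground_truth, sample_dataset

        gt = default_ground_truth(13)
        train = sample_dataset(gt, n=60, seed=1)
        test = sample_dataset(gt, n=60, seed=2)
        config = ModelConfig(hidden_size=16, fc_width=8, iterations=600, seed=0)
        ens = train_ensemble(train, n_models=8, config=config, base_seed=0)
        tails = [r.tail for r in test]
        obs = np.array([r.response for r in test])
        member_mse = [float(np.mean((predict(m, tails) - obs) ** 2))
                      for m in ens.members]
        means, _ = ensemble_predict(ens, tails)
        ens_mse = float(np.mean((means - obs) ** 2))
        assert ens_mse <= float(np.median(member_mse))

    def test_empty_ensemble_rejected(self, random_tails):
        with pytest.raises(ValueError, match="no members"):
            member_predictions(EnsembleModel(members=[], base_seed=0), random_tails(2))


class TestEvaluate:
    def test_identical_vectors_give_unit_correlations(self):
        rep = evaluate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep.value_correlation == pytest.approx(1.0)
        assert rep.rank_correlation == pytest.approx(1.0)
        assert rep.n == 4

    def test_reversed_order_gives_rank_minus_one(self):
        rep = evaluate([4.0, 3.0, 2.0, 1.0], [1.0, 2.0, 5.0, 9.0])
        assert rep.rank_correlation == pytest.approx(-1.0)

    def test_hand_expanded_pearson_oracle(self):
        # predicted (1,2,3,5), observed (2,4,6,8):
        # r = cov / (sd_p * sd_o) computed by hand:
        # means 2.75, 5; cov*4 = sum(p*o) - 4*2.75*5 = (2+8+18+40) - 55 = 13
        # var_p*4 = (1+4+9+25) - 4*2.75^2 = 39 - 30.25 = 8.75
        # var_o*4 = (4+16+36+64) - 100 = 20
        expected = 13 / np.sqrt(8.75 * 20)
        rep = evaluate([1.0, 2.0, 3.0, 5.0], [2.0, 4.0, 6.0, 8.0])
        assert rep.value_correlation == pytest.approx(expected)
        assert rep.rank_correlation == pytest.approx(1.0)

    def test_errors_on_mismatch_and_constant_vectors(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def pool_and_data():
    rng = np.random.default_rng(99)
    from conftest import random_tail

    tails = [random_tail(rng) for _ in range(30)]
    records = [SecretionRecord(t, float(r))
               for t, r in zip(tails, rng.uniform(0.3, 5.0, 30))]
    config = ModelConfig(hidden_size=8, fc_width=4, iterations=40, seed=0)
    pool = train_ensemble(records, n_models=8, config=config, base_seed=100)
    return pool, records


class TestConvergence:
    def test_sd_zero_at_full_pool_and_nonincreasing_trend(self, pool_and_data):
        pool, records = pool_and_data
        curve = convergence_analysis(pool, records, n_bootstrap=60, rng_seed=1)
        sd = curve.table["sd_pearson_r"].to_numpy()
        assert sd[-1] == pytest.approx(0.0, abs=1e-12)
        # dispersion shrinks as more members are averaged (MC tolerance)
        for k in range(1, len(sd)):
            assert sd[k] <= sd[:k].max() + 0.01

    def test_identical_members_converge_at_k1(self, small_records, tiny_config):
        m = train_model(small_records, tiny_config)
        pool = EnsembleModel(members=[m] * 4, base_seed=0)
        curve = convergence_analysis(pool, small_records, n_bootstrap=20, rng_seed=0)
        assert np.allclose(curve.table["sd_pearson_r"], 0.0)
        assert curve.converged_k == 2  # slope defined from the first difference

    def test_seeded_curve_is_reproducible(self, pool_and_data):
        pool, records = pool_and_data
        c1 = convergence_analysis(pool, records, n_bootstrap=25, rng_seed=7)
        c2 = convergence_analysis(pool, records, n_bootstrap=25, rng_seed=7)
        assert c1.table.equals(c2.table)

    def test_constant_responses_rejected(self, pool_and_data):
        pool, _ = pool_and_data
        flat = [SecretionRecord("TAEKDEL", 2.0)] * 5
        with pytest.raises(ValueError, match="distinct"):
            convergence_analysis(pool, flat)


class TestCrossValidation:
    def test_fold_assignment_is_a_partition(self):
        labels = assign_folds(10, folds=2, seed=4)
        assert sorted(np.bincount(labels)) == [5, 5]
        labels10 = assign_folds(95, folds=10, seed=1)
        assert labels10.size == 95 and set(labels10) == set(range(10))

    def test_single_config_grid_returns_it(self, small_records, tiny_config):
        best, table = crossvalidate(small_records, folds=3, grid=[tiny_config], seed=0)
        assert best == tiny_config
        assert len(table) == 1

    def test_trained_config_beats_untrained(self, small_records, rng):
        """A config with zero iterations cannot fit the data; CV must prefer
        the trained one."""
        trained = ModelConfig(hidden_size=8, fc_width=4, iterations=60, seed=0)
        untrained = trained.replace(iterations=0)
        best, table = crossvalidate(small_records, folds=3,
                                    grid=[untrained, trained], seed=2)
        assert best == trained
        assert table["mean_val_mse"].idxmin() == 1

    def test_errors(self, small_records):
        with pytest.raises(ValueError, match="grid"):
            crossvalidate(small_records, folds=2, grid=[], seed=0)
        with pytest.raises(ValueError, match="exceed"):
            crossvalidate(small_records[:3], folds=5,
                          grid=[ModelConfig(iterations=0)], seed=0)


class TestSerialization:
    def test_ensemble_directory_round_trip(self, small_records, tiny_config,
                                           tmp_path, random_tails):
        ens = train_ensemble(small_records, n_models=3, config=tiny_config, base_seed=9)
        save_ensemble(ens, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        tails = random_tails(6)
        m1, _ = ensemble_predict(ens, tails)
        m2, _ = ensemble_predict(back, tails)
        assert np.array_equal(m1, m2)
        assert back.base_seed == 9
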