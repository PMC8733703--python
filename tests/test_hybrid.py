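import numpy as np
import pytest

from hybridoe.ann_core import TrainConfig, fit_scaler, init_network
from hybridoe.hybrid import (
    CvConfig,
    Ensemble,
    HybridModel,
    MODEL_INPUT_NAMES,
    _input_matrix,
    average_predict,
    evaluate,
    fit_hybrid,
    hybrid_residuals,
    nrmse,
    predict_at_samples,
    predict_run,
)
from hybridoe.mechanistic import integrate_states


@pytest.fixture(scope="module")
def scaler(transfer_data):
    runs = transfer_data["train"]
    return fit_scaler(_input_matrix(runs, MODEL_INPUT_NAMES), names=list(MODEL_INPUT_NAMES))


def _model_with_constant_rates(scaler, mu, vpx):
    net = init_network(0)
    net.set_weights(np.zeros_like(net.get_weights()))
    model = HybridModel(scaler=scaler, net=net)
    net.b_o = np.array([mu / model.mu_ref, vpx / model.v_ref])
    return model


class TestNrmse:
    def test_hand_computed_values(self):
        assert nrmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert nrmse([2.0, 2.0], [1.0, 3.0]) == pytest.approx(50.0)
        assert nrmse([1, 2, 3], [1, 2, 6]) == pytest.approx(86.6025, abs=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            nrmse([1, 2], [1.0])
        with pytest.raises(ValueError, match="zero"):
            nrmse([1.0, -1.0], [0.0, 0.0])


class TestPredictRun:
    def test_zero_rates_give_pure_dilution_decay(self, scaler, transfer_data):
        run = transfer_data["train"][0]  # shake flask
        model = _model_with_constant_rates(scaler, 0.0, 0.0)
        traj = predict_run(model, run)
        # cells only diluted by boluses: X * V conserved
        NV = traj.X * traj.V
        np.testing.assert_allclose(NV, NV[0], rtol=1e-6)
        np.testing.assert_allclose(traj.P, 0.0, atol=1e-12)

    def test_constant_growth_is_exponential(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        model = _model_with_constant_rates(scaler, 0.02, 0.0)
        traj = predict_run(model, run)
        NV = traj.X * traj.V
        np.testing.assert_allclose(
            NV, NV[0] * np.exp(0.02 * traj.times), rtol=1e-6
        )

    def test_oracle_rates_reproduce_the_simulator(
        self, shaker_cp_noiseless, shaker_cp_truth
    ):
        """Wrapping the simulator's true rates as the rate function and
        integrating the mass balances reproduces the simulated states."""
        truth = shaker_cp_truth
        rate_fn = lambda t: (
            np.interp(t, truth["times"], truth["mu"]),
            np.interp(t, truth["times"], truth["vpx"]),
        )
        traj = integrate_states(rate_fn, shaker_cp_noiseless, X0=0.25, P0=0.0)
        t_s = shaker_cp_noiseless.samples.times
        Xs = np.interp(t_s, traj.times, traj.X)
        X_true = shaker_cp_noiseless.samples.vcc
        assert np.max(np.abs(Xs - X_true) / X_true.max()) < 0.01

    def test_quadrature_path_matches_ode_path(self, scaler, transfer_data):
        runs = [transfer_data["train"][0], transfer_data["test"][0]]
        for seed in (3, 11):
            net = init_network(seed)
            model = HybridModel(scaler=scaler, net=net)
            for run in runs:
                traj = predict_run(model, run)
                Xq, Pq = predict_at_samples(model, run)
                idx = np.searchsorted(traj.times, run.samples.times)
                sx = max(np.abs(traj.X).max(), 1e-9)
                sp = max(np.abs(traj.P).max(), 1e-9)
                assert np.max(np.abs(Xq - traj.X[idx])) / sx < 1e-3
                assert np.max(np.abs(Pq - traj.P[idx])) / sp < 1e-3


class TestResiduals:
    def test_perfect_predictions_give_zero_residuals(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        model = _model_with_constant_rates(scaler, 0.01, 1e-4)
        X, P = predict_at_samples(model, run)
        fake = type(run)(**{**run.__dict__})
        fake.samples = type(run.samples)(
            times=run.samples.times, vcc=X, viability=run.samples.viability,
            titer=P, analytes=run.samples.analytes,
        )
        r = hybrid_residuals(model, [fake])
        assert np.max(np.abs(r)) < 1e-9

    def test_length_counts_both_targets(self, scaler, transfer_data):
        runs = transfer_data["train"][:3]
        model = _model_with_constant_rates(scaler, 0.01, 1e-4)
        r = hybrid_residuals(model, runs)
        assert len(r) == sum(2 * rr.samples.n_samples() for rr in runs)

    def test_unit_entry_for_mean_sized_error(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        model = _model_with_constant_rates(scaler, 0.01, 1e-4)
        X, P = predict_at_samples(model, run)
        mean_vcc = float(np.mean(run.samples.vcc))
        fake = type(run)(**{**run.__dict__})
        vcc = X.copy()
        vcc[4] += mean_vcc  # off by exactly one training-set mean
        fake.samples = type(run.samples)(
            times=run.samples.times, vcc=vcc, viability=run.samples.viability,
            titer=P, analytes=run.samples.analytes,
        )
        r = hybrid_residuals(model, [fake], weighting=(mean_vcc, float(np.mean(P))))
        np.testing.assert_allclose(r[4], 1.0, rtol=1e-9)


class TestFitHybrid:
    def test_member_counts_random_split(self, transfer_data):
        runs = transfer_data["train"][:6] + transfer_data["train"][18:20]
        ens = fit_hybrid(
            runs, CvConfig(n_repeats=3, seed=5), TrainConfig(max_iter=5, patience=2)
        )
        assert len(ens.members) == 3
        assert all(len(p["val_runs"]) >= 1 for p in ens.partitions)

    def test_member_counts_leave_one_run_out(self, transfer_data):
        runs = transfer_data["test"][:4]
        ens = fit_hybrid(
            runs,
            CvConfig(mode="leave_one_run_out", seed=5),
            TrainConfig(max_iter=5, patience=2),
        )
        assert len(ens.members) == 4
        val_ids = [tuple(p["val_runs"]) for p in ens.partitions]
        assert len(set(val_ids)) == 4  # each member validated on a distinct run

    def test_ensemble_roundtrip(self, tmp_path, transfer_data):
        runs = transfer_data["train"][:4] + transfer_data["train"][18:20]
        ens = fit_hybrid(
            runs, CvConfig(n_repeats=2, seed=1), TrainConfig(max_iter=4, patience=2)
        )
        ens.save(tmp_path / "ens")
        loaded = Ensemble.load(tmp_path / "ens")
        assert len(loaded.members) == len(ens.members)
        for a, b in zip(ens.members, loaded.members):
            np.testing.assert_array_equal(a.net.get_weights(), b.net.get_weights())


class TestEnsembleAveraging:
    def _two_member_ensemble(self, scaler, mus):
        members = [_model_with_constant_rates(scaler, mu, 1e-4) for mu in mus]
        return Ensemble(members=members, seed=0)

    def test_identical_members_have_zero_sd(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        ens = self._two_member_ensemble(scaler, [0.01, 0.01])
        pred = average_predict(ens, run)
        np.testing.assert_allclose(pred.sd_x, 0.0, atol=1e-12)
        np.testing.assert_allclose(pred.ci_x_upper, pred.ci_x_lower, atol=1e-12)

    def test_two_member_spread_matches_hand_formula(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        ens = self._two_member_ensemble(scaler, [0.005, 0.02])
        pred = average_predict(ens, run)
        X0, _ = predict_at_samples(ens.members[0], run)
        X1, _ = predict_at_samples(ens.members[1], run)
        # n=2: SD(t) = sqrt( sum (avg - member)^2 / (n-1) ) = |x0-x1|/sqrt(2)
        np.testing.assert_allclose(pred.sd_x, np.abs(X0 - X1) / np.sqrt(2), rtol=1e-10)
        np.testing.assert_allclose(pred.x_hat, 0.5 * (X0 + X1), rtol=1e-12)

    def test_hand_arithmetic_of_sd_definition(self):
        # members predicting 1 and 3: mean 2, SD = sqrt((1+1)/1)
        vals = np.array([1.0, 3.0])
        sd = np.sqrt(np.sum((vals.mean() - vals) ** 2) / (len(vals) - 1))
        assert sd == pytest.approx(np.sqrt(2.0))
        assert np.std(vals, ddof=1) == pytest.approx(sd)

    def test_ci_symmetric_about_mean(self, scaler, transfer_data):
        run = transfer_data["train"][1]
        ens = self._two_member_ensemble(scaler, [0.005, 0.02])
        pred = average_predict(ens, run)
        np.testing.assert_allclose(
            pred.ci_x_upper - pred.x_hat, pred.x_hat - pred.ci_x_lower, rtol=1e-12
        )

    def test_sd_zero_iff_members_agree(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        same = self._two_member_ensemble(scaler, [0.01, 0.01])
        diff = self._two_member_ensemble(scaler, [0.01, 0.011])
        assert np.all(average_predict(same, run).sd_x < 1e-12)
        assert np.all(average_predict(diff, run).sd_x[1:] > 0)


class TestEvaluate:
    def test_single_run_matches_nrmse(self, scaler, transfer_data):
        run = transfer_data["train"][0]
        ens = Ensemble(
            members=[
                _model_with_constant_rates(scaler, 0.005, 1e-4),
                _model_with_constant_rates(scaler, 0.02, 1e-4),
            ],
            seed=0,
        )
        rep = evaluate(ens, [run])
        pred = average_predict(ens, run)
        assert rep["nrmse_vcc"] == pytest.approx(nrmse(run.samples.vcc, pred.x_hat))
        assert rep["per_run"][run.run_id]["nrmse_vcc"] == pytest.approx(rep["nrmse_vcc"])

    def test_pooled_between_min_and_max_when_means_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y1 = rng.uniform(1, 3, size=8)
            y1 = y1 / y1.mean() * 2.0
            y2 = rng.uniform(1, 3, size=8)
            y2 = y2 / y2.mean() * 2.0
            e1 = rng.normal(scale=0.3, size=8)
            e2 = rng.normal(scale=0.3, size=8)
            n1 = nrmse(y1, y1 + e1)
            n2 = nrmse(y2, y2 + e2)
            pooled = nrmse(np.concatenate([y1, y2]), np.concatenate([y1 + e1, y2 + e2]))
            assert min(n1, n2) - 1e-9 <= pooled <= max(n1, n2) + 1e-9
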