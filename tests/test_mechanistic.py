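import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridoe.datamodel import CultivationRun, Design, FeedSchedule, SampleSeries, Segment
from hybridoe.mechanistic import (
    apply_bolus,
    dilution_rate,
    estimate_specific_rates,
    integrate_states,
    interpolate_inputs,
)
from hybridoe.synthetic import feed_composition


def _bare_run(scale="shake_flask", mode="bolus", t_end=96.0, n=5, working_volume=0.3):
    """Minimal run with flat analytes, for integrator unit tests."""
    times = np.linspace(0.0, t_end, n)
    return CultivationRun(
        run_id="unit",
        scale=scale,
        working_volume=working_volume,
        design=Design(doe_mode="static", segments=[Segment(72.0, 34.0, "F2")],
                      planned_duration=t_end),
        feed=FeedSchedule(mode=mode, composition=feed_composition()),
        samples=SampleSeries(
            times=times,
            vcc=np.full(n, 1.0),
            viability=np.full(n, 99.0),
            titer=np.zeros(n),
            analytes={"glutamine": np.linspace(1.0, 0.2, n)},
        ),
    )


class TestDilutionRate:
    def test_values_and_errors(self):
        assert dilution_rate(0.0, 15.0) == 0.0
        assert dilution_rate(0.015, 15.0) == pytest.approx(0.001)
        assert dilution_rate(0.5, 0.3) == pytest.approx(1.6667, rel=1e-4)
        with pytest.raises(ValueError):
            dilution_rate(0.1, 0.0)
        with pytest.raises(ValueError):
            dilution_rate(-0.1, 1.0)


class TestApplyBolus:
    def test_cell_dilution(self):
        X, P, _, V = apply_bolus(10.0, 0.0, {}, 0.3, 0.01, {})
        assert X == pytest.approx(10 * 0.3 / 0.31, abs=1e-10)
        assert V == pytest.approx(0.31)

    def test_zero_volume_is_identity(self):
        X, P, a, V = apply_bolus(5.0, 0.2, {"glucose": 3.0}, 0.3, 0.0, {"glucose": 41.0})
        assert (X, P, V) == (5.0, 0.2, 0.3)
        assert a["glucose"] == 3.0

    def test_analyte_mixing(self):
        _, _, a, _ = apply_bolus(1.0, 0.0, {"glucose": 1.0}, 0.3, 0.0099, {"glucose": 41.0})
        assert a["glucose"] == pytest.approx((0.3 + 0.4059) / 0.3099, rel=1e-4)

    @settings(deadline=None, max_examples=30)
    @given(
        X=st.floats(0.01, 30.0),
        P=st.floats(0.0, 2.0),
        V=st.floats(0.05, 20.0),
        frac=st.floats(1e-4, 0.099),
    )
    def test_mass_conservation(self, X, P, V, frac):
        vB = frac * V
        Xn, Pn, _, Vn = apply_bolus(X, P, {}, V, vB, {})
        assert Xn * Vn == pytest.approx(X * V, rel=1e-12)
        assert Pn * Vn == pytest.approx(P * V, rel=1e-12)


class TestIntegrateStates:
    def test_exponential_growth_closed_form(self):
        run = _bare_run(t_end=24.0, n=2)
        run.design = Design(doe_mode="static", segments=[Segment(72.0, 34.0, "F2")],
                            planned_duration=24.0)
        traj = integrate_states(lambda t: (0.03, 0.0), run, X0=0.25, P0=0.0)
        X24 = traj.X[np.searchsorted(traj.times, 24.0)]
        assert X24 == pytest.approx(0.25 * np.exp(0.72), rel=1e-6)

    def test_product_accumulation_closed_form(self):
        run = _bare_run(t_end=48.0, n=3)
        traj = integrate_states(lambda t: (0.0, 2e-4), run, X0=10.0, P0=0.0)
        # no boluses before 72 h, so P = v*X*t exactly
        P48 = traj.P[np.searchsorted(traj.times, 48.0)]
        assert P48 == pytest.approx(0.096, rel=1e-6)

    def test_steady_state_when_growth_matches_dilution(self):
        run = _bare_run(scale="bioreactor", mode="continuous", t_end=240.0, n=11,
                        working_volume=15.0)
        flow = run.feed.flow_at(100.0, 15.0)
        assert flow > 0
        # mu(t) tracks the (slowly declining) dilution rate of the linear feed
        traj = integrate_states(
            lambda t: (flow / (15.0 + flow * (t - 72.0)) if t >= 72.0 else 0.0, 0.0),
            run, X0=1.0, P0=0.0,
        )
        assert np.all(np.abs(traj.X - 1.0) < 1e-5)

    def test_grid_refinement_converges(self):
        run = _bare_run(t_end=96.0, n=5)
        rate = lambda t: (0.02 * np.sin(t / 30.0) + 0.01, 1e-4)
        t1 = integrate_states(rate, run, 0.25, 0.0, rtol=1e-8)
        t2 = integrate_states(rate, run, 0.25, 0.0, rtol=1e-10,
                              extra_times=np.arange(0, 96.1, 1.0))
        common = np.intersect1d(t1.times, t2.times)
        i1 = np.searchsorted(t1.times, common)
        i2 = np.searchsorted(t2.times, common)
        assert np.max(np.abs(t1.X[i1] - t2.X[i2]) / np.abs(t2.X[i2])) < 1e-6

    def test_non_finite_rate_names_time(self):
        run = _bare_run(t_end=48.0, n=3)
        with pytest.raises(RuntimeError, match="t="):
            integrate_states(lambda t: (np.nan, 0.0), run, 0.25, 0.0)


class TestInterpolateInputs:
    def test_nodes_midpoints_and_steps(self, small_noisy_runs):
        run = small_noisy_runs[0]
        t3 = run.samples.times[3]
        vec = interpolate_inputs(run, t3, ["glutamine", "alanine"])
        assert vec[0] == pytest.approx(run.samples.analytes["glutamine"][3])
        assert vec[1] == pytest.approx(run.samples.analytes["alanine"][3])
        mid = 0.5 * (run.samples.times[3] + run.samples.times[4])
        vec = interpolate_inputs(run, mid, ["glutamine"])
        expect = 0.5 * (
            run.samples.analytes["glutamine"][3] + run.samples.analytes["glutamine"][4]
        )
        assert vec[0] == pytest.approx(expect)

    def test_cpp_steps_are_right_continuous(self, transfer_data):
        idoe = [r for r in transfer_data["test"] if r.design.doe_mode == "intensified"][0]
        shift = idoe.design.segments[1].start_time
        before = interpolate_inputs(idoe, shift - 1e-6, ["temperature"])[0]
        after = interpolate_inputs(idoe, shift, ["temperature"])[0]
        assert before == idoe.design.segments[0].temperature
        assert after == idoe.design.segments[1].temperature

    def test_outside_span_raises(self, small_noisy_runs):
        with pytest.raises(ValueError, match="span"):
            interpolate_inputs(small_noisy_runs[0], 1e6, ["glutamine"])

    def test_ratio_uses_denominator_floor(self, small_noisy_runs):
        run = small_noisy_runs[0]
        run2 = CultivationRun(**{**run.__dict__})
        run2.samples = SampleSeries(
            times=run.samples.times,
            vcc=run.samples.vcc,
            viability=run.samples.viability,
            titer=run.samples.titer,
            analytes={**run.samples.analytes,
                      "glutamate": np.zeros_like(run.samples.times)},
        )
        vec = interpolate_inputs(run2, 24.0, ["asp_glu_ratio"])
        asp = np.interp(24.0, run2.samples.times, run2.samples.analytes["aspartate"])
        assert vec[0] == pytest.approx(asp / 1e-3)


class TestEstimateSpecificRates:
    def test_noiseless_exponential_growth(self):
        run = _bare_run(t_end=96.0, n=9)
        t = run.samples.times
        run.samples.vcc = 0.25 * np.exp(0.02 * t)
        run.samples.titer = np.zeros_like(t)
        rates = estimate_specific_rates(run)
        assert np.all(np.abs(rates.mu - 0.02) < 0.02 * 0.02)

    def test_constant_product_gives_zero_vpx(self):
        run = _bare_run(t_end=96.0, n=9)
        t = run.samples.times
        run.samples.vcc = 0.25 * np.exp(0.02 * t)
        run.samples.titer = np.full_like(t, 0.3)
        rates = estimate_specific_rates(run)
        assert np.max(np.abs(rates.vpx)) < 1e-8

    def test_recovers_simulator_growth_rate(self, shaker_cp_noiseless, shaker_cp_truth):
        """On the noiseless center point, the spline estimate at the end of
        the batch phase matches the simulator's true growth rate."""
        rates = estimate_specific_rates(shaker_cp_noiseless)
        mu_hat = rates.mu[np.searchsorted(rates.times, 72.0)]
        mu_true = np.interp(72.0, shaker_cp_truth["times"], shaker_cp_truth["mu"])
        assert mu_hat == pytest.approx(mu_true, rel=0.05)

    def test_rejects_nonpositive_vcc_and_short_series(self):
        run = _bare_run(t_end=96.0, n=9)
        run.samples.vcc = run.samples.vcc.copy()
        run.samples.vcc[2] = 0.0
        with pytest.raises(ValueError, match="positive"):
            estimate_specific_rates(run)
        short = _bare_run(t_end=48.0, n=3)
        with pytest.raises(ValueError, match="4 sampling points"):
            estimate_specific_rates(short)
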