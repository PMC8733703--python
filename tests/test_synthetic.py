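import numpy as np
import pytest
from dataclasses import replace

from hybridoe.datamodel import Design, Segment, validate_run
from hybridoe.synthetic import (
    GroundTruth,
    effective_cpp,
    make_bioreactor_designs,
    make_dataset,
    make_shaker_doe,
    simulate_run,
    simulate_truth,
)


class TestDesignFactories:
    def test_shaker_full_factorial_in_duplicate(self):
        designs = make_shaker_doe()
        assert len(designs) == 18
        cells = {}
        for d in designs:
            assert d.doe_mode == "static" and len(d.segments) == 1
            seg = d.segments[0]
            cells[(seg.temperature, seg.feed_level)] = cells.get(
                (seg.temperature, seg.feed_level), 0
            ) + 1
        assert len(cells) == 9 and all(v == 2 for v in cells.values())
        # run 9 (1-based) sits in the (34 C, F2) cell
        seg9 = designs[8].segments[0]
        assert (seg9.temperature, seg9.feed_level) == (34.0, "F2")

    def test_bioreactor_design_table(self):
        designs = make_bioreactor_designs()
        assert len(designs) == 11
        assert sum(d.doe_mode == "static" for d in designs) == 5
        assert sum(d.doe_mode == "intensified" for d in designs) == 6
        # run 1: the 36.3 C static culture
        assert designs[0].segments[0].temperature == 36.3
        assert designs[0].segments[0].feed_level == "F3"
        # run 4: full shift sequence
        segs = [(s.start_time, s.temperature, s.feed_level) for s in designs[3].segments]
        assert segs == [
            (72.0, 34.0, "F2"),
            (120.0, 37.0, "F2"),
            (192.0, 34.0, "F1"),
            (240.0, 31.0, "F1"),
        ]
        # run 3 shifts only at 192 h
        assert designs[2].shift_times == [192.0]
        # static runs have no shifts; the center point appears in triplicate
        assert all(d.shift_times == [] for d in designs if d.doe_mode == "static")
        center = [
            d for d in designs
            if d.doe_mode == "static"
            and (d.segments[0].temperature, d.segments[0].feed_level) == (34.0, "F2")
        ]
        assert len(center) == 3


class TestEffectiveCpp:
    def test_static_design_reaches_set_point(self):
        d = Design(doe_mode="static", segments=[Segment(72.0, 31.0, "F1")])
        T, G = effective_cpp(d, tau=48.0, t=350.0)
        assert T == pytest.approx(31.0, abs=0.02)
        assert G == pytest.approx(10.0)

    def test_first_order_step_response(self):
        # pure step 34 -> 37 at 120 h from an equilibrated start
        d = Design(
            doe_mode="intensified",
            segments=[Segment(0.0, 34.0, "F2"), Segment(120.0, 37.0, "F2")],
            batch_end=0.0,
        )
        T, _ = effective_cpp(d, tau=48.0, t=168.0)
        assert T == pytest.approx(37.0 - 3.0 * np.exp(-1.0), abs=1e-9)

    def test_zero_lag_limit_is_the_step_profile(self):
        d = Design(
            doe_mode="intensified",
            segments=[Segment(72.0, 34.0, "F2"), Segment(120.0, 37.0, "F3")],
        )
        for t, expect_T, expect_G in [(100.0, 34.0, 20.0), (120.0, 37.0, 30.0), (300.0, 37.0, 30.0)]:
            T, G = effective_cpp(d, tau=0.0, t=t)
            assert (T, G) == (expect_T, expect_G)

    def test_continuity_across_shift(self):
        d = Design(
            doe_mode="intensified",
            segments=[Segment(72.0, 31.0, "F1"), Segment(192.0, 37.0, "F3")],
        )
        T1, _ = effective_cpp(d, 48.0, 192.0 - 1e-9)
        T2, _ = effective_cpp(d, 48.0, 192.0 + 1e-9)
        assert T1 == pytest.approx(T2, abs=1e-6)


class TestSimulateRun:
    def test_noiseless_is_deterministic_and_seed_free(self, gt, center_design_shaker):
        a = simulate_run(center_design_shaker, "shake_flask", gt, seed=1, noiseless=True)
        b = simulate_run(center_design_shaker, "shake_flask", gt, seed=99, noiseless=True)
        np.testing.assert_array_equal(a.samples.vcc, b.samples.vcc)
        np.testing.assert_array_equal(a.samples.titer, b.samples.titer)

    def test_noise_is_seeded_and_only_noise(self, gt, center_design_shaker):
        a = simulate_run(center_design_shaker, "shake_flask", gt, seed=7)
        b = simulate_run(center_design_shaker, "shake_flask", gt, seed=7)
        c = simulate_run(center_design_shaker, "shake_flask", gt, seed=8)
        np.testing.assert_array_equal(a.samples.vcc, b.samples.vcc)
        assert not np.array_equal(a.samples.vcc, c.samples.vcc)
        ref = simulate_run(center_design_shaker, "shake_flask", gt, noiseless=True)
        n = min(a.samples.n_samples(), ref.samples.n_samples())
        ratio = a.samples.vcc[1:n] / ref.samples.vcc[1:n]
        assert np.all(np.abs(np.log(ratio)) < 0.3)  # multiplicative, bounded

    def test_shaker_truncates_at_viability_threshold(self, shaker_cp_noiseless):
        v = shaker_cp_noiseless.samples.viability
        assert v[-1] < 70.0
        assert np.all(v[:-1] >= 70.0)

    def test_bioreactor_runs_to_day_15(self, bioreactor_cp_noiseless):
        run = bioreactor_cp_noiseless
        assert run.samples.times[-1] == 360.0
        assert np.all(run.samples.viability >= 70.0)
        # VCC shows no meaningful decline (daily drops below 2%)
        X = run.samples.vcc
        assert np.all(np.diff(X) > -0.02 * X[:-1])

    def test_simulated_runs_pass_validation(self, gt):
        d = make_bioreactor_designs()[3]
        run = simulate_run(d, "bioreactor", gt, seed=3, run_id="idoe")
        assert validate_run(run) == []
        # intensified runs get the extra post-shift samples
        for t_shift in d.shift_times:
            assert t_shift + 6.0 in run.samples.times

    def test_scale_design_pairing_enforced(self, gt, center_design_shaker):
        with pytest.raises(ValueError, match="scale"):
            simulate_run(center_design_shaker, "microreactor", gt)


class TestGroundTruthStructure:
    def test_growth_increases_with_temperature(self, gt):
        mus = [
            gt.mu_true(T, asn=2.3, gln=1.0, ala=0.1, stress=0.0, age_fb=0.0, mode="bolus")
            for T in (31.0, 34.0, 37.0)
        ]
        assert mus[0] < mus[1] < mus[2]

    def test_rates_respect_magnitude_bound(self, gt):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mu = gt.mu_true(
                T_eff=rng.uniform(30, 38), asn=rng.uniform(0, 3), gln=rng.uniform(0, 1.5),
                ala=rng.uniform(0, 5), stress=rng.uniform(0, 2), age_fb=rng.uniform(0, 300),
                mode=rng.choice(["bolus", "continuous"]),
            )
            assert abs(mu) <= 0.1

    def test_batch_analytes_conserved_without_kinetics(self, center_design_shaker):
        """With all yields, maintenance and degradation turned off, the batch
        phase (no feeding) leaves every analyte at its initial value."""
        gt0 = replace(
            GroundTruth(),
            y_glc=0, m_glc=0, y_gln=0, m_gln=0, k_gln_deg=0, y_asn=0, m_asn=0,
            y_ala=0, s_ala=0, q_ala_cont=0, c_ala_cont=0, y_asp=0, m_asp=0,
            m_glu=0, lam_glu=0, y_ser=0, m_ser=0, g_gly=0, m_gly=0, m_tyr=0,
            y_tyr=0, m_hyp=0, m_pro=0, y_pro=0,
        )
        truth = simulate_truth(center_design_shaker, "shake_flask", gt0)
        batch = truth["times"] <= 72.0
        for name, trace in truth["analytes"].items():
            np.testing.assert_allclose(trace[batch], trace[0], rtol=1e-7)

    def test_proline_tracks_hydroxyproline(
        self, shaker_cp_noiseless, bioreactor_cp_noiseless
    ):
        # structural (noise-free) collinearity of the shadow pair
        pro = np.concatenate(
            [r.samples.analytes["proline"]
             for r in (shaker_cp_noiseless, bioreactor_cp_noiseless)]
        )
        hyp = np.concatenate(
            [r.samples.analytes["hydroxyproline"]
             for r in (shaker_cp_noiseless, bioreactor_cp_noiseless)]
        )
        assert np.corrcoef(pro, hyp)[0, 1] > 0.95


class TestMakeDataset:
    def test_scenario_compositions(self, gt):
        t = make_dataset("transfer_training", gt, seed=0)
        assert len(t["train"]) == 21 and len(t["test"]) == 8
        i = make_dataset("idoe_training", gt, seed=0)
        assert len(i["train"]) == 6 and len(i["test"]) == 5
        assert all(r.design.doe_mode == "intensified" for r in i["train"])
        assert all(r.design.doe_mode == "static" for r in i["test"])
        s = make_dataset("shaker_doe", gt, seed=0)
        assert len(s["train"]) == 18 and not s["test"]

    def test_train_test_disjoint(self, transfer_data):
        train_ids = {r.run_id for r in transfer_data["train"]}
        test_ids = {r.run_id for r in transfer_data["test"]}
        assert not train_ids & test_ids

    def test_unknown_scenario_rejected(self, gt):
        with pytest.raises(ValueError, match="scenario"):
            make_dataset("everything", gt)
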