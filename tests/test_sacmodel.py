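import numpy as np
import pytest

from sacglu import sacmodel as sm
from sacglu.sacmodel import (
    BarStimulus,
    Morphology,
    PassiveParams,
    SACModel,
    Section,
    SimResult,
    Synapse,
    TruncatedGaussian,
    build_release_for_speed,
    build_roster,
    compute_dsi,
    conductance_scale,
    inject_current,
    regress_dsi_distance,
    sample_synapse_locations,
    schedule_activation,
    simulate,
)
from sacglu.synth import ReleaseProfileSpec


class TestConductanceScale:
    def test_anchor_values(self):
        assert conductance_scale(5.0) == pytest.approx(172.2)
        assert conductance_scale(145.0) == pytest.approx(68.6)

    def test_midpoint(self):
        assert conductance_scale(75.0) == pytest.approx((172.2 + 68.6) / 2)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert conductance_scale(200.0) == pytest.approx(68.6)

    def test_bad_anchors(self):
        with pytest.raises(ValueError):
            conductance_scale(10.0, d_min=50.0, d_max=50.0)


class TestSchedule:
    def test_dwell_from_bar_and_rf(self):
        stim = BarStimulus(velocity_mm_s=0.15)
        assert stim.dwell_s == pytest.approx((400 + 60) / 150.0)

    def test_onset_spacing(self):
        stim = BarStimulus(velocity_mm_s=0.15)
        onset, offset = schedule_activation(stim, np.array([50.0, 95.0]))
        assert onset[1] - onset[0] == pytest.approx(45 / 150.0)
        np.testing.assert_allclose(offset - onset, stim.dwell_s)

    def test_direction_reverses_order(self):
        pos = np.array([10.0, 60.0, 140.0])
        cf, _ = schedule_activation(BarStimulus(0.3, "centrifugal"), pos)
        cp, _ = schedule_activation(BarStimulus(0.3, "centripetal"), pos)
        assert np.argsort(cf).tolist() == np.argsort(cp)[::-1].tolist()
        assert cf.min() == 0 and cp.min() == 0


class TestSampling:
    def test_point_mass_deterministic(self):
        d = TruncatedGaussian(30.0, 1e-6, 5.0, 45.0)
        prox, _ = sample_synapse_locations(6, 12, d, seed=0)
        np.testing.assert_allclose(prox, 30.0, atol=1e-4)

    def test_empirical_means_match_density(self):
        prox_d = TruncatedGaussian(25.0, 10.0, 5.0, 45.0)
        dist_d = TruncatedGaussian(75.0, 20.0, 45.0, 145.0)
        prox, dist = sample_synapse_locations(10_000, 10_000, prox_d, dist_d, seed=1)
        for samples, density in ((prox, prox_d), (dist, dist_d)):
            se = density.expected_sd_um / np.sqrt(samples.size)
            assert abs(samples.mean() - density.expected_mean_um) < 3 * se

    def test_seed_reproducibility(self):
        a = sample_synapse_locations(6, 12, seed=7)
        b = sample_synapse_locations(6, 12, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestWindowedRelease:
    def test_truncated_transient(self):
        spec = ReleaseProfileSpec.transient()
        rr = build_release_for_speed(spec, 1.0, 1.1)
        assert rr.time_s.size == pytest.approx(100, abs=1)
        assert rr.rate_vps[0] > rr.rate_vps[-1]  # still on the onset transient

    def test_plateau_held(self):
        spec = ReleaseProfileSpec.sustained()
        rr = build_release_for_speed(spec, 0.0, 3.0)
        late = rr.rate_vps[rr.time_s > 2.0]
        np.testing.assert_allclose(late, spec.baseline_vps + spec.plateau_vps, rtol=0.01)

    def test_integral_grows_linearly_beyond_transient(self):
        spec = ReleaseProfileSpec.sustained()
        totals = [
            np.trapezoid(r.rate_vps, r.time_s)
            for r in (build_release_for_speed(spec, 0.0, w) for w in (2.0, 3.0, 4.0))
        ]
        d1, d2 = totals[1] - totals[0], totals[2] - totals[1]
        assert d1 == pytest.approx(spec.baseline_vps + spec.plateau_vps, rel=0.02)
        assert d2 == pytest.approx(d1, rel=0.02)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            build_release_for_speed(ReleaseProfileSpec.sustained(), 1.0, 1.0)


class TestCableSolver:
    def test_no_synapses_rests_at_leak(self):
        model = SACModel()
        res = simulate(model, [], BarStimulus(1.0), duration_s=0.3)
        np.testing.assert_allclose(res.soma_vm_mv, model.passive.e_leak_mv, atol=1e-6)
        # resting Ca settles to the (small) steady state of the Boltzmann tail
        assert res.terminal_ca[-1] == pytest.approx(res.terminal_ca[-2], rel=1e-3)

    def test_steady_state_matches_finite_cable_solution(self):
        # sealed-end cylinder, current injected at x=0:
        # V(x) = I·R∞·cosh((L−x)/λ)/sinh(L/λ)
        L_um, d_um = 150.0, 0.5
        passive = PassiveParams(rm_kohm_cm2=20.0, ra_ohm_cm=100.0, e_leak_mv=-60.0)
        morph = Morphology(sections=[Section(L_um, d_um)], soma_diam_um=None, dx_um=2.0)
        amp = 1e-12  # 1 pA
        t, vm = inject_current(morph, passive, amp, comp=0, duration_s=0.4)
        v_dev = vm[-1] - passive.e_leak_mv  # deviation profile, mV

        rm = passive.rm_kohm_cm2 * 1e3
        ra = passive.ra_ohm_cm
        d_cm, L_cm = d_um * 1e-4, L_um * 1e-4
        lam = np.sqrt(rm * d_cm / (4 * ra))
        r_inf = np.sqrt(rm * ra) * 2 / (np.pi * d_cm**1.5)
        x = (np.arange(v_dev.size) + 0.5) * 2e-4
        analytic = amp * r_inf * np.cosh((L_cm - x) / lam) / np.sinh(L_cm / lam) * 1e3
        np.testing.assert_allclose(v_dev, analytic, rtol=0.01)

    def test_epsp_attenuates_with_distance(self):
        model = SACModel()
        peaks = []
        for x in (10.0, 50.0, 90.0, 130.0):
            roster = [Synapse(x, "sustained", 150.0)]
            res = simulate(
                model, roster, BarStimulus(2.0), trains=[np.array([0.02])], duration_s=0.15
            )
            peaks.append(res.soma_vm_mv.max() - model.passive.e_leak_mv)
        assert all(a > b for a, b in zip(peaks, peaks[1:]))
        assert peaks[0] > 0

    def test_refinement_convergence(self):
        model = SACModel()
        roster = build_roster(model, seed=1)
        stim = BarStimulus(2.0)
        trains = sm._draw_trains(model, roster, stim, seed=3)
        base = simulate(model, roster, stim, trains=trains)
        fine_dt = SACModel(dt_s=model.dt_s / 2)
        half = simulate(fine_dt, roster, stim, trains=trains)
        p0 = base.soma_vm_mv.max() - model.passive.e_leak_mv
        p1 = half.soma_vm_mv.max() - model.passive.e_leak_mv
        assert abs(p1 - p0) / p0 < 0.01
        fine_dx = SACModel(morphology=Morphology(dx_um=1.0))
        halfx = simulate(fine_dx, roster, stim, trains=trains)
        p2 = halfx.soma_vm_mv.max() - model.passive.e_leak_mv
        assert abs(p2 - p0) / p0 < 0.01

    def test_mirror_symmetry(self):
        # uniform cylinder: mirrored roster + reversed motion = mirrored voltages
        L = 150.0
        morph = Morphology(sections=[Section(L, 0.5)], soma_diam_um=None, dx_um=2.0)
        model = SACModel(morphology=morph)
        trains = [np.array([0.02, 0.05]), np.array([0.08])]
        # positions on compartment centers so the mirrored mapping is exact
        ros = [Synapse(31.0, "sustained", 120.0), Synapse(71.0, "transient", 90.0)]
        mirror = [Synapse(L - s.position_um, s.kind, s.g_peak_ps) for s in ros]
        cf = simulate(model, ros, BarStimulus(2.0, "centrifugal"), trains=trains, record_all=True)
        cp = simulate(model, mirror, BarStimulus(2.0, "centripetal"), trains=trains, record_all=True)
        np.testing.assert_allclose(cf.vm_all_mv, cp.vm_all_mv[:, ::-1], atol=1e-9)

    def test_charge_scales_with_vesicle_count(self):
        # driving force ≈ constant far from the AMPA reversal, so the summed
        # depolarization integral grows ~linearly with coincident vesicles
        model = SACModel()
        areas = []
        for n in (1, 2, 4):
            roster = [Synapse(20.0, "sustained", 100.0)]
            res = simulate(
                model, roster, BarStimulus(2.0), trains=[np.full(n, 0.02)], duration_s=0.2
            )
            areas.append(np.trapezoid(res.soma_vm_mv - model.passive.e_leak_mv, res.time_s))
        assert areas[1] == pytest.approx(2 * areas[0], rel=0.1)
        assert areas[2] == pytest.approx(4 * areas[0], rel=0.1)

    def test_seed_determinism(self):
        model = SACModel()
        roster = build_roster(model, seed=2)
        a = simulate(model, roster, BarStimulus(1.0), seed=11)
        b = simulate(model, roster, BarStimulus(1.0), seed=11)
        np.testing.assert_array_equal(a.terminal_ca, b.terminal_ca)


class TestVelocityTuning:
    def test_low_velocity_preference_in_expectation(self):
        # in the infinite-vesicle limit the directional signal is strongest
        # at slow bar speeds and collapses toward zero at 2 mm/s
        model = SACModel()
        mags = {}
        for vel in (0.15, 2.0):
            vals = []
            for r in range(3):
                roster = build_roster(model, seed=[4, r], condition="native")
                cf, cp = sm.run_direction_pair(model, roster, vel, seed=1, deterministic=True)
                vals.append(compute_dsi(cf, cp, mode="normalized"))
            mags[vel] = np.mean(vals)
        assert mags[0.15] > 0
        assert abs(mags[2.0]) < abs(mags[0.15])


class TestDsi:
    def _res(self, peak):
        return SimResult("centrifugal", np.arange(2.0), np.zeros(2), np.zeros(2), peak, [], None)

    def test_plug_in(self):
        cf, cp = self._res(0.5), self._res(0.3)
        assert compute_dsi(cf, cp) == pytest.approx(0.2)
        assert compute_dsi(cf, cp, mode="normalized") == pytest.approx(0.25)

    def test_identical_gives_zero(self):
        cf, cp = self._res(0.4), self._res(0.4)
        assert compute_dsi(cf, cp) == 0.0
        assert compute_dsi(cf, cp, mode="normalized") == 0.0

    def test_antisymmetry(self):
        cf, cp = self._res(0.7), self._res(0.2)
        assert compute_dsi(cf, cp) == -compute_dsi(cp, cf)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_dsi(self._res(0.0), self._res(0.0), mode="normalized")


class TestExperimentPlumbing:
    def test_roster_conditions(self):
        model = SACModel()
        native = build_roster(model, seed=5, condition="native")
        swapped = build_roster(model, seed=5, condition="swapped")
        assert [s.kind for s in native[:6]] == ["sustained"] * 6
        assert [s.kind for s in native[6:]] == ["transient"] * 12
        assert [s.kind for s in swapped[:6]] == ["transient"] * 6
        np.testing.assert_allclose(
            [s.position_um for s in native], [s.position_um for s in swapped]
        )
        with pytest.raises(ValueError):
            build_roster(model, seed=5, condition="sideways")

    def test_conductance_follows_position(self):
        roster = build_roster(SACModel(), seed=8)
        for s in roster:
            assert s.g_peak_ps == pytest.approx(conductance_scale(s.position_um))

    def test_regression_collinear(self):
        d = np.linspace(30, 70, 20)
        slope, r2 = regress_dsi_distance(d, 0.001 * d)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.001)

    def test_regression_null(self):
        rng = np.random.default_rng(0)
        r2s = [
            regress_dsi_distance(rng.permutation(np.linspace(30, 70, 40)), rng.normal(0.5, 0.1, 40))[1]
            for _ in range(30)
        ]
        assert np.mean(r2s) < 0.1

    def test_regression_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            regress_dsi_distance(np.full(10, 50.0), np.random.default_rng(0).random(10))
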