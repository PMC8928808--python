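"""Generators: determinism, analytic metadata, and generator/estimator round trips."""

import numpy as np
import pytest

from lamincurv import (
    Channel,
    GeneratorConfig,
    SigmoidFit,
    count_distribution,
    curvature_profile,
    detach_probability,
    estimate_critical_rate,
    fit_sigmoid,
    make_contour,
    pole_mean,
    render_profiles,
    simulate_aspiration,
    simulate_migration_cohort,
)
from lamincurv.io import write_cohort


def flat_percent_sigmoid(p: float) -> SigmoidFit:
    """Curvature-independent response with rupture probability p at every pore."""
    return SigmoidFit(amplitude_B=200.0 * p, epsilon=0.0, alpha=0.0)


class TestMakeContour:
    def test_circle_measured_curvature(self):
        c = make_contour("circle", {"radius": 4.0})
        for s in curvature_profile(c, c.arc_length / 20):
            assert s.curvature_kappa == pytest.approx(0.25, rel=0.01)

    def test_ellipse_metadata(self):
        c = make_contour("ellipse", {"a": 10.0, "b": 3.0})
        assert c.metadata["pole_curvature"] == pytest.approx(10 / 9)
        assert c.metadata["side_curvature"] == pytest.approx(3 / 100)

    def test_spindle_pole_by_construction(self):
        c = make_contour("spindle", {"pole_radius": 1.0, "length": 10.0})
        assert c.metadata["pole_curvature"] == 1.0
        ks = [s.curvature_kappa for s in curvature_profile(c, c.arc_length / 40)]
        assert max(ks) == pytest.approx(1.0, rel=0.02)
        assert min(ks) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            make_contour("circle", {"radius": -1.0})
        with pytest.raises(ValueError):
            make_contour("spindle", {"pole_radius": 3.0, "length": 5.0})
        with pytest.raises(ValueError):
            make_contour("ellipse", {"a": 2.0, "b": 5.0})
        with pytest.raises(ValueError):
            make_contour("circle", {"radius": 1.0}, n_points=8)


class TestRenderProfiles:
    def test_constant_curvature_gives_flat_profiles(self, noiseless_config):
        c = make_contour("circle", {"radius": 6.0})
        profs = render_profiles(c, noiseless_config)
        for prof in profs.values():
            assert np.ptp(prof.value) == pytest.approx(0.0, abs=1e-12)

    def test_pole_side_ratio_matches_model_exactly(self, noiseless_config):
        c = make_contour("spindle", {"pole_radius": 1.0, "length": 12.0})
        profs = render_profiles(c, noiseless_config, strain_rate=0.0)
        b = profs[Channel.LAMIN_B]
        expected = (1 - detach_probability(1.0, noiseless_config.filament)) / (
            1 - detach_probability(0.0, noiseless_config.filament)
        )
        assert b.value[0] / b.value[-1] == pytest.approx(expected, rel=1e-12)

    def test_laminA_flat_below_critical_rate(self, noiseless_config):
        c = make_contour("spindle", {"pole_radius": 0.8, "length": 12.0})
        slow = render_profiles(c, noiseless_config, strain_rate=0.1)  # below 0.2 um/s
        assert np.ptp(slow[Channel.LAMIN_A].value) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(slow[Channel.LAMIN_B].value) > 0.1
        fast = render_profiles(c, noiseless_config, strain_rate=0.9)
        assert np.ptp(fast[Channel.LAMIN_A].value) > 0.05

    def test_measured_dilution_consistent_with_model(self, noiseless_config):
        c = make_contour("spindle", {"pole_radius": 1.0, "length": 12.0})
        profs = render_profiles(c, noiseless_config)
        with pytest.warns(UserWarning):  # interior window spans the whole profile
            interior = pole_mean(profs[Channel.LAMIN_B], window=12.0)
        phi = interior / pole_mean(profs[Channel.LAMIN_B], window=0.5) - 1
        assert phi > 0  # pole (tip) depleted relative to the deeper interior


class TestMigrationCohort:
    def test_probability_zero_gives_no_ruptures(self):
        cfg = GeneratorConfig(seed=1, sigmoid=flat_percent_sigmoid(0.0), cells_per_pore=50)
        assert all(r.n_sites == 0 for r in simulate_migration_cohort(cfg))

    def test_probability_one_caps_at_three_plus(self):
        cfg = GeneratorConfig(seed=1, sigmoid=flat_percent_sigmoid(1.0), cells_per_pore=50)
        assert all(r.n_sites == 3 for r in simulate_migration_cohort(cfg))

    def test_class_fractions_match_independence_model(self):
        p = 0.3
        cfg = GeneratorConfig(
            seed=11, sigmoid=flat_percent_sigmoid(p), pore_diameters=(4.0,), cells_per_pore=10000
        )
        d = count_distribution(simulate_migration_cohort(cfg))
        n = 10000
        for frac, expect in [(d.one, p - p**2), (d.two, p**2 - p**3), (d.three_plus, p**3)]:
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(frac - expect) <= 2 * se

    def test_myosin_inhibition_halves_probability(self):
        base = GeneratorConfig(seed=5, sigmoid=flat_percent_sigmoid(0.4), cells_per_pore=5000)
        inhibited = GeneratorConfig(
            seed=5, sigmoid=flat_percent_sigmoid(0.4), cells_per_pore=5000,
            condition="myosin_inhibited",
        )
        f0 = count_distribution(simulate_migration_cohort(base)).ruptured
        f1 = count_distribution(simulate_migration_cohort(inhibited)).ruptured
        assert f1 / f0 == pytest.approx(0.5, rel=0.1)

    def test_determinism_byte_identical_csv(self, tmp_path):
        cfg = GeneratorConfig(seed=42, cells_per_pore=100)
        for name in ("a.csv", "b.csv"):
            write_cohort(tmp_path / name, simulate_migration_cohort(cfg))
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_end_to_end_amplitude_recovery(self, percent_sigmoid):
        """With calibrated (eps, alpha) fixed, refitting the simulated rupture
        percentages recovers the generating amplitude; full three-parameter
        recovery is checked over replicate cohorts in the acceptance suite."""
        cfg = GeneratorConfig(seed=0, sigmoid=percent_sigmoid)
        records = simulate_migration_cohort(cfg)
        pts = []
        for d_pore in cfg.pore_diameters:
            kappa = 2.0 / d_pore
            sub = [r for r in records if abs(r.imposed_curvature - kappa) < 1e-9]
            pts.append((kappa, 100.0 * np.mean([r.n_sites >= 1 for r in sub]), len(sub)))
        fit = fit_sigmoid(
            pts, mode="B_only",
            fixed_eps_alpha=(percent_sigmoid.epsilon, percent_sigmoid.alpha),
        )
        assert fit.amplitude_B == pytest.approx(percent_sigmoid.amplitude_B, rel=0.15)


class TestAspiration:
    def test_zero_rate_no_dilution(self, noiseless_config):
        (trace,) = simulate_aspiration(noiseless_config, [0.0])
        for ch in Channel:
            assert trace.dilution_at(600.0, ch) == pytest.approx(0.0, abs=1e-12)

    def test_below_critical_early_time(self, noiseless_config):
        (trace,) = simulate_aspiration(noiseless_config, [0.1])  # below 0.2 um/s
        t = noiseless_config.measure_time
        assert trace.dilution_at(t, Channel.LAMIN_A) == pytest.approx(0.0, abs=1e-12)
        assert trace.dilution_at(t, Channel.LAMIN_B) > 0.05

    def test_long_time_convergence(self, noiseless_config):
        (trace,) = simulate_aspiration(noiseless_config, [0.1])
        late = trace.time[-1]
        phi_a = trace.dilution_at(late, Channel.LAMIN_A)
        phi_b = trace.dilution_at(late, Channel.LAMIN_B)
        assert abs(phi_a - phi_b) < 0.25 * phi_b

    def test_projection_length_is_rate_times_time(self, noiseless_config):
        (trace,) = simulate_aspiration(noiseless_config, [0.3])
        np.testing.assert_allclose(trace.projection_length_dL, 0.3 * trace.time)

    def test_noiseless_roundtrip_recovers_hinge(self, noiseless_config):
        traces = simulate_aspiration(noiseless_config, np.linspace(0.05, 1.0, 30))
        t = noiseless_config.measure_time
        pairs = [(tr.rate, tr.dilution_at(t, Channel.LAMIN_A)) for tr in traces]
        fit = estimate_critical_rate(pairs)
        assert fit.critical_rate == pytest.approx(noiseless_config.laminA_hinge[1], abs=1e-6)
        assert fit.slope_c == pytest.approx(noiseless_config.laminA_hinge[0], rel=1e-6)

    def test_laminB_elastic_zero_critical_rate(self, noiseless_config):
        traces = simulate_aspiration(noiseless_config, np.linspace(0.05, 1.0, 30))
        t = noiseless_config.measure_time
        pairs = [(tr.rate, tr.dilution_at(t, Channel.LAMIN_B)) for tr in traces]
        fit = estimate_critical_rate(pairs, Channel.LAMIN_B)
        assert fit.critical_rate == pytest.approx(0.0, abs=1e-9)
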