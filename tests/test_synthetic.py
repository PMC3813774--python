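"""Generator: determinism, calibration, two-level variance, waveform shape."""

import math

import numpy as np
import pytest

from fgrtools.synthetic import (
    CellMeans,
    ConfigError,
    FetusRecord,
    GeneratorConfig,
    SYSTOLE_FRACTION,
    generate_accumulation,
    generate_cohort,
    generate_plasma_curve,
    generate_velocity_trace,
    waveform_cycle_mean,
)


def _cfg(**kw):
    return GeneratorConfig(**kw)


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(_cfg(seed=3))
        b = generate_cohort(_cfg(seed=3))
        assert [vars(x) for x in a[1]] == [vars(x) for x in b[1]]
        assert [vars(x) for x in a[0]] == [vars(x) for x in b[0]]

    def test_degenerate_variance_hits_cell_mean_exactly(self):
        cfg = _cfg(
            seed=1, litter_sd=0.0, pup_sd=0.0,
            placental_litter_sd=0.0, placental_pup_sd=0.0,
        )
        _, fetuses = generate_cohort(cfg)
        p0_water = [f for f in fetuses
                    if f.genotype == "P0" and f.treatment == "water"]
        assert p0_water
        assert all(f.fetal_weight == pytest.approx(0.94) for f in p0_water)

    def test_large_sample_mean_matches_calibration(self):
        # law of large numbers: cell sample mean -> configured mean
        cfg = _cfg(seed=9, n_litters={"water": 1500}, litter_size_mean={"water": 8.0})
        _, fetuses = generate_cohort(cfg)
        w = np.array([f.fetal_weight for f in fetuses
                      if f.genotype == "P0" and f.treatment == "water"])
        marginal_sd = math.hypot(cfg.litter_sd, cfg.pup_sd)
        # litter intercepts correlate pups, so allow for the design effect
        se = marginal_sd / math.sqrt(len(w) / 4.0)
        assert abs(w.mean() - 0.94) < 3 * se

    def test_two_level_marginal_variance(self):
        cfg = _cfg(seed=21, n_litters={"water": 3000},
                   litter_size_mean={"water": 8.0}, wt_fraction=0.52)
        _, fetuses = generate_cohort(cfg)
        w = np.array([f.fetal_weight for f in fetuses if f.genotype == "WT"
                      and f.treatment == "water"])
        expected_var = cfg.litter_sd**2 + cfg.pup_sd**2
        assert len(w) > 1e4
        assert np.var(w, ddof=1) == pytest.approx(expected_var, rel=0.08)

    def test_wt_fraction_within_binomial_bounds(self):
        cfg = _cfg(seed=13, n_litters={"water": 1500},
                   litter_size_mean={"water": 8.0})
        _, fetuses = generate_cohort(cfg)
        n = len(fetuses)
        assert n >= 1e4
        frac = sum(f.genotype == "WT" for f in fetuses) / n
        half_width = 2.576 * math.sqrt(0.52 * 0.48 / n)  # 99% binomial bounds
        assert abs(frac - 0.52) < half_width

    def test_all_weights_positive_and_litters_nonempty(self, default_cohort):
        _, litters, fetuses, _ = default_cohort
        assert all(l.litter_size >= 1 for l in litters)
        assert all(f.fetal_weight > 0 and f.placental_weight > 0 for f in fetuses)

    @pytest.mark.parametrize(
        "kw",
        [
            {"wt_fraction": 0.0},
            {"wt_fraction": 1.2},
            {"litter_sd": -0.1},
            {"n_litters": {"water": 0}},
            {"tail_tip_fraction": 0.25},
            {"trace_psv": 5.0, "trace_edv": 10.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            _cfg(**kw).validate()


class TestPlasmaCurve:
    def test_no_decay_gives_constant(self):
        samples = generate_plasma_curve(100.0, 0.0, [0, 1, 5, 30], noise_cv=0.0)
        assert [s.concentration for s in samples] == [100.0] * 4

    def test_closed_form_decay(self):
        (s,) = generate_plasma_curve(100.0, 0.2, [5.0], noise_cv=0.0)
        assert s.concentration == pytest.approx(100.0 * math.exp(-1.0))

    def test_loglinear_regression_recovers_k(self, rng):
        # independent recovery oracle: regression of log C on t
        times = np.linspace(0.5, 10, 50)
        samples = generate_plasma_curve(100.0, 0.3, times, noise_cv=0.05,
                                        seed=int(rng.integers(2**31)))
        c = np.array([s.concentration for s in samples])
        slope, _ = np.polyfit(times, np.log(c), 1)
        assert -slope == pytest.approx(0.3, rel=0.10)

    def test_negative_concentration_clamped(self, caplog):
        samples = generate_plasma_curve(1.0, 0.0, [1.0] * 200, noise_cv=5.0, seed=0)
        assert all(s.concentration >= 0 for s in samples)
        assert any("clamped" in r.message for r in caplog.records)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_plasma_curve(0.0, 0.1, [1.0])
        with pytest.raises(ValueError):
            generate_plasma_curve(1.0, 0.1, [-1.0])


class TestAccumulation:
    def _fetus(self, pw=0.1):
        return FetusRecord("f1", "l1", "WT", "water", 1.0, pw, 28, 25, 24)

    def test_zero_clearance_zero_accumulation(self):
        assert generate_accumulation(0.0, self._fetus(), (100, 0.2), 5.0) == 0.0

    def test_closed_form_value(self):
        # 100 * 0.1 * (100/0.2) * (1 - e^-1) = 3160.6 dpm
        nx = generate_accumulation(100.0, self._fetus(0.1), (100.0, 0.2), 5.0)
        assert nx == pytest.approx(3160.6028, rel=1e-6)

    def test_matches_numeric_quadrature(self):
        from scipy.integrate import quad

        C0, k, x = 87.0, 0.13, 3.7
        expected = 42.0 * 0.09 * quad(lambda t: C0 * np.exp(-k * t), 0, x)[0]
        nx = generate_accumulation(42.0, self._fetus(0.09), (C0, k), x)
        assert nx == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            generate_accumulation(1.0, self._fetus(), (100, 0.2), 0.0)


class TestVelocityTrace:
    def test_flat_trace_when_psv_equals_edv(self):
        tr = generate_velocity_trace(50, 50, 2.0, 3.0, 500, noise_sd=0.0)
        assert np.allclose(tr.velocities, 50.0)

    def test_cycle_count_by_construction(self):
        from fgrtools.doppler import find_cycle_peaks

        tr = generate_velocity_trace(60, 10, 2.0, 3.0, 1000, noise_sd=0.0)
        assert len(find_cycle_peaks(tr)) == 6

    def test_noiseless_trace_matches_analytic_pi(self):
        from fgrtools.doppler import aggregate_trace

        psv, edv = 60.0, 10.0
        tr = generate_velocity_trace(psv, edv, 2.0, 3.0, 1000, noise_sd=0.0)
        m = aggregate_trace(tr)
        analytic_mv = waveform_cycle_mean(psv, edv)
        assert m.mv == pytest.approx(analytic_mv, rel=1e-3)
        assert m.pi == pytest.approx((psv - edv) / analytic_mv, rel=1e-3)

    def test_analytic_mean_formula(self):
        assert waveform_cycle_mean(60, 10) == 10 + 50 * SYSTOLE_FRACTION / 2

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="3 cardiac cycles"):
            generate_velocity_trace(60, 10, 2.0, 1.0, 1000)


class TestTracerRoundTrip:
    def test_zero_noise_kmf_round_trip(self):
        # generate -> correct -> compute returns the ground-truth clearance
        from fgrtools.clearance import DecayFit, compute_Kmf

        f = FetusRecord("f1", "l1", "WT", "water", 1.1, 0.09, 28, 25, 24,
                        tail_tip_fraction=0.05, sample_time_x=3.0)
        true_kmf = 77.0
        nx = generate_accumulation(true_kmf, f, (100.0, 0.15), 3.0, noise_cv=0.0)
        f.dpm_accumulated = nx * (1 - f.tail_tip_fraction)
        fit = DecayFit(C0=100.0, k=0.15, r2=1.0, n_samples=10)
        res = compute_Kmf(f, fit)
        assert res.kmf_per_g_placenta == pytest.approx(true_kmf, rel=1e-12)
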