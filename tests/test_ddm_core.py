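"""First-passage-time mathematics: densities, CDFs, simulation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from driftbias.ddm_core import (DDMParams, ParameterError,
                                absorption_probability,
                                euler_maruyama_trials, fpt_cdf, fpt_density,
                                simulate_trial, simulate_trials)
from driftbias.ddm_core import _ft_large, _ft_small


@pytest.mark.parametrize("kwargs", [
    dict(a=0.0, zr=0.5, v=1.0),
    dict(a=-1.0, zr=0.5, v=1.0),
    dict(a=1.0, zr=0.0, v=1.0),
    dict(a=1.0, zr=1.0, v=1.0),
    dict(a=1.0, zr=0.5, v=1.0, t0=-0.1),
    dict(a=1.0, zr=0.5, v=1.0, szr=-0.1),
    dict(a=1.0, zr=0.9, v=1.0, szr=0.5),      # zr + szr/2 leaves (0, 1)
    dict(a=1.0, zr=0.5, v=1.0, t0=0.1, st0=0.3),  # t0 - st0/2 < 0
    dict(a=1.0, zr=0.5, v=np.inf),
])
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        DDMParams(**kwargs)


class TestAbsorptionProbability:
    def test_drift_free_equals_relative_start(self):
        # symmetric start -> 1/2; zr=0.3 -> 0.3 (classical gambler's-ruin limit)
        assert absorption_probability(DDMParams(a=1, zr=0.5, v=0), "upper") \
            == pytest.approx(0.5, abs=1e-12)
        assert absorption_probability(DDMParams(a=1, zr=0.3, v=0), "upper") \
            == pytest.approx(0.3, abs=1e-9)

    def test_boundaries_sum_to_one(self):
        p = DDMParams(a=1.3, zr=0.4, v=-0.7, szr=0.2, sv=0.6)
        total = (absorption_probability(p, "upper")
                 + absorption_probability(p, "lower"))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_against_euler_maruyama_oracle(self):
        # independent path-discretisation oracle, fine dt so overshoot bias
        # stays inside the Monte-Carlo tolerance
        params = DDMParams(a=1.0, zr=0.5, v=1.5)
        n = 10_000
        upper, _ = euler_maruyama_trials(params, n, rng=123, dt=1e-5)
        p_hat = upper.mean()
        p = absorption_probability(params, "upper")
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se

    def test_monotone_in_drift_and_start(self):
        ups_v = [absorption_probability(DDMParams(a=1.2, zr=0.45, v=v), "upper")
                 for v in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(ups_v) > 0)
        ups_z = [absorption_probability(DDMParams(a=1.2, zr=z, v=0.5), "upper")
                 for z in np.linspace(0.15, 0.85, 9)]
        assert np.all(np.diff(ups_z) > 0)

    def test_bad_boundary_name(self, simple_params):
        with pytest.raises(ValueError):
            absorption_probability(simple_params, "top")


class TestDensity:
    @pytest.mark.parametrize("variability", [False, True])
    @pytest.mark.parametrize("a,zr,v", [(0.8, 0.3, -1.0), (1.2, 0.5, 0.0),
                                        (2.0, 0.65, 1.2)])
    def test_conservation(self, a, zr, v, variability):
        # defective densities over both boundaries integrate to 1
        extra = dict(szr=0.1, sv=0.5) if variability else {}
        p = DDMParams(a=a, zr=zr, v=v, **extra)
        total = quad(lambda t: fpt_density(p, t, "upper")
                     + fpt_density(p, t, "lower"), 0, 400,
                     limit=400, epsabs=1e-10)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_reflection_symmetry(self):
        t = np.linspace(0.05, 5.0, 50)
        p = DDMParams(a=1.1, zr=0.35, v=0.9)
        mirrored = DDMParams(a=1.1, zr=0.65, v=-0.9)
        np.testing.assert_allclose(fpt_density(p, t, "upper"),
                                   fpt_density(mirrored, t, "lower"),
                                   rtol=0, atol=1e-12)

    def test_drift_variability_against_quadrature_oracle(self):
        # closed-form normal-drift integration vs midpoint rule over drift
        p = DDMParams(a=1.0, zr=0.5, v=2.0, sv=0.8)
        val = fpt_density(p, 0.5, "upper")
        grid = np.linspace(2.0 - 6 * 0.8, 2.0 + 6 * 0.8, 2001)
        step = grid[1] - grid[0]
        weights = np.exp(-(grid - 2.0) ** 2 / (2 * 0.8 ** 2)) / (
            0.8 * np.sqrt(2 * np.pi))
        dens = np.array([fpt_density(DDMParams(a=1.0, zr=0.5, v=vi), 0.5,
                                     "upper") for vi in grid])
        assert val == pytest.approx(float(np.sum(dens * weights) * step),
                                    abs=1e-4)

    def test_nonfinite_time_rejected(self, simple_params):
        with pytest.raises(ValueError):
            fpt_density(simple_params, np.nan, "upper")

    def test_series_expansions_agree(self):
        # small- and large-time representations on their overlap region
        u = np.linspace(0.05, 2.0, 40)
        for w in (0.2, 0.5, 0.8):
            small = _ft_small(u, np.full_like(u, w), 30)
            large = _ft_large(u, np.full_like(u, w), 300)
            np.testing.assert_allclose(small, large, rtol=0, atol=1e-6)


class TestCdf:
    def test_zero_at_origin(self, simple_params):
        assert fpt_cdf(simple_params, 0.0, "upper") == 0.0

    def test_limit_is_absorption_probability(self):
        p = DDMParams(a=1.0, zr=0.5, v=1.0)
        assert fpt_cdf(p, 100.0, "upper") == pytest.approx(
            absorption_probability(p, "upper"), abs=1e-6)

    def test_matches_density_integral(self):
        p = DDMParams(a=1.0, zr=0.5, v=1.0)
        num = quad(lambda s: fpt_density(p, s, "upper"), 0, 0.8,
                   limit=200, epsabs=1e-10)[0]
        assert fpt_cdf(p, 0.8, "upper") == pytest.approx(num, abs=1e-5)

    def test_nondecreasing(self):
        p = DDMParams(a=1.4, zr=0.3, v=-0.8, szr=0.15, sv=0.4)
        t = np.linspace(0.01, 10, 200)
        vals = fpt_cdf(p, t, "lower")
        assert np.all(np.diff(vals) >= -1e-12)


class TestSimulation:
    def test_deterministic_given_seed(self, simple_params):
        assert simulate_trial(simple_params, 99) == simulate_trial(simple_params, 99)
        up1, rt1 = simulate_trials(simple_params, 50, 7)
        up2, rt2 = simulate_trials(simple_params, 50, 7)
        np.testing.assert_array_equal(up1, up2)
        np.testing.assert_array_equal(rt1, rt2)

    def test_rejects_empty_request(self, simple_params):
        with pytest.raises(ValueError):
            simulate_trials(simple_params, 0, 1)

    def test_choice_fractions_match_absorption(self):
        params = DDMParams(a=1.0, zr=0.6, v=0.5)
        n = 40_000
        upper, _ = simulate_trials(params, n, 11)
        p = absorption_probability(params, "upper")
        assert abs(upper.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_rt_support_bound(self):
        params = DDMParams(a=1.0, zr=0.5, v=1.0, t0=0.4, d=0.1, st0=0.2)
        _, rt = simulate_trials(params, 10_000, 3)
        assert rt.min() >= params.t0 - params.st0 / 2 - abs(params.d) / 2

    def test_ks_agreement_with_analytic_cdf(self):
        # exact sampler vs analytic conditional RT distribution
        params = DDMParams(a=1.2, zr=0.5, v=1.0, t0=0.3)
        n = 100_000
        upper, rt = simulate_trials(params, n, 2718)
        p_up = absorption_probability(params, "upper")
        res = kstest(rt[upper], _gridded_cdf(params, p_up, rt[upper]))
        n_up = int(upper.sum())
        critical = 1.628 / np.sqrt(n_up)  # alpha = 0.01
        assert res.statistic < critical

    def test_variability_draws_respect_analytic_mixture(self):
        params = DDMParams(a=1.0, zr=0.5, v=0.8, t0=0.25, szr=0.2, sv=0.5,
                           st0=0.1)
        upper, rt = simulate_trials(params, 40_000, 17)
        p_up = absorption_probability(params, "upper")
        assert abs(upper.mean() - p_up) < 3 * np.sqrt(p_up * (1 - p_up) / 40_000)
        res = kstest(rt[upper], _gridded_cdf(params, p_up, rt[upper]))
        assert res.pvalue > 0.01


def _gridded_cdf(params, p_up, sample):
    """Conditional upper-boundary RT CDF, tabulated once on a dense grid.

    Interpolation error on the 4000-point grid is orders of magnitude below
    the KS resolution at these sample sizes.
    """
    grid = np.linspace(0.0, sample.max() * 1.001, 4000)
    vals = fpt_cdf(params, grid, "upper", rt=True) / p_up
    return lambda x: np.interp(x, grid, vals)
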