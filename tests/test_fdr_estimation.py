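"""pi0 estimation, Storey q-values, Grenander density, local FDR."""

import numpy as np
import pytest

from mtlab import (
    MethodInapplicable,
    PValueVector,
    bh_adjust,
    grenander_fit,
    storey_pi0,
    storey_qvalues,
    strimmer_lfdr,
    strimmer_pi0,
    strimmer_qvalues,
)
from mtlab.fdr_estimation import DEFAULT_LAMBDA_GRID, Pi0Estimate
from mtlab.simulation import SimulationScenario, simulate_scenario, z_to_pvalue


def _sim_pvalues(m, pi0, beta, rep, seed=1):
    scn = SimulationScenario(m=m, pi0=pi0, beta=beta, reps=100, seed=seed)
    z, _ = simulate_scenario(scn, rep)
    return PValueVector(z_to_pvalue(z))


class TestStoreyPi0:
    def test_single_lambda_clamped(self, rng):
        # 60 of 100 p-values above 0.5 -> raw ratio 1.2 -> clamp to 1
        p = np.concatenate([rng.uniform(0.5, 1, 60) + 1e-9, rng.uniform(0, 0.5, 40)])
        est = storey_pi0(PValueVector(p), np.array([0.5]))
        assert est.value == 1.0
        assert est.method == "storey-point"

    def test_uniform_grid_estimates_one(self):
        p = np.linspace(0.001, 0.999, 500)
        assert storey_pi0(PValueVector(p)).value > 0.9

    def test_default_grid(self):
        assert DEFAULT_LAMBDA_GRID[0] == 0.05
        assert DEFAULT_LAMBDA_GRID[-1] == 0.95
        assert np.allclose(np.diff(DEFAULT_LAMBDA_GRID), 0.05)

    def test_fallback_on_all_small_pvalues(self):
        """All p tiny -> every tail count is zero -> stepwise shrink to terminal."""
        pv = PValueVector(np.full(20, 1e-8))
        est = storey_pi0(pv)
        assert est.fallback_steps > 0
        assert 0 < est.value <= 1

    def test_recovery_at_large_m(self):
        """Mean estimate over reps lands near the truth for strong signal."""
        for pi0_true in (0.25, 0.5, 0.75):
            ests = [
                storey_pi0(_sim_pvalues(1000, pi0_true, 2.5, r)).value
                for r in range(60)
            ]
            assert abs(np.mean(ests) - pi0_true) < 0.1

    def test_overestimates_under_weak_signal(self):
        """With beta = 1 the alternatives look nearly null, inflating pi0-hat."""
        ests = [storey_pi0(_sim_pvalues(1000, 0.5, 1.0, r)).value for r in range(60)]
        assert np.mean(ests) > 0.5


class TestStoreyQValues:
    def test_pi0_one_equals_bh_bitwise(self, random_pvector_batch):
        for p in random_pvector_batch(40, max_m=100):
            pv = PValueVector(p)
            q = storey_qvalues(pv, Pi0Estimate(1.0, "fixed")).qvalues
            assert (q == bh_adjust(pv).values).all()

    def test_worked_example(self):
        pv = PValueVector(np.array([0.01, 0.02, 0.04]))
        q = storey_qvalues(pv, Pi0Estimate(0.5, "fixed")).qvalues
        assert q.tolist() == pytest.approx([0.015, 0.015, 0.02])

    def test_qvalues_below_bh_when_pi0_below_one(self, random_pvector_batch):
        for p in random_pvector_batch(30):
            pv = PValueVector(p)
            q = storey_qvalues(pv, Pi0Estimate(0.7, "fixed")).qvalues
            assert (q <= bh_adjust(pv).values + 1e-15).all()

    def test_monotone_in_p(self, random_pvector_batch):
        for p in random_pvector_batch(30):
            pv = PValueVector(p)
            q = storey_qvalues(pv).qvalues
            order = np.argsort(pv.values, kind="stable")
            assert (np.diff(q[order]) >= -1e-15).all()


class TestGrenander:
    def test_uniform_ecdf_gives_flat_density(self):
        den = grenander_fit(PValueVector(np.array([0.25, 0.5, 0.75, 1.0])))
        np.testing.assert_allclose(den.slopes, [1.0])

    def test_worked_majorant_example(self):
        den = grenander_fit(PValueVector(np.array([0.1, 0.2, 0.9, 1.0])))
        np.testing.assert_allclose(den.breakpoints, [0.0, 0.2, 1.0])
        np.testing.assert_allclose(den.slopes, [2.5, 0.625])

    def test_inapplicable_below_two_distinct(self):
        with pytest.raises(MethodInapplicable):
            grenander_fit(PValueVector(np.array([0.3, 0.3, 0.3])))

    def test_normalization_monotonicity_majorant(self, random_pvector_batch):
        """Unit integral, nonincreasing slopes, and CDF >= ECDF below the censor point."""
        for p in random_pvector_batch(40, min_m=4, max_m=200):
            den = grenander_fit(PValueVector(p))
            widths = np.diff(den.breakpoints)
            assert np.sum(den.slopes * widths) == pytest.approx(1.0)
            assert (np.diff(den.slopes) <= 1e-12).all()
            ps = np.sort(p)
            ecdf = np.arange(1, len(p) + 1) / len(p)
            below = ps <= 0.5
            assert (den.cdf(ps[below]) >= ecdf[below] - 1e-12).all()


class TestStrimmerPi0:
    def test_flat_density_gives_one(self):
        den = grenander_fit(PValueVector(np.array([0.25, 0.5, 0.75, 1.0])))
        assert strimmer_pi0(den).value == 1.0

    def test_terminal_slope_example(self):
        den = grenander_fit(PValueVector(np.array([0.1, 0.2, 0.9, 1.0])))
        assert strimmer_pi0(den).value == pytest.approx(0.625)

    def test_clamped_to_one(self):
        from mtlab.fdr_estimation import GrenanderDensity

        den = GrenanderDensity(np.array([0.0, 1.0]), np.array([1.4]))
        assert strimmer_pi0(den).value == 1.0

    def test_recovery_at_large_m(self):
        for pi0_true in (0.25, 0.5, 0.75):
            ests = [
                strimmer_pi0(
                    grenander_fit(_sim_pvalues(1000, pi0_true, 2.5, r)), 1000
                ).value
                for r in range(60)
            ]
            assert abs(np.mean(ests) - pi0_true) < 0.1

    def test_overestimates_under_weak_signal(self):
        ests = [
            strimmer_pi0(grenander_fit(_sim_pvalues(1000, 0.5, 1.0, r)), 1000).value
            for r in range(60)
        ]
        assert np.mean(ests) > 0.5

    def test_storey_shows_larger_spread_at_small_m(self):
        """Observed estimation ranges: tail-count smoothing varies more for Storey."""
        for m in (8, 16):
            storey, strimmer = [], []
            for r in range(100):
                pv = _sim_pvalues(m, 0.5, 2.5, r)
                storey.append(storey_pi0(pv).value)
                strimmer.append(strimmer_pi0(grenander_fit(pv), m).value)
            assert np.ptp(storey) > np.ptp(strimmer)


class TestLfdr:
    def test_flat_density_saturates(self):
        pv = PValueVector(np.array([0.1, 0.3, 0.5, 0.7, 0.82, 0.9, 0.95, 0.99]))
        out = strimmer_lfdr(pv)
        assert out.lfdr.max() <= 1.0

    def test_worked_example_value(self):
        pv = PValueVector(np.array([0.1, 0.2, 0.9, 1.0]))
        out = strimmer_lfdr(pv, min_m=2)
        assert out.lfdr[0] == pytest.approx(0.625 / 2.5)  # 0.25

    def test_terminal_interval_saturates(self):
        pv = PValueVector(np.array([0.1, 0.2, 0.9, 1.0]))
        out = strimmer_lfdr(pv, min_m=2)
        assert out.lfdr[2] == 1.0 and out.lfdr[3] == 1.0

    def test_min_m_gate(self):
        with pytest.raises(MethodInapplicable):
            strimmer_lfdr(PValueVector(np.array([0.01, 0.5, 0.9])))

    def test_monotone_in_p(self, random_pvector_batch):
        for p in random_pvector_batch(30, min_m=8, max_m=100):
            pv = PValueVector(p)
            out = strimmer_lfdr(pv)
            order = np.argsort(p, kind="stable")
            assert (np.diff(out.lfdr[order]) >= -1e-12).all()


class TestStrimmerQValues:
    def test_uniform_data_saturates_at_pi0(self):
        # flat density, pi0 = 1: pFDR of any rejection region is 1
        pv = PValueVector(np.array([0.25, 0.5, 0.75, 1.0]))
        q = strimmer_qvalues(pv).qvalues
        np.testing.assert_allclose(q, np.ones(4))

    def test_worked_example(self):
        pv = PValueVector(np.array([0.1, 0.2, 0.9, 1.0]))
        q = strimmer_qvalues(pv).qvalues
        assert q[0] == pytest.approx(0.25)

    def test_qvalues_tend_below_lfdr(self):
        """Tail-averaging makes q <= lfdr for most hypotheses under signal."""
        frac = []
        for r in range(20):
            pv = _sim_pvalues(200, 0.5, 2.5, r)
            q = strimmer_qvalues(pv).qvalues
            l = strimmer_lfdr(pv).lfdr
            frac.append(np.mean(q <= l + 1e-12))
        assert np.mean(frac) > 0.5

    def test_monotone_in_p(self, random_pvector_batch):
        for p in random_pvector_batch(30, min_m=4, max_m=100):
            q = strimmer_qvalues(PValueVector(p)).qvalues
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-12).all()
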