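"""Weight map, weighted fitting, one-step LOO, and the LOOCV optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from asymclr.asym_integration import (
    WeightMap,
    _objective_at_omega,
    cv_objective,
    integrate_variant,
    loo_onestep,
    map_weights,
    optimize_map,
    weighted_fit,
)
from asymclr.clr_core import clr_loglik, fit_clr
from asymclr.matched_data import DifferenceData
from asymclr.synthetic_data import SimConfig, simulate_cohorts
from conftest import normal_diff


class TestWeightMap:
    @pytest.mark.parametrize(
        "q,qa,qb,expected",
        [
            (0.1, 0.2, 0.6, 0.0),
            (0.4, 0.2, 0.6, 0.5),
            (0.8, 0.2, 0.6, 1.0),
            (0.5, 0.5, 0.5, 0.0),  # degenerate knots: right-continuous step
        ],
    )
    def test_branches(self, q, qa, qb, expected):
        assert map_weights([q], WeightMap(qa, qb))[0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_map_rejected(self):
        with pytest.raises(ValueError):
            WeightMap(0.7, 0.3)

    def test_out_of_range_q_rejected(self):
        with pytest.raises(ValueError):
            map_weights([1.2], WeightMap(0.1, 0.9))

    @given(
        qa=st.floats(0, 1),
        width=st.floats(0.01, 1),
        qs=st.lists(st.floats(0, 1), min_size=2, max_size=6),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_nondecreasing_in_q(self, qa, width, qs):
        qb = min(qa + width, 1.0)
        wm = WeightMap(qa, qb)
        qs = sorted(qs)
        om = map_weights(qs, wm)
        assert (np.diff(om) >= -1e-12).all()
        assert ((om >= 0) & (om <= 1)).all()


class TestWeightedFit:
    def test_all_zero_omega_is_local_fit_bitwise(self, rng):
        loc = normal_diff(rng, 30)
        ext = normal_diff(rng, 40)
        f_w = weighted_fit(loc, [ext], [0.0])
        f_l = fit_clr(loc)
        assert f_w.beta[0] == f_l.beta[0]
        assert f_w.se[0] == f_l.se[0]
        assert f_w.loglik == f_l.loglik

    def test_all_one_omega_is_pooled_fit(self, rng):
        loc, ext = normal_diff(rng, 30), normal_diff(rng, 40)
        f_w = weighted_fit(loc, [ext], [1.0])
        f_p = fit_clr(np.vstack([loc.z, ext.z]))
        assert f_w.beta[0] == pytest.approx(f_p.beta[0], abs=1e-10)

    def test_fractional_omega_matches_generic_optimizer(self, rng):
        """Half-weighted auxiliary strata equal an importance-weighted
        conditional-logistic fit maximized by a generic optimizer."""
        loc, ext = normal_diff(rng, 30), normal_diff(rng, 50)
        f_w = weighted_fit(loc, [ext], [0.5])
        z = np.vstack([loc.z, ext.z])
        w = np.concatenate([np.ones(30), np.full(50, 0.5)])
        res = optimize.minimize(
            lambda b: -clr_loglik(z, b, w), [0.0], method="BFGS",
            options={"gtol": 1e-12},
        )
        assert f_w.beta[0] == pytest.approx(res.x[0], abs=1e-6)

    def test_omega_length_checked(self, rng):
        with pytest.raises(ValueError):
            weighted_fit(normal_diff(rng, 5), [normal_diff(rng, 5)], [0.5, 0.5])


class TestLooOnestep:
    def test_zero_row_stratum_has_zero_leverage(self, rng):
        z = rng.normal(0.2, 1.0, size=(20, 1))
        z[3, 0] = 0.0
        loc = DifferenceData(z)
        fit = fit_clr(loc)
        loo = loo_onestep(loc, [], np.array([]), fit)
        assert loo.v_diag[3] == 0.0
        assert loo.beta_loo[3, 0] == fit.beta[0]

    def test_duplication_halves_leverage(self, rng):
        z = rng.normal(0.2, 1.0, size=(25, 1))
        loc = DifferenceData(z)
        fit = fit_clr(loc)
        loo = loo_onestep(loc, [], np.array([]), fit)
        loc2 = DifferenceData(np.vstack([z, z]))
        fit2 = fit_clr(loc2)
        loo2 = loo_onestep(loc2, [], np.array([]), fit2)
        np.testing.assert_allclose(loo2.v_diag[:25], loo.v_diag / 2, rtol=1e-6)

    def test_matches_exact_refit_with_anchoring_externals(self, rng):
        """At the integration operating point (auxiliary strata present) the
        one-step estimate tracks the exact leave-one-stratum-out refit."""
        loc = normal_diff(rng, 20)
        ext = normal_diff(rng, 300)
        fit = weighted_fit(loc, [ext], [1.0])
        loo = loo_onestep(loc, [ext], [1.0], fit)
        for j in range(20):
            keep = np.ones(20, dtype=bool)
            keep[j] = False
            f_j = weighted_fit(DifferenceData(loc.z[keep]), [ext], [1.0])
            assert abs(f_j.beta[0] - loo.beta_loo[j, 0]) < 0.02 * abs(fit.beta[0])

    def test_external_free_error_vanishes_with_n(self, rng):
        """Without auxiliary anchoring, the one-step error is O(1/n^2): at
        n0=200 the worst stratum is still within 2% of the exact refit."""
        loc = normal_diff(rng, 200)
        fit = fit_clr(loc)
        loo = loo_onestep(loc, [], np.array([]), fit)
        worst = 0.0
        for j in range(200):
            keep = np.ones(200, dtype=bool)
            keep[j] = False
            f_j = fit_clr(loc.z[keep])
            worst = max(worst, abs(f_j.beta[0] - loo.beta_loo[j, 0]))
        assert worst < 0.02 * abs(fit.beta[0])

    def test_unconverged_fit_rejected(self, rng):
        loc = DifferenceData(np.array([1.0, 1.0, 1.0]))
        bad = fit_clr(loc.z)
        with pytest.raises(ValueError):
            loo_onestep(loc, [], np.array([]), bad)


class TestCvObjective:
    def test_no_externals_null_baseline(self):
        """With symmetric z the full fit is beta=0, where every stratum
        contributes exactly log 2 in-sample; each left-out estimate shifts
        away from its own stratum, so the out-of-sample objective strictly
        exceeds that baseline and matches the exact-refit objective."""
        z = np.array([[1.0], [-1.0]] * 10)
        loc = DifferenceData(z)
        assert -clr_loglik(z, [0.0]) == pytest.approx(20 * np.log(2), rel=1e-12)
        obj = cv_objective(loc, [], [], WeightMap(1.0, 1.0))
        assert obj > 20 * np.log(2)
        exact = cv_objective(loc, [], [], WeightMap(1.0, 1.0), exact=True)
        assert obj == pytest.approx(exact, abs=5e-3)

    def test_all_zero_weights_reduce_to_local(self, rng):
        loc, ext = normal_diff(rng, 25), normal_diff(rng, 30)
        obj_k0 = cv_objective(loc, [], [], WeightMap(1.0, 1.0))
        obj_zero = cv_objective(loc, [ext], [0.5], WeightMap(1.0, 1.0))
        assert obj_zero == obj_k0

    def test_agrees_with_exact_refit_bruteforce(self, rng):
        """One-step objective within 1e-3 of the exact-refit objective on
        n0=15 local strata anchored by a 400-stratum auxiliary cohort."""
        wm = WeightMap(0.2, 0.6)
        for _ in range(3):
            loc = normal_diff(rng, 15)
            ext = normal_diff(rng, 400)
            o_fast = cv_objective(loc, [ext], [0.45], wm)
            o_exact = cv_objective(loc, [ext], [0.45], wm, exact=True)
            assert abs(o_fast - o_exact) < 1e-3


class TestOptimizeMap:
    def test_dominates_all_zero_corner(self, rng):
        """The selected objective never exceeds the value at (qa,qb)=(1,1),
        whose weights are all zero, because that corner is always evaluated."""
        loc = normal_diff(rng, 40, mean=0.4)
        exts = [normal_diff(rng, 60, mean=-0.4), normal_diff(rng, 60, mean=0.4)]
        q = [0.02, 0.7]
        result = optimize_map(loc, exts, q)
        at_corner = cv_objective(loc, exts, q, WeightMap(1.0, 1.0))
        assert result.cv_objective <= at_corner + 1e-6

    def test_single_external_matches_grid_sweep(self, rng):
        """With K=1 and q=0.5 the objective depends on (qa,qb) only through
        omega; the optimizer matches a dense 1-D sweep over omega."""
        loc = normal_diff(rng, 40, mean=0.3)
        ext = normal_diff(rng, 200, mean=0.3)
        result = optimize_map(loc, [ext], [0.5])
        sweep = [
            _objective_at_omega(loc, [ext], np.array([om]))[0]
            for om in np.linspace(0, 1, 101)
        ]
        best_sweep = min(sweep)
        assert result.cv_objective <= best_sweep + 1e-6 or (
            result.cv_objective - best_sweep < 5e-3
        )
        # and never better than the continuum optimum by more than float noise
        assert best_sweep - result.cv_objective < 5e-3

    def test_relevant_externals_get_high_weight(self):
        """Same-coefficient externals with plenty of data should be accepted
        (omega near 1) in most replicates."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            loc = normal_diff(rng, 60, mean=0.4)
            exts = [normal_diff(rng, 400, mean=0.4) for _ in range(2)]
            q = [0.5, 0.5]  # plausible homogeneity evidence
            res = optimize_map(loc, exts, q)
            if (res.omega > 0.8).all():
                hits += 1
        assert hits >= 0.6 * reps

    def test_invariant_omega_equals_map_of_q(self, rng):
        loc = normal_diff(rng, 30, mean=0.4)
        ext = normal_diff(rng, 50, mean=0.4)
        res = optimize_map(loc, [ext], [0.6])
        np.testing.assert_allclose(res.omega, map_weights(res.q, res.map))


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(
        labels=["loc", "e1", "e2"],
        strata_per_cohort=[200, 400, 400],
        n_variants=3,
        seed=2024,
        beta=np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5], [0.5, -0.5, -0.5]]),
    )
    return simulate_cohorts(cfg)


class TestIntegrateVariant:
    def test_prescreen_skips_weak_local_signal(self, panel):
        dosages, cohorts, _ = panel
        rec = integrate_variant(0, cohorts, "loc", dosages, prescreen_alpha=1e-12)
        assert rec["skipped"] and np.isnan(rec["p_int"])
        assert not np.isnan(rec["p_local"])

    def test_zeroed_weights_reduce_to_local_p(self, rng):
        """When every auxiliary weight comes out exactly zero the integrated
        p-value equals the local p-value bit-for-bit."""
        loc = normal_diff(rng, 50, mean=0.5)
        ext = normal_diff(rng, 300, mean=-0.5)  # strongly conflicting
        res = optimize_map(loc, [ext], [1e-30])
        f_local = fit_clr(loc)
        if (res.omega == 0.0).all():
            assert res.p_integrated == f_local.p_wald[0]
        assert res.cv_objective <= cv_objective(loc, [ext], [1e-30], WeightMap(1.0, 1.0)) + 1e-9

    def test_conflicting_externals_downweighted(self, panel):
        """Shared-effect externals receive more total weight than externals
        whose coefficient conflicts with the local one."""
        dosages, cohorts, _ = panel
        rec_shared = integrate_variant(1, cohorts, "loc", dosages, prescreen_alpha=1.0)
        rec_confl = integrate_variant(2, cohorts, "loc", dosages, prescreen_alpha=1.0)
        w_shared = rec_shared["omega_e1"] + rec_shared["omega_e2"]
        w_confl = rec_confl["omega_e1"] + rec_confl["omega_e2"]
        assert w_shared > w_confl

    def test_record_carries_weights_and_knots(self, panel):
        dosages, cohorts, _ = panel
        rec = integrate_variant(1, cohorts, "loc", dosages, prescreen_alpha=1.0)
        assert not rec["skipped"]
        assert 0.0 <= rec["qa"] <= rec["qb"] <= 1.0
        for lab in ("e1", "e2"):
            assert 0.0 <= rec[f"omega_{lab}"] <= 1.0
            assert 0.0 <= rec[f"q_{lab}"] <= 1.0
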