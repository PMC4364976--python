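"""Closed-form kinetic models validated against an independent ODE integration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dcefit import (
    AifParams,
    TissueParams,
    aif_concentration,
    batch_tissue_concentration,
    ees_concentration,
    elapsed_infusion_time,
    ode_reference_solution,
    sse_objective,
    system_eigenvalues,
    tissue_concentration,
)
from dcefit.exceptions import (
    CoincidentRateError,
    DimensionError,
    InvalidInfusionWindowError,
    ModelError,
)

from conftest import random_valid_aif


class TestElapsedInfusionTime:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.5, 0.0), (2.0, 0.5), (10.0, 2.0)],
        ids=["before-arrival", "during-infusion", "after-infusion"],
    )
    def test_piecewise_branches(self, t, expected):
        assert elapsed_infusion_time(t, t0=1.0, t1=3.0, tlag=0.5) == expected

    def test_vectorised_and_bounded(self):
        t = np.linspace(0, 20, 200)
        tau = elapsed_infusion_time(t, 1.0, 3.0, 0.5)
        assert np.all((tau >= 0) & (tau <= 2.0))

    def test_invalid_window_raises(self):
        with pytest.raises(InvalidInfusionWindowError):
            elapsed_infusion_time(1.0, t0=3.0, t1=3.0)


class TestSystemEigenvalues:
    def test_decoupled_system(self):
        # k12 = 0 decouples the compartments: eigenvalues are the rates
        lam1, lam2 = system_eigenvalues(0.3, 0.0, 0.1)
        assert lam1 == pytest.approx(0.3, abs=1e-15)
        assert lam2 == pytest.approx(0.1, abs=1e-15)

    def test_against_polynomial_roots(self):
        # independent oracle: roots of lambda^2 - 0.6 lambda + 0.03
        expected = sorted(np.roots([1.0, -0.6, 0.03]), reverse=True)
        lam = system_eigenvalues(0.3, 0.2, 0.1)
        assert lam == pytest.approx(expected, rel=1e-12)

    @given(
        k10=st.floats(0.05, 3.0),
        k12=st.floats(0.0, 3.0),
        k21=st.floats(0.05, 3.0),
    )
    def test_vieta_identities(self, k10, k12, k21):
        try:
            lam1, lam2 = system_eigenvalues(k10, k12, k21)
        except CoincidentRateError:
            return
        assert lam1 >= lam2 > 0
        assert lam1 + lam2 == pytest.approx(k10 + k12 + k21, rel=1e-12)
        assert lam1 * lam2 == pytest.approx(k10 * k21, rel=1e-12)

    def test_coincident_raises(self):
        # k12 = 0 and k10 = k21 makes the eigenvalues coincide
        with pytest.raises(CoincidentRateError):
            system_eigenvalues(0.3, 0.0, 0.3)


class TestClosedFormsAgainstOde:
    def test_aif_matches_ode_at_spec_points(self, aif_example):
        t = np.array([0.5, 2.0, 5.0])
        c1 = aif_concentration(t, aif_example)
        o1, _ = ode_reference_solution(t, aif_example, k30=1.2)
        assert np.max(np.abs(c1 - o1)) / np.max(np.abs(o1)) < 1e-6

    def test_ees_matches_ode_at_spec_points(self, aif_example):
        t = np.array([0.5, 2.0, 5.0])
        c3 = ees_concentration(t, aif_example, 1.2)
        _, o3 = ode_reference_solution(t, aif_example, k30=1.2)
        assert np.max(np.abs(c3 - o3)) / np.max(np.abs(o3)) < 1e-6

    def test_random_parameter_sets_agree_with_oracle(self):
        # closed-form / ODE equivalence over 20 random valid parameter sets
        rng = np.random.default_rng(42)
        t = np.linspace(0.1, 10.0, 25)
        worst = 0.0
        for _ in range(20):
            p = random_valid_aif(rng)
            k30 = rng.uniform(0.1, 3.0)
            lam1, lam2 = p.eigenvalues
            if min(abs(k30 - lam1), abs(k30 - lam2)) < 1e-3:
                k30 += 5e-3
            o1, o3 = ode_reference_solution(t, p, k30)
            c1 = aif_concentration(t, p)
            c3 = ees_concentration(t, p, k30)
            worst = max(
                worst,
                np.max(np.abs(c1 - o1)) / np.max(np.abs(o1)),
                np.max(np.abs(c3 - o3)) / np.max(np.abs(o3)),
            )
        assert worst < 1e-6

    def test_tissue_matches_ode_combination(self, aif_example):
        t = np.array([0.5, 2.0, 5.0])
        tp = TissueParams(ve=0.3, k30=0.5, vb=0.05, tlag=0.0)
        o1, o3 = ode_reference_solution(t, aif_example, tp.k30)
        expected = tp.ve * o3 + tp.vb * o1
        got = tissue_concentration(t, aif_example, tp)
        assert np.max(np.abs(got - expected)) / np.max(np.abs(expected)) < 1e-6


class TestModelProperties:
    def test_causality_exact_zero_before_arrival(self):
        p = AifParams(
            r0_over_v1=10.0, k10=0.5, k12=0.25, k21=0.15,
            t0=1.0, t1=2.0, tlag=0.5,
        )
        t = np.array([0.1, 0.7, 1.2, 1.5, 3.0])
        pre = t <= p.t0 + p.tlag
        assert np.all(aif_concentration(t, p)[pre] == 0.0)
        assert np.all(ees_concentration(t, p, 0.8)[pre] == 0.0)

    def test_linearity_in_infusion_rate(self, aif_example):
        from dataclasses import replace

        t = np.linspace(0.1, 8.0, 30)
        scaled = replace(aif_example, r0_over_v1=3.7 * aif_example.r0_over_v1)
        np.testing.assert_allclose(
            aif_concentration(t, scaled), 3.7 * aif_concentration(t, aif_example),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            ees_concentration(t, scaled, 0.9),
            3.7 * ees_concentration(t, aif_example, 0.9),
            rtol=1e-12,
        )

    def test_continuity_at_infusion_end(self, aif_example):
        eps = 1e-8
        te = aif_example.t1 + aif_example.tlag
        t = np.array([te - eps, te + eps])
        c = aif_concentration(t, aif_example)
        peak = np.max(aif_concentration(np.linspace(0.01, 10, 500), aif_example))
        assert abs(c[1] - c[0]) < 1e-5 * peak

    def test_late_time_decay(self):
        p = AifParams(
            r0_over_v1=10.0, k10=0.5, k12=0.25, k21=0.15, t0=0.0, t1=1.0
        )
        c_end = aif_concentration(np.array([0.5, p.t1 + p.tlag]), p)[-1]
        c_late = aif_concentration(np.array([1.0, 200.0]), p)[-1]
        assert abs(c_late) < abs(c_end) * 1e-6

    def test_fast_exchange_tracks_plasma(self, aif_example):
        # k30 >> lambda1 makes the EES follow the arterial curve closely
        t = np.linspace(0.1, 8.0, 80)
        c1 = aif_concentration(t, aif_example)
        c3 = ees_concentration(t, aif_example, 50.0)
        assert np.max(np.abs(c3 - c1)) / np.max(c1) < 0.05

    def test_near_coincident_k30_is_nudged(self, aif_example):
        lam1, _ = aif_example.eigenvalues
        c = ees_concentration(np.array([0.5, 2.0]), aif_example, lam1)
        assert np.all(np.isfinite(c))


class TestTissueModel:
    def test_vanishing_ve_leaves_plasma_term(self, aif_example):
        t = np.linspace(0.1, 8.0, 40)
        tp = TissueParams(ve=1e-9, k30=0.6, vb=0.2, tlag=0.0)
        np.testing.assert_allclose(
            tissue_concentration(t, aif_example, tp),
            tp.vb * aif_concentration(t, aif_example),
            rtol=0, atol=1e-8,
        )

    def test_pure_ees_term_is_scaled_ees(self, aif_example):
        t = np.array([0.5, 2.0])
        tp = TissueParams(ve=0.5, k30=0.6, vb=0.0, tlag=0.0)
        got = tissue_concentration(t, aif_example, tp)
        assert got[1] == 0.5 * ees_concentration(t, aif_example, 0.6)[1]

    def test_batch_matches_scalar_path_bitwise(self, aif_example):
        t = np.linspace(0.2, 8.0, 40)
        rng = np.random.default_rng(3)
        ve = rng.uniform(0.05, 0.45, 6)
        k30 = rng.uniform(0.1, 2.0, 6)
        vb = rng.uniform(0.0, 0.1, 6)
        tlag = rng.uniform(0.0, 0.3, 6)
        batch = batch_tissue_concentration(t, aif_example, ve, k30, vb, tlag)
        for i in range(6):
            tp = TissueParams(ve=ve[i], k30=k30[i], vb=vb[i], tlag=tlag[i])
            np.testing.assert_array_equal(
                batch[i], tissue_concentration(t, aif_example, tp)
            )

    def test_ktrans_identity(self):
        tp = TissueParams(ve=0.31, k30=0.7, vb=0.02)
        assert tp.ktrans == 0.7 * 0.31


class TestSseObjective:
    def test_known_values_and_symmetry(self):
        assert sse_objective([1.0, 2.0], [0.0, 0.0]) == 5.0
        assert sse_objective([1.0, 2.0], [1.0, 2.0]) == 0.0
        # permuting both series together leaves the sum unchanged
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        assert sse_objective(a, b) == pytest.approx(
            sse_objective(a[perm], b[perm]), rel=1e-12
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            sse_objective([1.0, 2.0], [1.0])


class TestOdeOracle:
    def test_zero_input_rate_gives_zero(self):
        p = AifParams(
            r0_over_v1=0.0, k10=0.5, k12=0.25, k21=0.15, t0=0.0, t1=1.0
        )
        c1, c3 = ode_reference_solution(np.linspace(0.1, 5, 20), p, 0.8)
        assert np.all(c1 == 0) and np.all(c3 == 0)

    def test_mass_conservation_with_negligible_elimination(self):
        # with k10 ~ 0 and no peripheral exchange, everything infused stays in
        # compartment 1: late C1 -> R0/V1 * (t1 - t0)
        p = AifParams(
            r0_over_v1=5.0, k10=1e-9, k12=0.0, k21=0.2, t0=0.0, t1=1.0
        )
        c1, _ = ode_reference_solution(np.array([0.5, 30.0]), p, 0.8)
        assert c1[-1] == pytest.approx(p.r0_over_v1 * (p.t1 - p.t0), rel=1e-6)


class TestValidation:
    def test_tissue_params_invariants(self):
        with pytest.raises(ModelError):
            TissueParams(ve=1.2, k30=0.5, vb=0.0)
        with pytest.raises(ModelError):
            TissueParams(ve=0.3, k30=-0.5, vb=0.0)

    def test_time_grid_must_increase(self):
        p = AifParams(r0_over_v1=1, k10=0.5, k12=0.2, k21=0.1, t0=0, t1=1)
        with pytest.raises(ModelError):
            aif_concentration(np.array([1.0, 0.5]), p)
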