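"""Energy-partition tests: closed forms, numerical quadrature, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from viscowork import (
    AdhesionModel,
    EnergyBudget,
    HillParams,
    Trace,
    ViscoelasticParams,
    crossover_time,
    elastic_work,
    hill_vmax,
    make_linear_ramp,
    partition_trace,
    sample_trace,
    total_work_per_contraction,
    viscous_work_ramp,
)


class TestClosedForms:
    @pytest.mark.parametrize("k, D, expected", [
        (1000.0, 0.10, 5.0),
        (0.010, 1.00e-7, 5.00e-17),
        (1234.0, 0.0, 0.0),
    ])
    def test_elastic_work(self, k, D, expected):
        assert elastic_work(k, D) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eta, D, T, expected", [
        (50.0, 0.10, 1.0, 0.50),
        (50.0, 0.10, 0.01, 50.0),
        (1.0e-6, 1.00e-7, 1.00e-4, 1.00e-16),
    ])
    def test_viscous_work_ramp(self, eta, D, T, expected):
        assert viscous_work_ramp(eta, D, T) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            elastic_work(-1.0, 0.1)
        with pytest.raises(ValueError):
            viscous_work_ramp(50.0, 0.1, 0.0)

    @settings(deadline=None)
    @given(eta=st.floats(1e-9, 1e3), D=st.floats(1e-9, 1.0),
           T=st.floats(1e-9, 1e3), c=st.floats(1e-6, 1e6))
    def test_inverse_time_scaling(self, eta, D, T, c):
        """W_visc(T/c) = c * W_visc(T): dissipation is exactly ∝ 1/T."""
        assert viscous_work_ramp(eta, D, T / c) == pytest.approx(
            c * viscous_work_ramp(eta, D, T), rel=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(T1=st.floats(1e-3, 1e2), T2=st.floats(1e-3, 1e2))
    def test_elastic_storage_rate_independent(self, T1, T2):
        """Stored spring energy of a ramp is the same at any loading rate."""
        p = ViscoelasticParams(k=1000.0, eta=50.0)
        D = 0.10
        b1 = partition_trace(sample_trace(make_linear_ramp(D, T1, 201), p), p)
        b2 = partition_trace(sample_trace(make_linear_ramp(D, T2, 201), p), p)
        assert b1.w_el == pytest.approx(b2.w_el, rel=1e-9)
        assert b1.w_el == pytest.approx(elastic_work(p.k, D), rel=1e-9)


class TestCrossoverTime:
    @pytest.mark.parametrize("k, eta", [(1000.0, 50.0), (0.01, 1e-6)])
    def test_matches_numerical_root(self, k, eta):
        """T* solves η·D²/T = ½·k·D² ; found independently by brentq."""
        D = 0.37  # arbitrary: T* must not depend on it
        oracle = brentq(lambda T: viscous_work_ramp(eta, D, T)
                        - elastic_work(k, D), 1e-12, 1e6, xtol=1e-15)
        p = ViscoelasticParams(k=k, eta=eta)
        assert crossover_time(p) == pytest.approx(oracle, rel=1e-9)

    def test_budget_balanced_at_crossover(self, tendon_kv):
        T_star = crossover_time(tendon_kv)
        assert T_star == pytest.approx(0.1, rel=1e-12)
        trace = sample_trace(make_linear_ramp(0.10, T_star, 1001), tendon_kv)
        budget = partition_trace(trace, tendon_kv)
        assert budget.w_visc == pytest.approx(budget.w_el, rel=1e-9)

    def test_rigid_spring_rejected(self):
        with pytest.raises(ValueError, match="k > 0"):
            crossover_time(ViscoelasticParams(k=0.0, eta=1.0))


class TestPartitionTrace:
    def test_tendon_slow_ramp_total(self, tendon_kv):
        trace = sample_trace(make_linear_ramp(0.10, 1.0, 10_001), tendon_kv)
        budget = partition_trace(trace, tendon_kv)
        assert budget.w_total == pytest.approx(5.50, rel=1e-6)
        assert budget.w_el == pytest.approx(5.0, rel=1e-6)
        assert budget.w_visc == pytest.approx(0.50, rel=1e-6)
        assert budget.method == "numerical"

    def test_zero_displacement_zero_budget(self, tendon_kv):
        trace = sample_trace(make_linear_ramp(0.0, 1.0, 101), tendon_kv)
        budget = partition_trace(trace, tendon_kv)
        assert budget.w_total == 0.0 == budget.w_el == budget.w_visc

    def test_constant_adhesion_closed_form(self):
        """With k = η = 0 and constant pull f0, total work is f0·D."""
        p = ViscoelasticParams(k=0.0, eta=0.0)
        adh = AdhesionModel(kind="constant", f0=1e-9)
        trace = sample_trace(make_linear_ramp(1e-7, 0.1, 10_001), p, adh)
        budget = partition_trace(trace, p, adh)
        assert budget.w_adh == pytest.approx(1.0e-16, rel=1e-4)
        assert budget.w_total == pytest.approx(budget.w_adh, rel=1e-12)

    def test_unloading_rejected(self, tendon_kv):
        t = np.linspace(0, 1.0, 5)
        x = np.array([0.0, 0.01, 0.02, 0.015, 0.01])  # retracts
        v = np.gradient(x, t)
        F = tendon_kv.k * x + tendon_kv.eta * v
        trace = Trace(t=t, x=x, v=v, F=F, P=F * v)
        with pytest.raises(ValueError, match="unloading not modeled"):
            partition_trace(trace, tendon_kv)

    def test_budget_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            EnergyBudget(w_el=1.0, w_visc=1.0, w_adh=0.0, w_total=3.0,
                         method="analytic")

    def test_quadratic_error_decay(self):
        """Trapezoid error of the partition falls as O(n^-2).

        The spring/dashpot integrands of a linear ramp are affine and hence
        integrated exactly; the order of accuracy is exposed through the
        curved adhesion integrand, whose work has the closed form
        f0·λ·(1 − exp(−D/λ)).
        """
        p = ViscoelasticParams(k=0.0, eta=0.0)
        f0, lam, D, T = 1e-9, 3e-8, 1e-7, 0.1
        adh = AdhesionModel(kind="exponential", f0=f0, lam=lam)
        exact = f0 * lam * (1.0 - np.exp(-D / lam))
        errs = []
        ns = [11, 21, 41, 81]
        for n in ns:
            trace = sample_trace(make_linear_ramp(D, T, n), p, adh)
            budget = partition_trace(trace, p, adh)
            errs.append(abs(budget.w_adh - exact))
        rates = [np.log2(errs[i] / errs[i + 1]) for i in range(len(ns) - 1)]
        assert all(r == pytest.approx(2.0, abs=0.1) for r in rates)

    def test_default_grid_tolerance(self, tendon_kv):
        """At the default grid the numerical split is within 1e-6 relative."""
        trace = sample_trace(make_linear_ramp(0.10, 0.01, 10_001), tendon_kv)
        budget = partition_trace(trace, tendon_kv)
        assert budget.w_el == pytest.approx(5.0, rel=1e-6)
        assert budget.w_visc == pytest.approx(50.0, rel=1e-6)
        assert budget.w_total == pytest.approx(55.0, rel=1e-6)


class TestHillWork:
    @pytest.mark.parametrize("v, expected", [
        (0.10, 4.0833), (0.50, 2.25),
    ])
    def test_reference_contractions(self, muscle, v, expected):
        W = total_work_per_contraction(muscle, 0.05, v)
        assert W == pytest.approx(expected, rel=1e-4)

    def test_isometric_and_vmax_limits(self, muscle):
        D = 0.05
        assert total_work_per_contraction(muscle, D, 0.0) == pytest.approx(
            muscle.fmax * D)
        vmax = hill_vmax(muscle)
        assert total_work_per_contraction(muscle, D, vmax) == pytest.approx(
            0.0, abs=1e-12)

    @settings(deadline=None)
    @given(fmax=st.floats(1.0, 1e4), a=st.floats(0.1, 1e3),
           b=st.floats(0.01, 10.0), D=st.floats(1e-3, 1.0))
    def test_work_strictly_decreasing_in_velocity(self, fmax, a, b, D):
        p = HillParams(fmax=fmax, a=a, b=b)
        v = np.linspace(0.0, hill_vmax(p), 12)
        W = np.array([total_work_per_contraction(p, D, vi) for vi in v])
        assert np.all(np.diff(W) < 0)
        assert W[0] == pytest.approx(fmax * D, rel=1e-12)
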