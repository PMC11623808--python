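"""Resource-competition fitness model: steady states, equilibria, regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecograph.ecology import (
    AbsorbingStateError,
    EcoEvoParams,
    EcotypeStrategy,
    NoEquilibriumError,
    PopulationState,
    ResourceEnvironment,
    classify_regime,
    effective_selection,
    equilibrium_concentrations,
    equilibrium_frequency,
    equilibrium_frequency_closed_form,
    overall_fitness,
    relative_mutant_fitness,
)


def _sym(alpha, s=0.0, N=100):
    return EcoEvoParams(N=N, s=s, alpha=alpha)


class TestEquilibriumConcentrations:
    def test_all_wildtype_generalists(self):
        p = _sym(0.5, N=100)
        c = equilibrium_concentrations(PopulationState(0, 100), p.wt, p.mut, p.environment)
        assert np.allclose(c, [0.01, 0.01])

    def test_mixed_population_direct_balance(self):
        # 70 wt consuming (0.2, 0.8) and 30 mut consuming (0.8, 0.2)
        p = _sym(0.8, N=100)
        c = equilibrium_concentrations(PopulationState(30, 70), p.wt, p.mut, p.environment)
        assert np.allclose(c, [0.5 / 38.0, 0.5 / 62.0])

    def test_symmetry_at_equal_counts(self):
        p = _sym(0.73, N=40)
        c = equilibrium_concentrations(PopulationState(20, 20), p.wt, p.mut, p.environment)
        assert c[0] == pytest.approx(c[1], rel=1e-14)

    def test_zero_consumption_is_degenerate(self):
        from ecograph.ecology import DegenerateEnvironmentError

        wt = EcotypeStrategy("wt", 1.0, (1.0, 0.0))
        mut = EcotypeStrategy("mut", 1.0, (1.0, 0.0))
        with pytest.raises(DegenerateEnvironmentError):
            equilibrium_concentrations((1, 9), wt, mut, ResourceEnvironment())

    def test_nonlinear_law_inverts_numerically(self):
        env = ResourceEnvironment(consumption_law=lambda c: c**2)
        p = _sym(0.5, N=10)
        c = equilibrium_concentrations(PopulationState(0, 10), p.wt, p.mut, env)
        # S = T c^2 -> c = sqrt(S/T), T = 10 * 0.5 = 5
        assert np.allclose(c, np.sqrt(0.5 / 5.0))


class TestRelativeFitness:
    def test_generalists_reduce_to_constant_selection(self):
        p = _sym(0.5, s=0.01)
        for n in (1, 17, 50, 99):
            assert relative_mutant_fitness(n, p) == pytest.approx(1.01, rel=1e-14)

    def test_neutral_symmetric_midpoint(self):
        p = _sym(0.8, s=0.0)
        assert relative_mutant_fitness(50, p) == pytest.approx(1.0, rel=1e-14)

    def test_identical_ecology_gives_ratio_one_plus_s(self):
        p = _sym(0.5, s=0.01)
        c = equilibrium_concentrations(PopulationState(30, 70), p.wt, p.mut, p.environment)
        assert overall_fitness(p.mut, c, p.environment) / overall_fitness(
            p.wt, c, p.environment
        ) == pytest.approx(1.01)

    def test_absorbing_states_rejected(self):
        p = _sym(0.7)
        with pytest.raises(AbsorbingStateError):
            relative_mutant_fitness(0, p)
        with pytest.raises(AbsorbingStateError):
            relative_mutant_fitness(p.N, p)

    @given(
        alpha=st.floats(0.5, 1.0),
        n=st.integers(1, 49),
        scale=st.floats(0.1, 10.0),
        s=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance_and_reflection(self, alpha, n, scale, s):
        """Multiplying allocations by a constant, or swapping alpha for
        1 - alpha, leaves the relative mutant fitness unchanged."""
        N = 50
        base = EcoEvoParams(N=N, s=s, alpha=alpha)
        f0 = relative_mutant_fitness(n, base)
        scaled = EcoEvoParams(
            N=N,
            s=s,
            wt=EcotypeStrategy("wt", 1.0, tuple(scale * a for a in base.wt.alphas)),
            mut=EcotypeStrategy(
                "mut", 1.0 + s, tuple(scale * a for a in base.mut.alphas)
            ),
        )
        assert relative_mutant_fitness(n, scaled) == pytest.approx(f0, abs=1e-12)
        if alpha > 0.5:
            a2 = 1.0 - alpha
            reflected = EcoEvoParams(
                N=N,
                s=s,
                wt=EcotypeStrategy("wt", 1.0, (1.0 - a2, a2)),
                mut=EcotypeStrategy("mut", 1.0 + s, (a2, 1.0 - a2)),
            )
            assert relative_mutant_fitness(n, reflected) == pytest.approx(f0, abs=1e-12)


class TestEquilibriumFrequency:
    @pytest.mark.parametrize("alpha", [0.6, 0.8, 0.99])
    def test_neutral_equilibrium_is_half(self, alpha):
        p = _sym(alpha, s=0.0)
        assert equilibrium_frequency(p) == pytest.approx(0.5, abs=1e-9)
        assert equilibrium_frequency_closed_form(p) == 0.5

    def test_deleterious_mutant_sits_below_half(self):
        x = equilibrium_frequency(_sym(0.8, s=-0.01))
        assert x < 0.5
        assert equilibrium_frequency(_sym(0.8, s=0.01)) > 0.5

    @pytest.mark.parametrize("s", np.linspace(-0.1, 0.1, 9))
    @pytest.mark.parametrize("alpha", [0.55, 0.7, 0.85, 1.0])
    def test_root_matches_closed_form(self, s, alpha):
        p = _sym(alpha, s=float(s))
        x_closed = equilibrium_frequency_closed_form(p)
        x_root = equilibrium_frequency(p, check_range=False)
        if not 0.0 < x_closed < 1.0:
            # strong s pushes the balance point out of (0, 1): no interior root
            assert x_root is None
        else:
            assert x_root == pytest.approx(x_closed, abs=1e-6)

    def test_no_equilibrium_without_ecology(self):
        with pytest.raises(NoEquilibriumError):
            equilibrium_frequency(_sym(0.5))

    def test_out_of_range_equilibrium_flagged(self):
        # strong s pushes x* outside (1/N, 1-1/N) at small N
        p = EcoEvoParams(N=10, s=-0.9, alpha=0.6)
        assert equilibrium_frequency(p) is None


class TestEffectiveSelection:
    def test_generalists_feel_only_intrinsic_selection(self):
        p = _sym(0.5, s=-0.003)
        for x in (0.0, 0.3, 1.0):
            assert effective_selection(x, p) == -0.003

    def test_combined_coefficient_at_one_third(self):
        p = _sym(0.53, s=-0.001)
        s_e = effective_selection(1.0 / 3.0, p)
        assert s_e == pytest.approx(-0.001 + (2.0 / 3.0) * 0.06**2, rel=1e-12)

    def test_vanishes_at_equilibrium_to_first_order(self):
        for s in (1e-3, -1e-3, 5e-3):
            p = _sym(0.7, s=s)
            x_star = equilibrium_frequency(p, check_range=False)
            assert abs(effective_selection(x_star, p)) <= 10 * s**2

    def test_generalized_strategies_use_exact_differential(self):
        p = EcoEvoParams(
            N=100,
            s=0.0,
            wt=EcotypeStrategy("wt", 1.0, (0.3, 0.7)),
            mut=EcotypeStrategy("mut", 1.0, (0.7, 0.3)),
        )
        sym = _sym(0.7, s=0.0)
        # same allocations: the exact differential matches the weak form near x*
        assert effective_selection(0.5, p) == pytest.approx(0.0, abs=1e-12)
        assert np.sign(effective_selection(0.2, p)) == np.sign(
            effective_selection(0.2, sym)
        )


class TestRegimeClassification:
    def test_weak_regime_example(self):
        assert classify_regime(_sym(0.53, N=100)) == "weak"

    def test_strong_regime_example(self):
        assert classify_regime(_sym(0.99, N=500)) == "strong"

    def test_no_ecology_is_weak_for_any_size(self):
        for N in (10, 1000, 100000):
            assert classify_regime(_sym(0.5, N=N)) == "weak"

    def test_intermediate_between(self):
        assert classify_regime(_sym(0.8, N=100)) == "intermediate"
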