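"""Resource-competition fitness model.

Two ecotypes (a resident wild type and an invading mutant) compete for a
set of externally supplied, substitutable resources.  Each ecotype sigma is
characterised by an enzyme-allocation strategy ``alpha_sigma`` (how much
metabolic machinery it devotes to each resource) and an intrinsic fitness
``s_sigma`` orthogonal to the ecological axis (wild type 1, mutant 1 + s).

Resource ``i`` is supplied at constant rate ``S_i`` and consumed at per-enzyme
rate ``mu(c_i)``; with a linear consumption law the steady-state concentration
is ``c_i* = S_i / total_consumption_i``.  The ecological fitness of ecotype
sigma is ``r_sigma = sum_i v_i alpha_sigma_i mu(c_i*)`` and the overall
fitness multiplies in the intrinsic component, ``f_sigma = s_sigma r_sigma``.
Because concentrations fall in whichever resource is over-consumed, the
relative mutant fitness ``f_mut`` is negatively frequency dependent and the
two ecotypes share an unstable interior coexistence equilibrium ``x*``.

In the symmetric two-resource parameterisation the wild type allocates
``(1 - alpha, alpha)`` and the mutant ``(alpha, 1 - alpha)``: the mutant
simply swaps which resource it prefers.  ``alpha = 0.5`` means identical
generalists (no ecological selection; the model reduces exactly to constant
selection ``1 + s``), ``alpha = 1`` means fully separated specialists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ResourceEnvironment",
    "EcotypeStrategy",
    "EcoEvoParams",
    "PopulationState",
    "DegenerateEnvironmentError",
    "AbsorbingStateError",
    "NoEquilibriumError",
    "equilibrium_concentrations",
    "ecological_fitness",
    "overall_fitness",
    "relative_mutant_fitness",
    "fitness_table",
    "equilibrium_frequency",
    "equilibrium_frequency_closed_form",
    "effective_selection",
    "classify_regime",
]


class DegenerateEnvironmentError(ValueError):
    """Raised when total consumption of some resource is zero."""


class AbsorbingStateError(ValueError):
    """Raised when an operation requires both ecotypes to be present."""


class NoEquilibriumError(ValueError):
    """Raised when no interior coexistence equilibrium exists (alpha = 0.5)."""


def _linear(c):
    return c


@dataclass(frozen=True)
class ResourceEnvironment:
    """Externally supplied resources.

    Parameters
    ----------
    supply : per-resource supply rate S_i (default 0.5 per resource).
    values : per-resource biomass value v_i (default 1).
    consumption_law : per-enzyme consumption rate mu(c); default linear.
    """

    supply: tuple[float, ...] = (0.5, 0.5)
    values: tuple[float, ...] = (1.0, 1.0)
    consumption_law: Callable[[np.ndarray], np.ndarray] = _linear

    def __post_init__(self):
        supply = tuple(float(s) for s in np.atleast_1d(self.supply))
        values = tuple(float(v) for v in np.atleast_1d(self.values))
        object.__setattr__(self, "supply", supply)
        object.__setattr__(self, "values", values)
        if len(supply) != len(values):
            raise ValueError("supply and values must have equal length")
        if any(s <= 0 for s in supply):
            raise ValueError("supply rates must be positive")
        if any(v <= 0 for v in values):
            raise ValueError("resource values must be positive")

    @property
    def n_resources(self) -> int:
        return len(self.supply)

    @property
    def is_linear(self) -> bool:
        return self.consumption_law is _linear


@dataclass(frozen=True)
class EcotypeStrategy:
    """An ecotype: a label, an intrinsic fitness and an allocation vector."""

    label: Literal["wt", "mut"]
    intrinsic_fitness: float
    alphas: tuple[float, ...]

    def __post_init__(self):
        alphas = tuple(float(a) for a in np.atleast_1d(self.alphas))
        object.__setattr__(self, "alphas", alphas)
        if self.intrinsic_fitness <= 0:
            raise ValueError("intrinsic fitness must be positive")
        if any(a < 0 for a in alphas) or not any(a > 0 for a in alphas):
            raise ValueError("allocations must be >= 0 and not all zero")


@dataclass(frozen=True)
class PopulationState:
    """Mutant/wild-type counts (node occupancy lives in the engine)."""

    n_mut: int
    n_wt: int

    def __post_init__(self):
        if self.n_mut < 0 or self.n_wt < 0:
            raise ValueError("counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_mut + self.n_wt


@dataclass(frozen=True)
class EcoEvoParams:
    """Population size, intrinsic selection and niche-overlap parameters.

    Either pass ``alpha`` (symmetric mode: wt allocates ``(1-alpha, alpha)``,
    mut ``(alpha, 1-alpha)``) or explicit ``wt``/``mut`` strategies.
    """

    N: int
    s: float = 0.0
    alpha: float | None = None
    wt: EcotypeStrategy | None = None
    mut: EcotypeStrategy | None = None
    environment: ResourceEnvironment = field(default_factory=ResourceEnvironment)

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.s <= -1:
            raise ValueError("intrinsic selection s must exceed -1")
        if self.alpha is not None:
            if self.wt is not None or self.mut is not None:
                raise ValueError("give either alpha or explicit strategies, not both")
            if not 0.5 <= self.alpha <= 1.0:
                raise ValueError("symmetric niche overlap alpha must lie in [0.5, 1]")
            a = float(self.alpha)
            object.__setattr__(
                self, "wt", EcotypeStrategy("wt", 1.0, (1.0 - a, a))
            )
            object.__setattr__(
                self, "mut", EcotypeStrategy("mut", 1.0 + self.s, (a, 1.0 - a))
            )
        else:
            if self.wt is None or self.mut is None:
                raise ValueError("need alpha or both wt and mut strategies")
            if len(self.wt.alphas) != self.environment.n_resources:
                raise ValueError("strategy length must match n_resources")
            if len(self.mut.alphas) != len(self.wt.alphas):
                raise ValueError("wt and mut strategies must have equal length")

    @property
    def symmetric(self) -> bool:
        return self.alpha is not None


# ---------------------------------------------------------------------------
# fitness operations


def _counts(state: PopulationState | tuple[float, float]) -> tuple[float, float]:
    if isinstance(state, PopulationState):
        return float(state.n_mut), float(state.n_wt)
    n_mut, n_wt = state
    return float(n_mut), float(n_wt)


def equilibrium_concentrations(
    state: PopulationState | tuple[float, float],
    wt: EcotypeStrategy,
    mut: EcotypeStrategy,
    env: ResourceEnvironment,
) -> np.ndarray:
    """Steady-state resource concentrations ``c_i*``.

    Balances supply against total consumption: ``S_i = T_i mu(c_i*)`` with
    ``T_i = n_wt alpha_wt_i + n_mut alpha_mut_i``.  Under the default linear
    law this is ``c_i* = S_i / T_i``; a nonlinear law is inverted numerically.
    """
    n_mut, n_wt = _counts(state)
    a_wt = np.asarray(wt.alphas, dtype=float)
    a_mut = np.asarray(mut.alphas, dtype=float)
    total = n_wt * a_wt + n_mut * a_mut
    supply = np.asarray(env.supply, dtype=float)
    if np.any(total <= 0):
        raise DegenerateEnvironmentError(
            "total consumption of some resource is zero; concentrations diverge"
        )
    if env.is_linear:
        return supply / total
    mu = env.consumption_law
    out = np.empty_like(supply)
    for i, (S_i, T_i) in enumerate(zip(supply, total)):
        g = lambda c: T_i * mu(c) - S_i  # noqa: E731
        hi = 1.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                raise DegenerateEnvironmentError("consumption law never balances supply")
        out[i] = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return out


def ecological_fitness(
    strategy: EcotypeStrategy, concentrations: np.ndarray, env: ResourceEnvironment
) -> float:
    """Ecological component ``r_sigma = sum_i v_i alpha_sigma_i mu(c_i*)``."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    mu = env.consumption_law(c)
    return float(np.dot(np.asarray(env.values), np.asarray(strategy.alphas) * mu))


def overall_fitness(
    strategy: EcotypeStrategy, concentrations: np.ndarray, env: ResourceEnvironment
) -> float:
    """Overall fitness ``f_sigma = s_sigma r_sigma`` (intrinsic x ecological)."""
    return strategy.intrinsic_fitness * ecological_fitness(strategy, concentrations, env)


def relative_mutant_fitness(n_mut: float, params: EcoEvoParams) -> float:
    """Relative mutant overall fitness ``f_mut = f~_mut / f~_wt`` at mutant count n.

    Accepts real-valued counts (the continuous-frequency extension used for
    root finding); raises at the absorbing states 0 and N.
    """
    N = params.N
    if not 0 < n_mut < N:
        raise AbsorbingStateError("relative fitness undefined at absorbing states")
    env = params.environment
    c = equilibrium_concentrations((n_mut, N - n_mut), params.wt, params.mut, env)
    return overall_fitness(params.mut, c, env) / overall_fitness(params.wt, c, env)


def fitness_table(params: EcoEvoParams) -> np.ndarray:
    """Vector ``f[n] = f_mut(n)`` for n = 0..N (endpoints padded with 1).

    With well-mixed resources the Birth-death reproduction weights depend on
    the mutant count only, so the whole frequency dependence of a simulation
    or an exact chain is captured by this table.
    """
    N = params.N
    f = np.ones(N + 1)
    for n in range(1, N):
        f[n] = relative_mutant_fitness(n, params)
    return f


def _fmut_continuous(x: float, params: EcoEvoParams) -> float:
    return relative_mutant_fitness(x * params.N, params)


def equilibrium_frequency_closed_form(params: EcoEvoParams) -> float:
    """Interior equilibrium ``x* = 1/2 + (1/2) (2a-1)^-2 s/(2+s)`` (symmetric mode).

    Derived from the linear-law steady state: the relative ecological fitness
    at frequency x is ``r(x) = (1 - w)/(1 + w)`` with ``w = (2a-1)^2 (2x-1)``,
    and ``f_mut(x*) = 1`` gives ``w = s/(2+s)``.
    """
    if not params.symmetric:
        raise ValueError("closed form requires the symmetric parameterisation")
    if params.alpha == 0.5:
        raise NoEquilibriumError("alpha = 0.5: no ecological selection, no equilibrium")
    beta2 = (2.0 * params.alpha - 1.0) ** 2
    return 0.5 + 0.5 * params.s / ((2.0 + params.s) * beta2)


def equilibrium_frequency(
    params: EcoEvoParams, *, check_range: bool = True
) -> float | None:
    """Root of ``f_mut(x) = 1`` on the continuous frequency line.

    Returns ``None`` when x* falls outside ``(1/N, 1 - 1/N)`` (establishment
    is then undefined) and ``check_range`` is set.  Raises
    :class:`NoEquilibriumError` when there is no ecological selection.
    """
    if params.symmetric and params.alpha == 0.5:
        raise NoEquilibriumError("alpha = 0.5: no ecological selection, no equilibrium")
    N = params.N
    g = lambda x: _fmut_continuous(x, params) - 1.0  # noqa: E731
    lo, hi = 0.25 / N, 1.0 - 0.25 / N
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        # root lies outside the open interval: establishment undefined
        return None
    x_star = brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if check_range and not (1.0 / N < x_star < 1.0 - 1.0 / N):
        return None
    return float(x_star)


def effective_selection(x: float, params: EcoEvoParams) -> float:
    """Frequency-dependent selection differential ``s(x)``.

    Symmetric mode returns the weak-selection form
    ``s(x) = s + 2 (2a-1)^2 (1 - 2x)``; generalized strategies return the
    exact differential ``f_mut(x) - 1`` evaluated on the continuous line.
    The combined effective coefficient that governs fixation in the weak
    regime is ``s_e = s(1/3) = s + (2/3)(2a-1)^2``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("frequency must lie in [0, 1]")
    if params.symmetric:
        beta2 = (2.0 * params.alpha - 1.0) ** 2
        return params.s + 2.0 * beta2 * (1.0 - 2.0 * x)
    x = min(max(x, 0.5 / params.N), 1.0 - 0.5 / params.N)
    return _fmut_continuous(x, params) - 1.0


def classify_regime(
    params: EcoEvoParams,
    *,
    weak_threshold: float = 0.3,
    strong_threshold: float = 0.05,
) -> Literal["weak", "strong", "intermediate"]:
    """Classify the strength of ecological selection.

    Weak when ``N (2/3)(2a-1)^2 < weak_threshold`` (frequency dependence is
    drowned by drift); strong when the establishment-failure ratio
    ``[(2a-1)^-2 - 1 + 2/N] / [(2a-1)^-2 + 1 - 2/N] < strong_threshold``
    (establishment is near deterministic); otherwise intermediate.
    """
    if params.symmetric:
        beta2 = (2.0 * params.alpha - 1.0) ** 2
    else:
        # effective overlap read off the selection differential at x = 1/3,
        # where s(x) = s + (2/3)(2a-1)^2 in the symmetric model
        beta2 = min(1.0, max(0.0, 1.5 * (effective_selection(1.0 / 3.0, params) - params.s)))
    N = params.N
    if N * (2.0 / 3.0) * beta2 < weak_threshold:
        return "weak"
    if beta2 > 0:
        inv = 1.0 / beta2
        ratio = (inv - 1.0 + 2.0 / N) / (inv + 1.0 - 2.0 / N)
        if ratio < strong_threshold:
            return "strong"
    return "intermediate"
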