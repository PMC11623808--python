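"""Closed-form approximations for fixation on graphs.

Weak ecological selection (generalists): the frequency dependence collapses
into a constant effective coefficient ``s_e = s + (2/3)(2a-1)^2`` and a
graph of amplification factor ``a_Bd`` fixes a new mutant with probability
``1/N + (1/2) a_Bd s_e``.

Strong ecological selection (specialists): fixation factorises into
establishment (drift to the interior equilibrium; governed purely by the
invasion fitness ``r_inv``, independent of s) and conditional fixation
(escape from the equilibrium to N; governed purely by ``a_Bd s``,
independent of the niche overlap).  The star reshapes establishment as
``r -> r^2``.  For arbitrary amplifiers, fixation is approximately linear
in ``a_Bd`` between the exact well-mixed and star endpoints.

Each operation returns an :class:`ApproxReport` carrying the clipped value,
the raw formula value and the validity-condition diagnostics, so callers
can warn rather than refuse outside the stated regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ecology import EcoEvoParams, classify_regime, effective_selection

__all__ = [
    "ApproxReport",
    "pfix_weak",
    "invasion_fitness",
    "pest_strong",
    "pcfix_strong",
    "pfix_strong_linear",
]


@dataclass(frozen=True)
class ApproxReport:
    value: float
    raw_value: float
    regime: Literal["weak", "strong", "intermediate"]
    validity: float
    formula_id: str


def _report(raw: float, params: EcoEvoParams, validity: float, formula_id: str):
    return ApproxReport(
        value=float(np.clip(raw, 0.0, 1.0)),
        raw_value=float(raw),
        regime=classify_regime(params),
        validity=float(validity),
        formula_id=formula_id,
    )


def pfix_weak(params: EcoEvoParams, a_bd: float = 1.0) -> ApproxReport:
    """Weak-regime fixation ``1/N + (1/2) a_Bd (s + (2/3)(2a-1)^2)``.

    ``a_bd = 1`` is the well-mixed special case.  Valid while the combined
    effective selection is nearly neutral (``|N s_e| << 1``); the report's
    ``validity`` carries ``|N s_e|``.
    """
    if a_bd <= 0:
        raise ValueError("amplification factor must be positive")
    s_e = effective_selection(1.0 / 3.0, params)
    raw = 1.0 / params.N + 0.5 * a_bd * s_e
    return _report(raw, params, abs(params.N * s_e), "eq_weak_graph" if a_bd != 1 else "eq_weak_wm")


def invasion_fitness(params: EcoEvoParams) -> float:
    """Relative ecological fitness of a lone mutant, ``r_inv = r_mut(1/N)``.

    Controls establishment in the strong regime: a lone specialist feeds on
    an untouched resource, so ``r_inv > 1`` whenever niches separate
    (``alpha > 0.5``) and grows without bound as overlap vanishes.
    Exactly 1 at ``alpha = 0.5``.
    """
    if params.symmetric and params.alpha == 0.5:
        return 1.0
    from .ecology import equilibrium_concentrations, ecological_fitness

    env = params.environment
    c = equilibrium_concentrations((1.0, params.N - 1.0), params.wt, params.mut, env)
    return ecological_fitness(params.mut, c, env) / ecological_fitness(
        params.wt, c, env
    )


def pest_strong(
    params: EcoEvoParams, structure: Literal["wellmixed", "star"] = "wellmixed"
) -> ApproxReport:
    """Strong-regime establishment probability.

    Well-mixed: ``1 - r_inv^-1`` (equivalently
    ``1 - [(2a-1)^-2 - 1 + 2/N] / [(2a-1)^-2 + 1 - 2/N]``); star amplifiers
    reshape effective fitness ``r -> r^2`` giving ``1 - r_inv^-2``.
    Independent of s; saturates at 1 as the niches fully separate.
    """
    r_inv = invasion_fitness(params)
    if structure == "wellmixed":
        raw = 1.0 - 1.0 / r_inv
        fid = "eq_est_wm"
    elif structure == "star":
        raw = 1.0 - 1.0 / r_inv**2
        fid = "eq_est_star"
    else:
        raise ValueError("structure must be 'wellmixed' or 'star'")
    validity = (1.0 - raw) / (1.0 + raw) if raw < 1 else 0.0
    return _report(raw, params, validity, fid)


def pcfix_strong(params: EcoEvoParams, a_bd: float = 1.0) -> ApproxReport:
    """Strong-regime conditional fixation ``(1-(1+a s)^-N)/(1-(1+a s)^-2N)``.

    From the interior equilibrium (at frequency ~1/2 for small s) the niche
    term cancels and only the graph-rescaled intrinsic coefficient
    ``a_Bd s`` matters; ``s = 0`` gives the limit 1/2.  ``a_bd = 2`` is the
    star closed form.
    """
    N = params.N
    s_eff = a_bd * params.s
    if s_eff <= -1.0:
        raise ValueError("a_bd * s must exceed -1")
    if s_eff == 0.0:
        raw = 0.5
    else:
        logr = np.log1p(s_eff)
        raw = np.expm1(-N * logr) / np.expm1(-2.0 * N * logr)
    validity = _strong_validity(params)
    return _report(raw, params, validity, "eq_cfix_graph" if a_bd != 1 else "eq_cfix_wm")


def _strong_validity(params: EcoEvoParams) -> float:
    if not params.symmetric:
        return float("nan")
    beta2 = (2.0 * params.alpha - 1.0) ** 2
    if beta2 == 0:
        return float("inf")
    inv = 1.0 / beta2
    return (inv - 1.0 + 2.0 / params.N) / (inv + 1.0 - 2.0 / params.N)


def pfix_strong_linear(
    params: EcoEvoParams, a_bd: float, *, star_a_bd: float = 2.0
) -> ApproxReport:
    """Linear interpolation of fixation in the amplification factor.

    Uses the two exactly solvable endpoints — the well-mixed population
    (a_Bd = 1) and the star (a_Bd ~ 2) — and linearly interpolates:
    ``P_fix(a) = (P_fix^S - P_fix^WM) (a - 1) / (a_S - 1) + P_fix^WM``.
    """
    from .exact import star_fixation, wellmixed_fixation

    p_wm = wellmixed_fixation(params)
    p_star = star_fixation(params)
    raw = (p_star - p_wm) * (a_bd - 1.0) / (star_a_bd - 1.0) + p_wm
    return _report(raw, params, _strong_validity(params), "eq_fix_linear")
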