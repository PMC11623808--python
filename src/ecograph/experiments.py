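"""Experiment drivers: parameter sweeps over graphs, serialized to tables.

An :class:`ExperimentSpec` couples a list of graphs with a cartesian
parameter grid over (N, s, alpha, D) and a simulation configuration; the
driver produces one result row per (graph, parameter) cell, carrying the
Monte-Carlo estimates, exact/approximate reference values where available
and the regime label.  Failures in a cell are recorded as error rows and
the sweep continues.

Two named presets reproduce the headline analyses at configurable scale:

* ``fig_weak_families`` — fixation probability across network families as a
  function of the amplification factor (weakly deleterious mutant, weak
  ecological selection).
* ``fig_crossing_star`` — the exact star vs well-mixed crossing curve
  N s*(alpha): the role-reversal boundary for deleterious mutants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .ecology import EcoEvoParams, classify_regime
from .engine import SimulationConfig, estimate_fixation
from .exact import intersection_point, star_fixation, wellmixed_fixation
from .graphs import GraphFamilySpec, PopulationGraph, estimate_amplification, generate

logger = logging.getLogger("ecograph")

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "crossing_sweep",
    "weak_families_preset",
]

RESULT_COLUMNS = [
    "graph",
    "family",
    "N",
    "s",
    "alpha",
    "D",
    "resource_mode",
    "replicates",
    "p_fix",
    "se_fix",
    "p_est",
    "p_cfix",
    "t_unconditional",
    "t_conditional_fix",
    "truncated",
    "a_bd",
    "p_fix_weak_approx",
    "regime",
    "error",
]


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    graph_specs: list
    s_values: tuple = (0.0,)
    alpha_values: tuple = (0.5,)
    D_values: tuple = (None,)  # None = well-mixed resources
    replicates: int = 10_000
    seed: int = 0
    estimate_a_bd: bool = False
    a_bd_replicates: int = 100_000

    def __post_init__(self):
        if not self.graph_specs:
            raise ValueError("experiment needs at least one graph")
        if not (self.s_values and self.alpha_values and self.D_values):
            raise ValueError("parameter grid must be non-empty")


def _materialise(spec) -> tuple[str, str, PopulationGraph]:
    if isinstance(spec, PopulationGraph):
        return repr(spec), "custom", spec
    if isinstance(spec, GraphFamilySpec):
        return f"{spec.family}{spec.parameters}", spec.family, generate(spec)
    raise TypeError("graph_specs entries must be PopulationGraph or GraphFamilySpec")


def run_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Run the full sweep; returns one row per (graph, s, alpha, D) cell."""
    from .approx import pfix_weak

    rows = []
    rng = np.random.SeedSequence(spec.seed)
    for gspec in spec.graph_specs:
        name, family, graph = _materialise(gspec)
        N = graph.n_nodes
        a_bd = None
        if spec.estimate_a_bd:
            a_est = estimate_amplification(
                graph,
                replicates=spec.a_bd_replicates,
                seed=int(rng.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF),
            )
            a_bd = a_est.a_bd
        for s, alpha, D in product(spec.s_values, spec.alpha_values, spec.D_values):
            cell_seed = int(rng.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
            row = dict.fromkeys(RESULT_COLUMNS)
            row.update(
                graph=name, family=family, N=N, s=s, alpha=alpha,
                D=D, resource_mode="well_mixed" if D is None else "diffusible",
                replicates=spec.replicates, a_bd=a_bd,
            )
            try:
                params = EcoEvoParams(N=N, s=s, alpha=alpha)
                config = SimulationConfig(
                    replicates=spec.replicates,
                    seed=cell_seed,
                    resource_mode="well_mixed" if D is None else "diffusible",
                    D=D if D is not None else 1.0,
                    track_establishment=alpha > 0.5,
                )
                est = estimate_fixation(graph, params, config)
                row.update(
                    p_fix=est.p_fix,
                    se_fix=est.se_fix,
                    p_est=est.p_est,
                    p_cfix=est.p_cfix,
                    t_unconditional=est.t_unconditional,
                    t_conditional_fix=est.t_conditional_fix,
                    truncated=est.truncated,
                    p_fix_weak_approx=pfix_weak(params, a_bd or 1.0).value,
                    regime=classify_regime(params),
                )
            except Exception as e:  # noqa: BLE001 - error rows by design
                logger.warning("cell failed (%s, s=%s, alpha=%s): %s", name, s, alpha, e)
                row["error"] = str(e)
            rows.append(row)
            logger.info(
                "cell done: %s s=%s alpha=%s p_fix=%s", name, s, alpha, row["p_fix"]
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def crossing_sweep(
    N: int = 50,
    alphas=None,
    *,
    s_lo: float = -0.12,
    structure: str = "star",
) -> pd.DataFrame:
    """Exact star/well-mixed crossing point s*(alpha) over an alpha grid.

    Returns columns (alpha, s_star, N_s_star); s_star is NaN where no
    crossing exists in [s_lo, 0].
    """
    if alphas is None:
        alphas = np.arange(0.51, 1.0, 0.01)
    if structure != "star":
        raise ValueError("exact crossing sweeps support the star structure")
    rows = []
    for alpha in alphas:
        star = lambda s: star_fixation(EcoEvoParams(N=N, s=s, alpha=float(alpha)))  # noqa: B023,E731
        wm = lambda s: wellmixed_fixation(EcoEvoParams(N=N, s=s, alpha=float(alpha)))  # noqa: B023,E731
        s_star = intersection_point(star, wm, s_lo=s_lo)
        rows.append(
            {
                "alpha": float(alpha),
                "s_star": np.nan if s_star is None else s_star,
                "N_s_star": np.nan if s_star is None else N * s_star,
            }
        )
        logger.info("crossing alpha=%.4f -> %s", alpha, rows[-1]["N_s_star"])
    return pd.DataFrame(rows)


def weak_families_preset(
    *, N: int = 100, s: float = -0.001, alpha: float = 0.53, replicates: int = 100_000,
    seed: int = 0,
) -> ExperimentSpec:
    """Graph families spanning amplifiers and suppressors, weak-regime sweep."""
    specs = [
        GraphFamilySpec("complete", {"n": N}),
        GraphFamilySpec("k_regular", {"n": N, "k": 8}, seed=seed),
        GraphFamilySpec("star", {"n": N}),
        GraphFamilySpec("pa_star", {"n": N, "i": 5}),
        GraphFamilySpec("detour", {"n1": int(0.9 * N), "n2": N - int(0.9 * N)}, seed=seed),
        GraphFamilySpec("bipartite", {"n1": N // 4, "n2": N - N // 4}),
    ]
    return ExperimentSpec(
        name="weak_families",
        graph_specs=specs,
        s_values=(s,),
        alpha_values=(alpha,),
        replicates=replicates,
        seed=seed,
        estimate_a_bd=True,
    )
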