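"""Stochastic Moran Birth-death simulator on graphs.

Two resource modes:

* ``well_mixed`` — every individual sees the same steady-state resource
  pool, so fitness depends only on the total mutant count and trajectories
  run in a compiled kernel (:mod:`ecograph._kernels`).
* ``diffusible`` — each node has its own resource concentrations; resources
  are produced locally, consumed by the occupant and diffuse along edges
  with constant D.  The steady state solves ``(D L + diag(a_i)) c_i* = S_i``
  per resource (L the graph Laplacian), re-solved after every replacement
  that changes the consumption pattern.  As D grows the per-node
  concentrations flatten onto the well-mixed values.

Establishment is the first passage of the mutant count from 1 to
``ceil(N x*)`` (the interior-equilibrium count); replicate RNG streams are
spawned from the master seed so estimates are reproducible regardless of
batching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ecology import (
    EcoEvoParams,
    NoEquilibriumError,
    equilibrium_frequency,
    fitness_table,
)

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "FixationEstimate",
    "NodeResourceField",
    "moran_run",
    "estimate_fixation",
    "diffusible_steady_state",
    "diffusible_fitness",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Replicates, seeding, resource mode and safety caps."""

    replicates: int = 10_000
    seed: int = 0
    resource_mode: Literal["well_mixed", "diffusible"] = "well_mixed"
    D: float = 1.0
    max_steps: int | None = None  # default 10 N^3, set at run time
    track_establishment: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.resource_mode == "diffusible" and self.D <= 0:
            raise ValueError("diffusion constant D must be positive")


@dataclass(frozen=True)
class TrajectoryRecord:
    outcome: Literal["fixation", "loss", "truncated"]
    steps: int
    established: bool | None = None
    establishment_step: int | None = None


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    if x.size == 1:
        return float(x[0]), float("nan")
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size))


@dataclass(frozen=True)
class FixationEstimate:
    """Monte-Carlo estimates with binomial / sample standard errors."""

    p_fix: float
    se_fix: float
    replicates_used: int
    truncated: int = 0
    p_est: float | None = None
    se_est: float | None = None
    p_cfix: float | None = None
    se_cfix: float | None = None
    t_unconditional: float | None = None
    se_t_unconditional: float | None = None
    t_conditional_fix: float | None = None
    se_t_conditional_fix: float | None = None
    establishment_count: int | None = None


def _csr(graph) -> tuple[np.ndarray, np.ndarray]:
    g = getattr(graph, "nx_graph", graph)
    import networkx as nx

    N = g.number_of_nodes()
    indptr = np.zeros(N + 1, dtype=np.int64)
    nbrs = [sorted(g.neighbors(v)) for v in range(N)]
    for v in range(N):
        indptr[v + 1] = indptr[v] + len(nbrs[v])
    indices = np.fromiter(
        (w for v in range(N) for w in nbrs[v]), dtype=np.int64, count=indptr[-1]
    )
    return indptr, indices


def _establishment_threshold(params: EcoEvoParams) -> int:
    x_star = equilibrium_frequency(params)
    if x_star is None:
        raise NoEquilibriumError(
            "interior equilibrium outside (1/N, 1-1/N): establishment undefined"
        )
    return math.ceil(params.N * x_star)


def _replicate_seeds(master: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def moran_run(
    graph, params: EcoEvoParams, config: SimulationConfig, seed: int
) -> TrajectoryRecord:
    """A single Bd trajectory from one uniformly placed mutant to absorption."""
    cfg = SimulationConfig(
        replicates=1,
        seed=seed,
        resource_mode=config.resource_mode,
        D=config.D,
        max_steps=config.max_steps,
        track_establishment=config.track_establishment,
    )
    est = estimate_fixation(graph, params, cfg, _collect=True)
    outcome, steps, established, est_step = est
    out = {1: "fixation", 0: "loss", -1: "truncated"}[int(outcome[0])]
    if config.track_establishment:
        return TrajectoryRecord(
            out,
            int(steps[0]),
            bool(established[0]),
            int(est_step[0]) if est_step[0] >= 0 else None,
        )
    return TrajectoryRecord(out, int(steps[0]))


def estimate_fixation(
    graph, params: EcoEvoParams, config: SimulationConfig, *, _collect: bool = False
):
    """Monte-Carlo fixation/establishment estimates over independent replicates.

    ``p_est`` is the fraction of runs whose mutant count reaches the
    establishment threshold; ``p_cfix`` the fraction fixing among those, so
    ``p_est * p_cfix`` equals ``p_fix`` exactly on the realised sample.
    Truncated runs (safety cap hit) are excluded from the estimates and
    counted separately.
    """
    N = params.N
    indptr, indices = _csr(graph)
    if indptr.size - 1 != N:
        raise ValueError("graph size must match params.N")
    max_steps = config.max_steps if config.max_steps is not None else 10 * N**3
    est_threshold = 0
    if config.track_establishment:
        est_threshold = _establishment_threshold(params)
    seeds = _replicate_seeds(config.seed, config.replicates)

    if config.resource_mode == "well_mixed":
        from ._kernels import bd_replicates

        fitness = fitness_table(params)
        outcomes, steps, established, est_steps = bd_replicates(
            indptr, indices, fitness, seeds, max_steps, est_threshold
        )
    else:
        outcomes, steps, established, est_steps = _diffusible_replicates(
            indptr, indices, params, config.D, seeds, max_steps, est_threshold
        )
    if _collect:
        return outcomes, steps, established, est_steps

    ok = outcomes >= 0
    used = int(ok.sum())
    fixed = outcomes[ok] == 1
    p_fix = float(fixed.mean()) if used else float("nan")
    se_fix = math.sqrt(max(p_fix * (1 - p_fix), 0.0) / used) if used else float("nan")
    t_unc, se_t_unc = _mean_se(steps[ok].astype(float))
    t_fix, se_t_fix = _mean_se(steps[ok][fixed].astype(float))
    kwargs = {}
    if config.track_establishment:
        est = established[ok] == 1
        p_est = float(est.mean()) if used else float("nan")
        n_est = int(est.sum())
        p_cfix = float(fixed[est].mean()) if n_est else float("nan")
        kwargs = dict(
            p_est=p_est,
            se_est=math.sqrt(max(p_est * (1 - p_est), 0.0) / used) if used else None,
            p_cfix=p_cfix,
            se_cfix=(
                math.sqrt(max(p_cfix * (1 - p_cfix), 0.0) / n_est) if n_est else None
            ),
            establishment_count=est_threshold,
        )
    return FixationEstimate(
        p_fix=p_fix,
        se_fix=se_fix,
        replicates_used=used,
        truncated=int((~ok).sum()),
        t_unconditional=t_unc,
        se_t_unconditional=se_t_unc,
        t_conditional_fix=t_fix,
        se_t_conditional_fix=se_t_fix,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# diffusible resources


@dataclass(frozen=True)
class NodeResourceField:
    """Per-node steady-state concentrations, shape (n_resources, N)."""

    concentrations: np.ndarray
    residual: float = 0.0


def _diffusible_matrices(indptr, indices, params: EcoEvoParams, D: float):
    """Dense ``D L`` plus per-type consumption diagonals."""
    N = indptr.size - 1
    L = np.zeros((N, N))
    for v in range(N):
        nb = indices[indptr[v] : indptr[v + 1]]
        L[v, v] = len(nb)
        L[v, nb] = -1.0
    a_wt = np.asarray(params.wt.alphas, dtype=float)
    a_mut = np.asarray(params.mut.alphas, dtype=float)
    supply = np.asarray(params.environment.supply, dtype=float)
    return D * L, a_wt, a_mut, supply


def diffusible_steady_state(
    graph, occupancy: np.ndarray, params: EcoEvoParams, D: float
) -> NodeResourceField:
    """Solve ``(D L + diag(a_i)) c_i* = S_i`` for every resource.

    ``occupancy`` holds 1 for mutant-occupied nodes.  The solve is dense
    (the simulator's graphs are modest) and the reported residual is the
    max-norm of ``(D L + diag(a_i)) c_i* - S_i``.
    """
    if not params.environment.is_linear:
        raise NotImplementedError("diffusible mode requires the linear consumption law")
    indptr, indices = _csr(graph)
    N = indptr.size - 1
    occupancy = np.asarray(occupancy)
    if occupancy.size != N:
        raise ValueError("occupancy length must equal the number of nodes")
    DL, a_wt, a_mut, supply = _diffusible_matrices(indptr, indices, params, D)
    n_res = supply.size
    conc = np.empty((n_res, N))
    resid = 0.0
    for i in range(n_res):
        alpha_vec = np.where(occupancy == 1, a_mut[i], a_wt[i])
        if np.all(alpha_vec == 0):
            raise ValueError(
                f"no consumption of resource {i}: steady state singular"
            )
        M = DL + np.diag(alpha_vec)
        rhs = np.full(N, supply[i])
        c = np.linalg.solve(M, rhs)
        resid = max(resid, float(np.abs(M @ c - rhs).max()))
        conc[i] = c
    if np.any(conc <= 0):
        raise ValueError("non-positive steady-state concentration")
    field = NodeResourceField(conc, resid)
    if resid > 1e-9:
        raise ArithmeticError(f"steady-state residual {resid:.2e} exceeds 1e-9")
    return field


def diffusible_fitness(
    field: NodeResourceField, occupancy: np.ndarray, params: EcoEvoParams
) -> np.ndarray:
    """Per-node overall fitness ``f_j = s_j sum_i v_i a_ij c_ij*``."""
    occupancy = np.asarray(occupancy)
    a_wt = np.asarray(params.wt.alphas, dtype=float)
    a_mut = np.asarray(params.mut.alphas, dtype=float)
    values = np.asarray(params.environment.values, dtype=float)
    s_node = np.where(
        occupancy == 1, params.mut.intrinsic_fitness, params.wt.intrinsic_fitness
    )
    alpha = np.where(occupancy[None, :] == 1, a_mut[:, None], a_wt[:, None])
    r = (values[:, None] * alpha * field.concentrations).sum(axis=0)
    f = s_node * r
    if np.any(f <= 0):
        raise ValueError("non-positive fitness")
    return f


def _diffusible_replicates(
    indptr, indices, params, D, seeds, max_steps, est_threshold, refresh_every=64
):
    """Dispatch the diffusible-mode trajectories to the compiled kernel.

    The kernel keeps, per resource, the inverse of ``D L + diag(alpha_i)``
    and applies a Sherman-Morrison rank-1 update at every replacement (the
    consumption diagonal changes at exactly one node), re-factorising every
    ``refresh_every`` updates so roundoff cannot accumulate; the update is
    consistent with a from-scratch solve to well below the 1e-9 residual
    tolerance of :func:`diffusible_steady_state`.
    """
    if not params.environment.is_linear:
        raise NotImplementedError("diffusible mode requires the linear consumption law")
    from ._kernels import bd_replicates_diffusible

    return bd_replicates_diffusible(
        indptr,
        indices,
        np.asarray(params.wt.alphas, dtype=float),
        np.asarray(params.mut.alphas, dtype=float),
        np.asarray(params.environment.values, dtype=float),
        np.asarray(params.environment.supply, dtype=float),
        float(params.wt.intrinsic_fitness),
        float(params.mut.intrinsic_fitness),
        float(D),
        seeds,
        max_steps,
        est_threshold,
        refresh_every,
    )
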