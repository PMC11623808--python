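"""Exact absorbing-Markov-chain solvers for the Birth-death process.

All chains here are *skip free* in the total mutant count: a Bd replacement
event changes the count by at most one, and the configuration only changes
when the count does.  Absorption probabilities are therefore computed by a
level-by-level first-passage recursion

    R_n = (I - B_n R_{n-1})^{-1} A_n,

where ``A_n``/``B_n`` are the up/down blocks of the embedded jump chain at
count level n and ``R_n[i, j]`` is the probability, starting from level-n
state i, of first hitting level n+1 in state j before the mutant is lost.
Every intermediate quantity is a probability, and fixation, establishment
and conditional-fixation probabilities are all read off the ``R_n``:

    P_fix   = start_distribution . (R_1 R_2 ... R_{N-1}) e_fix
    P_est   = row sums of H = R_1 ... R_{m-1}  (first passage to m mutants)
    P_cfix  = H-weighted average of P_fix from the level-m states,

with ``m = ceil(N x*)`` the establishment count, so ``P_fix = P_est P_cfix``
holds by construction (strong Markov property at the first passage of m).

Near-singularity of ``I - B_n R_{n-1}`` above the interior equilibrium is
*inherent*: its spectral gap equals the probability of crossing the lower
potential barrier, which underflows fixed precision for strong niche
separation.  The structured solvers therefore run in adaptive multiprecision
(mpmath), with working digits scaled to the total log-fitness barrier; the
well-mixed chain, which admits the classical product formula, is evaluated
in log space with ``logsumexp`` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from mpmath import mp, mpf, matrix, lu_solve
from scipy.optimize import brentq
from scipy.special import logsumexp

from .ecology import (
    EcoEvoParams,
    NoEquilibriumError,
    equilibrium_frequency,
    fitness_table,
)

__all__ = [
    "DecompositionResult",
    "wellmixed_fixation",
    "wellmixed_decomposition",
    "star_fixation",
    "pastar_fixation",
    "brute_force_fixation",
    "intersection_point",
    "constant_selection_fixation",
]


@dataclass(frozen=True)
class DecompositionResult:
    """Fixation split into establishment and conditional fixation."""

    p_est: float
    p_cfix: float
    p_fix: float
    establishment_count: int | None = None


def constant_selection_fixation(N: int, s: float, start: int = 1) -> float:
    """Classical Moran Bd closed form ``(1-(1+s)^-start)/(1-(1+s)^-N)``."""
    if s == 0:
        return start / N
    r = 1.0 + s
    return float(np.expm1(-start * np.log(r)) / np.expm1(-N * np.log(r)))


# ---------------------------------------------------------------------------
# well-mixed chain (1-D birth-death; log-space product formula)


def _log_pi(params: EcoEvoParams) -> np.ndarray:
    """log pi_k for k = 0..N-1 with pi_k = prod_{j<=k} T-_j/T+_j = prod 1/f(j)."""
    f = fitness_table(params)[1:-1]
    return np.concatenate([[0.0], np.cumsum(-np.log(f))])


def wellmixed_fixation(params: EcoEvoParams, start: int = 1) -> float:
    """Exact fixation probability on the complete graph from ``start`` mutants.

    The Bd step ratio on the complete graph is ``T-_n / T+_n = 1/f_mut(n)``,
    giving the standard product formula; evaluated with logsumexp so that
    strong frequency dependence (barrier products spanning hundreds of
    orders of magnitude) loses no precision.
    """
    N = params.N
    if not 0 <= start <= N:
        raise ValueError("start must lie in [0, N]")
    if start == 0:
        return 0.0
    if start == N:
        return 1.0
    logpi = _log_pi(params)
    return float(np.exp(logsumexp(logpi[:start]) - logsumexp(logpi)))


def _wm_hit_before_zero(logpi: np.ndarray, start: int, target: int) -> float:
    """P(hit ``target`` before 0 | start) in the 1-D chain."""
    return float(np.exp(logsumexp(logpi[:start]) - logsumexp(logpi[:target])))


def wellmixed_decomposition(
    params: EcoEvoParams, start: int = 1
) -> DecompositionResult:
    """Establishment / conditional-fixation split for the well-mixed chain.

    Establishment is the first passage from ``start`` to ``m = ceil(N x*)``
    mutants; conditional fixation runs from m.  ``p_fix = p_est p_cfix``
    exactly (the 1-D chain must pass through m on its way to N).
    """
    x_star = equilibrium_frequency(params)
    if x_star is None:
        raise NoEquilibriumError("interior equilibrium outside (1/N, 1-1/N)")
    N = params.N
    m = math.ceil(N * x_star)
    logpi = _log_pi(params)
    if m <= start:
        p_est = 1.0
        p_cfix = wellmixed_fixation(params, start)
    else:
        p_est = _wm_hit_before_zero(logpi, start, m)
        p_cfix = wellmixed_fixation(params, m)
    return DecompositionResult(p_est, p_cfix, p_est * p_cfix, m)


# ---------------------------------------------------------------------------
# multiprecision level recursion


def _required_dps(params: EcoEvoParams) -> int:
    """Working digits: a pad plus the total log10 fitness barrier."""
    with np.errstate(all="ignore"):
        barrier = float(np.abs(np.log10(fitness_table(params)[1:-1])).sum())
    return int(30 + barrier)


def _mp_fitness_table(params: EcoEvoParams):
    """fitness_table recomputed in mpmath (linear consumption law)."""
    env = params.environment
    if not env.is_linear:
        # fall back on double-precision values promoted to mpf
        return [mpf(float(v)) for v in fitness_table(params)]
    N = params.N
    a_wt = [mpf(float(a)) for a in params.wt.alphas]
    a_mut = [mpf(float(a)) for a in params.mut.alphas]
    supply = [mpf(float(s)) for s in env.supply]
    values = [mpf(float(v)) for v in env.values]
    s_wt = mpf(float(params.wt.intrinsic_fitness))
    s_mut = mpf(float(params.mut.intrinsic_fitness))
    out = [mpf(1)] * (N + 1)
    for n in range(1, N):
        c = [S / ((N - n) * aw + n * am) for S, aw, am in zip(supply, a_wt, a_mut)]
        r_mut = sum(v * am * ci for v, am, ci in zip(values, a_mut, c))
        r_wt = sum(v * aw * ci for v, aw, ci in zip(values, a_wt, c))
        out[n] = (s_mut * r_mut) / (s_wt * r_wt)
    return out


def _solve_levels(A, B, sizes):
    """Run the R recursion; returns the list of first-passage matrices R_n.

    ``A[n]`` (sizes[n] x sizes[n+1]) and ``B[n]`` (sizes[n] x sizes[n-1]) are
    the jump-chain up/down blocks for levels n = 1..N-1; level 0 is the loss
    state and level N fixation.
    """
    R = [None] * len(A)
    Rprev = None
    for n in range(1, len(A)):
        An, Bn = A[n], B[n]
        d = sizes[n]
        if Rprev is None:
            BR = matrix(d, d)
        else:
            BR = Bn * Rprev
        M = matrix(d, d)
        for i in range(d):
            for j in range(d):
                M[i, j] = (1 if i == j else 0) - BR[i, j]
        if d == 1:
            X = matrix(1, An.cols)
            for j in range(An.cols):
                X[0, j] = An[0, j] / M[0, 0]
        else:
            X = matrix(d, An.cols)
            for j in range(An.cols):
                col = lu_solve(M, matrix([An[i, j] for i in range(d)]))
                for i in range(d):
                    X[i, j] = col[i]
        R[n] = X
        Rprev = X
    return R


def _pastar_levels(N: int, i: int, f_table):
    """Jump-chain blocks for the preferential-attachment star.

    Level n holds states (c, l): c mutants among the i fully connected core
    nodes, l = n - c among the N - i leaves (each leaf sees all cores).
    """
    n_leaves = N - i

    def states(n):
        c_lo = max(0, n - n_leaves)
        c_hi = min(i, n)
        return list(range(c_lo, c_hi + 1))

    sizes = [len(states(n)) for n in range(N + 1)]
    A = [None] * N
    B = [None] * N
    for n in range(1, N):
        st = states(n)
        up_st = {c: k for k, c in enumerate(states(n + 1))}
        dn_st = {c: k for k, c in enumerate(states(n - 1))}
        f = f_table[n]
        W = n * f + (N - n)
        An = matrix(len(st), len(up_st))
        Bn = matrix(len(st), len(dn_st))
        for k, c in enumerate(st):
            l = n - c
            moves_up = {}
            moves_dn = {}
            # core mutant reproduces (weight c f), offspring to one of N-1 others
            if c > 0:
                if c < i:
                    moves_up[c + 1] = moves_up.get(c + 1, mpf(0)) + c * f * mpf(i - c) / (N - 1)
                if l < n_leaves:
                    moves_up[c] = moves_up.get(c, mpf(0)) + c * f * mpf(n_leaves - l) / (N - 1)
            # core wild type reproduces (weight i - c)
            if c < i:
                if c > 0:
                    moves_dn[c - 1] = moves_dn.get(c - 1, mpf(0)) + (i - c) * mpf(c) / (N - 1)
                if l > 0:
                    moves_dn[c] = moves_dn.get(c, mpf(0)) + (i - c) * mpf(l) / (N - 1)
            # leaf mutant reproduces (weight l f), offspring to one of i cores
            if l > 0 and c < i:
                moves_up[c + 1] = moves_up.get(c + 1, mpf(0)) + l * f * mpf(i - c) / i
            # leaf wild type reproduces (weight n_leaves - l)
            if l < n_leaves and c > 0:
                moves_dn[c - 1] = moves_dn.get(c - 1, mpf(0)) + (n_leaves - l) * mpf(c) / i
            # embedded jump chain: self-loops carry no information for
            # absorption probabilities, so normalise over real moves only
            tot = sum(moves_up.values()) + sum(moves_dn.values())
            for cc, w in moves_up.items():
                An[k, up_st[cc]] = w / tot
            for cc, w in moves_dn.items():
                Bn[k, dn_st[cc]] = w / tot
        A[n], B[n] = An, Bn
    return A, B, sizes, states


def _pastar_solve(N: int, i: int, params: EcoEvoParams):
    """R matrices plus bookkeeping, in a working precision context."""
    f_table = _mp_fitness_table(params)
    A, B, sizes, states = _pastar_levels(N, i, f_table)
    R = _solve_levels(A, B, sizes)
    return R, sizes, states


def _uniform_start_weights(N: int, i: int, states1) -> list:
    """Single mutant on a uniform node: core w.p. i/N, leaf w.p. (N-i)/N."""
    w = []
    for c in states1:  # level-1 states: c in {0, 1} (l = 1 - c)
        if c == 1:
            w.append(mpf(i) / N)
        else:
            w.append(mpf(N - i) / N)
    return w


def pastar_fixation(
    N: int, i: int, params: EcoEvoParams, *, decompose: bool = True
) -> DecompositionResult:
    """Exact fixation (and establishment split) on the PA star.

    The (i+1)(N-i+1)-state symmetry reduction makes the exact computation
    tractable; ``i = 1`` is the star and ``i = N - 1`` the complete graph.
    When ``decompose`` is false, or no interior equilibrium exists, only
    ``p_fix`` is reported (``p_est``/``p_cfix`` are nan).
    """
    if params.N != N:
        raise ValueError("params.N must match N")
    if not 1 <= i <= N - 1:
        raise ValueError("core size i must lie in [1, N-1]")
    m = None
    if decompose:
        try:
            x_star = equilibrium_frequency(params)
        except NoEquilibriumError:
            x_star = None
        m = math.ceil(N * x_star) if x_star is not None else None
    with mp.workdps(_required_dps(params)):
        R, sizes, states = _pastar_solve(N, i, params)
        start_w = _uniform_start_weights(N, i, states(1))
        # u_n = R_n u_{n+1}; level N is a single state (full fixation)
        u = matrix([mpf(1)] * sizes[N])
        for n in range(N - 1, 0, -1):
            u = R[n] * u
        p_fix = float(sum(w * u[k] for k, w in enumerate(start_w)))
        if m is None or m <= 1:
            if m is not None and m <= 1:
                return DecompositionResult(1.0, p_fix, p_fix, m)
            return DecompositionResult(float("nan"), float("nan"), p_fix, None)
        # hitting distribution on level m, then fixation from level m
        H = R[1]
        for n in range(2, m):
            H = H * R[n]
        hit = [sum(start_w[k] * H[k, j] for k in range(sizes[1])) for j in range(sizes[m])]
        um = matrix([mpf(1)] * sizes[N])
        for n in range(N - 1, m - 1, -1):
            um = R[n] * um
        p_est = float(sum(hit))
        p_cfix = float(sum(h * um[j] for j, h in enumerate(hit))) / p_est
        return DecompositionResult(p_est, p_cfix, p_est * p_cfix, m)


def star_fixation(params: EcoEvoParams, *, decompose: bool = False):
    """Exact fixation probability on the star (hub + N-1 leaves).

    The chain over (hub occupant, mutant leaf count) has 2N states; a leaf's
    only neighbour is the hub, while the hub reproduces into a uniform leaf.
    Uniform initial placement weights the hub start 1/N.  This is the i = 1
    PA star; kept as its own entry point because it is the canonical
    amplifier and the Fig-style analyses sweep it directly.
    """
    res = pastar_fixation(params.N, 1, params, decompose=decompose)
    return res if decompose else res.p_fix


# ---------------------------------------------------------------------------
# brute force over all 2^N occupancies (oracle for small graphs)


def brute_force_fixation(graph, params: EcoEvoParams, *, max_nodes: int = 14):
    """Absorption solve over all 2^N mutant configurations of a small graph.

    Returns ``(per_start, uniform_average)`` where ``per_start[v]`` is the
    fixation probability of a single mutant placed on node v.  This is the
    ground-truth oracle the structured solvers are validated against; it
    refuses graphs with more than ``max_nodes`` nodes.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    adj = _adjacency_lists(graph)
    N = len(adj)
    if params.N != N:
        raise ValueError("params.N must match the graph size")
    if N > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes (2^N states)")
    f_tab = fitness_table(params)
    n_states = 1 << N
    full = n_states - 1
    rows, cols, vals = [], [], []
    b = np.zeros(n_states)
    for S in range(1, full):
        n = S.bit_count()
        f = f_tab[n]
        W = n * f + (N - n)
        diag = 0.0
        for u in range(N):
            w_u = f if (S >> u) & 1 else 1.0
            deg = len(adj[u])
            for v in adj[u]:
                p = w_u / (W * deg)
                T = (S | (1 << v)) if (S >> u) & 1 else (S & ~(1 << v))
                if T == full:
                    b[S] += p
                elif T == 0:
                    pass
                elif T == S:
                    diag += p
                else:
                    rows.append(S)
                    cols.append(T)
                    vals.append(p)
        if diag:
            rows.append(S)
            cols.append(S)
            vals.append(diag)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    eye = sp.identity(n_states, format="csr")
    u = spla.spsolve(eye - Q, b)
    per_start = np.array([u[1 << v] for v in range(N)])
    return per_start, float(per_start.mean())


def _adjacency_lists(graph):
    """Accept a PopulationGraph or a networkx graph."""
    g = getattr(graph, "nx_graph", graph)
    nodes = sorted(g.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    return [sorted(index[w] for w in g.neighbors(v)) for v in nodes]


# ---------------------------------------------------------------------------
# role-reversal boundary


def intersection_point(
    graph_solver,
    wm_solver,
    *,
    s_lo: float = -0.12,
    n_scan: int = 61,
    xtol: float = 1e-8,
):
    """Crossing point s* < 0 of two exact fixation-probability curves.

    ``graph_solver(s)`` and ``wm_solver(s)`` return the exact fixation
    probabilities of the structured and well-mixed populations at intrinsic
    selection s.  Scans downward from 0 for the first sign change of the
    difference and bisects it; returns 0.0 when the curves only meet at
    s = 0 (no ecological selection), and ``None`` when no crossing exists
    in ``[s_lo, 0]``.
    """
    g = lambda s: graph_solver(s) - wm_solver(s)  # noqa: E731
    grid = np.linspace(0.0, s_lo, n_scan)
    g0 = g(grid[0])
    if abs(g0) < 1e-13:
        # curves meet at s = 0; look for an interior crossing anyway
        g0 = g(grid[1] / 8.0)
        if abs(g0) < 1e-13 or g0 < 0:
            return 0.0
    for k in range(1, n_scan):
        g1 = g(grid[k])
        if g0 > 0 >= g1:
            return float(brentq(g, grid[k - 1], grid[k], xtol=xtol))
        g0 = g1
    return None
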