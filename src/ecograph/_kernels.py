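"""Numba kernels for the Birth-death Moran simulator (well-mixed resources).

With spatially uniform resources the reproduction weights depend only on
the total mutant count n, so the whole eco-evolutionary fitness model
enters through a lookup table ``fitness[n] = f_mut(n)`` (wild type weight
1).  A step samples a reproducer fitness-proportionally over all N nodes,
then replaces a uniformly chosen neighbour of the parent; mutant/wild-type
node sets are kept as swap lists for O(1) type-uniform sampling.

Randomness comes from an inline xorshift64* generator (one 64-bit state
per replicate, seeded through splitmix64 from the caller-provided stream
seeds): star-like topologies need ~N^3 steps per fixing trajectory, so the
per-step cost is kept to a handful of integer ops.
"""

import numpy as np
from numba import njit

OUTCOME_LOSS = 0
OUTCOME_FIX = 1
OUTCOME_TRUNCATED = -1

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    return x, z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _xorshift(state):
    x = state
    x ^= x << _U64(13)
    x &= _U64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(7)
    x ^= x << _U64(17)
    x &= _U64(0xFFFFFFFFFFFFFFFF)
    return x


@njit(cache=True, inline="always")
def _uniform(state):
    state = _xorshift(state)
    return state, ((state * _U64(0x2545F4914F6CDD1D)) >> _U64(11)) * _INV53


@njit(cache=True)
def bd_replicates(
    indptr,
    indices,
    fitness,
    seeds,
    max_steps,
    est_threshold,
):
    """Run one Bd trajectory per seed; returns outcome/step/establishment arrays.

    est_threshold <= 0 disables establishment tracking.
    """
    N = indptr.size - 1
    reps = seeds.size
    outcomes = np.empty(reps, dtype=np.int8)
    steps_arr = np.zeros(reps, dtype=np.int64)
    established = np.zeros(reps, dtype=np.uint8)
    est_steps = np.full(reps, -1, dtype=np.int64)

    occ = np.zeros(N, dtype=np.uint8)
    members = np.empty(N, dtype=np.int64)  # wt block [0, N-n), mut block [N-n, N)
    pos = np.empty(N, dtype=np.int64)

    for r in range(reps):
        # warm up the per-replicate stream
        sm = _U64(seeds[r])
        sm, s0 = _splitmix64(sm)
        sm, s1 = _splitmix64(sm)
        state = s0 ^ (s1 << _U64(1))
        if state == _U64(0):
            state = _U64(0x9E3779B97F4A7C15)

        for v in range(N):
            occ[v] = 0
            members[v] = v
            pos[v] = v
        state, u = _uniform(state)
        start = np.int64(u * N)
        if start >= N:
            start = N - 1
        j = pos[start]
        other = members[N - 1]
        members[N - 1] = start
        members[j] = other
        pos[start] = N - 1
        pos[other] = j
        occ[start] = 1
        n = 1

        steps = np.int64(0)
        est_flag = np.uint8(0)
        est_step = np.int64(-1)
        if est_threshold > 0 and n >= est_threshold:
            est_flag = np.uint8(1)
            est_step = 0
        outcome = np.int8(OUTCOME_TRUNCATED)
        while steps < max_steps:
            steps += 1
            f = fitness[n]
            w_mut = n * f
            p_mut = w_mut / (w_mut + (N - n))
            state, u = _uniform(state)
            if u < p_mut:
                state, u = _uniform(state)
                k = np.int64(u * n)
                if k >= n:
                    k = n - 1
                parent = members[N - n + k]
            else:
                state, u = _uniform(state)
                k = np.int64(u * (N - n))
                if k >= N - n:
                    k = N - n - 1
                parent = members[k]
            lo = indptr[parent]
            deg = indptr[parent + 1] - lo
            state, u = _uniform(state)
            k = np.int64(u * deg)
            if k >= deg:
                k = deg - 1
            child = indices[lo + k]
            t = occ[parent]
            if occ[child] != t:
                if t == 1:
                    # child joins the mutant block: swap to slot N-n-1
                    j = pos[child]
                    tgt = N - n - 1
                    other = members[tgt]
                    members[tgt] = child
                    members[j] = other
                    pos[child] = tgt
                    pos[other] = j
                    occ[child] = 1
                    n += 1
                else:
                    # child joins the wild-type block: swap to slot N-n
                    j = pos[child]
                    tgt = N - n
                    other = members[tgt]
                    members[tgt] = child
                    members[j] = other
                    pos[child] = tgt
                    pos[other] = j
                    occ[child] = 0
                    n -= 1
                if est_threshold > 0 and est_flag == 0 and n >= est_threshold:
                    est_flag = np.uint8(1)
                    est_step = steps
                if n == 0:
                    outcome = np.int8(OUTCOME_LOSS)
                    break
                if n == N:
                    outcome = np.int8(OUTCOME_FIX)
                    break
        outcomes[r] = outcome
        steps_arr[r] = steps
        established[r] = est_flag
        est_steps[r] = est_step
    return outcomes, steps_arr, established, est_steps


@njit(cache=True)
def bd_replicates_diffusible(
    indptr,
    indices,
    a_wt,
    a_mut,
    values,
    supply,
    s_wt,
    s_mut,
    D,
    seeds,
    max_steps,
    est_threshold,
    refresh_every,
):
    """Bd trajectories with per-node diffusible resources.

    Maintains, per resource i, the inverse of M_i = D L + diag(alpha_i) and
    the steady state c_i = M_i^-1 S_i.  A replacement changes the
    consumption diagonal at one node, so the inverse follows by a
    Sherman-Morrison rank-1 update; it is re-factorised from scratch every
    ``refresh_every`` updates to keep roundoff from accumulating.
    """
    N = indptr.size - 1
    n_res = supply.size
    reps = seeds.size
    outcomes = np.empty(reps, dtype=np.int8)
    steps_arr = np.zeros(reps, dtype=np.int64)
    established = np.zeros(reps, dtype=np.uint8)
    est_steps = np.full(reps, -1, dtype=np.int64)

    # dense D*L is shared across replicates
    DL = np.zeros((N, N))
    for v in range(N):
        lo, hi = indptr[v], indptr[v + 1]
        DL[v, v] = D * (hi - lo)
        for e in range(lo, hi):
            DL[v, indices[e]] = -D

    occ = np.zeros(N, dtype=np.uint8)
    inv = np.empty((n_res, N, N))
    conc = np.empty((n_res, N))
    cum = np.empty(N)
    M = np.empty((N, N))

    for r in range(reps):
        sm = _U64(seeds[r])
        sm, s0 = _splitmix64(sm)
        sm, s1 = _splitmix64(sm)
        state = s0 ^ (s1 << _U64(1))
        if state == _U64(0):
            state = _U64(0x9E3779B97F4A7C15)

        for v in range(N):
            occ[v] = 0
        state, u = _uniform(state)
        start = np.int64(u * N)
        if start >= N:
            start = N - 1
        occ[start] = 1
        n = 1

        for i in range(n_res):
            for v in range(N):
                for w in range(N):
                    M[v, w] = DL[v, w]
                M[v, v] += a_mut[i] if occ[v] == 1 else a_wt[i]
            inv[i] = np.linalg.inv(M)
            for v in range(N):
                acc = 0.0
                for w in range(N):
                    acc += inv[i, v, w]
                conc[i, v] = acc * supply[i]

        # fitness + cumulative weights
        tot = 0.0
        for v in range(N):
            acc = 0.0
            for i in range(n_res):
                a = a_mut[i] if occ[v] == 1 else a_wt[i]
                acc += values[i] * a * conc[i, v]
            f = (s_mut if occ[v] == 1 else s_wt) * acc
            tot += f
            cum[v] = tot

        updates = 0
        steps = np.int64(0)
        est_flag = np.uint8(0)
        est_step = np.int64(-1)
        if est_threshold > 0 and n >= est_threshold:
            est_flag = np.uint8(1)
            est_step = 0
        outcome = np.int8(OUTCOME_TRUNCATED)
        while steps < max_steps:
            steps += 1
            state, u = _uniform(state)
            target = u * cum[N - 1]
            lo_i, hi_i = 0, N - 1
            while lo_i < hi_i:
                mid = (lo_i + hi_i) >> 1
                if cum[mid] <= target:
                    lo_i = mid + 1
                else:
                    hi_i = mid
            parent = lo_i
            elo = indptr[parent]
            deg = indptr[parent + 1] - elo
            state, u = _uniform(state)
            k = np.int64(u * deg)
            if k >= deg:
                k = deg - 1
            child = indices[elo + k]
            t = occ[parent]
            if occ[child] != t:
                occ[child] = t
                n += 1 if t == 1 else -1
                updates += 1
                for i in range(n_res):
                    old = a_wt[i] if t == 1 else a_mut[i]
                    new = a_mut[i] if t == 1 else a_wt[i]
                    delta = new - old
                    if delta != 0.0:
                        if refresh_every > 0 and updates % refresh_every == 0:
                            for v in range(N):
                                for w in range(N):
                                    M[v, w] = DL[v, w]
                                M[v, v] += a_mut[i] if occ[v] == 1 else a_wt[i]
                            inv[i] = np.linalg.inv(M)
                        else:
                            denom = 1.0 + delta * inv[i, child, child]
                            scale = delta / denom
                            # inv <- inv - scale * inv[:, child] inv[child, :]
                            for v in range(N):
                                cv = inv[i, v, child] * scale
                                if cv != 0.0:
                                    for w in range(N):
                                        inv[i, v, w] -= cv * inv[i, child, w]
                        for v in range(N):
                            acc = 0.0
                            for w in range(N):
                                acc += inv[i, v, w]
                            conc[i, v] = acc * supply[i]
                tot = 0.0
                for v in range(N):
                    acc = 0.0
                    for i in range(n_res):
                        a = a_mut[i] if occ[v] == 1 else a_wt[i]
                        acc += values[i] * a * conc[i, v]
                    f = (s_mut if occ[v] == 1 else s_wt) * acc
                    tot += f
                    cum[v] = tot
                if est_threshold > 0 and est_flag == 0 and n >= est_threshold:
                    est_flag = np.uint8(1)
                    est_step = steps
                if n == 0:
                    outcome = np.int8(OUTCOME_LOSS)
                    break
                if n == N:
                    outcome = np.int8(OUTCOME_FIX)
                    break
        outcomes[r] = outcome
        steps_arr[r] = steps
        established[r] = est_flag
        est_steps[r] = est_step
    return outcomes, steps_arr, established, est_steps
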