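"""Compiled inner loops of the evolution engine.

Everything here is an implementation detail of :mod:`plastevo.evolution`.
The public contracts live there; these kernels exist so that million-
generation Wright-Fisher runs are feasible on one CPU.

Numerical note: the reference (numpy) engine path calls the same
``_eval_pair`` / ``_build_alias`` / ``_mean`` primitives, so the fast and
reference paths produce bit-identical outputs.  Numba guarantees that
``Generator.random`` draws match numpy's stream for the same seed, which
makes the two paths interchangeable draw-for-draw.
"""

import numpy as np
from numba import njit

# status codes returned by _wf_chunk
CONT = 0   # chunk exhausted, run continues
DONE = 1   # acquisition verified (streak reached window + 1)
CAP = 2    # generation cap reached


@njit(cache=True)
def _mean(a):
    # sequential mean, shared by both engine paths for bit-identity
    s = 0.0
    for i in range(a.shape[0]):
        s += a[i]
    return s / a.shape[0]


@njit(cache=True)
def _eval_pair(row, n, alpha, tau_c, tau_v, tau_l, denom, X1, X2, out):
    """(w1, w2) of one packed genotype row: develop under full sensor
    activation scored against X1, and sensor-silent scored against X2."""
    for env in range(2):
        s = 1.0 if env == 0 else 0.0
        x = row[:n].copy()
        xn = np.empty(n)
        log_w = 0.0
        for tau in range(tau_l):
            d = s / alpha if tau < tau_c else 0.0
            for i in range(n):
                u = row[n + n * n + i] * d
                for j in range(n):
                    u += row[n + i * n + j] * x[j]
                xn[i] = (1.0 - alpha) * x[i] + 0.5 * (1.0 + np.tanh(u))
            for i in range(n):
                x[i] = xn[i]
            if tau + 1 >= tau_v:
                if env == 0:
                    for i in range(n):
                        log_w -= (x[i] - X1[i]) ** 2 / denom
                else:
                    for i in range(n):
                        log_w -= (x[i] - X2[i]) ** 2 / denom
        out[env] = np.exp(log_w)


@njit(cache=True)
def _eval_rows(rows, n, alpha, tau_c, tau_v, tau_l, denom, X1, X2):
    """Batch version of :func:`_eval_pair`; returns a (k, 2) array."""
    k = rows.shape[0]
    out = np.empty((k, 2))
    fb = np.empty(2)
    for r in range(k):
        _eval_pair(rows[r], n, alpha, tau_c, tau_v, tau_l, denom, X1, X2, fb)
        out[r, 0] = fb[0]
        out[r, 1] = fb[1]
    return out


@njit(cache=True)
def _build_alias(weights):
    """Walker/Vose alias table for fitness-proportional sampling.

    Falls back to uniform weights when the total weight is zero or
    non-finite (a population whose every fitness underflowed).
    """
    N = weights.shape[0]
    prob = np.empty(N)
    alias = np.empty(N, np.int64)
    tot = 0.0
    for i in range(N):
        tot += weights[i]
    if tot <= 0.0 or not np.isfinite(tot):
        for i in range(N):
            prob[i] = 1.0
            alias[i] = i
        return prob, alias
    scaled = np.empty(N)
    small = np.empty(N, np.int64)
    large = np.empty(N, np.int64)
    ns = 0
    nl = 0
    for i in range(N):
        scaled[i] = weights[i] * N / tot
        if scaled[i] < 1.0:
            small[ns] = i
            ns += 1
        else:
            large[nl] = i
            nl += 1
    while ns > 0 and nl > 0:
        ns -= 1
        nl -= 1
        s = small[ns]
        lg = large[nl]
        prob[s] = scaled[s]
        alias[s] = lg
        scaled[lg] = scaled[lg] - (1.0 - scaled[s])
        if scaled[lg] < 1.0:
            small[ns] = lg
            ns += 1
        else:
            large[nl] = lg
            nl += 1
    while nl > 0:
        nl -= 1
        prob[large[nl]] = 1.0
        alias[large[nl]] = large[nl]
    while ns > 0:
        ns -= 1
        prob[small[ns]] = 1.0
        alias[small[ns]] = small[ns]
    return prob, alias


@njit(cache=True)
def _alias_pick(prob, alias, u):
    """Sample one index from the alias table using a single uniform."""
    N = prob.shape[0]
    scaled = u * N
    k = int(scaled)
    if k >= N:
        k = N - 1
    if scaled - k < prob[k]:
        return k
    return alias[k]


@njit(cache=True)
def _alias_sample(prob, alias, us):
    out = np.empty(us.shape[0], np.int64)
    for i in range(us.shape[0]):
        out[i] = _alias_pick(prob, alias, us[i])
    return out


_FNV_OFFSET = np.uint64(1469598103934665603)
_FNV_PRIME = np.uint64(1099511628211)


@njit(cache=True)
def _row_hash(bits, L):
    """FNV-1a over the bit patterns of one packed row."""
    h = _FNV_OFFSET
    for j in range(L):
        h = (h ^ np.uint64(bits[j])) * _FNV_PRIME
    return h


@njit(cache=True)
def _cache_find(table, store, store_w, bits_of, row, L, out):
    """Probe an open-addressing table; verified by full row comparison.

    Returns the matching store slot, or -(insertion bucket) - 1 on miss.
    """
    mask = np.uint64(table.shape[0] - 1)
    idx = np.int64((_row_hash(bits_of, L) >> np.uint64(13)) & mask)
    while True:
        e = table[idx]
        if e == 0:
            return -idx - 1
        k = e - 1
        eq = True
        for j in range(L):
            if store[k, j] != row[j]:
                eq = False
                break
        if eq:
            out[0] = store_w[k, 0]
            out[1] = store_w[k, 1]
            return k
        idx = (idx + 1) & np.int64(mask)


@njit(cache=True)
def _wf_chunk(pop, w1, w2, T0, max_gens, t_stop, it, init_e1,
              n, alpha, tau_c, tau_v, tau_l, denom, X1, X2,
              mu_vec, gamma_vec, threshold, window,
              state, store_a, wa, table_a, store_b, wb, table_b,
              cache_meta, rng, m1_out, m2_out):
    """Advance the population by up to ``max_gens`` generations.

    Per generation, in this order: record the population mean fitnesses of
    the current generation; update the acquisition monitor (run-length
    counter in ``state = [streak, candidate_Tp]``); stop if the monitor
    verified or the generation cap ``t_stop`` was recorded; otherwise apply
    fitness-proportional selection of N independent parent pairs, free
    recombination (each scalar locus from either parent with probability
    1/2), and per-locus mutation with clamping of the g block to
    [0, 1/alpha].

    Random draw protocol per advanced generation (fixed; the reference
    engine replicates it exactly): S = random(2N) parent-pair uniforms, then
    R = random((N, L)) recombination uniforms, M = random((N, L)) mutation
    trials, D = random((N, L)) mutation effect uniforms.

    Fitness bookkeeping: a child identical to one of its parents inherits
    that parent's (w1, w2); any other child is looked up in a hash cache of
    genotypes evaluated this generation (store_b) or referenced last
    generation (store_a), with every hit verified by full row comparison,
    before falling back to a fresh evaluation.  Fitness is a deterministic
    function of the genotype row, so the caching returns exactly the same
    numbers as evaluating every individual, at near constant cost per
    generation in the near-monomorphic regime.

    Returns (generations_recorded, status).
    """
    N, L = pop.shape
    g_hi = 1.0 / alpha
    new = np.empty_like(pop)
    nw1 = np.empty(N)
    nw2 = np.empty(N)
    fb = np.empty(2)
    child = np.empty(L)
    child_bits = child.view(np.int64)
    streak = state[0]
    cand = state[1]
    cap = store_a.shape[0]
    tbl = table_a.shape[0]
    n_a = cache_meta[0]
    g = 0
    status = CONT
    while g < max_gens:
        T = T0 + g
        m1 = _mean(w1)
        m2 = _mean(w2)
        m1_out[g] = m1
        m2_out[g] = m2
        g += 1
        mn = m1 if m1 < m2 else m2
        if mn > threshold:
            if streak == 0:
                cand = T
            streak += 1
            if streak >= window + 1:
                status = DONE
                break
        else:
            streak = 0
        if T >= t_stop:
            status = CAP
            break
        # selection weights: w1 in E1 epochs, w2 in E2 epochs
        epoch_even = (T // it) % 2 == 0
        wt = w1 if epoch_even == init_e1 else w2
        prob, alias = _build_alias(wt)
        S = rng.random(2 * N)
        R = rng.random((N, L))
        M = rng.random((N, L))
        D = rng.random((N, L))
        n_b = 0
        for idx in range(tbl):
            table_b[idx] = 0
        for i in range(N):
            ia = _alias_pick(prob, alias, S[i])
            ib = _alias_pick(prob, alias, S[N + i])
            same_a = True
            same_b = True
            for j in range(L):
                v = pop[ia, j] if R[i, j] < 0.5 else pop[ib, j]
                if M[i, j] < mu_vec[j]:
                    v = v + (2.0 * D[i, j] - 1.0) * gamma_vec[j]
                    if j < n:
                        if v < 0.0:
                            v = 0.0
                        elif v > g_hi:
                            v = g_hi
                child[j] = v
                if v != pop[ia, j]:
                    same_a = False
                if v != pop[ib, j]:
                    same_b = False
            for j in range(L):
                new[i, j] = child[j]
            if same_a:
                nw1[i] = w1[ia]
                nw2[i] = w2[ia]
                continue
            if same_b:
                nw1[i] = w1[ib]
                nw2[i] = w2[ib]
                continue
            hit_b = _cache_find(table_b, store_b, wb, child_bits, child,
                                L, fb)
            if hit_b >= 0:
                nw1[i] = fb[0]
                nw2[i] = fb[1]
                continue
            hit_a = _cache_find(table_a, store_a, wa, child_bits, child,
                                L, fb)
            if hit_a < 0:
                _eval_pair(child, n, alpha, tau_c, tau_v, tau_l,
                           denom, X1, X2, fb)
            nw1[i] = fb[0]
            nw2[i] = fb[1]
            if n_b < cap:  # remember for this and the next generation
                for j in range(L):
                    store_b[n_b, j] = child[j]
                wb[n_b, 0] = fb[0]
                wb[n_b, 1] = fb[1]
                table_b[-hit_b - 1] = n_b + 1
                n_b += 1
        pop[:] = new
        w1[:] = nw1
        w2[:] = nw2
        # promote this generation's entries for lookup next generation
        for idx in range(tbl):
            table_a[idx] = 0
        for k in range(n_b):
            for j in range(L):
                store_a[k, j] = store_b[k, j]
                child[j] = store_b[k, j]
            wa[k, 0] = wb[k, 0]
            wa[k, 1] = wb[k, 1]
            h = _cache_find(table_a, store_a, wa, child_bits, child, L, fb)
            if h < 0:
                table_a[-h - 1] = k + 1
        n_a = n_b
    state[0] = streak
    state[1] = cand
    cache_meta[0] = n_a
    return g, status
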