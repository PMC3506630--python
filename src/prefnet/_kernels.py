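"""Low-level jit-compiled kernels for the adaptive-network SIS simulator.

Everything in here operates on plain arrays so that numba can compile it:

* the network lives in a fixed-capacity adjacency-list matrix ``nbr`` of
  shape (N, N-1) plus a degree vector ``deg`` (undirected simple graph,
  every edge stored in both rows);
* node states live in an int8 vector ``sig`` (0 = susceptible, 1 = infected);
* randomness comes from an explicit xorshift128+ state (two uint64 words),
  so runs are bit-reproducible and the network and SIS dynamics can consume
  independent streams (a frozen-network run then matches a w=inf run
  sample for sample).

The Python-facing modules (`preferred_network`, `sis_dynamics`,
`adaptive_coupling`) wrap these kernels; they are not part of the public API.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "seed_state",
    "FEAR_NONE",
    "FEAR_RECKLESS",
    "FEAR_TYPICAL",
    "FEAR_NOSOPHOBIC",
]

# fear-factor kind codes shared with adaptive_coupling
FEAR_NONE = 0
FEAR_RECKLESS = 1
FEAR_TYPICAL = 2
FEAR_NOSOPHOBIC = 3

# diagnostics slots
DIAG_ADDS = 0
DIAG_CUTS = 1
DIAG_NOOP_FULL = 2
DIAG_NOOP_EMPTY = 3
DIAG_FALLBACK = 4
N_DIAG = 5

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def seed_state(seed: int, stream: int = 0) -> np.ndarray:
    """Initialise an xorshift128+ state from (seed, stream) via splitmix64."""
    mask = 0xFFFFFFFFFFFFFFFF
    state = np.empty(2, dtype=np.uint64)
    z = (int(seed) + int(stream) * 0x9E3779B97F4A7C15) & mask
    for k in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        w = z
        w = ((w ^ (w >> 30)) * 0xBF58476D1CE4E5B9) & mask
        w = ((w ^ (w >> 27)) * 0x94D049BB133111EB) & mask
        state[k] = np.uint64(w ^ (w >> 31))
    if state[0] == 0 and state[1] == 0:  # all-zero state is a fixed point
        state[0] = np.uint64(1)
    return state


@njit(cache=True)
def _next_u64(rs):
    x = rs[0]
    y = rs[1]
    rs[0] = y
    x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(17)
    x ^= y ^ (y >> np.uint64(26))
    rs[1] = x
    return (x + y) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _rand01(rs):
    # 53-bit mantissa uniform in [0, 1)
    return (_next_u64(rs) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _randint(rs, n):
    # modulo bias is < n / 2^64: irrelevant for n <= a few thousand
    return np.int64(_next_u64(rs) % np.uint64(n))


@njit(cache=True)
def _wplus(k, kappa, beta):
    """Fermi add-probability w+(k); w- = 1 - w+."""
    if np.isinf(beta):
        if k < kappa:
            return 1.0
        return 0.0
    z = beta * (k - kappa)
    if z > 40.0:
        return 0.0
    if z < -40.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def _kappa_of_x(kind, kappa0, kappa_inf, x_c, a, x):
    """Preferred degree kappa(x) = kappa0 * f(x) for the three fear factors."""
    if kind == 0:  # none
        return kappa0
    if kind == 1:  # reckless: step down at x_c
        if x < x_c:
            return kappa0
        return kappa_inf
    if kind == 2:  # typical: linear ramp, clamped at kappa_inf
        s = (1.0 - kappa_inf / kappa0) / x_c
        val = kappa0 * (1.0 - s * x)
        if val < kappa_inf:
            return kappa_inf
        return val
    # nosophobic: exponential drop
    return kappa0 * np.exp(-a * x)


@njit(cache=True)
def _is_neighbor(nbr, deg, i, j):
    for a in range(deg[i]):
        if nbr[i, a] == j:
            return True
    return False


@njit(cache=True)
def _add_edge(nbr, deg, i, j):
    nbr[i, deg[i]] = j
    deg[i] += 1
    nbr[j, deg[j]] = i
    deg[j] += 1


@njit(cache=True)
def _remove_from_row(nbr, deg, i, j):
    for a in range(deg[i]):
        if nbr[i, a] == j:
            nbr[i, a] = nbr[i, deg[i] - 1]
            deg[i] -= 1
            return


@njit(cache=True)
def _cut_edge(nbr, deg, i, j):
    _remove_from_row(nbr, deg, i, j)
    _remove_from_row(nbr, deg, j, i)


@njit(cache=True)
def _count_inf_neighbors(nbr, deg, sig, i):
    m = 0
    for a in range(deg[i]):
        if sig[nbr[i, a]] == 1:
            m += 1
    return m


@njit(cache=True)
def _sample_partner(nbr, deg, sig, rs, i, target, pool):
    """Uniform draw from the non-neighbors of i (excluding i).

    target: -1 = any state, 0 = susceptible only, 1 = infected only.
    pool: number of eligible nodes (must be > 0).
    """
    n = nbr.shape[0]
    if pool * 8 >= n:
        # large pool: rejection sampling
        while True:
            j = _randint(rs, n)
            if j == i:
                continue
            if target >= 0 and sig[j] != target:
                continue
            if not _is_neighbor(nbr, deg, i, j):
                return j
    # small pool: index into an ordered scan of eligible nodes
    idx = _randint(rs, pool)
    c = 0
    for j in range(n):
        if j == i:
            continue
        if target >= 0 and sig[j] != target:
            continue
        if _is_neighbor(nbr, deg, i, j):
            continue
        if c == idx:
            return j
        c += 1
    return -1  # unreachable if pool was counted correctly


@njit(cache=True)
def _link_attempt(nbr, deg, sig, n_inf, rs, kappa, beta, selective, bias, diag):
    """One elementary link update of a uniformly chosen node.

    The updating node decides add vs cut through the Fermi rule at the
    current preferred degree; the partner is drawn uniformly from the
    eligible pool.  When ``selective`` is on, a *susceptible* updater routes
    the move by disease state first: cuts favour infected contacts and
    additions favour susceptible partners, both with odds weight (1+bias)
    on the favoured class.  Infected updaters (and every node in the blind
    model) pick partners regardless of state.  The recipient has no veto.
    """
    n = nbr.shape[0]
    i = _randint(rs, n)
    k = deg[i]
    if _rand01(rs) < _wplus(k, kappa, beta):
        # --- add a link ---
        if k >= n - 1:
            diag[DIAG_NOOP_FULL] += 1
            return
        if selective and sig[i] == 0 and n_inf > 0:
            k_i = _count_inf_neighbors(nbr, deg, sig, i)
            k_s = k - k_i
            pool_s = (n - n_inf) - 1 - k_s  # eligible susceptible non-neighbors
            pool_i = n_inf - k_i  # eligible infected non-neighbors
            if pool_s == 0 and pool_i == 0:
                diag[DIAG_NOOP_FULL] += 1
                return
            p_ss = (1.0 + bias) * pool_s / ((1.0 + bias) * pool_s + pool_i)
            if _rand01(rs) < p_ss:
                target, pool = 0, pool_s
            else:
                target, pool = 1, pool_i
            if pool == 0:  # routed class empty: fall back to the other one
                diag[DIAG_FALLBACK] += 1
                if target == 0:
                    target, pool = 1, pool_i
                else:
                    target, pool = 0, pool_s
            j = _sample_partner(nbr, deg, sig, rs, i, target, pool)
        else:
            j = _sample_partner(nbr, deg, sig, rs, i, -1, n - 1 - k)
        _add_edge(nbr, deg, i, j)
        diag[DIAG_ADDS] += 1
    else:
        # --- cut a link ---
        if k == 0:
            diag[DIAG_NOOP_EMPTY] += 1
            return
        if selective and sig[i] == 0:
            k_i = _count_inf_neighbors(nbr, deg, sig, i)
            k_s = k - k_i
            p_ci = (1.0 + bias) * k_i / ((1.0 + bias) * k_i + k_s)
            if _rand01(rs) < p_ci:
                target, cnt = 1, k_i
            else:
                target, cnt = 0, k_s
            if cnt == 0:
                diag[DIAG_FALLBACK] += 1
                if target == 1:
                    target, cnt = 0, k_s
                else:
                    target, cnt = 1, k_i
            idx = _randint(rs, cnt)
            c = 0
            j = -1
            for a in range(k):
                if sig[nbr[i, a]] == target:
                    if c == idx:
                        j = nbr[i, a]
                        break
                    c += 1
        else:
            j = nbr[i, _randint(rs, k)]
        _cut_edge(nbr, deg, i, j)
        diag[DIAG_CUTS] += 1


@njit(cache=True)
def _network_mcs(nbr, deg, sig, n_inf, rs, kappa, beta, selective, bias, diag):
    """One network Monte Carlo step: N link attempts on random nodes."""
    for _ in range(nbr.shape[0]):
        _link_attempt(nbr, deg, sig, n_inf, rs, kappa, beta, selective, bias, diag)


@njit(cache=True)
def _grow_network(nbr, deg, rs, kappa, beta, n_mcs, diag):
    """Evolve a disease-free network for n_mcs Monte Carlo steps."""
    sig = np.zeros(nbr.shape[0], dtype=np.int8)
    for _ in range(n_mcs):
        _network_mcs(nbr, deg, sig, 0, rs, kappa, beta, False, 0.0, diag)


@njit(cache=True)
def _sis_mcs(nbr, deg, sig, rs, mu, lam, immortal, n_inf):
    """One SIS Monte Carlo step: N node attempts on random nodes.

    An infected node recovers with probability mu, except that with the
    immortal device on, the last infected node never recovers.  A
    susceptible node with m infected contacts is infected with probability
    1-(1-lam)^m (simultaneous exposure).
    """
    n = nbr.shape[0]
    for _ in range(n):
        i = _randint(rs, n)
        if sig[i] == 1:
            if immortal and n_inf == 1:
                continue
            if _rand01(rs) < mu:
                sig[i] = 0
                n_inf -= 1
        else:
            m = _count_inf_neighbors(nbr, deg, sig, i)
            if m > 0:
                p = 1.0 - (1.0 - lam) ** m
                if _rand01(rs) < p:
                    sig[i] = 1
                    n_inf += 1
    return n_inf


@njit(cache=True)
def _count_links(nbr, deg, sig):
    """Edge counts by endpoint states: (n_SS, n_SI, n_II)."""
    n_ss = 0
    n_si = 0
    n_ii = 0
    for i in range(nbr.shape[0]):
        for a in range(deg[i]):
            j = nbr[i, a]
            if j > i:
                t = sig[i] + sig[j]
                if t == 0:
                    n_ss += 1
                elif t == 1:
                    n_si += 1
                else:
                    n_ii += 1
    return n_ss, n_si, n_ii


@njit(cache=True)
def _accumulate_hist(deg, sig, hist_all, hist_s, hist_i):
    for i in range(deg.shape[0]):
        d = deg[i]
        hist_all[d] += 1
        if sig[i] == 1:
            hist_i[d] += 1
        else:
            hist_s[d] += 1


@njit(cache=True)
def _run_coupled(
    nbr,
    deg,
    sig,
    n_inf,
    rs_net,
    rs_sis,
    mu,
    lam,
    beta,
    immortal,
    fear_kind,
    kappa0,
    kappa_inf,
    x_c,
    fear_a,
    selective,
    bias,
    net_per_cycle,
    sis_per_cycle,
    burn_mcs,
    sample_mcs,
    interval,
    out_t,
    out_x,
    out_ss,
    out_si,
    out_ii,
    out_kap,
    hist_all,
    hist_s,
    hist_i,
    record_hist,
    diag,
):
    """Two-timescale coupled loop.

    Per cycle: ``net_per_cycle`` network MCS (the global prevalence x, and
    with it kappa(x), is re-read at the start of each network MCS), then
    ``sis_per_cycle`` SIS MCS.  Time t counts SIS MCS; observables are
    recorded every ``interval`` MCS once t exceeds ``burn_mcs``.

    Returns (n_infected, minimum n_infected seen, number of samples taken).
    """
    n = nbr.shape[0]
    total = burn_mcs + sample_mcs
    t = 0
    samp = 0
    min_inf = n_inf
    while t < total:
        for _ in range(net_per_cycle):
            x = n_inf / n
            kap = _kappa_of_x(fear_kind, kappa0, kappa_inf, x_c, fear_a, x)
            _network_mcs(nbr, deg, sig, n_inf, rs_net, kap, beta, selective, bias, diag)
        for _ in range(sis_per_cycle):
            if t >= total:
                break
            n_inf = _sis_mcs(nbr, deg, sig, rs_sis, mu, lam, immortal, n_inf)
            if n_inf < min_inf:
                min_inf = n_inf
            t += 1
            if t > burn_mcs and (t - burn_mcs) % interval == 0 and samp < out_t.shape[0]:
                x = n_inf / n
                n_ss, n_si, n_ii = _count_links(nbr, deg, sig)
                out_t[samp] = t
                out_x[samp] = x
                out_ss[samp] = n_ss
                out_si[samp] = n_si
                out_ii[samp] = n_ii
                out_kap[samp] = _kappa_of_x(
                    fear_kind, kappa0, kappa_inf, x_c, fear_a, x
                )
                if record_hist:
                    _accumulate_hist(deg, sig, hist_all, hist_s, hist_i)
                samp += 1
    return n_inf, min_inf, samp
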