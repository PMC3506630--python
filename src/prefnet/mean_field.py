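"""Deterministic theories for SIS on preferred-degree (adaptive) networks.

Four levels of description are implemented.

**Simple mean field (MF).**  With every node carrying kappa contacts of
which a fraction x is infected, the infected fraction evolves as

    dx/dt = -mu x + (1 - x) [1 - (1 - lam)^(kappa x)],

whose active stationary state inverts in closed form to the explicit
lambda(x) curve (`mf_lambda_of_x`).  The printed threshold formula is
``lambda_c = 1 - (1 - mu)^(1/kappa)`` (`mf_threshold`); the onset limit of
the lambda(x) curve itself is ``1 - exp(-mu/kappa)`` (`mf_onset_lambda`).
The two agree to mu/kappa at small mu (relative difference ~ mu/2) — see
the methods note for why both are kept.

**Heterogeneous mean field (HMF).**  The threshold scales with the degree
ratio <k>/<k^2>; because preferred-degree networks have narrow (Laplace)
degree distributions this essentially reproduces the simple MF value.

**Annealed adjacency matrix (AAM).**  The fluctuating adjacency is replaced
by pairwise connection probabilities and the per-node infection
probabilities rho_n are iterated through the discrete Markov map

    rho_n(t+1) = (1 - mu) rho_n + (1 - rho_n) (1 - prod_l (1 - lam a_nl rho_l)).

**Local mean field theory (LMFT).**  For selective adaptation the state is
(x, l_SS, l_SI, l_II) — infected fraction and mean links per node by
endpoint type.  Infection is driven by the mean number of infected contacts
per susceptible, l_SI/(1-x); recovery relabels SI->SS and II->SI;
infection relabels SS->SI and SI->II; and the adaptation add/cut fluxes
act at rate 1/w with the Fermi decision at kappa(x) and selective bias
sigma.  Local degrees are closed by the global class averages.  At
sigma = 0 the random-mixing state is an exact fixed point and the LMFT
collapses onto the (adaptive) simple MF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .adaptive_coupling import FearFactor, preferred_degree, smoothed_preferred_degree
from .preferred_network import DegreeHistogram, NetworkState

_EPS = 1e-12


# ---------------------------------------------------------------------------
# simple and heterogeneous mean field
# ---------------------------------------------------------------------------

def mf_threshold(mu: float, kappa: float) -> float:
    """Printed mean-field epidemic threshold lambda_c = 1 - (1-mu)^(1/kappa).

    Reduces to mu/kappa for small mu.
    """
    if not (0.0 < mu <= 1.0) or kappa <= 0:
        raise ValueError("need 0 < mu <= 1 and kappa > 0")
    return 1.0 - (1.0 - mu) ** (1.0 / kappa)


def mf_onset_lambda(mu: float, kappa: float) -> float:
    """Onset limit of the stationary lambda(x) curve: 1 - exp(-mu/kappa).

    Agrees with `mf_threshold` to O(mu^2/kappa); use this value when
    checking continuity of the curve at x -> 0.
    """
    return 1.0 - math.exp(-mu / kappa)


def x_max(mu: float) -> float:
    """Saturation level of the infection, 1/(1+mu) (the lam = 1 fixed point)."""
    return 1.0 / (1.0 + mu)


def mf_lambda_of_x(x: float, mu: float, kappa: float) -> float:
    """Infection rate at which x is the stationary infected fraction.

    Closed-form inverse of the stationarity relation
    ``mu x = (1 - x)(1 - (1 - lam)^(kappa x))``:

        lam(x) = 1 - (1 - mu x / (1 - x))^(1 / (kappa x)).

    Raises ValueError outside the feasible range 0 < x < 1/(1+mu).
    """
    if not (0.0 < x < x_max(mu)):
        raise ValueError(f"x={x} outside the feasible range (0, {x_max(mu):.6f})")
    inner = 1.0 - mu * x / (1.0 - x)
    return 1.0 - inner ** (1.0 / (kappa * x))


def mf_x_of_lambda(lam: float, mu: float, kappa: float) -> float:
    """Stable stationary infected fraction at infection rate lam (0 below onset)."""
    from scipy.optimize import brentq

    if lam <= mf_onset_lambda(mu, kappa):
        return 0.0
    hi = x_max(mu) - 1e-12
    f = lambda x: mf_lambda_of_x(x, mu, kappa) - lam
    lo = 1e-12
    if f(hi) < 0:  # lam beyond the curve's range (lam >= 1 numerically)
        return x_max(mu)
    if f(lo) > 0:  # lam below the onset of the nontrivial branch
        return 0.0
    return float(brentq(f, lo, hi, xtol=1e-14))


def mf_adaptive_lambda_of_x(x: float, mu: float, fear: FearFactor) -> float:
    """Stationary lambda(x) with the prevalence-dependent kappa(x) = kappa0 f(x).

    The threshold is unchanged because f(0) = 1; above it, producing the same
    x requires lam enhanced by a factor involving 1/f(x).  Returns inf when
    f(x) = 0 (no contacts can sustain any infection level).
    """
    kap = preferred_degree(fear, x)
    if kap <= _EPS:
        return math.inf
    return mf_lambda_of_x(x, mu, kap)


def hmf_threshold(mu: float, hist: DegreeHistogram) -> float:
    """Heterogeneous-mean-field threshold from the degree ratio <k>/<k^2>.

    Uses the discrete-rate form 1 - (1-mu)^(<k>/<k^2>), which collapses to
    `mf_threshold` for a degree distribution concentrated at kappa.
    """
    ratio = hist.moment(1) / hist.moment(2)
    return 1.0 - (1.0 - mu) ** ratio


# ---------------------------------------------------------------------------
# annealed adjacency matrix
# ---------------------------------------------------------------------------

@dataclass
class AAMModel:
    """Annealed adjacency: symmetric per-pair connection probabilities."""

    abar: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abar, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("annealed adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("annealed adjacency must be symmetric")
        if a.min() < 0 or a.max() > 1:
            raise ValueError("annealed entries must be probabilities")
        self.abar = a

    @classmethod
    def uniform(cls, n: int, kappa: float) -> "AAMModel":
        """Homogeneous rank-1 annealed matrix abar = kappa/(n-1) off-diagonal."""
        a = np.full((n, n), kappa / (n - 1))
        np.fill_diagonal(a, 0.0)
        return cls(a)

    @classmethod
    def from_networks(cls, nets: Sequence[NetworkState]) -> "AAMModel":
        """Empirical annealed matrix: time-averaged adjacency over snapshots."""
        nets = list(nets)
        if not nets:
            raise ValueError("empty snapshot ensemble")
        n = nets[0].n_nodes
        acc = np.zeros((n, n))
        for net in nets:
            for i, j in net.edges():
                acc[i, j] += 1.0
                acc[j, i] += 1.0
        return cls(acc / len(nets))


def aam_stationary_x(
    model: AAMModel,
    mu: float,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    rho0: float | np.ndarray = 0.5,
) -> tuple[float, np.ndarray]:
    """Fixed point of the AAM discrete Markov map; returns (x, per-node rho)."""
    a = model.abar
    n = a.shape[0]
    rho = np.full(n, float(rho0)) if np.isscalar(rho0) else np.asarray(rho0, dtype=float).copy()
    for _ in range(max_iter):
        q = np.exp(np.log1p(-lam * a * rho[None, :]).sum(axis=1))
        rho_new = (1.0 - mu) * rho + (1.0 - rho) * (1.0 - q)
        delta = np.abs(rho_new - rho).max()
        rho = rho_new
        if delta < tol:
            return float(rho.mean()), rho
    raise RuntimeError(f"AAM iteration did not converge within {max_iter} steps")


# ---------------------------------------------------------------------------
# local mean field theory (link-level pair closure)
# ---------------------------------------------------------------------------

@dataclass
class LMFTState:
    """Infected fraction and mean links per node by type (SS, SI, II)."""

    x: float
    l_ss: float
    l_si: float
    l_ii: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.l_ss, self.l_si, self.l_ii])

    @property
    def mean_degree(self) -> float:
        return 2.0 * (self.l_ss + self.l_si + self.l_ii)

    @classmethod
    def mixing(cls, x: float, kappa: float) -> "LMFTState":
        """Random-mixing link composition at mean degree kappa."""
        s = 1.0 - x
        return cls(x=x, l_ss=kappa * s * s / 2.0, l_si=kappa * x * s, l_ii=kappa * x * x / 2.0)


def _fermi(k: float, kappa: float, beta: float) -> float:
    z = beta * (k - kappa)
    if z > 40.0:
        return 0.0
    if z < -40.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def lmft_rhs(
    state: LMFTState | np.ndarray,
    mu: float,
    lam: float,
    w: float,
    sigma: float,
    fear: FearFactor,
    beta: float = 1.0,
    smooth_width: float = 0.0,
) -> np.ndarray:
    """Time derivatives of (x, l_SS, l_SI, l_II).

    ``w`` is the number of SIS MCS per network MCS, so the adaptation fluxes
    act at rate 1/w on the epidemic clock.  ``beta`` is the effective Fermi
    slope used for the class-averaged add/cut decision (the simulation's
    beta = inf is represented by a finite slope of order one, matching the
    spread of the stationary degree distribution).  ``smooth_width`` > 0
    regularizes the reckless fear discontinuity for the ODE solver.
    """
    if isinstance(state, LMFTState):
        arr = state.as_array()
    else:
        arr = np.asarray(state, dtype=float)
    x, l_ss, l_si, l_ii = arr
    x = min(max(x, 0.0), 1.0)
    l_ss, l_si, l_ii = max(l_ss, 0.0), max(l_si, 0.0), max(l_ii, 0.0)
    s = 1.0 - x
    rate = 0.0 if math.isinf(w) else 1.0 / w
    kap = smoothed_preferred_degree(fear, x, smooth_width)

    # class-averaged degrees (global closure of the local degrees)
    if s > _EPS:
        k_ss, k_si = 2.0 * l_ss / s, l_si / s
    else:
        k_ss = k_si = 0.0
    if x > _EPS:
        k_ii, k_is = 2.0 * l_ii / x, l_si / x
    else:
        k_ii = k_is = 0.0
    k_s = k_ss + k_si
    k_i = k_ii + k_is

    # epidemic conversions
    p_inf = 1.0 - (1.0 - lam) ** k_si if lam < 1.0 else (1.0 if k_si > 0 else 0.0)
    r_inf = s * p_inf  # infection events per node per MCS
    dx = -mu * x + r_inf
    d_ss = mu * l_si - r_inf * k_ss
    d_si = 2.0 * mu * l_ii - mu * l_si + r_inf * (k_ss - k_si)
    d_ii = -2.0 * mu * l_ii + r_inf * k_si

    if rate > 0.0:
        # susceptible updaters: selective routing with odds weight (1+sigma)
        a_s = _fermi(k_s, kap, beta)
        denom_add = (1.0 + sigma) * s + x
        p_add_ss = (1.0 + sigma) * s / denom_add if denom_add > _EPS else 1.0
        if k_s > _EPS:
            p_cut_si = (1.0 + sigma) * k_si / ((1.0 + sigma) * k_si + k_ss)
            cut_s = 1.0 - a_s
        else:
            p_cut_si, cut_s = 0.0, 0.0
        d_ss += rate * s * (a_s * p_add_ss - cut_s * (1.0 - p_cut_si))
        d_si += rate * s * (a_s * (1.0 - p_add_ss) - cut_s * p_cut_si)

        # infected updaters adapt blindly
        a_i = _fermi(k_i, kap, beta)
        if k_i > _EPS:
            frac_is = k_is / k_i
            cut_i = 1.0 - a_i
        else:
            frac_is, cut_i = 0.0, 0.0
        d_si += rate * x * (a_i * s - cut_i * frac_is)
        d_ii += rate * x * (a_i * x - cut_i * (1.0 - frac_is))

    return np.array([dx, d_ss, d_si, d_ii])


@dataclass
class LMFTFixedPoint:
    """A stationary (or oscillatory) LMFT solution with its stability."""

    state: LMFTState
    converged: bool
    oscillatory: bool
    stable: bool
    residual: float


def _numeric_jacobian(f, y: np.ndarray, h: float = 1e-7) -> np.ndarray:
    n = len(y)
    jac = np.empty((n, n))
    f0 = f(y)
    for j in range(n):
        step = h * max(1.0, abs(y[j]))
        yp = y.copy()
        yp[j] += step
        jac[:, j] = (f(yp) - f0) / step
    return jac


def lmft_relax(
    initial: LMFTState,
    mu: float,
    lam: float,
    w: float,
    sigma: float,
    fear: FearFactor,
    beta: float = 1.0,
    smooth_width: float = 0.0,
    t_max: float = 20_000.0,
    tol: float = 1e-9,
) -> LMFTFixedPoint:
    """Integrate the LMFT to stationarity (or detect sustained oscillation).

    Stationarity is declared when the max-norm of the derivative drops below
    ``tol``; a bounded non-convergent trajectory whose x keeps swinging past
    10x the relaxation horizon is flagged oscillatory.
    """
    f = lambda y: lmft_rhs(y, mu, lam, w, sigma, fear, beta, smooth_width)
    y = initial.as_array()
    chunk = t_max / 20.0
    t_done = 0.0
    last_xs: np.ndarray | None = None
    while t_done < t_max:
        sol = solve_ivp(
            lambda t, yy: f(yy),
            (0.0, chunk),
            y,
            method="LSODA",
            rtol=1e-9,
            atol=1e-11,
            dense_output=False,
        )
        y = sol.y[:, -1]
        y = np.clip(y, 0.0, None)
        y[0] = min(y[0], 1.0)
        t_done += chunk
        resid = float(np.abs(f(y)).max())
        if resid < tol:
            state = LMFTState(*y)
            jac = _numeric_jacobian(f, y)
            eigs = np.linalg.eigvals(jac)
            stable = bool(np.all(eigs.real < 1e-7))
            return LMFTFixedPoint(state, True, False, stable, resid)
        last_xs = sol.y[0]
    # no convergence: oscillation if x still has finite amplitude
    amp = float(last_xs.max() - last_xs.min()) if last_xs is not None else 0.0
    oscillatory = amp > 1e-4 and np.isfinite(y).all()
    return LMFTFixedPoint(LMFTState(*y), False, oscillatory, False, float(np.abs(f(y)).max()))


def lmft_phase_scan(
    mu: float,
    w: float,
    sigma: float,
    fear: FearFactor,
    lambda_grid: Sequence[float],
    initial_xs: Sequence[float] = (1e-3, 0.3, 0.8),
    beta: float = 1.0,
    smooth_width: float = 1e-3,
    t_max: float = 20_000.0,
):
    """Map the LMFT branch structure over a lambda grid.

    From each initial condition (random-mixing link composition at the
    fear-adjusted degree) and additionally by continuation — sweeping lambda
    up and down re-using the previous fixed point — collect the distinct
    stationary solutions at every lambda, classify their stability, and
    flag bistable windows (>= 2 stable branches), tristable windows (>= 3)
    and oscillatory trajectories.

    Returns a tidy DataFrame: lam, branch, x, l_ss, l_si, l_ii, stable,
    oscillatory.
    """
    import pandas as pd

    lambdas = sorted(float(l) for l in lambda_grid)

    def seeds_for(lam: float) -> list[LMFTState]:
        out = []
        for x0 in initial_xs:
            kap = smoothed_preferred_degree(fear, x0, smooth_width)
            out.append(LMFTState.mixing(x0, kap))
        return out

    def relax_all(lam: float, seeds: list[LMFTState]):
        sols = []
        for st in seeds:
            sols.append(
                lmft_relax(st, mu, lam, w, sigma, fear, beta, smooth_width, t_max=t_max)
            )
        return sols

    # continuation sweeps
    carried_up: list[LMFTState] = []
    carried_down: list[LMFTState] = []
    per_lambda: dict[float, list[LMFTFixedPoint]] = {lam: [] for lam in lambdas}
    for lam in lambdas:
        sols = relax_all(lam, seeds_for(lam) + carried_up)
        per_lambda[lam].extend(sols)
        carried_up = [s.state for s in sols if s.converged]
    for lam in reversed(lambdas):
        sols = relax_all(lam, carried_down) if carried_down else []
        per_lambda[lam].extend(sols)
        pool = per_lambda[lam]
        carried_down = [s.state for s in pool if s.converged]

    rows = []
    for lam in lambdas:
        fixed: list[LMFTFixedPoint] = []
        oscillatory_seen = False
        for sol in per_lambda[lam]:
            if sol.oscillatory:
                oscillatory_seen = True
            if not sol.converged:
                continue
            if any(abs(sol.state.x - g.state.x) < 1e-3 and abs(sol.state.l_si - g.state.l_si) < 1e-2 for g in fixed):
                continue
            fixed.append(sol)
        fixed.sort(key=lambda sfp: sfp.state.x)
        for branch, sol in enumerate(fixed):
            rows.append(
                {
                    "lam": lam,
                    "branch": branch,
                    "x": sol.state.x,
                    "l_ss": sol.state.l_ss,
                    "l_si": sol.state.l_si,
                    "l_ii": sol.state.l_ii,
                    "stable": sol.stable,
                    "oscillatory": oscillatory_seen,
                }
            )
    return pd.DataFrame(rows)


def stable_branch_count(scan, lam: float, x_tol: float = 1e-3) -> int:
    """Number of distinct stable branches at one lambda of a phase scan."""
    sub = scan[(np.isclose(scan["lam"], lam)) & (scan["stable"])]
    return int(len(sub))
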