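"""Prevalence-dependent preferred degree ("fear factors") and the blind vs
selective link-update rules that couple the epidemic back onto the network.

The preferred degree responds to the global infected fraction x through
``kappa(x) = kappa0 * f(x)`` with a monotonically nonincreasing fear factor
f (f(0) = 1).  Three behavioural archetypes are provided:

* **reckless** — ignore the epidemic until x reaches a threshold x_c, then
  drop abruptly to the minimal contact set kappa_inf (Heaviside form);
* **typical** — reduce contacts linearly, reaching kappa_inf exactly at
  x = x_c and staying there (slope s with s * x_c = 1 - kappa_inf/kappa0);
* **nosophobic** — irrational fear: kappa drops exponentially,
  kappa0 * exp(-a x), as soon as any infection is detected.

With *blind* adaptation the partner of an add/cut is chosen with no regard
to its disease state (an "invisible" disease).  With *selective* adaptation
(a "visible" disease) a susceptible updater weights the favoured class by
odds (1 + sigma): cuts are routed towards infected contacts and additions
towards susceptible partners; infected updaters adapt blindly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .preferred_network import NetworkState, _single_attempt

_KIND_CODES = {
    "none": K.FEAR_NONE,
    "reckless": K.FEAR_RECKLESS,
    "typical": K.FEAR_TYPICAL,
    "nosophobic": K.FEAR_NOSOPHOBIC,
}


@dataclass
class FearFactor:
    """Behavioral response curve f(x): prevalence -> preferred-degree multiplier."""

    kind: str = "none"
    kappa0: float = 20.5
    kappa_inf: float = 12.5
    x_c: float = 0.4
    severity_a: float = 25.0  # nosophobic only

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown fear kind {self.kind!r}")
        if not (0 < self.kappa_inf <= self.kappa0):
            raise ValueError("need 0 < kappa_inf <= kappa0")
        if self.kind in ("reckless", "typical") and not (0 < self.x_c <= 1):
            raise ValueError("x_c must be in (0, 1]")

    @property
    def code(self) -> int:
        return _KIND_CODES[self.kind]

    @property
    def slope(self) -> float:
        """Linear-ramp slope s of the typical response (s * x_c = 1 - kappa_inf/kappa0)."""
        return (1.0 - self.kappa_inf / self.kappa0) / self.x_c

    def __call__(self, x: float) -> float:
        """The fear factor f(x) itself (kappa(x) = kappa0 * f(x))."""
        return preferred_degree(self, x) / self.kappa0

    def curve_frame(self, n_points: int = 201):
        """Tabulate (x, f(x), kappa(x)) for plotting."""
        import pandas as pd

        xs = np.linspace(0.0, 1.0, n_points)
        kap = np.array([preferred_degree(self, x) for x in xs])
        return pd.DataFrame({"x": xs, "f": kap / self.kappa0, "kappa": kap})


@dataclass
class SelectiveBias:
    """Bias sigma >= 0 of susceptibles towards susceptible partners.

    sigma = 0 reproduces the unbiased (degree/population-proportional)
    partner choice; sigma -> inf makes the favoured class certain whenever
    it is available.
    """

    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def preferred_degree(fear: FearFactor, x: float) -> float:
    """kappa(x) = kappa0 * f(x) for the given behavioural archetype."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("prevalence x must lie in [0, 1]")
    return float(
        K._kappa_of_x(fear.code, fear.kappa0, fear.kappa_inf, fear.x_c, fear.severity_a, x)
    )


def smoothed_preferred_degree(fear: FearFactor, x: float, width: float = 1e-3) -> float:
    """kappa(x) with the reckless discontinuity regularized by a steep sigmoid.

    Used by the deterministic theory only; the stochastic simulation always
    evaluates the exact (possibly discontinuous) form.
    """
    if fear.kind != "reckless" or width <= 0:
        return preferred_degree(fear, x)
    z = (x - fear.x_c) / width
    if z > 40:
        step = 1.0
    elif z < -40:
        step = 0.0
    else:
        step = 1.0 / (1.0 + math.exp(-z))
    return fear.kappa0 + (fear.kappa_inf - fear.kappa0) * step


def selective_cut_target_prob(sigma: float, k_i: int, k_s: int) -> float:
    """Probability that a cutting susceptible removes a link to an *infected*
    contact, given it has k_i infected and k_s susceptible contacts.

    The favoured (infected) class carries odds weight (1 + sigma):
    ``P = (1+sigma) k_i / ((1+sigma) k_i + k_s)``.  sigma = 0 is the
    degree-proportional choice; the probability increases with sigma and
    tends to 1 whenever k_i > 0.
    """
    if k_i < 0 or k_s < 0 or k_i + k_s < 1:
        raise ValueError("node must have at least one contact to cut")
    return (1.0 + sigma) * k_i / ((1.0 + sigma) * k_i + k_s)


def selective_add_target_prob(sigma: float, n_s: int, n_i: int) -> float:
    """Probability that an adding susceptible connects to a *susceptible*
    partner, given n_s susceptible and n_i infected eligible non-neighbors.

    ``P = (1+sigma) n_s / ((1+sigma) n_s + n_i)``; sigma = 0 is the
    population-proportional choice, and P -> 1 as sigma -> inf whenever an
    eligible susceptible exists.
    """
    if n_s < 0 or n_i < 0:
        raise ValueError("pool counts must be nonnegative")
    if n_s + n_i == 0:
        raise ValueError("no eligible partner")
    return (1.0 + sigma) * n_s / ((1.0 + sigma) * n_s + n_i)


def _current_x(epi) -> float:
    return epi.n_infected / len(epi.state)


def blind_link_update(net: NetworkState, epi, node: int, fear: FearFactor, beta: float, rng) -> NetworkState:
    """One blind adaptive link attempt: the Fermi rule at kappa(x), partner
    chosen regardless of disease state."""
    kap = preferred_degree(fear, _current_x(epi))
    sig = np.asarray(epi.state, dtype=np.int8)
    _single_attempt(net, node, sig, epi.n_infected, kap, beta, False, 0.0, rng)
    return net


def selective_link_update(
    net: NetworkState,
    epi,
    node: int,
    fear: FearFactor,
    beta: float,
    sigma: float,
    rng,
) -> NetworkState:
    """One selective adaptive link attempt.

    Add/cut is decided by the Fermi rule at kappa(x).  A susceptible updater
    routes the move by partner state (see `selective_cut_target_prob` /
    `selective_add_target_prob`) and then picks uniformly within the routed
    class; an infected updater picks blindly.  If the routed class turns out
    to be empty the move falls back to the other class so that exactly one
    link still changes whenever the pools are nonempty.
    """
    kap = preferred_degree(fear, _current_x(epi))
    sig = np.asarray(epi.state, dtype=np.int8)
    _single_attempt(net, node, sig, epi.n_infected, kap, beta, True, sigma, rng)
    return net
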