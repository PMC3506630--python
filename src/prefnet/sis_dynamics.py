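"""SIS node dynamics on static or co-evolving preferred-degree networks.

The epidemic is the standard susceptible-infected-susceptible process in
discrete time (the time step is 1, so rates are probabilities): an infected
node recovers with probability mu per attempt, and a susceptible node in
contact with m infected nodes contracts the disease with probability
``1 - (1 - lam)^m`` (simultaneous exposure).  One Monte Carlo step (MCS) is
N such attempts on uniformly random nodes.

Because finite systems fall into the absorbing all-susceptible state, the
simulator uses the *immortal node* device: no single node is special, but
the last remaining infected node is never allowed to recover.  The system
then keeps evolving forever and steady-state time averages stand in for
ensemble averages; in the inactive phase <x> sits at the 1/N floor rather
than at 0.

Network and disease dynamics run on different clocks: for every network
MCS the scheduler performs w SIS MCS (w = inf freezes the network; w < 1
with integer 1/w expresses network adaptation *faster* than the epidemic,
used for selective adaptation studies).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels as K
from .adaptive_coupling import FearFactor
from .preferred_network import DegreeHistogram, FlexibilityProfile, NetworkState


class KernelRng:
    """Deterministic xorshift128+ stream shared with the jit kernels.

    Also carries the add/cut/no-op diagnostics counters so that detailed
    bookkeeping (edges after = edges before + adds - cuts) can be audited.
    """

    def __init__(self, seed: int, stream: int = 0):
        self.state = K.seed_state(int(seed), int(stream))
        self.diag = np.zeros(K.N_DIAG, dtype=np.int64)

    def random(self) -> float:
        return float(K._rand01(self.state))

    def integers(self, n: int) -> int:
        return int(K._randint(self.state, int(n)))

    @property
    def diagnostics(self) -> dict[str, int]:
        names = ["adds", "cuts", "noop_full", "noop_empty", "fallback"]
        return {name: int(self.diag[i]) for i, name in enumerate(names)}


@dataclass
class SISRates:
    """Recovery probability mu and per-contact transmission probability lam."""

    mu: float = 0.1
    lam: float = 0.01

    def __post_init__(self) -> None:
        for name, v in (("mu", self.mu), ("lam", self.lam)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")


@dataclass
class EpidemicState:
    """Per-node S/I labels with cached infected count and the immortal flag."""

    state: np.ndarray
    n_infected: int
    immortal_enabled: bool = True

    @classmethod
    def initial(cls, n_nodes: int, x0: float, rng: np.random.Generator, immortal: bool = True):
        n0 = max(1, int(round(x0 * n_nodes)))
        sig = np.zeros(n_nodes, dtype=np.int8)
        sig[rng.choice(n_nodes, size=n0, replace=False)] = 1
        return cls(state=sig, n_infected=n0, immortal_enabled=immortal)

    @property
    def x(self) -> float:
        return self.n_infected / len(self.state)

    def validate(self) -> None:
        if int(self.state.sum()) != self.n_infected:
            raise AssertionError("n_infected cache inconsistent with labels")


@dataclass
class SimulationConfig:
    """Full description of one coupled run (self-contained for exact replay)."""

    n: int = 1000
    rates: SISRates = field(default_factory=SISRates)
    kappa0: float = 20.5
    beta: float = math.inf
    fear: FearFactor | None = None
    selective: bool = False
    sigma: float = 0.0
    w: float = 10.0  # SIS MCS per network MCS; inf = static, 1/w integer if < 1
    x0: float = 0.1
    immortal: bool = True
    net_burn_in_mcs: int = 1000  # disease-free growth from the empty graph
    burn_in_mcs: int = 1000  # coupled thermalization before sampling
    sample_mcs: int = 1000
    interval: int = 10
    record_degree_hist: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two nodes")
        if not (0.0 < self.x0 <= 1.0):
            raise ValueError("x0 must lie in (0, 1]")
        if self.burn_in_mcs < 0 or self.sample_mcs <= 0 or self.interval <= 0:
            raise ValueError("MCS intervals must be positive")
        if not math.isinf(self.w):
            if self.w >= 1:
                if abs(self.w - round(self.w)) > 1e-9:
                    raise ValueError("w >= 1 must be an integer")
            elif self.w > 0:
                inv = 1.0 / self.w
                if abs(inv - round(inv)) > 1e-9:
                    raise ValueError("w < 1 must have integer 1/w")
            else:
                raise ValueError("w must be positive")
        if self.fear is not None and abs(self.fear.kappa0 - self.kappa0) > 1e-12:
            raise ValueError("fear.kappa0 must match config.kappa0")

    @property
    def fear_or_none(self) -> FearFactor:
        return self.fear if self.fear is not None else FearFactor(kind="none", kappa0=self.kappa0, kappa_inf=self.kappa0)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "mu": self.rates.mu,
            "lam": self.rates.lam,
            "kappa0": self.kappa0,
            "beta": "inf" if math.isinf(self.beta) else self.beta,
            "selective": self.selective,
            "sigma": self.sigma,
            "w": "inf" if math.isinf(self.w) else self.w,
            "x0": self.x0,
            "immortal": self.immortal,
            "net_burn_in_mcs": self.net_burn_in_mcs,
            "burn_in_mcs": self.burn_in_mcs,
            "sample_mcs": self.sample_mcs,
            "interval": self.interval,
            "record_degree_hist": self.record_degree_hist,
            "seed": self.seed,
        }
        if self.fear is not None:
            d["fear"] = {
                "kind": self.fear.kind,
                "kappa0": self.fear.kappa0,
                "kappa_inf": self.fear.kappa_inf,
                "x_c": self.fear.x_c,
                "severity_a": self.fear.severity_a,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        fear = d.pop("fear", None)
        mu = d.pop("mu", 0.1)
        lam = d.pop("lam", 0.01)
        for key in ("beta", "w"):
            if d.get(key) == "inf":
                d[key] = math.inf
        cfg = cls(
            rates=SISRates(mu=mu, lam=lam),
            fear=FearFactor(**fear) if fear else None,
            **d,
        )
        return cfg


@dataclass
class TimeSeriesRecord:
    """Sampled observables of one run, on the SIS-MCS clock."""

    config: SimulationConfig
    t: np.ndarray
    x: np.ndarray
    n_ss: np.ndarray
    n_si: np.ndarray
    n_ii: np.ndarray
    kappa_t: np.ndarray
    min_n_infected: int
    final_network: NetworkState
    final_epidemic: EpidemicState
    degree_hists: dict[str, DegreeHistogram] | None = None
    diagnostics: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_mcs": self.t,
                "x": self.x,
                "n_SS": self.n_ss,
                "n_SI": self.n_si,
                "n_II": self.n_ii,
                "kappa_current": self.kappa_t,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps({"config": self.config.to_dict(), "diagnostics": self.diagnostics}, indent=2))


def infection_probability(m: int, lam: float) -> float:
    """Probability 1 - (1 - lam)^m of catching the disease from m infected contacts."""
    if m < 0:
        raise ValueError("contact count must be nonnegative")
    return 1.0 - (1.0 - lam) ** m


def node_update_attempt(net: NetworkState, epi: EpidemicState, node: int, rates: SISRates, rng: KernelRng) -> EpidemicState:
    """One SIS update attempt of ``node`` (recovery or exposure)."""
    if not (0 <= node < net.n_nodes):
        raise ValueError(f"invalid node id {node}")
    sig = epi.state
    if sig[node] == 1:
        if epi.immortal_enabled and epi.n_infected == 1:
            return epi  # the last infected never recovers
        if rng.random() < rates.mu:
            sig[node] = 0
            epi.n_infected -= 1
    else:
        m = int(K._count_inf_neighbors(net._nbr, net._deg, sig, node))
        if m > 0 and rng.random() < infection_probability(m, rates.lam):
            sig[node] = 1
            epi.n_infected += 1
    return epi


def sis_mcs(net: NetworkState, epi: EpidemicState, rates: SISRates, rng: KernelRng, n_mcs: int = 1) -> EpidemicState:
    """n_mcs SIS Monte Carlo steps (N random node attempts each)."""
    n_inf = epi.n_infected
    for _ in range(int(n_mcs)):
        n_inf = int(
            K._sis_mcs(net._nbr, net._deg, epi.state, rng.state, rates.mu, rates.lam, epi.immortal_enabled, n_inf)
        )
    epi.n_infected = n_inf
    return epi


def _cycle_shape(w: float) -> tuple[int, int]:
    if math.isinf(w):
        return 0, 1
    if w >= 1:
        return 1, int(round(w))
    return int(round(1.0 / w)), 1


def run_coupled(config: SimulationConfig) -> TimeSeriesRecord:
    """Run the full two-timescale simulation described by ``config``.

    Stages: grow a disease-free network from the empty graph; seed x0*N
    infected nodes; thermalize the coupled dynamics; then sample x, the
    link-type counts and kappa(x) every ``interval`` MCS.  Deterministic
    given the seed: the network and SIS dynamics consume independent
    streams, so a w=inf run reproduces a frozen-network run exactly.
    """
    cfg = config
    rng_net = KernelRng(cfg.seed, stream=1)
    rng_sis = KernelRng(cfg.seed, stream=2)
    rng_init = np.random.default_rng(cfg.seed)

    net = NetworkState(cfg.n)
    K._grow_network(net._nbr, net._deg, rng_net.state, cfg.kappa0, cfg.beta, cfg.net_burn_in_mcs, rng_net.diag)

    epi = EpidemicState.initial(cfg.n, cfg.x0, rng_init, immortal=cfg.immortal)
    fear = cfg.fear_or_none
    net_per, sis_per = _cycle_shape(cfg.w)

    n_samples = cfg.sample_mcs // cfg.interval
    out_t = np.zeros(n_samples, dtype=np.int64)
    out_x = np.zeros(n_samples)
    out_ss = np.zeros(n_samples, dtype=np.int64)
    out_si = np.zeros(n_samples, dtype=np.int64)
    out_ii = np.zeros(n_samples, dtype=np.int64)
    out_kap = np.zeros(n_samples)
    hist_all = np.zeros(cfg.n, dtype=np.int64)
    hist_s = np.zeros(cfg.n, dtype=np.int64)
    hist_i = np.zeros(cfg.n, dtype=np.int64)

    edges_before = net.n_edges
    adds_before, cuts_before = int(rng_net.diag[K.DIAG_ADDS]), int(rng_net.diag[K.DIAG_CUTS])

    n_inf, min_inf, samp = K._run_coupled(
        net._nbr,
        net._deg,
        epi.state,
        epi.n_infected,
        rng_net.state,
        rng_sis.state,
        cfg.rates.mu,
        cfg.rates.lam,
        cfg.beta,
        cfg.immortal,
        fear.code,
        cfg.kappa0,
        fear.kappa_inf,
        fear.x_c,
        fear.severity_a,
        cfg.selective,
        cfg.sigma,
        net_per,
        sis_per,
        cfg.burn_in_mcs,
        cfg.sample_mcs,
        cfg.interval,
        out_t,
        out_x,
        out_ss,
        out_si,
        out_ii,
        out_kap,
        hist_all,
        hist_s,
        hist_i,
        cfg.record_degree_hist,
        rng_net.diag,
    )
    epi.n_infected = int(n_inf)

    # conservation audit: every counted add/cut moved exactly one edge
    adds = int(rng_net.diag[K.DIAG_ADDS]) - adds_before
    cuts = int(rng_net.diag[K.DIAG_CUTS]) - cuts_before
    if net.n_edges != edges_before + adds - cuts:
        raise AssertionError("edge bookkeeping violated: edges != before + adds - cuts")

    hists = None
    if cfg.record_degree_hist:
        hists = {
            "all": DegreeHistogram(hist_all, label="all"),
            "S": DegreeHistogram(hist_s, label="S"),
            "I": DegreeHistogram(hist_i, label="I"),
        }
    return TimeSeriesRecord(
        config=cfg,
        t=out_t[:samp],
        x=out_x[:samp],
        n_ss=out_ss[:samp],
        n_si=out_si[:samp],
        n_ii=out_ii[:samp],
        kappa_t=out_kap[:samp],
        min_n_infected=int(min_inf),
        final_network=net,
        final_epidemic=epi,
        degree_hists=hists,
        diagnostics=rng_net.diagnostics,
    )


def ensemble_mean_x(
    config: SimulationConfig, n_realizations: int = 10, base_seed: int | None = None
) -> tuple[float, float, np.ndarray]:
    """Steady-state <x> averaged over independent realizations.

    Returns (mean, standard error over realizations, per-realization means).
    """
    base = config.seed if base_seed is None else base_seed
    means = np.empty(n_realizations)
    for r in range(n_realizations):
        rec = run_coupled(replace(config, seed=(base + 1000003 * (r + 1)) % (2**31)))
        means[r] = rec.x.mean()
    se = means.std(ddof=1) / math.sqrt(n_realizations) if n_realizations > 1 else 0.0
    return float(means.mean()), float(se), means


@dataclass
class ThresholdEstimate:
    """Epidemic threshold read off an <x>(lambda) scan."""

    lambda_c: float
    ci_low: float
    ci_high: float
    bracketed: bool
    lambdas: np.ndarray
    mean_x: np.ndarray
    se_x: np.ndarray
    realization_means: np.ndarray  # shape (n_lambda, n_realizations)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lam": self.lambdas, "mean_x": self.mean_x, "se_x": self.se_x})


def _threshold_from_means(lambdas: np.ndarray, means: np.ndarray, ses: np.ndarray, floor: float) -> tuple[float, bool]:
    """Largest lambda whose <x> is statistically indistinguishable from the
    immortal floor 1/N; the estimate is the midpoint to the next grid point."""
    inactive = (means - floor) <= np.maximum(2.0 * ses, 2.0 * floor)
    if inactive.all() or not inactive.any():
        return float(lambdas[0] if not inactive.any() else lambdas[-1]), False
    last_inactive = int(np.where(inactive)[0].max())
    if last_inactive == len(lambdas) - 1:
        return float(lambdas[-1]), False
    return 0.5 * float(lambdas[last_inactive] + lambdas[last_inactive + 1]), True


def estimate_threshold(
    config: SimulationConfig,
    lambda_grid: Sequence[float],
    n_realizations: int = 10,
    n_boot: int = 200,
    base_seed: int | None = None,
) -> ThresholdEstimate:
    """Scan <x>(lambda) over a grid and estimate the epidemic threshold.

    The point estimate is the largest grid lambda whose steady <x> is
    statistically indistinguishable from the immortal floor 1/N (midpointed
    to the next grid value); the confidence interval comes from a bootstrap
    over realizations.  A grid that does not bracket the transition is
    flagged (``bracketed=False``).
    """
    lambdas = np.asarray(sorted(lambda_grid), dtype=float)
    base = config.seed if base_seed is None else base_seed
    all_means = np.empty((len(lambdas), n_realizations))
    for li, lam in enumerate(lambdas):
        cfg = replace(config, rates=SISRates(mu=config.rates.mu, lam=float(lam)))
        _, _, means = ensemble_mean_x(cfg, n_realizations, base_seed=base + 7919 * li)
        all_means[li] = means
    mean_x = all_means.mean(axis=1)
    se_x = all_means.std(axis=1, ddof=1) / math.sqrt(n_realizations)
    floor = 1.0 / config.n
    est, bracketed = _threshold_from_means(lambdas, mean_x, se_x, floor)

    boot_rng = np.random.default_rng(base + 13)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = boot_rng.integers(0, n_realizations, size=n_realizations)
        bm = all_means[:, idx].mean(axis=1)
        bs = all_means[:, idx].std(axis=1, ddof=1) / math.sqrt(n_realizations)
        boots[b], _ = _threshold_from_means(lambdas, bm, bs, floor)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ThresholdEstimate(
        lambda_c=est,
        ci_low=float(lo),
        ci_high=float(hi),
        bracketed=bracketed,
        lambdas=lambdas,
        mean_x=mean_x,
        se_x=se_x,
        realization_means=all_means,
    )
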