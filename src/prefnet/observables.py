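"""Steady-state estimation and structural statistics.

Time averages in the (immortalized) steady state stand in for ensemble
averages, so the central tool is a mean with an autocorrelation-aware
standard error (blocking).  Structural observables quantify what the
adaptive rules do to the contact graph: degree distributions conditioned on
disease state, the Newman two-group modularity of the S/I bipartition, and
a reflection-collapse distance that makes the "shifted mirror image"
description of the blind-reckless degree crossover quantitative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preferred_network import DegreeHistogram, NetworkState
from .sis_dynamics import EpidemicState, TimeSeriesRecord


@dataclass
class SteadyStateEstimate:
    mean: float
    se: float
    n_samples: int
    burn_in: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples for a steady-state estimate")
        if self.se < 0:
            raise ValueError("standard error cannot be negative")


@dataclass
class PartitionScore:
    """Newman modularity Q of the S/I bipartition; Q = 0 for one group."""

    q: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.q <= 1.0):
            raise ValueError("modularity must lie in [-1, 1]")


def _blocking_se(y: np.ndarray) -> float:
    """Autocorrelation-aware SE by successive pair-blocking.

    Climbs blocking levels while the SE estimate keeps growing clearly
    (> 5% per level) and stops at the plateau; for uncorrelated data this
    stays at level zero and returns the plain sigma/sqrt(n).
    """
    y = np.asarray(y, dtype=float)
    se = y.std(ddof=1) / math.sqrt(len(y))
    while len(y) >= 64:
        if len(y) % 2:
            y = y[:-1]
        y2 = 0.5 * (y[0::2] + y[1::2])
        se2 = y2.std(ddof=1) / math.sqrt(len(y2))
        if se2 <= se * 1.05:
            break
        y, se = y2, se2
    return se


def steady_state_average(
    series: TimeSeriesRecord | np.ndarray,
    burn_in: int = 0,
    interval: int = 1,
) -> SteadyStateEstimate:
    """Mean and blocking standard error of x over post-burn-in samples.

    ``series`` may be a TimeSeriesRecord (its x samples are used; burn_in is
    in MCS on the record's clock) or a plain array of samples (burn_in in
    samples).  ``interval`` additionally thins the retained samples.
    """
    if isinstance(series, TimeSeriesRecord):
        mask = series.t > (series.t[0] - 1 + burn_in)
        y = series.x[mask][::interval]
    else:
        y = np.asarray(series, dtype=float)[burn_in:][::interval]
    if y.size < 2:
        raise ValueError("insufficient samples after burn-in")
    if np.allclose(y, y[0]):
        return SteadyStateEstimate(float(y[0]), 0.0, int(y.size), burn_in)
    return SteadyStateEstimate(float(y.mean()), _blocking_se(y), int(y.size), burn_in)


def ensemble_steady_state(means: np.ndarray) -> SteadyStateEstimate:
    """Combine per-realization steady-state means into an ensemble estimate."""
    means = np.asarray(means, dtype=float)
    se = means.std(ddof=1) / math.sqrt(len(means)) if len(means) > 1 else 0.0
    return SteadyStateEstimate(float(means.mean()), float(se), len(means), 0)


def state_conditioned_degree_distributions(
    net: NetworkState, epi: EpidemicState
) -> dict[str, DegreeHistogram]:
    """Degree histograms of susceptibles, infected, and the whole population.

    An empty class yields a histogram with total 0 (flagged by its
    normalization raising on use).
    """
    deg = net._deg
    mask = np.asarray(epi.state, dtype=bool)
    n_max = net.n_nodes
    return {
        "all": DegreeHistogram(np.bincount(deg, minlength=n_max), label="all"),
        "S": DegreeHistogram(np.bincount(deg[~mask], minlength=n_max), label="S"),
        "I": DegreeHistogram(np.bincount(deg[mask], minlength=n_max), label="I"),
    }


def si_modularity(net: NetworkState, epi: EpidemicState) -> PartitionScore:
    """Newman modularity Q of the two-group partition {S nodes, I nodes}.

    Q = sum_g (e_gg - a_g^2) over the edge fractions e_gg within group g and
    the fraction a_g of edge ends attached to g.
    """
    n_edges = net.n_edges
    if n_edges == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    sig = np.asarray(epi.state, dtype=np.int8)
    from ._kernels import _count_links

    n_ss, n_si, n_ii = _count_links(net._nbr, net._deg, sig)
    return PartitionScore(modularity_from_link_counts(int(n_ss), int(n_si), int(n_ii)))


def modularity_from_link_counts(n_ss: int, n_si: int, n_ii: int) -> float:
    """Two-group Newman modularity from the SS/SI/II edge counts."""
    m = n_ss + n_si + n_ii
    if m == 0:
        raise ValueError("no edges")
    e_ss, e_si, e_ii = n_ss / m, n_si / m, n_ii / m
    a_s = e_ss + e_si / 2.0
    a_i = e_ii + e_si / 2.0
    return float(e_ss + e_ii - a_s**2 - a_i**2)


def link_type_conservation(record: TimeSeriesRecord) -> bool:
    """Check n_SS + n_SI + n_II matches a consistent total at every sample.

    The sum is the live edge count; it must never be negative and must match
    the final network's edge count at the final sample.
    """
    total = record.n_ss + record.n_si + record.n_ii
    if (total < 0).any():
        return False
    return int(total[-1]) == record.final_network.n_edges


def excursion_durations(n_infected: np.ndarray, floor: int = 1) -> np.ndarray:
    """Durations (in samples) of contiguous excursions with n_infected > floor.

    In the inactive phase these are expected to be exponentially
    distributed.  Open excursions at either end of the series are dropped.
    """
    above = np.asarray(n_infected) > floor
    durations = []
    run = 0
    started_inside = above[0]
    for flag in above:
        if flag:
            run += 1
        else:
            if run > 0 and not started_inside:
                durations.append(run)
            started_inside = False
            run = 0
    return np.asarray(durations, dtype=float)


def find_plateau(
    lams: np.ndarray, means: np.ndarray, min_len: int = 4
) -> tuple[float, tuple[int, int], float] | None:
    """Locate a plateau in an <x>(lambda) scan.

    Searches every window of at least ``min_len`` consecutive grid points
    for a least-squares slope statistically consistent with zero (|t| < 2
    against the residual-based slope error); among such windows the longest
    (then flattest) wins.  Returns (mean level, (start, stop) indices,
    slope) or None if no window qualifies.
    """
    lams = np.asarray(lams, dtype=float)
    means = np.asarray(means, dtype=float)
    n = len(lams)
    best: tuple[float, tuple[int, int], float] | None = None
    best_key = (-1, math.inf)
    for i in range(n - min_len + 1):
        for j in range(i + min_len, n + 1):
            xv, yv = lams[i:j], means[i:j]
            slope, icpt = np.polyfit(xv, yv, 1)
            resid = yv - (slope * xv + icpt)
            dof = len(xv) - 2
            s2 = float((resid**2).sum()) / dof if dof > 0 else 0.0
            sxx = float(((xv - xv.mean()) ** 2).sum())
            se_slope = math.sqrt(s2 / sxx) if sxx > 0 else math.inf
            if se_slope == 0.0:
                flat = slope == 0.0
            else:
                flat = abs(slope) < 2.0 * se_slope
            if flat:
                key = (j - i, abs(slope))
                if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
                    best_key = key
                    best = (float(yv.mean()), (i, j), float(slope))
    return best


def reflection_collapse_check(
    hist: DegreeHistogram, center_lo: float, center_hi: float
) -> tuple[float, float]:
    """Collapse distance between a degree histogram and its mirror image.

    Scans the reflection point Delta over a window around center_lo +
    center_hi and returns (min L1 distance, best Delta), where the distance
    compares rho(k) with rho(Delta - k).  A histogram symmetric about c
    collapses onto itself at Delta = 2c with distance 0; two identical
    displaced lobes collapse at Delta = c_lo + c_hi.
    """
    p = hist.probability
    if np.count_nonzero(p) < 2:
        raise ValueError("degenerate histogram")
    n = len(p)
    centre = center_lo + center_hi
    deltas = np.arange(int(math.floor(centre - n / 2)), int(math.ceil(centre + n / 2)) + 1)
    best = (math.inf, float(deltas[0]))
    ks = np.arange(n)
    for d in deltas:
        ref = np.zeros(n)
        src = d - ks
        ok = (src >= 0) & (src < n)
        ref[ok] = p[src[ok]]
        dist = float(np.abs(p - ref).sum())
        if dist < best[0]:
            best = (dist, float(d))
    return best
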