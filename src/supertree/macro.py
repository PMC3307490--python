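"""Diversification analyses on dated trees.

Covers lineages-through-time (LTT) curves; the Pybus–Harvey gamma statistic
(0 in expectation under pure birth, negative for early bursts, positive for
recent accelerations); segmented least-squares regression of ln(lineages) on
time with up to two breakpoints selected by AIC; net diversification rates
localized to fixed-width time bins (branching events over lineage exposure);
equal-rates-Markov random resolution of polytomies; the Slowinski–Guyer
sister-clade imbalance probability; crown-versus-origin lag percentages; and
the family-table correlations of species richness against crown age, origin
age and lag.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

import dendropy

from .datedtree import DatedTree


# ---------------------------------------------------------------------------
# LTT
# ---------------------------------------------------------------------------

@dataclass
class LTTCurve:
    """Branching times (Ma before present, oldest first) and the lineage count
    reached after each event; counts start at 2 and polytomies contribute one
    event per extra child."""

    event_times: list
    lineage_counts: list

    def __post_init__(self):
        if list(self.event_times) != sorted(self.event_times, reverse=True):
            raise ValueError("event times must be sorted oldest first")
        if self.lineage_counts and self.lineage_counts[0] != 2:
            raise ValueError("lineage counts must start at 2")


def ltt(tree: DatedTree) -> LTTCurve:
    """Lineages-through-time curve of a dated ultrametric tree."""
    times = tree.branching_times()
    if not times:
        raise ValueError("tree has no internal nodes")
    counts = list(range(2, 2 + len(times)))
    return LTTCurve(event_times=times, lineage_counts=counts)


# ---------------------------------------------------------------------------
# gamma statistic
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma: float
    p_two_tailed: float
    n: int
    internode_intervals: list  # g_k, k = 2..n


def gamma_stat(tree: DatedTree) -> GammaResult:
    """Pybus–Harvey gamma with its two-tailed standard-normal p value.

    Requires a binary dated tree (resolve polytomies first) with at least
    three leaves.
    """
    if not tree.is_binary():
        raise ValueError("polytomies present: resolve them (e.g. ERM) before gamma")
    times = tree.branching_times()  # descending; len = n - 1
    n = len(times) + 1
    if n < 3:
        raise ValueError("need at least 3 leaves")
    bounds = times + [0.0]
    g = [bounds[i] - bounds[i + 1] for i in range(len(times))]  # g_2 .. g_n
    ks = np.arange(2, n + 1)
    contrib = ks * np.array(g)
    T = np.cumsum(contrib)  # T_2 .. T_n
    total = T[-1]
    mean_inner = T[:-1].mean()  # (1/(n-2)) * sum_{i=2}^{n-1} T_i
    gamma = (mean_inner - total / 2.0) / (total * np.sqrt(1.0 / (12.0 * (n - 2))))
    p = 2.0 * (1.0 - stats.norm.cdf(abs(gamma)))
    return GammaResult(gamma=float(gamma), p_two_tailed=float(p), n=n,
                       internode_intervals=list(g))


# ---------------------------------------------------------------------------
# segmented regression on the LTT curve
# ---------------------------------------------------------------------------

@dataclass
class SegmentedFit:
    """Continuous piecewise-linear fit of ln(lineages) against time.

    Breakpoints are in Ma before present (oldest first); slopes are per-Ma
    rates on ln(lineages), one per segment from oldest to newest; ``aic`` maps
    breakpoint count to AIC; ``n_breakpoints`` identifies the chosen model.
    """

    breakpoints: list
    slopes: list
    aic: dict
    n_breakpoints: int
    rss: float


def _piecewise_fit(x: np.ndarray, y: np.ndarray, bps: tuple):
    cols = [np.ones_like(x), x]
    for b in bps:
        cols.append(np.maximum(x - b, 0.0))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def segmented_fit(curve: LTTCurve, max_breakpoints: int = 2) -> SegmentedFit:
    """AIC-selected segmented regression of the log LTT curve.

    Candidate breakpoints are the observed event times (exhaustive search);
    continuity is enforced by the hinge parametrization.  AIC is
    ``n·ln(RSS/n) + 2·(2 + 2·breakpoints)``.
    """
    t = np.asarray(curve.event_times, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 events")
    x = -t  # increases toward the present; slopes are per-Ma growth rates
    y = np.log(np.asarray(curve.lineage_counts, dtype=float))

    interior = sorted(set(x[1:-1]))
    n = len(x)
    best = None
    aic_by_k = {}
    for k in range(max_breakpoints + 1):
        n_params = 2 + 2 * k
        if n <= n_params:
            continue
        # floor the RSS at numerical-noise scale so exact fits do not let
        # spurious extra breakpoints win on floating-point dust
        rss_floor = n * 1e-16
        for bps in itertools.combinations(interior, k):
            beta, rss = _piecewise_fit(x, y, bps)
            aic = n * np.log(max(rss, rss_floor) / n) + 2 * n_params
            if k not in aic_by_k or aic < aic_by_k[k][0]:
                aic_by_k[k] = (aic, bps, beta, rss)
        if best is None or aic_by_k[k][0] < best[0]:
            best = aic_by_k[k] + (k,)

    aic, bps, beta, rss, k = best
    slopes = list(np.cumsum(beta[1:]))
    return SegmentedFit(
        breakpoints=sorted((-b for b in bps), reverse=True),
        slopes=slopes,
        aic={kk: v[0] for kk, v in aic_by_k.items()},
        n_breakpoints=k,
        rss=rss,
    )


# ---------------------------------------------------------------------------
# binned net diversification rates
# ---------------------------------------------------------------------------

@dataclass
class RateBins:
    """Per-bin net diversification estimates: uniform edges in Ma before
    present (ascending), events per bin, lineage-time exposure per bin, and
    the events/exposure rate (0 with a flag where exposure is zero)."""

    bin_edges: np.ndarray
    rates: np.ndarray
    events: np.ndarray
    exposure: np.ndarray
    zero_exposure: np.ndarray


def binned_rates(tree: DatedTree, width: float = 0.25, method: str = "events-exposure") -> RateBins:
    """Maximum-likelihood pure-birth rate per time bin.

    ``events-exposure`` divides the branching events in each bin by the total
    lineage-duration within it; ``ln-diff`` uses the difference of log lineage
    counts across the bin instead.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    root_age = tree.root_age
    n_bins = int(np.ceil(root_age / width)) or 1
    edges = np.arange(n_bins + 1) * width

    times = np.asarray(tree.branching_times())
    events = np.histogram(times, bins=edges)[0].astype(float)

    exposure = np.zeros(n_bins)
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lo, hi = node.age, node.parent_node.age
        if hi <= lo:
            continue
        first = int(lo // width)
        last = min(int(np.ceil(hi / width)), n_bins)
        for b in range(first, last):
            exposure[b] += max(0.0, min(hi, edges[b + 1]) - max(lo, edges[b]))

    if method == "events-exposure":
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(exposure > 0, events / exposure, 0.0)
    elif method == "ln-diff":
        curve = ltt(tree)
        t = np.asarray(curve.event_times)
        counts = np.asarray(curve.lineage_counts, dtype=float)

        def n_at(time):  # lineage count at a moment (before present)
            return counts[t > time].max(initial=np.nan) if np.any(t > time) else np.nan

        rates = np.zeros(n_bins)
        for b in range(n_bins):
            n_lo = n_at(edges[b])        # more recent edge -> more lineages
            n_hi = n_at(edges[b + 1])
            if np.isnan(n_lo) or np.isnan(n_hi) or n_hi <= 0:
                rates[b] = 0.0
            else:
                rates[b] = (np.log(n_lo) - np.log(n_hi)) / width
    else:
        raise ValueError("method must be 'events-exposure' or 'ln-diff'")

    return RateBins(
        bin_edges=edges, rates=rates, events=events,
        exposure=exposure, zero_exposure=(exposure == 0),
    )


# ---------------------------------------------------------------------------
# sister-clade shift statistic and lag
# ---------------------------------------------------------------------------

def slowinski_guyer(r: int, s: int) -> float:
    """Equal-rates-Markov probability of a sister split at least as imbalanced
    as (r, s): p = 2·min(r, s)/(r + s - 1), capped at 1."""
    if r < 1 or s < 1:
        raise ValueError("clade sizes must be at least 1")
    n = r + s
    if n < 3:
        raise ValueError("need at least 3 species across the two clades")
    return min(1.0, 2.0 * min(r, s) / (n - 1))


def lag_percent(crown_age: float, origin_age: float) -> float:
    """Percent of a lineage's existence elapsed before its crown radiation."""
    if not (0 < crown_age <= origin_age):
        raise ValueError("need 0 < crown_age <= origin_age")
    return 100.0 * (origin_age - crown_age) / origin_age


@dataclass
class ShiftTest:
    node_id: int
    clade_sizes: tuple  # (r, s) with r <= s
    p_slowinski_guyer: float


def shift_tests(tree: DatedTree) -> list[ShiftTest]:
    """Slowinski–Guyer p for every bifurcating internal node of the tree."""
    sets = tree.clades()
    out = []
    for node_id, node in enumerate(tree.internal_nodes(), start=1):
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        r, s = sorted((len(sets[kids[0]]), len(sets[kids[1]])))
        if r + s < 3:
            continue
        out.append(ShiftTest(node_id=node_id, clade_sizes=(r, s),
                             p_slowinski_guyer=slowinski_guyer(r, s)))
    return out


# ---------------------------------------------------------------------------
# ERM polytomy resolution
# ---------------------------------------------------------------------------

def resolve_polytomies_erm(tree: DatedTree, rng_seed: int = 0) -> DatedTree:
    """Randomly resolve every polytomy by sequential random joins (the
    equal-rates-Markov process); new nodes are dated uniformly between the
    polytomy's age and its oldest child.  Deterministic per seed."""
    rng = random.Random(rng_seed)
    out = tree.copy()
    for node in list(out.tree.postorder_internal_node_iter()):
        kids = node.child_nodes()
        c = len(kids)
        if c <= 2:
            continue
        oldest_child = max(getattr(k, "age", 0.0) for k in kids)
        ages = sorted(
            rng.uniform(oldest_child, node.age) for _ in range(c - 2)
        )
        for k in kids:
            node.remove_child(k)
        lineages = list(kids)
        for new_age in ages:
            i = rng.randrange(len(lineages))
            a = lineages.pop(i)
            j = rng.randrange(len(lineages))
            b = lineages.pop(j)
            joint = dendropy.Node()
            joint.age = new_age
            joint.age_origin = "erm-resolution"
            joint.add_child(a)
            joint.add_child(b)
            lineages.append(joint)
        for lin in lineages:
            node.add_child(lin)
    out.refresh_branch_lengths()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# family-table correlations
# ---------------------------------------------------------------------------

def family_correlations(table) -> dict:
    """Pearson correlations of species richness against crown age, origin age
    and % lag over a family table.

    *table* is a pandas DataFrame (or dict of sequences) with columns
    ``crown_age``, ``origin_age``, ``lag_percent`` and ``n_species``; returns
    ``{"crown_age": (r, p), "origin_age": (r, p), "lag_percent": (r, p)}``
    with two-tailed p from the t distribution on n - 2 df.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    out = {}
    for col in ("crown_age", "origin_age", "lag_percent"):
        x = df[col].to_numpy(dtype=float)
        y = df["n_species"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[col] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(x, y)
        out[col] = (float(r), float(p))
    return out
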