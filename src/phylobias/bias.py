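"""Bias of the naive estimators measured against simulation ground truth.

Given a :class:`~phylobias.simulate.SimulationRecord` the functions here
compare, tip by tip and interval by interval, what the naive procedures
report on the subsampled tree with the truth recorded by the simulator:

* origin-age inflation — naive origin ages from the sampled tree vs true
  origin ages from the fully sampled reconstructed tree, summarised as the
  mean percent inflation and the squared Pearson correlation on log–log
  scale;
* ancestral-state error — naive per-interval medians vs the true average
  trait over all complete-tree lineages alive at each interval midpoint
  (linear interpolation along a branch is the Brownian-bridge mean);
* rate bias — the naive ln(n)/t rate-through-time series vs the constant
  true net diversification rate lambda − mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .naive import interval_median_states, naive_origin_ages, naive_rate_through_time
from .phylogeny import IntervalGrid, Phylogeny, prune_to_tips
from .simulate import SimulationRecord


@dataclass
class BiasReport:
    """Per-tip (naive, true) origin-age pairs with inflation summaries.

    ``mean_percent_older`` averages the per-tip ratios, 100·mean(o/τ − 1);
    ``percent_older_of_means`` is the alternative aggregation
    100·(mean(o)/mean(τ) − 1), reported because "average inflation" is
    ambiguous between the two.  ``loglog_r2`` is the squared Pearson
    correlation of (ln o, ln τ), NaN when either side is constant.
    """

    pairs: pd.DataFrame  # columns: tip, naive_age, true_age
    mean_percent_older: float
    percent_older_of_means: float
    loglog_r2: float
    n: int


def origin_age_bias(record: SimulationRecord) -> BiasReport:
    """Compare naive origin ages on the sampled tree with the truth.

    For every sampled tip, the naive age is its parent-node age in the
    sampled tree and the true age its parent-node age in the fully sampled
    reconstructed tree.  Pruning can only merge nodes upward, so naive ages
    dominate true ages tip-wise and the mean percent inflation is >= 0.
    """
    naive = record.sampled_tree.parent_ages()
    if len(naive) < 2:
        raise ValueError("sampled tree needs >= 2 tips")
    rows = []
    for tip in sorted(naive):
        tau = record.true_origin_age[tip]
        if tau <= 0:
            raise ValueError(f"true origin age for {tip!r} must be > 0")
        rows.append({"tip": tip, "naive_age": naive[tip], "true_age": tau})
    pairs = pd.DataFrame(rows)
    ratio = pairs["naive_age"] / pairs["true_age"]
    mean_pct = 100.0 * float(ratio.mean() - 1.0)
    pct_of_means = 100.0 * float(
        pairs["naive_age"].mean() / pairs["true_age"].mean() - 1.0
    )
    ln_o, ln_t = np.log(pairs["naive_age"]), np.log(pairs["true_age"])
    if np.std(ln_o) == 0 or np.std(ln_t) == 0:
        r2 = 1.0 if np.allclose(pairs["naive_age"], pairs["true_age"]) else math.nan
    else:
        r2 = float(np.corrcoef(ln_o, ln_t)[0, 1] ** 2)
    return BiasReport(
        pairs=pairs,
        mean_percent_older=mean_pct,
        percent_older_of_means=pct_of_means,
        loglog_r2=r2,
        n=len(pairs),
    )


def true_lineage_means(record: SimulationRecord, grid: IntervalGrid) -> pd.DataFrame:
    """True average trait over complete-tree lineages alive at each interval midpoint.

    A branch is alive at age m when child age < m < parent age; its state
    at m is the linear interpolation between its endpoint states, which is
    the expected value of the Brownian bridge pinning the simulated
    endpoints.  A node exactly at m counts as already split (its state
    enters once per child branch), mirroring the time-slice convention of
    :func:`~phylobias.phylogeny.lineage_count_at`.  Intervals whose
    midpoint is older than the root are absent (NaN with zero lineages).
    """
    tree = record.complete_tree
    ages = tree.ages()
    states = record.node_states
    tol = 1e-9
    rows = []
    for k in range(grid.n_intervals):
        lo, hi = grid.bounds(k)
        m = (lo + hi) / 2
        if m > tree.crown_age + tol:
            rows.append({"interval": k, "lo": lo, "hi": hi, "n_lineages": 0,
                         "true_mean": math.nan})
            continue
        vals = []
        for node in tree.dtree.preorder_node_iter():
            a = ages[node]
            if abs(a - m) <= tol:
                mult = len(node.child_nodes()) if not node.is_leaf() else 1
                vals.extend([states[_label(node)]] * mult)
            elif (
                node is not tree.root
                and a < m
                and ages[node.parent_node] > m + tol
            ):
                a_parent = ages[node.parent_node]
                s_parent = states[_label(node.parent_node)]
                s_child = states[_label(node)]
                frac = (a_parent - m) / (a_parent - a)
                vals.append(s_parent + (s_child - s_parent) * frac)
        rows.append({
            "interval": k, "lo": lo, "hi": hi, "n_lineages": len(vals),
            "true_mean": float(np.mean(vals)) if vals else math.nan,
        })
    return pd.DataFrame(rows)


def _label(node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


@dataclass
class AsrBiasReport:
    """Naive interval medians vs true lineage means, plus a sampling-sensitivity probe."""

    table: pd.DataFrame  # interval, lo, hi, count, naive_median, true_mean, abs_error
    sensitivity: pd.DataFrame  # interval, lo, hi, median_full, median_dropped, changed
    dropped_tip: str


def asr_bias(
    record: SimulationRecord, grid: IntervalGrid, drop_seed: int = 0
) -> AsrBiasReport:
    """Absolute error of naive interval medians, and their sensitivity to one tip.

    The main table pairs the naive medians computed on the sampled tree
    with the true lineage means; ``abs_error`` is defined only for
    intervals where both sides exist.  The sensitivity table recomputes the
    medians after dropping one uniformly chosen tip from the sampled tree —
    a minimal change in taxon sampling — and reports which interval medians
    moved even though the underlying history is unchanged.
    """
    traits = record.tip_traits
    origins = naive_origin_ages(record.sampled_tree, grid)
    naive = interval_median_states(origins, traits, grid)
    truth = true_lineage_means(record, grid)
    table = naive.rename(columns={"median": "naive_median"}).merge(
        truth[["interval", "n_lineages", "true_mean"]], on="interval"
    )
    table["abs_error"] = (table["naive_median"] - table["true_mean"]).abs()

    rng = np.random.default_rng(drop_seed)
    tips = sorted(record.sampled_tree.tip_labels)
    dropped = tips[rng.integers(len(tips))]
    reduced = prune_to_tips(record.sampled_tree, set(tips) - {dropped})
    if reduced.n_tips >= 2:
        med2 = interval_median_states(
            naive_origin_ages(reduced, grid), traits, grid
        )["median"]
    else:
        med2 = pd.Series([math.nan] * grid.n_intervals)
    sens = naive[["interval", "lo", "hi"]].copy()
    sens["median_full"] = naive["median"]
    sens["median_dropped"] = med2.to_numpy()
    with np.errstate(invalid="ignore"):
        same = (sens["median_full"] == sens["median_dropped"]) | (
            sens["median_full"].isna() & sens["median_dropped"].isna()
        )
    sens["changed"] = ~same
    return AsrBiasReport(table=table, sensitivity=sens, dropped_tip=dropped)


def rate_bias_curve(record: SimulationRecord, grid: IntervalGrid) -> pd.DataFrame:
    """Naive rate-through-time on the sampled tree vs the true net rate lambda − mu."""
    if record.params is None:
        raise ValueError("record has no simulation parameters (truth unknown)")
    stem = record.sampled_tree.stem_age or record.reconstructed_tree.stem_age
    series = naive_rate_through_time(record.sampled_tree, grid, stem_age=stem)
    series = series.rename(columns={"rate": "naive_rate"})
    series["true_rate"] = record.params.lam - record.params.mu
    return series


def sampling_fraction(sampled: int, total: int) -> tuple[float, float]:
    """Percentage of described species present in the tree, exact then 2 s.f.

    Returns ``(percent, percent_2sf)`` where the first is exact rational
    arithmetic evaluated to float and the second is rounded to two
    significant figures (e.g. 232 of 359,208 -> 0.065).
    """
    if sampled <= 0:
        raise ValueError("sampled count must be > 0")
    if sampled > total:
        raise ValueError(f"sampled {sampled} exceeds total {total}")
    pct = Fraction(100 * sampled, total)
    exact = float(pct)
    return exact, float(f"{exact:.2g}")
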