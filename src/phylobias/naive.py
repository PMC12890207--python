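"""Naive diversification-rate and ancestral-trait estimators.

These are the procedures under critique, implemented exactly so their
behaviour under incomplete sampling can be measured rather than argued
about:

* per-tip "origin age" = age of the tip's parent node in the analysed
  (possibly subsampled) tree;
* per-interval "ancestral state" = median trait value of the tips whose
  origin age falls in that interval;
* clade-level diversification rate = ln(n)/t from tip count n and stem age
  t (the Magallon–Sanderson log form);
* Kendall–Moran speciation rate = (n − 2)/S from tip count and total branch
  length S, valid only for completely sampled trees without extinction;
* a rate-through-time series obtained by slicing the tree at each interval
  boundary T and computing ln(n_T)/(stem age − T).

All logarithms are natural; medians over an even number of contributors use
the mean of the two middle values; intervals with no contributors yield an
absent (NaN) median, never zero.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .phylogeny import IntervalGrid, Phylogeny, TreeError, lineage_count_at

#: Metadata stamped on outputs so interpretation choices are explicit.
LOG_BASE = "e"


def naive_origin_ages(tree: Phylogeny, grid: IntervalGrid | None = None) -> pd.DataFrame:
    """Per-tip naive origin ages: the age of each tip's parent node.

    Returns a DataFrame with columns ``tip``, ``origin_age`` and, when a
    grid is supplied, ``interval`` (the half-open age interval containing
    the origin; -1 if the origin falls beyond the grid).  On a subsampled
    tree these ages are inflated whenever the tip's true sister was not
    sampled.
    """
    if tree.n_tips < 2:
        raise TreeError("origin ages need >= 2 tips (a single tip has no split)")
    parents = tree.parent_ages()
    rows = []
    for tip in sorted(parents):
        age = parents[tip]
        row = {"tip": tip, "origin_age": age}
        if grid is not None:
            idx = grid.index_of(age)
            row["interval"] = -1 if idx is None else idx
        rows.append(row)
    return pd.DataFrame(rows)


def interval_median_states(
    origins: pd.DataFrame,
    traits: Mapping[str, float],
    grid: IntervalGrid,
) -> pd.DataFrame:
    """Median trait value per interval over the tips that originated in it.

    Returns a DataFrame with one row per grid interval: ``interval``,
    ``lo``, ``hi``, ``count`` and ``median`` (NaN when no tip originated in
    the interval).  Contributor counts sum to the number of tips whose
    origin lies inside the grid.
    """
    missing = [t for t in origins["tip"] if t not in traits]
    if missing:
        raise KeyError(f"no trait value for tip(s): {missing}")
    idx = origins.get("interval")
    if idx is None:
        idx = origins["origin_age"].map(lambda a: grid.index_of(a))
        idx = idx.fillna(-1).astype(int)
    rows = []
    for k in range(grid.n_intervals):
        lo, hi = grid.bounds(k)
        tips = origins.loc[np.asarray(idx) == k, "tip"]
        values = sorted(traits[t] for t in tips)
        med = float(np.median(values)) if values else math.nan
        rows.append({"interval": k, "lo": lo, "hi": hi, "count": len(values), "median": med})
    return pd.DataFrame(rows)


def magallon_sanderson_rate(n: int, t: float) -> float:
    """Naive clade diversification rate ln(n)/t from richness n and stem age t."""
    if n < 1:
        raise ValueError(f"tip count must be >= 1, got {n}")
    if t <= 0:
        raise ValueError(f"stem age must be > 0, got {t}")
    return math.log(n) / t


def kendall_moran_rate(tree: Phylogeny) -> float:
    """Kendall–Moran speciation rate (n − 2)/S for a complete ultrametric tree.

    S is the total branch length.  The estimator is the crown-conditioned
    pure-birth maximum-likelihood rate and assumes complete sampling and no
    extinction; applying it outside those assumptions is precisely the
    misuse this package measures.
    """
    n = tree.n_tips
    if n < 3:
        raise TreeError(f"Kendall-Moran rate needs >= 3 tips, got {n}")
    from .phylogeny import total_branch_length

    S = total_branch_length(tree)
    if S <= 0:
        raise TreeError("zero total branch length")
    return (n - 2) / S


def naive_rate_through_time(
    tree: Phylogeny, grid: IntervalGrid, stem_age: float | None = None
) -> pd.DataFrame:
    """ln(n_T)/(stem age − T) at each grid boundary T, youngest first.

    ``n_T`` is the number of lineages crossing the tree at age T (pruning
    everything younger than T and counting what remains).  Boundaries at or
    beyond the stem age are rejected; boundaries older than the crown age
    but below the stem age see a single stem lineage (rate 0).
    """
    if stem_age is None:
        stem_age = tree.stem_or_crown_age()
    if stem_age < tree.crown_age:
        raise TreeError("stem age younger than crown age")
    rows = []
    for T in grid.boundaries:
        if T >= stem_age:
            raise TreeError(f"grid boundary {T} is not below the stem age {stem_age}")
        if T > tree.crown_age:
            n_T = 1
        else:
            n_T = lineage_count_at(tree, T)
        rows.append(
            {
                "boundary": T,
                "n": n_T,
                "t": stem_age - T,
                "rate": math.log(n_T) / (stem_age - T),
            }
        )
    df = pd.DataFrame(rows).sort_values("boundary", ignore_index=True)
    df.attrs["log_base"] = LOG_BASE
    return df
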