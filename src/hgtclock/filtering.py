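"""Posterior filtering on HGT constraints and node-age summaries.

Trees are binned by how many constraints they satisfy: ``per_n[n]`` is the
set of tree indices passing *at least* n constraints, so the sets are
nested and shrink as n grows.  The selected stringency is the largest n
whose set still holds at least ``min_trees`` trees — enough to estimate an
age distribution.  Node ages are then summarized (mean and equal-tailed
credible interval, reported older-bound first) over the filtered set and
compared with the unfiltered summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronogram import PosteriorSample
from .clades import CladeDefinition, resolve_clade_age
from .compat import CompatibilityMatrix, _age_node_index
from .errors import ValidationError

#: Default smallest acceptable filtered-set size.  Chosen just below the
#: 28-tree set accepted in practice; always user-overridable.
DEFAULT_MIN_TREES = 25


@dataclass
class FilterSweep:
    """Sets of trees passing >= n constraints, for n = 1..N."""

    per_n: dict
    n_trees: int
    selected_n: int | None = None
    min_trees: int | None = None

    def sizes(self) -> pd.Series:
        return pd.Series({n: len(s) for n, s in self.per_n.items()},
                         name="trees_passing")


def sweep_filter(matrix: CompatibilityMatrix) -> FilterSweep:
    """Compile the nested sets of trees passing >= n constraints."""
    if matrix.n_trees == 0 or matrix.n_constraints == 0:
        raise ValidationError("compatibility matrix is empty")
    vals = matrix.values.to_numpy(dtype=bool)
    row_sums = vals.sum(axis=1)
    per_n = {n: frozenset(np.flatnonzero(row_sums >= n).tolist())
             for n in range(1, matrix.n_constraints + 1)}
    return FilterSweep(per_n=per_n, n_trees=matrix.n_trees)


def select_n(sweep: FilterSweep, min_trees: int = DEFAULT_MIN_TREES) -> int:
    """Most stringent n whose set still holds >= ``min_trees`` trees.

    Returns 0 when even n=1 leaves too few trees — the degenerate signal;
    the caller should then report unfiltered ages with a warning.
    """
    if min_trees < 1:
        raise ValueError("min_trees must be >= 1")
    sweep.min_trees = min_trees
    for n in sorted(sweep.per_n, reverse=True):
        if len(sweep.per_n[n]) >= min_trees:
            sweep.selected_n = n
            return n
    sweep.selected_n = 0
    return 0


@dataclass
class AgeSummary:
    """Posterior age summary for one clade: mean and 95% CI bounds,
    reported older-bound first, as in dating-study tables."""

    clade: str
    group_kind: str
    mean: float
    ci_older: float
    ci_younger: float
    n_trees: int
    filtered: bool

    @property
    def ci_width(self) -> float:
        return self.ci_older - self.ci_younger


def _hpd(ages: np.ndarray, level: float) -> tuple:
    """Shortest interval containing ``level`` of the sample
    (highest posterior density, assuming unimodality)."""
    s = np.sort(ages)
    n = len(s)
    k = max(1, int(np.ceil(level * n)))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1:] - s[: n - k + 1]
    j = int(np.argmin(widths))
    return float(s[j]), float(s[j + k - 1])


def summarize_ages(sample: PosteriorSample, subset, clades,
                   ci_level: float = 0.95,
                   interval: str = "equal-tailed") -> list:
    """Mean and credible interval of each clade's age over a tree subset.

    ``subset`` is an iterable of tree indices (``None`` for all trees).
    The default interval is equal-tailed percentiles with linear
    interpolation between order statistics; ``interval="hpd"`` gives the
    shortest (highest-density) interval instead.
    """
    if interval not in ("equal-tailed", "hpd"):
        raise ValueError(f"unknown interval type {interval!r}")
    all_idx = range(len(sample))
    if subset is None:
        subset = list(all_idx)
    else:
        subset = sorted(set(int(i) for i in subset))
    if not subset:
        raise ValidationError(
            "the filtered tree set is empty; lower min_trees (or accept "
            "the unfiltered summary)")
    filtered = set(subset) != set(all_idx)
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    shared = sample.shares_topology()
    ages_mat = sample.ages_matrix() if shared else None
    out = []
    for clade in clades:
        if shared:
            idx = _age_node_index(sample.trees[0], clade)
            ages = ages_mat[subset, idx]
        else:
            ages = np.array([resolve_clade_age(sample.trees[i], clade,
                                               tree_index=i).age
                             for i in subset])
        if interval == "hpd":
            lo, hi = _hpd(ages, ci_level)
        else:
            lo, hi = np.percentile(ages, [lo_q, hi_q])
        out.append(AgeSummary(clade=clade.name, group_kind=clade.group_kind,
                              mean=float(ages.mean()), ci_older=float(hi),
                              ci_younger=float(lo), n_trees=len(subset),
                              filtered=filtered))
    return out


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.clade, s.group_kind, s.mean, s.ci_older, s.ci_younger,
          s.n_trees, s.filtered) for s in summaries],
        columns=["clade", "group_kind", "mean", "ci_older", "ci_younger",
                 "n_trees", "filtered"])


def compare_filtered(unfiltered, filtered) -> pd.DataFrame:
    """Per-clade shift table: delta_mean (negative = younger after
    filtering) and delta CI width (negative = more precise)."""
    un = {s.clade: s for s in unfiltered}
    fi = {s.clade: s for s in filtered}
    if list(un) != list(fi):
        raise ValidationError("summaries cover different clade lists")
    rows = []
    for name, u in un.items():
        f = fi[name]
        rows.append((name, u.group_kind, f.mean - u.mean,
                     f.ci_width - u.ci_width))
    return pd.DataFrame(rows, columns=["clade", "group_kind", "delta_mean",
                                       "delta_ci_width"])
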