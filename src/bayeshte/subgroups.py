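"""Quintile-based subgrouping of baseline variables, respecting tied values.

Each heterogeneity analysis splits a baseline severity marker into five
ordered subgroups of near-equal size.  Patients sharing an identical value
must never be split across groups, so with heavily tied data the groups
cannot be exact quintiles; instead the variable's distinct values are treated
as indivisible blocks and partitioned into five contiguous runs *nearest to
equal size*.  Because the number of groups is fixed, minimizing the summed
squared deviation of group sizes from n/5 is equivalent to minimizing the sum
of squared group sizes, which is solved exactly by dynamic programming over
the tie blocks (ties in the objective resolved towards the earliest cuts,
compared from the last cut backwards).

Norepinephrine dose is zero-inflated: with ``zero_mass_group`` set, all exact
zeros (non-users) form the first group and the positive doses are partitioned
into four near-equal groups, keeping five groups in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["SubgroupScheme", "quintile_subgroups", "assign_subgroup"]


@dataclass(frozen=True)
class SubgroupScheme:
    """Ordered value ranges and per-patient assignments for one variable."""

    variable: str
    labels: tuple[str, ...]
    lowers: tuple[float, ...]  # smallest observed value in each group
    uppers: tuple[float, ...]  # largest observed value in each group
    assignments: np.ndarray  # group index per input row; -1 for missing
    counts: tuple[int, ...]
    zero_mass_group: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.labels,
            "lower": self.lowers,
            "upper": self.uppers,
            "n": self.counts,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _optimal_contiguous_partition(counts: np.ndarray, n_groups: int) -> list[int]:
    """Split blocks (given their sizes, in value order) into ``n_groups``
    contiguous nonempty runs minimizing the sum of squared run sizes.

    Returns the end index (exclusive) of each run.  Ties are broken towards
    the smallest predecessor index at every DP state, i.e. the cut sequence
    minimal under right-to-left lexicographic comparison.
    """
    b = len(counts)
    m = min(b, n_groups)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    # best[j]: minimal cost of partitioning blocks[:j] into t runs
    best = (csum[1:] ** 2).copy()  # t = 1
    back = [np.zeros(b, dtype=int)]
    for t in range(2, m + 1):
        # candidate[i, j] = best_{t-1}[i] + (csum[j+1] - csum[i+1])^2, i < j
        seg = (csum[None, 1:] - csum[1:, None]) ** 2  # seg[i, j] for end j+1, split i+1
        cand = best[:, None] + seg
        mask = np.tril(np.ones((b, b), dtype=bool))  # i >= j leaves an empty run
        cand[mask] = np.inf
        prev = np.argmin(cand, axis=0)  # first minimal index = smallest i
        best = cand[prev, np.arange(b)]
        back.append(prev)
    # Reconstruct ends from the final state (all b blocks used).
    ends = []
    j = b - 1
    for t in range(m, 0, -1):
        ends.append(j + 1)
        if t > 1:
            j = back[t - 1][j]
    return ends[::-1]


def _partition_values(values: np.ndarray, n_groups: int):
    """Partition sorted unique ``values`` (with multiplicity) into runs."""
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) < n_groups:
        warnings.warn(
            f"only {len(uniq)} distinct values; forming {len(uniq)} groups "
            f"instead of {n_groups}", stacklevel=3)
    ends = _optimal_contiguous_partition(counts.astype(float), n_groups)
    starts = [0] + ends[:-1]
    lowers = [float(uniq[s]) for s in starts]
    uppers = [float(uniq[e - 1]) for e in ends]
    sizes = [int(counts[s:e].sum()) for s, e in zip(starts, ends)]
    # Map each unique value to its group.
    group_of_uniq = np.empty(len(uniq), dtype=int)
    for g, (s, e) in enumerate(zip(starts, ends)):
        group_of_uniq[s:e] = g
    return uniq, group_of_uniq, lowers, uppers, sizes


def quintile_subgroups(
    values,
    zero_mass_group: bool = False,
    n_groups: int = 5,
    variable: str = "x",
) -> SubgroupScheme:
    """Build near-equal-size ordered subgroups of a baseline variable.

    Parameters
    ----------
    values
        Numeric vector (NaN = missing).  All patients sharing a value are
        assigned to the same group.
    zero_mass_group
        If set, exact zeros form the first group on their own and the
        positive values are split into ``n_groups - 1`` near-equal groups
        (the zero-inflated norepinephrine-dose convention).
    """
    arr = np.asarray(pd.to_numeric(pd.Series(values)), dtype=float)
    present = ~np.isnan(arr)
    if not present.any():
        raise InputError(f"{variable}: all values missing; cannot form subgroups")
    obs = arr[present]
    assignments = np.full(arr.shape, -1, dtype=int)

    if zero_mass_group:
        zeros = obs == 0.0
        positives = obs[~zeros]
        if len(positives) == 0:
            raise InputError(f"{variable}: zero_mass_group set but no positive values")
        uniq, g_of_u, lowers, uppers, sizes = _partition_values(positives, n_groups - 1)
        obs_groups = np.zeros(len(obs), dtype=int)
        obs_groups[~zeros] = 1 + g_of_u[np.searchsorted(uniq, positives)]
        lowers = [0.0] + lowers
        uppers = [0.0] + uppers
        sizes = [int(zeros.sum())] + sizes
    else:
        uniq, g_of_u, lowers, uppers, sizes = _partition_values(obs, n_groups)
        obs_groups = g_of_u[np.searchsorted(uniq, obs)]

    assignments[present] = obs_groups
    labels = tuple(f"{lo:g}–{hi:g}" for lo, hi in zip(lowers, uppers))
    return SubgroupScheme(
        variable=variable, labels=labels,
        lowers=tuple(lowers), uppers=tuple(uppers),
        assignments=assignments, counts=tuple(sizes),
        zero_mass_group=zero_mass_group,
    )


def assign_subgroup(scheme: SubgroupScheme, value: float) -> int:
    """Deterministic group index for a (possibly new) value.

    A value equal to a group's upper boundary falls to that (lower) group;
    values outside every observed range go to the nearest boundary group with
    a warning.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise InputError(f"{scheme.variable}: cannot assign a missing value")
    if value < scheme.lowers[0] or value > scheme.uppers[-1]:
        warnings.warn(
            f"{scheme.variable}: value {value} outside observed range "
            f"[{scheme.lowers[0]}, {scheme.uppers[-1]}]; assigned to nearest group",
            stacklevel=2)
    cuts = np.asarray(scheme.uppers[:-1])
    return int(np.searchsorted(cuts, value, side="left"))
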