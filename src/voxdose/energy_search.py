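"""Energy-interval location on a pointwise cross-section grid.

Cross-section libraries tabulate data on an energy grid whose nodes are not
uniformly spaced, so evaluating sigma(E) first requires finding the interval
``grid[j] <= E < grid[j+1]``.  Two interchangeable strategies are provided:

* :func:`binary_interval` — classic bisection, O(log n) comparisons.
* :func:`hash_interval`   — an auxiliary table of nodes uniform in ln(E) is
  built once per grid (:func:`build_hash_index`); a lookup maps E onto that
  uniform grid in O(1) and finishes with a short forward scan.  When the
  uniform grid is denser than the original one the scan touches O(1) nodes.

Both share one edge convention: intervals are left-closed, an energy equal to
an interior node belongs to the interval starting at that node, and E equal
to the grid maximum is assigned to the last interval.  The two routines are
exactly equivalent on the whole valid domain, which is what makes the hash
table a pure acceleration rather than a physics change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpCounter",
    "HashIndex",
    "build_hash_index",
    "binary_interval",
    "hash_interval",
]


class OpCounter:
    """Counts elementary comparisons so lookup cost is testable without clocks."""

    __slots__ = ("comparisons",)

    def __init__(self) -> None:
        self.comparisons = 0

    def reset(self) -> None:
        self.comparisons = 0


def _check_in_range(grid: np.ndarray, energy: float) -> None:
    if not grid[0] <= energy <= grid[-1]:
        raise ValueError(
            f"energy {energy!r} eV outside grid range [{grid[0]!r}, {grid[-1]!r}]"
        )


def binary_interval(grid: np.ndarray, energy: float, counter: OpCounter | None = None) -> int:
    """Locate j with ``grid[j] <= energy < grid[j+1]`` by bisection.

    ``energy == grid[-1]`` returns the last interval index ``len(grid) - 2``.
    """
    grid = np.asarray(grid)
    _check_in_range(grid, energy)
    lo, hi = 0, len(grid) - 1
    ncomp = 0
    # invariant: grid[lo] <= energy, grid[hi] >= energy
    while hi - lo > 1:
        mid = (lo + hi) // 2
        ncomp += 1
        if energy < grid[mid]:
            hi = mid
        else:
            lo = mid
    if counter is not None:
        counter.comparisons += ncomp
    return lo


@dataclass(frozen=True)
class HashIndex:
    """Acceleration table over an energy grid.

    ``M`` nodes uniform in ln(E) span exactly the old grid's range.  For each
    of the M-1 uniform intervals, ``first_old_node`` holds the index of the
    last old node at or below the interval's lower edge, so a lookup needs
    only a forward scan from there.
    """

    emin: float
    emax: float
    M: int
    first_old_node: np.ndarray  # int64, length M-1, nondecreasing

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError(f"hash index needs M >= 2, got M={self.M}")
        if np.any(np.diff(self.first_old_node) < 0):
            raise ValueError("first_old_node must be nondecreasing")


def build_hash_index(grid: np.ndarray, M: int | None = None) -> HashIndex:
    """Build the uniform-in-ln(E) lookup table for ``grid``.

    Default M is 4x the node count rounded up to a power of two, dense enough
    that most uniform intervals contain at most one old node.
    """
    grid = np.asarray(grid, dtype=np.float64)
    n = len(grid)
    if n < 2:
        raise ValueError("grid needs at least 2 nodes")
    if M is None:
        M = 1 << max(1, math.ceil(math.log2(4 * n)))
    if M < 2:
        raise ValueError(f"hash index needs M >= 2, got M={M}")
    ln_min = math.log(grid[0])
    ln_max = math.log(grid[-1])
    # lower edges of the M-1 uniform intervals spanned by M nodes on
    # [ln Emin, ln Emax]; an already log-uniform grid with M = node count
    # aligns exactly, giving first_old_node = [0, 1, 2, ...]
    u = np.arange(M - 1, dtype=np.float64)
    edges = np.exp(ln_min + u * (ln_max - ln_min) / (M - 1))
    # a node within 1 ulp-ish of an edge counts as on it (aligned grids);
    # the lookup's backward guard makes any residual round-off harmless
    first = np.searchsorted(grid, edges * (1.0 + 1e-12), side="right") - 1
    np.clip(first, 0, n - 2, out=first)
    return HashIndex(emin=float(grid[0]), emax=float(grid[-1]), M=M,
                     first_old_node=first.astype(np.int64))


def hash_interval(
    index: HashIndex,
    grid: np.ndarray,
    energy: float,
    counter: OpCounter | None = None,
) -> int:
    """Locate the old-grid interval for ``energy`` via the hash table.

    Maps E onto the uniform ln-grid, u = floor((ln E - ln Emin) * M /
    (ln Emax - ln Emin)) clamped to [0, M-2], then scans from
    ``first_old_node[u]``.  The factor-M map can land one cell to the right
    of the cell the table was built for; the short backward guard absorbs
    that (and any exp/ln round-off), so the result is identical to
    :func:`binary_interval` for every valid energy.
    """
    grid = np.asarray(grid)
    _check_in_range(grid, energy)
    span = math.log(index.emax) - math.log(index.emin)
    u = int((math.log(energy) - math.log(index.emin)) * index.M / span)
    if u < 0:
        u = 0
    elif u > index.M - 2:
        u = index.M - 2
    j = int(index.first_old_node[u])
    # guard against exp/ln round-off at uniform-interval edges
    while j > 0 and grid[j] > energy:
        j -= 1
    last = len(grid) - 2
    ncomp = 0
    while j < last:
        ncomp += 1
        if energy < grid[j + 1]:
            break
        j += 1
    if counter is not None:
        counter.comparisons += ncomp
    return j
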