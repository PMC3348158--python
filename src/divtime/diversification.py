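"""Split-age extraction and summaries for a category of species.

The unit of analysis is the *diversification event*: an internal node of
the chronogram induced by a chosen tip set, dated by its node age.  A
polytomy of k children stands for the k-1 bifurcations it collapses, so
every tree of n tips carries a total event weight of n-1 regardless of
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .chronogram_io import AgeBound, Chronogram, ChronogramError, Node

__all__ = [
    "EventSet",
    "LTTCurve",
    "prune_to_taxa",
    "split_events",
    "median_event_age",
    "event_histogram",
    "ltt_curve",
]


@dataclass(frozen=True)
class EventSet:
    """Weighted multiset of split ages (Myr) for one taxon subset."""

    ages: tuple[float, ...]
    weights: tuple[int, ...]
    category: Optional[str] = None
    bound: AgeBound = AgeBound.MEAN

    def __post_init__(self):
        if len(self.ages) != len(self.weights):
            raise ValueError("ages and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive integers")
        if any(a < 0 for a in self.ages):
            raise ValueError("ages must be >= 0")

    @property
    def total_weight(self) -> int:
        return int(sum(self.weights))

    def expanded(self) -> np.ndarray:
        """Ages repeated by weight, sorted ascending."""
        return np.sort(np.repeat(np.asarray(self.ages, float), self.weights))

    def __len__(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class LTTCurve:
    """Lineage-through-time curve: (age Myr, lineage count) from the root
    (oldest age, count = root degree) to the present (age 0, count = n_tips)."""

    ages: tuple[float, ...]
    counts: tuple[int, ...]


def prune_to_taxa(tree: Chronogram, keep: Iterable[str]) -> Chronogram:
    """Restrict a chronogram to a subset of tips.

    Degree-2 internal nodes created by the pruning are suppressed; every
    surviving internal node keeps its original age, which by construction
    equals the age of the most recent common ancestor (in the input tree)
    of its descendant kept tips.  Age intervals travel with the nodes.
    """
    keep = set(keep)
    if len(keep) < 2:
        raise ChronogramError(f"need >= 2 tips to prune to, got {len(keep)}")
    unknown = keep - set(tree.tip_labels())
    if unknown:
        raise ChronogramError(f"unknown tip label(s): {sorted(unknown)[:5]}")

    def _prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            if node.label not in keep:
                return None
            return Node(node.label, node.age, node.age_interval)
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(node.label, node.age, node.age_interval)
        for c in kept:
            new.add_child(c)
        return new

    root = _prune(tree.root)
    assert root is not None and not root.is_tip
    return Chronogram(root)


def split_events(
    tree: Chronogram,
    bound: AgeBound | str = AgeBound.MEAN,
    category: Optional[str] = None,
) -> EventSet:
    """Record the date of each split in the tree.

    One entry per internal node, weighted by (child count - 1); ages are
    read under ``bound`` (requires intervals on all internal nodes for
    lower/upper).  Total weight is always n_tips - 1.
    """
    bound = AgeBound.coerce(bound)
    if tree.n_tips < 2:
        raise ChronogramError("need >= 2 tips to have split events")
    ages, weights = [], []
    for node in tree.internal_nodes():
        ages.append(node.age_at(bound))
        weights.append(len(node.children) - 1)
    return EventSet(tuple(ages), tuple(weights), category=category, bound=bound)


def median_event_age(events: EventSet) -> float:
    """Weighted median split age: ages expanded by weight; for an even
    total the midpoint is the mean of the two central values."""
    if len(events) == 0:
        raise ValueError("empty EventSet has no median")
    return float(np.median(events.expanded()))


def event_histogram(
    events: EventSet, bin_width: float = 20.0, t_max: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of event ages in bins [0, w), [w, 2w), ... covering
    [0, t_max].

    Bins are half-open on the right except the last, which includes its
    upper edge so that an event exactly at ``t_max`` (typically the root)
    is counted and total weight is conserved.  Returns
    ``(counts, bin_edges)`` with counts summing event weights; empty bins
    are reported as 0, never omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ages = np.asarray(events.ages, float)
    weights = np.asarray(events.weights, float)
    if t_max is None:
        t_max = float(ages.max(initial=0.0))
    n_bins = max(1, math.ceil(t_max / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    if ages.size and ages.max() > edges[-1]:
        extra = math.ceil((ages.max() - edges[-1]) / bin_width)
        edges = np.arange(n_bins + extra + 1) * bin_width
    counts, _ = np.histogram(ages, bins=edges, weights=weights)
    return counts, edges


def ltt_curve(tree: Chronogram) -> LTTCurve:
    """Lineage-through-time curve of the extant tips.

    Starting from the root (count = root child count), each internal node
    encountered while moving toward the present adds (child count - 1)
    lineages; nodes sharing an age are merged into a single step.  The
    final count equals the number of tips at age 0.
    """
    if tree.n_tips < 2:
        raise ChronogramError("need >= 2 tips for an LTT curve")
    nodes = sorted(tree.internal_nodes(), key=lambda n: -n.age)
    ages: list[float] = []
    counts: list[int] = []
    running = 1  # the single root lineage before its first split
    for node in nodes:
        running += len(node.children) - 1
        if ages and math.isclose(node.age, ages[-1], rel_tol=0, abs_tol=0):
            counts[-1] = running
        else:
            ages.append(node.age)
            counts.append(running)
    if not math.isclose(ages[-1], 0.0, abs_tol=1e-12):
        ages.append(0.0)
        counts.append(running)
    assert counts[-1] == tree.n_tips
    return LTTCurve(tuple(ages), tuple(counts))
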