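"""Synthetic chronograms, status labellings, age intervals and alignments.

The empirical chronogram this analysis was designed for (a dated tree of a
few hundred Mediterranean teleosts with per-node 95% credibility
intervals) is not redistributable, so every downstream stage is exercised
on simulated stand-ins with the statistical structure the analysis
assumes:

* birth-death trees with extinct lineages pruned (extant species only),
* status labels that are either exchangeable across tips or enriched in
  clades originating inside a chosen time window (the signal the
  randomization test is built to detect),
* multiplicative age intervals around each internal node age,
* per-locus alignment fixtures whose dominant missingness mode is whole
  unsequenced taxon-by-locus blocks.

All randomness flows from one explicit integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chronogram_io import (
    Chronogram,
    Node,
    STATUSES,
    TaxonTable,
)
import pandas as pd

__all__ = [
    "Epoch",
    "BDParams",
    "LabelScheme",
    "SimulationError",
    "simulate_bd_chronogram",
    "assign_categories",
    "synthesize_age_intervals",
    "make_alignment_fixture",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its stopping rule."""


@dataclass(frozen=True)
class Epoch:
    """Constant birth/death rates over a forward-time interval.

    ``start``/``end`` are measured forward from the origin of the process
    (Myr); the last epoch may be open-ended (``end=None``).  Rates are per
    lineage per Myr.
    """

    start: float
    end: Optional[float]
    birth: float
    death: float = 0.0

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be >= 0")
        if self.end is not None and self.end <= self.start:
            raise ValueError("epoch end must exceed start")


@dataclass(frozen=True)
class BDParams:
    """Birth-death simulation settings with exactly one stopping rule."""

    epochs: tuple[Epoch, ...]
    n_tips: Optional[int] = None
    duration: Optional[float] = None
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self):
        if (self.n_tips is None) == (self.duration is None):
            raise ValueError("set exactly one of n_tips / duration")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not self.epochs:
            raise ValueError("at least one epoch required")
        t = 0.0
        for ep in self.epochs:
            if not math.isclose(ep.start, t, abs_tol=1e-12):
                raise ValueError("epochs must be contiguous from 0")
            if ep.end is None:
                break
            t = ep.end

    @classmethod
    def constant(cls, birth: float, death: float = 0.0, *,
                 n_tips: Optional[int] = None, duration: Optional[float] = None,
                 seed: int = 0) -> "BDParams":
        """Single-epoch constant-rate process (the common case)."""
        return cls(epochs=(Epoch(0.0, None, birth, death),),
                   n_tips=n_tips, duration=duration, seed=seed)

    def rates_at(self, t: float) -> tuple[float, float]:
        for ep in self.epochs:
            if ep.end is None or t < ep.end:
                return ep.birth, ep.death
        ep = self.epochs[-1]
        return ep.birth, ep.death


@dataclass(frozen=True)
class LabelScheme:
    """How tip statuses are assigned.

    ``proportions`` mode draws each tip's status independently from the
    given per-status probabilities.  ``clade_enriched`` mode first marks
    every tip descending from a node whose age lies inside
    ``window=(age_low, age_high)``; each marked tip receives
    ``target_status`` with probability ``strength``, and every other tip
    (and each marked tip that misses the coin flip) is drawn from
    ``proportions`` renormalized over the remaining statuses.
    """

    mode: str = "proportions"
    proportions: dict[str, float] = field(
        default_factory=lambda: {"endemic": 0.1, "native": 0.73, "exotic": 0.17}
    )
    target_status: str = "endemic"
    window: tuple[float, float] = (0.0, 50.0)
    strength: float = 1.0

    def __post_init__(self):
        if self.mode not in ("proportions", "clade_enriched"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for s in self.proportions:
            if s not in STATUSES:
                raise ValueError(f"unknown status {s!r}")
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"proportions sum to {total}, not 1")
        if self.mode == "clade_enriched":
            lo, hi = self.window
            if not lo < hi:
                raise ValueError("window age_low must be < age_high")
            if not 0.0 <= self.strength <= 1.0:
                raise ValueError("strength must be in [0, 1]")
            if self.target_status not in STATUSES:
                raise ValueError(f"unknown status {self.target_status!r}")


# ---------------------------------------------------------------------
# Birth-death simulation
# ---------------------------------------------------------------------


class _Lineage:
    __slots__ = ("node", "birth_time")

    def __init__(self, node: Node, birth_time: float):
        self.node = node
        self.birth_time = birth_time


def _simulate_once(params: BDParams, rng: np.random.Generator):
    """One forward pass. Returns (root Node of full tree, present time,
    node birth-time map) or None if the process died out / stayed trivial."""
    root = Node()
    extant = [_Lineage(root, 0.0)]
    times: dict[int, float] = {id(root): 0.0}
    t = 0.0
    while True:
        n = len(extant)
        if n == 0:
            return None
        birth, death = params.rates_at(t)
        total_rate = n * (birth + death)
        if total_rate == 0:
            # static process: only a duration rule can terminate it
            if params.duration is None and (
                params.n_tips is None or n != params.n_tips
            ):
                return None
            t_next = math.inf
        else:
            t_next = t + rng.exponential(1.0 / total_rate)

        if params.duration is not None and t_next >= params.duration:
            present = params.duration
            break
        if params.n_tips is not None and n == params.n_tips:
            # stop strictly before the next event fires
            present = t_next
            break

        # epoch boundary between t and t_next: re-draw from the boundary
        boundary = None
        for ep in params.epochs:
            if ep.end is not None and t < ep.end < t_next:
                boundary = ep.end
                break
        if boundary is not None:
            t = boundary
            continue

        t = t_next
        idx = rng.integers(n)
        lineage = extant[idx]
        is_birth = True if death == 0 else rng.random() < birth / (birth + death)
        if is_birth:
            # the lineage's node becomes the split node, dated at t
            left, right = Node(), Node()
            lineage.node.add_child(left)
            lineage.node.add_child(right)
            times[id(lineage.node)] = t
            extant[idx] = _Lineage(left, t)
            extant.append(_Lineage(right, t))
        else:
            # extinction: drop the lineage; its node stays a (dead) tip
            extant[idx] = extant[-1]
            extant.pop()

    survivors = {id(l.node) for l in extant}
    if len(survivors) < 2:
        return None
    return root, present, times, survivors


def _reconstruct(root: Node, present: float, times: dict[int, float],
                 survivors: set[int]) -> Chronogram:
    """Prune extinct lineages, suppress unary nodes, convert times to ages."""

    def _prune(node: Node) -> Optional[Node]:
        if not node.children:
            if id(node) not in survivors:
                return None
            return Node(age=0.0)  # label assigned later
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(age=present - times[id(node)])
        for c in kept:
            new.add_child(c)
        return new

    new_root = _prune(root)
    assert new_root is not None and len(new_root.children) >= 2
    tree = Chronogram(new_root)
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i}"
    return tree


def simulate_bd_chronogram(params: BDParams) -> Chronogram:
    """Simulate a birth-death chronogram of extant species.

    Forward Gillespie simulation under the epoch rates, stopping either
    when the extant lineage count first reaches ``n_tips`` (the present
    is then placed just before the next event would fire) or at
    ``duration`` Myr after the origin.  Extinct lineages are pruned and
    the root of the returned tree is the most recent common ancestor of
    the survivors, so the output is ultrametric with >= 2 tips.  A pass
    in which the process dies out (or leaves < 2 survivors) is retried
    with fresh randomness, up to ``params.max_retries`` times.
    """
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_retries):
        result = _simulate_once(params, rng)
        if result is None:
            continue
        root, present, times, survivors = result
        tree = _reconstruct(root, present, times, survivors)
        if params.n_tips is not None and tree.n_tips != params.n_tips:
            continue
        return tree
    raise SimulationError(
        f"no surviving tree in {params.max_retries} attempts "
        f"(rates may imply near-certain extinction)"
    )


# ---------------------------------------------------------------------
# Status labelling + taxonomy synthesis
# ---------------------------------------------------------------------


def _carve_genera(tree: Chronogram, rng: np.random.Generator) -> dict[str, int]:
    """Partition tips into genera that are maximal clades of expected
    size ~ 1 + Geometric(0.5).  Returns tip label -> genus index."""
    assignment: dict[str, int] = {}
    counter = 0

    def _tips_of(node: Node) -> list[Node]:
        return [n for n in Chronogram(node).preorder() if n.is_tip]

    def _carve(node: Node) -> None:
        nonlocal counter
        size = _count(node)
        target = 1 + rng.geometric(0.5)
        if node.is_tip or size <= target:
            for tip in _tips_of(node):
                assignment[tip.label] = counter
            counter += 1
            return
        for child in node.children:
            _carve(child)

    def _count(node: Node) -> int:
        return sum(1 for n in Chronogram(node).preorder() if n.is_tip)

    _carve(tree.root)
    return assignment


def assign_categories(
    tree: Chronogram,
    scheme: LabelScheme,
    seed: int,
    genera_per_family: int = 5,
    families_per_order: int = 5,
) -> TaxonTable:
    """Label every tip with a status and a synthetic taxonomy.

    Genera are maximal clades (expected size ~2 tips, so sister tips
    frequently share a genus); families group ~``genera_per_family``
    consecutive genera in tree order and orders group
    ~``families_per_order`` consecutive families.  Only the relative
    containment genus < family < order matters downstream (grafting).
    """
    rng = np.random.default_rng(seed)
    tips = tree.tips()
    genus_of = _carve_genera(tree, rng)

    statuses = list(scheme.proportions.keys())
    probs = np.array([scheme.proportions[s] for s in statuses], dtype=float)

    if scheme.mode == "clade_enriched":
        eligible = _window_tips(tree, scheme.window)
        if not eligible:
            raise ValueError(
                f"no clade originates inside window {scheme.window}; "
                f"cannot enrich"
            )
        rest = [s for s in statuses if s != scheme.target_status]
        rest_probs = np.array([scheme.proportions[s] for s in rest], dtype=float)
        if rest_probs.sum() == 0:
            rest_probs = np.ones(len(rest)) / max(len(rest), 1)
        else:
            rest_probs = rest_probs / rest_probs.sum()
        labels = {}
        for tip in tips:
            if tip.label in eligible and rng.random() < scheme.strength:
                labels[tip.label] = scheme.target_status
            else:
                labels[tip.label] = rest[rng.choice(len(rest), p=rest_probs)] \
                    if rest else scheme.target_status
    else:
        draws = rng.choice(len(statuses), size=len(tips), p=probs)
        labels = {tip.label: statuses[d] for tip, d in zip(tips, draws)}

    rows = []
    for tip in tips:
        g = genus_of[tip.label]
        fam = g // genera_per_family
        order = fam // families_per_order
        rows.append(
            dict(
                species=tip.label,
                genus=f"Genus{g:04d}",
                family=f"Family{fam:03d}",
                order=f"Order{order:02d}",
                status=labels[tip.label],
            )
        )
    return TaxonTable(pd.DataFrame(rows))


def _window_tips(tree: Chronogram, window: tuple[float, float]) -> set[str]:
    """Tips descending from (or at) a node whose age lies in the window."""
    lo, hi = window
    eligible: set[str] = set()

    def _walk(node: Node, under: bool) -> None:
        here = under or (not node.is_tip and lo <= node.age <= hi)
        if node.is_tip and here:
            eligible.add(node.label)
        for child in node.children:
            _walk(child, here)

    _walk(tree.root, False)
    return eligible


# ---------------------------------------------------------------------
# Age intervals
# ---------------------------------------------------------------------


def synthesize_age_intervals(
    tree: Chronogram, relative_halfwidth: float, seed: int
) -> Chronogram:
    """Attach a multiplicative age interval to every internal node.

    Each internal node of age ``a`` receives ``(a*(1-u), a*(1+u))`` with
    ``u`` drawn uniformly on ``(0, relative_halfwidth]``, emulating a
    posterior credibility interval.  Parent/child intervals may overlap,
    as they do in real relaxed-clock posteriors.  Returns a new tree;
    the input is not modified.
    """
    if not 0.0 < relative_halfwidth < 1.0:
        raise ValueError("relative_halfwidth must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in out.preorder():
        if node.is_tip:
            continue
        u = relative_halfwidth * (1.0 - rng.random())  # uniform on (0, hw]
        node.age_interval = (node.age * (1.0 - u), node.age * (1.0 + u))
    return out


# ---------------------------------------------------------------------
# Alignment fixtures
# ---------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_alignment_fixture(
    lengths: Sequence[int],
    n_taxa: int,
    missing_fraction: float = 0.0,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> dict[str, list[tuple[str, str]]]:
    """Generate one aligned FASTA per locus over a shared taxon set.

    Each taxon-by-locus block is independently replaced by all-``?``
    with probability ``missing_fraction``, emulating unsequenced loci
    (the dominant missingness mode of real multi-locus supermatrices).
    Returns ``{locus_name: [(taxon, sequence), ...]}``; when ``out_dir``
    is given, also writes ``locus_<i>.fasta`` files there.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("locus lengths must be positive")
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError("missing_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(1, n_taxa + 1)]
    loci: dict[str, list[tuple[str, str]]] = {}
    for li, length in enumerate(lengths, start=1):
        name = f"locus_{li}"
        records = []
        for taxon in taxa:
            if rng.random() < missing_fraction:
                seq = "?" * length
            else:
                seq = "".join(rng.choice(_BASES, size=length))
            records.append((taxon, seq))
        loci[name] = records
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, records in loci.items():
            with open(out_dir / f"{name}.fasta", "w") as fh:
                for taxon, seq in records:
                    fh.write(f">{taxon}\n{seq}\n")
    return loci
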