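"""Taxonomic grafting of sequence-less species onto a backbone chronogram.

Species without molecular data are attached as polytomies at the most
recent common ancestor (MRCA) of increasingly inclusive taxonomic ranks:

1. ``two_congeners``  — >= 2 congeners on the backbone: attach at their MRCA;
2. ``one_congener``   — exactly 1 congener: attach at that tip's parent
   (the node linking the congener with its closest relative);
3. ``family``         — >= 1 confamilial: attach at the MRCA of all backbone
   members of the family (a single member's MRCA is its parent node);
4. ``order``          — likewise at the ordinal level.

Each grafted tip receives a branch length equal to the age of its
attachment node, so the enriched tree stays ultrametric.  Running the
ladder with cumulative prefixes of these levels yields a series of
chronograms of increasing taxonomic coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .chronogram_io import Chronogram, ChronogramError, Node, TaxonTable

__all__ = [
    "GraftRequest",
    "GraftPlacement",
    "GraftReport",
    "LEVELS",
    "find_attachment",
    "apply_grafts",
    "chronogram_series",
]

LEVELS = ("two_congeners", "one_congener", "family", "order")


@dataclass(frozen=True)
class GraftRequest:
    """A species to add, with the taxonomy used to place it."""

    species: str
    genus: str
    family: str
    order: str
    status: str = "native"

    @classmethod
    def from_table(cls, taxa: TaxonTable, species: str) -> "GraftRequest":
        rec = taxa.record(species)
        return cls(species=rec["species"], genus=rec["genus"],
                   family=rec["family"], order=rec["order"], status=rec["status"])


@dataclass(frozen=True)
class GraftPlacement:
    """Where (if anywhere) one requested species was attached."""

    species: str
    level: str  # one of LEVELS or "unplaced"
    node_age: Optional[float]  # attachment node age; None if unplaced
    branch_length: Optional[float]  # always equals node_age when placed


@dataclass(frozen=True)
class GraftReport:
    placements: tuple[GraftPlacement, ...]

    def placed(self) -> list[GraftPlacement]:
        return [p for p in self.placements if p.level != "unplaced"]

    def unplaced(self) -> list[GraftPlacement]:
        return [p for p in self.placements if p.level == "unplaced"]

    def count_by_level(self) -> dict[str, int]:
        out = {level: 0 for level in (*LEVELS, "unplaced")}
        for p in self.placements:
            out[p.level] += 1
        return out


def _mrca(tree: Chronogram, labels: Sequence[str]) -> Node:
    """MRCA of a set of tips; for a single tip, its parent node."""
    tip_nodes = {t.label: t for t in tree.tips()}
    nodes = [tip_nodes[l] for l in labels]
    if len(nodes) == 1:
        parent = nodes[0].parent
        assert parent is not None
        return parent

    def _ancestors(node: Node) -> list[Node]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    common = set(map(id, _ancestors(nodes[0])))
    for node in nodes[1:]:
        common &= set(map(id, _ancestors(node)))
    # youngest common ancestor = deepest node on the first tip's path
    for anc in _ancestors(nodes[0]):
        if id(anc) in common:
            return anc
    raise AssertionError("disconnected tree")  # pragma: no cover


def find_attachment(
    tree: Chronogram,
    taxa: TaxonTable,
    request: GraftRequest,
    level: str,
    backbone_tips: Optional[set[str]] = None,
) -> Optional[Node]:
    """Attachment node for one species at one level, or None.

    ``backbone_tips`` restricts which tips count as present (used to make
    grafted tips invisible under the backbone-only policy).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    present = set(tree.tip_labels())
    if backbone_tips is not None:
        present &= backbone_tips

    if level in ("two_congeners", "one_congener"):
        members = [s for s in taxa.species_in_rank("genus", request.genus)
                   if s in present and s != request.species]
        if level == "two_congeners":
            return _mrca(tree, members) if len(members) >= 2 else None
        return _mrca(tree, members) if len(members) == 1 else None

    rank = "family" if level == "family" else "order"
    name = request.family if rank == "family" else request.order
    members = [s for s in taxa.species_in_rank(rank, name)
               if s in present and s != request.species]
    return _mrca(tree, members) if members else None


def apply_grafts(
    tree: Chronogram,
    taxa: TaxonTable,
    requests: Sequence[GraftRequest],
    escalation: Sequence[str] = LEVELS,
    sequential: bool = False,
) -> tuple[Chronogram, GraftReport]:
    """Attach each requested species at the first escalation level that
    succeeds.

    Under the default backbone-only policy all attachment points are
    computed against the original backbone, so previously grafted tips
    never serve as (or alter) attachment points and placement is
    independent of request order within a level.  With
    ``sequential=True`` each grafted tip immediately joins the tree and
    the pool for later placements, mimicking a stepwise manual protocol.

    Returns the enriched chronogram (the input is never modified) and a
    report enumerating every request.  Species that match no level are
    reported as unplaced, not errors.
    """
    labels = [r.species for r in requests]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ChronogramError(f"duplicate graft request label(s): {dups}")
    backbone = set(tree.tip_labels())
    clash = backbone & set(labels)
    if clash:
        raise ChronogramError(f"request label(s) already on the tree: {sorted(clash)}")
    for level in escalation:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")

    out = tree.copy()
    # taxonomy pool: backbone records plus the requests themselves
    pool_frame = taxa.frame[taxa.frame["species"].isin(backbone)]
    req_frame = pd.DataFrame(
        [dict(species=r.species, genus=r.genus, family=r.family,
              order=r.order, status=r.status) for r in requests]
    )
    pool_taxa = TaxonTable(
        pd.concat([pool_frame, req_frame], ignore_index=True)
        if len(requests) else pool_frame.reset_index(drop=True)
    )

    placements: list[GraftPlacement] = []
    visible = None if sequential else backbone
    for request in requests:
        node = None
        used_level = "unplaced"
        for level in escalation:
            node = find_attachment(out, pool_taxa, request, level,
                                   backbone_tips=visible)
            if node is not None:
                used_level = level
                break
        if node is None:
            placements.append(GraftPlacement(request.species, "unplaced", None, None))
            continue
        tip = Node(label=request.species, age=0.0)
        node.add_child(tip)
        placements.append(
            GraftPlacement(request.species, used_level, node.age, node.age)
        )
    return out, GraftReport(tuple(placements))


def chronogram_series(
    tree: Chronogram,
    taxa: TaxonTable,
    requests: Sequence[GraftRequest],
    sequential: bool = False,
) -> list[tuple[Chronogram, GraftReport]]:
    """The four enriched chronograms from cumulative level prefixes
    (congeners-2; +congener-1; +family; +order), in that order."""
    series = []
    for k in range(1, len(LEVELS) + 1):
        series.append(
            apply_grafts(tree, taxa, requests, escalation=LEVELS[:k],
                         sequential=sequential)
        )
    return series
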