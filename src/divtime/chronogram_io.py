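"""Reading, validating and writing dated phylogenies and taxon metadata.

A *chronogram* is a rooted ultrametric tree whose branch lengths are in
units of absolute time (Myr here), so that every node carries an age and
all extant tips sit at age 0.  Nodes may additionally carry a credibility
interval on their age estimate, serialized in Newick as a bracket comment
``[&age_interval={lower,upper}]`` attached to the node.

All downstream analysis modules operate exclusively on the
:class:`Chronogram` and :class:`TaxonTable` types defined here.
"""

from __future__ import annotations

import enum
import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy
import pandas as pd

__all__ = [
    "AgeBound",
    "Node",
    "Chronogram",
    "TaxonTable",
    "ChronogramError",
    "TaxonTableError",
    "STATUSES",
    "parse_chronogram",
    "write_chronogram",
    "load_taxon_table",
    "validate_chronogram",
]

#: Closed set of Mediterranean status classes: species with a distribution
#: restricted to the Mediterranean (endemic), naturally present but not
#: restricted (native), introduced in historical time (exotic), and
#: extra-Mediterranean outgroup taxa used only to root/date the tree.
STATUSES = ("endemic", "native", "exotic", "outgroup")


class ChronogramError(ValueError):
    """Raised for malformed trees (parse failures, invariant violations)."""


class TaxonTableError(ValueError):
    """Raised for malformed taxon tables."""


class AgeBound(str, enum.Enum):
    """Which node-age estimate to read: the point estimate or a
    credibility-interval bound (used for sensitivity reruns)."""

    MEAN = "mean"
    LOWER = "lower"
    UPPER = "upper"

    @classmethod
    def coerce(cls, value: "AgeBound | str") -> "AgeBound":
        return value if isinstance(value, AgeBound) else cls(str(value).lower())


class Node:
    """A node of a chronogram: age in Myr, optional age interval, children."""

    __slots__ = ("label", "age", "age_interval", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        age: float = 0.0,
        age_interval: Optional[tuple[float, float]] = None,
    ):
        self.label = label
        self.age = float(age)
        self.age_interval = age_interval
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def age_at(self, bound: AgeBound) -> float:
        """Age under the requested bound (tips are always at 0)."""
        bound = AgeBound.coerce(bound)
        if bound is AgeBound.MEAN or self.is_tip:
            return self.age
        if self.age_interval is None:
            raise ChronogramError(
                f"node at age {self.age} has no age interval but bound "
                f"{bound.value!r} was requested"
            )
        return self.age_interval[0] if bound is AgeBound.LOWER else self.age_interval[1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.label if self.is_tip else f"internal/{len(self.children)}ch"
        return f"<Node {kind} age={self.age:g}>"


class Chronogram:
    """A rooted, ultrametric, dated tree."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def height(self) -> float:
        return self.root.age

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def has_age_intervals(self) -> bool:
        return all(n.age_interval is not None for n in self.internal_nodes())

    def copy(self) -> "Chronogram":
        def _clone(node: Node) -> Node:
            new = Node(node.label, node.age, node.age_interval)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return Chronogram(_clone(self.root))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chronogram):
            return NotImplemented

        def _key(node: Node):
            if node.is_tip:
                return (node.label, node.age, node.age_interval)
            return (None, node.age, node.age_interval,
                    tuple(_key(c) for c in node.children))

        return _key(self.root) == _key(other.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram {self.n_tips} tips, height {self.height:g} Myr>"


@dataclass
class TaxonTable:
    """Species -> (genus, family, order, status) metadata table.

    Backed by a pandas DataFrame with columns
    ``species, genus, family, order, status``.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("species", "genus", "family", "order", "status")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TaxonTableError(f"taxon table missing column(s): {missing}")
        dup = self.frame["species"][self.frame["species"].duplicated()]
        if not dup.empty:
            raise TaxonTableError(f"duplicate species label(s): {sorted(dup)}")
        bad = self.frame[~self.frame["status"].isin(STATUSES)]
        if not bad.empty:
            row = bad.iloc[0]
            raise TaxonTableError(
                f"unknown status {row['status']!r} for species {row['species']!r} "
                f"(row {bad.index[0]}); allowed: {STATUSES}"
            )
        med = self.frame[self.frame["status"] != "outgroup"]
        for col in ("genus", "family", "order"):
            empty = med[med[col].isna() | (med[col].astype(str) == "")]
            if not empty.empty:
                raise TaxonTableError(
                    f"empty {col!r} for Mediterranean species "
                    f"{empty.iloc[0]['species']!r}"
                )

    # -- queries -------------------------------------------------------
    def status_counts(self) -> dict[str, int]:
        counts = self.frame["status"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in STATUSES}

    def species_with_status(self, status: str) -> list[str]:
        if status not in STATUSES:
            raise TaxonTableError(f"unknown status {status!r}")
        return self.frame.loc[self.frame["status"] == status, "species"].tolist()

    def mediterranean_species(self) -> list[str]:
        return self.frame.loc[self.frame["status"] != "outgroup", "species"].tolist()

    def record(self, species: str) -> dict:
        row = self.frame.loc[self.frame["species"] == species]
        if row.empty:
            raise TaxonTableError(f"species {species!r} not in table")
        return row.iloc[0].to_dict()

    def species_in_rank(self, rank: str, name: str) -> list[str]:
        """All species whose genus/family/order equals ``name``."""
        if rank not in ("genus", "family", "order"):
            raise TaxonTableError(f"unknown rank {rank!r}")
        return self.frame.loc[self.frame[rank] == name, "species"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Newick round trip
# ---------------------------------------------------------------------

_INTERVAL_RE = re.compile(
    r"&?age_interval=\{\s*([0-9eE.+-]+)\s*,\s*([0-9eE.+-]+)\s*\}"
)


def _interval_from_comments(comments: Sequence[str]) -> Optional[tuple[float, float]]:
    for comment in comments:
        m = _INTERVAL_RE.search(comment)
        if m:
            return float(m.group(1)), float(m.group(2))
    return None


def parse_chronogram(text: str, tolerance: float = 1e-6) -> Chronogram:
    """Parse a Newick string into a :class:`Chronogram`.

    Node ages are derived from branch lengths with tips pinned at age 0:
    a node's age is the tree height minus its root-to-node path length.
    Per-node ``[&age_interval={lower,upper}]`` comments are honoured;
    other comments (e.g. bootstrap support) are ignored.

    Parameters
    ----------
    text:
        A Newick tree with branch lengths on every non-root edge.
    tolerance:
        Maximum allowed spread of tip depths relative to tree height
        before the tree is rejected as non-ultrametric.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=False,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ChronogramError(f"unparseable Newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise ChronogramError("empty tree")

    # root-to-node depths
    depths: dict[dendropy.Node, float] = {dtree.seed_node: 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is dtree.seed_node:
            continue
        if dnode.edge.length is None:
            label = dnode.taxon.label if dnode.taxon else "<internal>"
            raise ChronogramError(f"missing branch length on edge to {label}")
        depths[dnode] = depths[dnode.parent_node] + float(dnode.edge.length)

    tip_depths = [depths[l] for l in dtree.leaf_node_iter()]
    height = max(tip_depths)
    spread = max(tip_depths) - min(tip_depths)
    if height > 0 and spread / height > tolerance:
        raise ChronogramError(
            f"tree is not ultrametric: tip depth spread {spread:g} exceeds "
            f"tolerance {tolerance:g} x height {height:g}"
        )

    labels_seen: set[str] = set()

    def _convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None:
                raise ChronogramError("tip without label")
            label = dnode.taxon.label
            if label in labels_seen:
                raise ChronogramError(f"duplicate tip label {label!r}")
            labels_seen.add(label)
            node = Node(label=label, age=0.0)
        else:
            node = Node(age=height - depths[dnode])
        node.age_interval = _interval_from_comments(dnode.comments)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    return Chronogram(_convert(dtree.seed_node))


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float."""
    return repr(float(x))


def write_chronogram(tree: Chronogram) -> str:
    """Serialize a chronogram to Newick.

    Branch lengths are parent age minus child age; age intervals are
    emitted as ``[&age_interval={lower,upper}]`` node comments.  Output
    is deterministic: children are written in stored order and floats in
    shortest round-trip decimal form.
    """
    out = _io.StringIO()

    def _comment(node: Node) -> str:
        if node.age_interval is None:
            return ""
        lo, hi = node.age_interval
        return f"[&age_interval={{{_fmt(lo)},{_fmt(hi)}}}]"

    def _write(node: Node, parent_age: Optional[float]) -> None:
        if node.is_tip:
            out.write(node.label)
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                _write(child, node.age)
            out.write(")")
        if parent_age is not None:
            out.write(f":{_fmt(parent_age - node.age)}")
        out.write(_comment(node))

    _write(tree.root, None)
    out.write(";")
    return out.getvalue()


def load_taxon_table(path) -> TaxonTable:
    """Load and validate a species/genus/family/order/status TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return TaxonTable(frame)


# ---------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------


def validate_chronogram(tree: Chronogram, tolerance: float = 1e-6) -> list[str]:
    """Collect every invariant violation without raising.

    Checks: tips at age 0, parent strictly older than child (no negative
    or zero implied edges at internal nodes), intervals bracketing the
    point age, unique tip labels.  Returns a list of human-readable
    violation messages; an empty list means the tree is valid.
    """
    violations: list[str] = []
    abs_tol = max(tree.height, 1.0) * tolerance
    seen: set[str] = set()
    for node in tree.preorder():
        if node.is_tip:
            if abs(node.age) > abs_tol:
                violations.append(f"tip {node.label!r} at age {node.age:g}, not 0")
            if node.label in seen:
                violations.append(f"duplicate tip label {node.label!r}")
            seen.add(node.label)
        for child in node.children:
            if child.age >= node.age:
                violations.append(
                    f"child age {child.age:g} >= parent age {node.age:g} "
                    f"(non-positive implied edge)"
                )
        if node.age_interval is not None:
            lo, hi = node.age_interval
            if not (lo <= node.age + abs_tol and node.age - abs_tol <= hi):
                violations.append(
                    f"age interval ({lo:g}, {hi:g}) does not bracket age {node.age:g}"
                )
    return violations
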