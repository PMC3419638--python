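"""Hierarchical ledger of repeat content.

Annotations carry a leaf family (Copia, Gypsy, L1, ...) that resolves to a
path in a rooted repeat taxonomy (Transposable Element > RNA transposon >
LTR Retrotransposon > Copia, and so on).  The ledger rolls element counts
and masked base totals up the tree and expresses each node as a percentage
of all read bases and of all repeat bases.

A node may carry bases attributed directly to it but to none of its
children (published repeat tables do this), so children are never forced
to sum exactly to their parent; the invariant is only that a parent holds
at least the sum of its children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io_formats import RepeatAnnotationRecord

ROOT = "Repeats"


@dataclass
class RepeatTaxonomy:
    """Rooted tree of repeat category labels."""

    parent: dict[str, str | None]
    children: dict[str, list[str]]

    @classmethod
    def from_edges(cls, edges: list[tuple[str | None, str]]) -> "RepeatTaxonomy":
        parent: dict[str, str | None] = {ROOT: None}
        children: dict[str, list[str]] = {ROOT: []}
        for par, child in edges:
            par = par if par is not None else ROOT
            if par not in parent:
                raise ValueError(f"taxonomy edge refers to unknown parent {par!r}")
            if child in parent:
                raise ValueError(f"duplicate taxonomy label {child!r}")
            parent[child] = par
            children[child] = []
            children[par].append(child)
        return cls(parent, children)

    @classmethod
    def from_text(cls, text: str) -> "RepeatTaxonomy":
        """Parse an indented outline (two spaces per level)."""
        edges: list[tuple[str | None, str]] = []
        stack: list[tuple[int, str]] = []
        for raw in text.splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            depth = (len(raw) - len(raw.lstrip())) // 2
            label = raw.strip()
            while stack and stack[-1][0] >= depth:
                stack.pop()
            edges.append((stack[-1][1] if stack else None, label))
            stack.append((depth, label))
        return cls.from_edges(edges)

    @classmethod
    def from_file(cls, path: str | Path) -> "RepeatTaxonomy":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def default(cls) -> "RepeatTaxonomy":
        """The grass-repeat taxonomy used throughout this package."""
        text = resources.files("bespipe").joinpath("data/taxonomy.txt").read_text()
        return cls.from_text(text)

    def lineage_of(self, label: str) -> tuple[str, ...]:
        """Path from the first level below the root down to ``label``."""
        if label not in self.parent:
            raise KeyError(f"unknown repeat family {label!r}")
        path = []
        node: str | None = label
        while node is not None and node != ROOT:
            path.append(node)
            node = self.parent[node]
        return tuple(reversed(path))

    def labels(self) -> list[str]:
        order: list[str] = []

        def walk(node: str) -> None:
            if node != ROOT:
                order.append(node)
            for child in self.children[node]:
                walk(child)

        walk(ROOT)
        return order

    def leaves(self) -> list[str]:
        return [n for n in self.labels() if not self.children[n]]


@dataclass
class LedgerNode:
    label: str
    n_elements: int = 0
    length_bp: int = 0


@dataclass
class RepeatLedger:
    taxonomy: RepeatTaxonomy
    nodes: dict[str, LedgerNode]
    total_read_bases: int
    total_repeat_bases: int

    def percent_of_total_bases(self, label: str) -> float:
        if self.total_read_bases <= 0:
            raise ValueError("total_read_bases must be positive")
        return round(100.0 * self.nodes[label].length_bp / self.total_read_bases, 2)

    def percent_of_repeat_bases(self, label: str) -> float:
        if self.total_repeat_bases <= 0:
            raise ValueError("no repeat bases in ledger")
        return round(100.0 * self.nodes[label].length_bp / self.total_repeat_bases, 1)


def summarize(annotations: list[RepeatAnnotationRecord], total_read_bases: int,
              taxonomy: RepeatTaxonomy) -> RepeatLedger:
    """Roll annotations up the taxonomy.

    Annotations must be non-overlapping within a read (the repeat masker
    guarantees this), so the repeat-base total is a plain sum of lengths.
    """
    nodes = {label: LedgerNode(label) for label in taxonomy.labels()}
    total_repeat = 0
    for ann in annotations:
        if ann.family not in nodes:
            raise KeyError(f"annotation family {ann.family!r} is not in the taxonomy")
        total_repeat += len(ann)
        for label in taxonomy.lineage_of(ann.family):
            node = nodes[label]
            node.length_bp += len(ann)
        # an element is counted once, at the level it was identified
        for label in taxonomy.lineage_of(ann.family):
            nodes[label].n_elements += 1
    return RepeatLedger(taxonomy, nodes, total_read_bases, total_repeat)


def ledger_from_table(rows: list[tuple[str, int, int]], total_read_bases: int,
                      taxonomy: RepeatTaxonomy) -> RepeatLedger:
    """Build a ledger directly from published (label, n_elements, length_bp)
    rows, e.g. a transcription of a repeat-content table.  Row values are
    taken as-is; no roll-up is applied, which preserves any
    internal-node-only bases the source table carries."""
    nodes = {label: LedgerNode(label) for label in taxonomy.labels()}
    total_repeat = 0
    for label, n, length in rows:
        if label == "Total":
            total_repeat = length
            continue
        if label not in nodes:
            raise KeyError(f"table row {label!r} is not in the taxonomy")
        nodes[label] = LedgerNode(label, n, length)
    if total_repeat == 0:
        total_repeat = sum(nodes[c].length_bp for c in taxonomy.children[ROOT])
    return RepeatLedger(taxonomy, nodes, total_read_bases, total_repeat)


def fraction_of(ledger: RepeatLedger, child: str, parent: str) -> float:
    """child bases as a percentage of parent bases, one decimal.

    ``parent`` may be ``"Repeats"`` (the root), meaning all repeat bases.
    """
    if parent == ROOT:
        parent_bp = ledger.total_repeat_bases
    else:
        if parent not in _ancestors_and_self(ledger.taxonomy, child):
            raise ValueError(f"{parent!r} is not an ancestor of {child!r}")
        parent_bp = ledger.nodes[parent].length_bp
    if parent_bp <= 0:
        raise ValueError(f"parent {parent!r} has zero length")
    child_bp = ledger.nodes[child].length_bp
    return round(100.0 * child_bp / parent_bp, 1)


def _ancestors_and_self(taxonomy: RepeatTaxonomy, label: str) -> set[str]:
    out = set()
    node: str | None = label
    while node is not None:
        out.add(node)
        node = taxonomy.parent.get(node)
    return out
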