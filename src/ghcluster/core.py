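"""Domain types shared across the pipeline.

Coordinate convention: all intervals are 0-based half-open internally.
Human-readable reports convert to 1-based inclusive at the formatting layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

DNA_ALPHABET = set("ACGTURYSWKMBDHVN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZJUO-X*")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return seq.translate(COMPLEMENT)[::-1]


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass
class SeqRecord:
    """A named sequence with a declared alphabet.

    ``alphabet_tag`` is ``"dna"`` or ``"protein"``.  Validation is strict for
    DNA (the IUPAC nucleotide set) and permissive for protein alignment rows
    ('-', 'X' and '*' are allowed).
    """

    id: str
    sequence: str
    description: str = ""
    alphabet_tag: str = "dna"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = DNA_ALPHABET if self.alphabet_tag == "dna" else PROTEIN_ALPHABET
        bad = set(self.sequence.upper()) - alphabet
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet_tag} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A typed gene occurrence on a locus.

    ``span`` and ``exon_spans`` are 0-based half-open on the plus strand;
    minus-strand features are stored as plus-strand spans with ``strand='-'``
    and are reverse-complemented on extraction (single convention, no
    double-RC bugs).
    """

    label: str
    family: str
    subtype: Optional[str]
    strand: str
    span: tuple[int, int]
    exon_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AnnotatedLocus:
    """A locus sequence plus its gene annotations."""

    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            s, e = f.span
            if not (0 <= s < e <= n):
                raise ValueError(f"feature {f.label}: span {f.span} outside locus")
            prev_end = s
            for es, ee in f.exon_spans:
                if not (s <= es < ee <= e):
                    raise ValueError(f"feature {f.label}: exon {es, ee} outside gene span")
                if es < prev_end:
                    raise ValueError(f"feature {f.label}: overlapping exons")
                prev_end = ee

    def extract(self, feature: GeneFeature) -> str:
        s, e = feature.span
        seq = self.sequence[s:e]
        return revcomp(seq) if feature.strand == "-" else seq

    def extract_cds(self, feature: GeneFeature) -> str:
        parts = [self.sequence[s:e] for s, e in feature.exon_spans]
        cds = "".join(parts)
        return revcomp(cds) if feature.strand == "-" else cds


class TreeNode:
    """Node of a rooted tree; polytomies allowed.

    Every non-root node owns its subtending branch: ``length`` (expected
    substitutions/codon) and ``cls`` (branch class label, 0 = background).
    """

    __slots__ = ("name", "length", "cls", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0, cls: int = 0):
        self.name = name
        self.length = float(length)
        self.cls = int(cls)
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LabeledTree:
    """Rooted tree whose branches carry small-integer class labels."""

    root: TreeNode

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for c in node.children:
                yield from walk(c)

        return walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[TreeNode]:
        """Non-root nodes; each represents the branch above it."""
        return [n for n in self.postorder() if n.parent is not None]

    def branch_classes(self) -> set[int]:
        return {n.cls for n in self.edges()}

    def leafset_under(self, node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def find_edge(self, leaf_names: Sequence[str]) -> TreeNode:
        """Return the node whose subtending branch has exactly this leaf set."""
        want = frozenset(leaf_names)
        for n in self.edges():
            if self.leafset_under(n) == want:
                return n
        raise KeyError(f"no branch subtends exactly {sorted(want)}")

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name
            if node.cls:
                label = f"{label}#{node.cls}"
            if node.is_leaf:
                core = label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if node.parent is not None:
                core += f":{node.length:.6g}"
            return core

        return fmt(self.root) + ";"


def to_one_based(span: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive, for human-readable reports."""
    return span[0] + 1, span[1]
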