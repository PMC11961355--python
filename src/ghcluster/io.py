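"""Readers and writers for FASTA, FASTQ and newick with branch-class labels.

Parsing of the standard formats is delegated to Biopython / dendropy; a light
structural pre-scan supplies line numbers for the error messages the rest of
the pipeline relies on.  Branch classes use the conventional codeml-style
``#k`` suffix dialect (``((A,B)#1,C);`` labels the internal branch class 1);
unlabeled branches are class 0 (background).
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator, Optional, Union

import dendropy
from Bio import SeqIO

from .core import LabeledTree, SeqRecord, TreeNode

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


def _open_text(path: PathLike):
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA


def _prescan_fasta(path: PathLike) -> None:
    with _open_text(path) as fh:
        header_line = None
        seq_len = 0
        started = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if not line[1:].strip():
                    raise ParseError(f"{path}: malformed header at line {lineno}")
                if started and seq_len == 0:
                    raise ParseError(
                        f"{path}: record ending before line {lineno} has empty sequence"
                    )
                header_line, seq_len, started = lineno, 0, True
            else:
                if not started:
                    raise ParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                seq_len += len(line.strip())
        if started and seq_len == 0:
            raise ParseError(
                f"{path}: record starting at line {header_line} has empty sequence"
            )


def read_fasta(path: PathLike, alphabet_tag: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file into validated records, order preserved."""
    _prescan_fasta(path)
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append(
                SeqRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    description=rec.description[len(rec.id):].strip(),
                    alphabet_tag=alphabet_tag,
                )
            )
    return out


def write_fasta(records, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def iter_fastq(path: PathLike, alphabet_tag: str = "dna") -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file without loading it whole.

    Qualities are parsed (format validation) but discarded: downstream stages
    are alignment/identity based and never consult base quality.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            plus = None
            lineno += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ParseError(f"{path}: truncated FASTQ record at line {lineno}")
            if not header.startswith("@"):
                raise ParseError(f"{path}: expected '@' at line {lineno}")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: expected '+' at line {lineno + 2}")
            seq = seq.strip()
            if len(seq) != len(qual.strip()):
                raise ParseError(
                    f"{path}: sequence/quality length mismatch at line {lineno}"
                )
            rid = header[1:].split()[0]
            yield SeqRecord(id=rid, sequence=seq, alphabet_tag=alphabet_tag)
            lineno += 3


def read_fastq(path: PathLike, alphabet_tag: str = "dna") -> list[SeqRecord]:
    return list(iter_fastq(path, alphabet_tag))


def write_fastq(records, path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


# ---------------------------------------------------------------------------
# Newick with "#k" branch-class labels

_CLASS_RE = re.compile(r"#(\d+)\s*$")


def _split_class(label: Optional[str]) -> tuple[str, Optional[int]]:
    if not label:
        return "", None
    m = _CLASS_RE.search(label)
    if m:
        return label[: m.start()].strip(), int(m.group(1))
    return label, None


def read_tree(newick: str) -> LabeledTree:
    """Parse a newick string; ``#k`` suffixes become branch class labels.

    Polytomies are preserved, never arbitrarily resolved.  Unlabeled branches
    get class 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        raw = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        name, cls = _split_class(raw)
        node = TreeNode(
            name=name,
            length=dnode.edge.length or 0.0,
            cls=cls or 0,
        )
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    tree = LabeledTree(root=convert(dtree.seed_node))
    names = tree.leaf_names()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ParseError(f"duplicate leaf names: {sorted(dupes)}")
    return tree


def read_tree_file(path: PathLike) -> LabeledTree:
    return read_tree(Path(path).read_text())


def write_tree(tree: LabeledTree, path: PathLike) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# tabular config (key=value TSV)


def read_config(path: PathLike) -> dict[str, str]:
    out = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, val = line.split("=", 1)
            elif "\t" in line:
                key, val = line.split("\t", 1)
            else:
                raise ParseError(f"{path}: expected key=value at line {lineno}")
            out[key.strip()] = val.strip()
    return out
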