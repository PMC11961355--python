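"""Turn per-read gene-hit lists into ordered cluster structures, build a
haplotype catalog, genotype individuals, and polish a consensus sequence for
homozygotes.

Haplotype identity is defined at the family level: subtype divergence (~0.5%)
is far below long-read noise, so subtypes refine but never split catalog
entries.  Unassigned gene hits become wildcard positions that match any
family during collapse (conservative against noise-induced spurious
haplotypes).
"""
from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .core import AnnotatedLocus, GeneFeature, revcomp
from .read_typing import (
    FlankResult,
    GeneHit,
    TypingConfig,
    TypingIndex,
    detect_flanks,
    scan_read,
)

WILDCARD = "*"


@dataclass
class CallerConfig:
    terminal_5: str = "GH"    # family expected at the 5' end of the cluster
    terminal_3: str = "CSH4"  # family expected at the 3' end


@dataclass
class ReadStructure:
    read_id: str
    genes: tuple          # ordered 5'->3' (family-or-'*', subtype-or-None)
    completeness: str     # "full" | "almost_full" | "partial"
    orientation: str
    flanks: tuple = (False, False)

    def family_vector(self) -> tuple:
        return tuple(f for f, _ in self.genes)

    def has_wildcards(self) -> bool:
        return any(f == WILDCARD for f, _ in self.genes)


def call_read_structure(
    read_id: str,
    gene_hits: Sequence[GeneHit],
    flanks: FlankResult,
    config: CallerConfig = CallerConfig(),
) -> ReadStructure:
    """Normalize orientation (CD79B side is 5') and emit the gene order.

    Completeness: full = both flank genes detected; almost_full = exactly one
    flank and the terminal gene on the flankless side present; else partial.
    Unassigned hits are retained as wildcard positions.
    """
    hits = sorted(gene_hits, key=lambda h: h.span[0])
    genes = [
        (h.family, h.subtype) if h.status == "assigned" else (WILDCARD, None)
        for h in hits
    ]
    orientation = flanks.orientation
    if orientation == "unknown" and hits:
        strand_votes = Counter(h.strand for h in hits)
        orientation = "forward" if strand_votes["+"] >= strand_votes["-"] else "reverse"
    if orientation == "reverse":
        genes = genes[::-1]
    has5, has3 = flanks.has_5prime, flanks.has_3prime
    if has5 and has3:
        completeness = "full"
    elif (has5 or has3) and genes:
        if has5 and genes[-1][0] == config.terminal_3:
            completeness = "almost_full"
        elif has3 and genes[0][0] == config.terminal_5:
            completeness = "almost_full"
        else:
            completeness = "partial"
    else:
        completeness = "partial"
    return ReadStructure(
        read_id=read_id,
        genes=tuple(genes),
        completeness=completeness,
        orientation=orientation,
        flanks=(has5, has3),
    )


def type_read(
    read_id: str,
    read: str,
    index: TypingIndex,
    typing_config: TypingConfig = TypingConfig(),
    caller_config: CallerConfig = CallerConfig(),
) -> ReadStructure:
    """Convenience: scan a raw read and call its structure."""
    hits = scan_read(read_id, read, index, typing_config)
    flanks = detect_flanks(read, index, typing_config)
    return call_read_structure(read_id, hits, flanks, caller_config)


# ---------------------------------------------------------------------------
# Catalog


def _matches(observed: tuple, entry: tuple) -> bool:
    return len(observed) == len(entry) and all(
        o == WILDCARD or o == e for o, e in zip(observed, entry)
    )


def _matches_anchored(observed: tuple, entry: tuple, anchor5: bool) -> bool:
    """Prefix (anchor5) or suffix match with wildcards."""
    if len(observed) > len(entry):
        return False
    segment = entry[: len(observed)] if anchor5 else entry[len(entry) - len(observed):]
    return all(o == WILDCARD or o == e for o, e in zip(observed, segment))


@dataclass
class CatalogEntry:
    families: tuple
    support: int = 0
    subtype_consensus: tuple = ()


@dataclass
class HaplotypeCatalog:
    entries: list            # CatalogEntry, ordered by descending support
    assignments: dict        # read_id -> tuple of entry indices (len 1 = unambiguous)

    def gene_counts(self) -> list[int]:
        return [len(e.families) for e in self.entries]


def catalog_haplotypes(read_structures: Sequence[ReadStructure]) -> HaplotypeCatalog:
    """Collapse full structures by exact family-level equality (wildcards
    match anything); assign almost-full structures to the compatible entries.

    Support counts the reads whose assignment is a single entry.
    """
    fulls = [rs for rs in read_structures if rs.completeness == "full"]
    almost = [rs for rs in read_structures if rs.completeness == "almost_full"]
    if not fulls and not almost:
        warnings.warn("only partial reads: empty catalog")
        return HaplotypeCatalog(entries=[], assignments={})
    if not fulls:
        # promote almost-full observed vectors to provisional entries
        fulls, almost = almost, []

    vectors: list[tuple] = []
    support: list[int] = []
    members: list[list[ReadStructure]] = []
    assignments: dict[str, tuple] = {}

    concrete = [rs for rs in fulls if not rs.has_wildcards()]
    wild = [rs for rs in fulls if rs.has_wildcards()]
    for rs in concrete:
        v = rs.family_vector()
        if v in vectors:
            i = vectors.index(v)
            support[i] += 1
            members[i].append(rs)
        else:
            vectors.append(v)
            support.append(1)
            members.append([rs])
        assignments[rs.read_id] = (vectors.index(v),)
    for rs in wild:
        v = rs.family_vector()
        compat = [i for i, ev in enumerate(vectors) if _matches(v, ev)]
        if len(compat) == 1:
            support[compat[0]] += 1
            members[compat[0]].append(rs)
            assignments[rs.read_id] = (compat[0],)
        elif compat:
            assignments[rs.read_id] = tuple(compat)
        else:
            vectors.append(v)
            support.append(1)
            members.append([rs])
            assignments[rs.read_id] = (len(vectors) - 1,)
    for rs in almost:
        v = rs.family_vector()
        anchor5 = rs.flanks[0]
        compat = [i for i, ev in enumerate(vectors) if _matches_anchored(v, ev, anchor5)]
        if len(compat) == 1:
            support[compat[0]] += 1
            members[compat[0]].append(rs)
            assignments[rs.read_id] = (compat[0],)
        elif compat:
            assignments[rs.read_id] = tuple(compat)
        else:
            warnings.warn(f"almost-full read {rs.read_id} matches no catalog entry")

    order = sorted(range(len(vectors)), key=lambda i: (-support[i], vectors[i]))
    rank = {old: new for new, old in enumerate(order)}
    entries = []
    for old in order:
        entries.append(
            CatalogEntry(
                families=vectors[old],
                support=support[old],
                subtype_consensus=_subtype_consensus(vectors[old], members[old]),
            )
        )
    assignments = {
        rid: tuple(sorted(rank[i] for i in idxs)) for rid, idxs in assignments.items()
    }
    return HaplotypeCatalog(entries=entries, assignments=assignments)


def _subtype_consensus(vector: tuple, members: list[ReadStructure]) -> tuple:
    """Per position, the subtype if every informative supporting read agrees."""
    out = []
    for pos in range(len(vector)):
        seen = {
            rs.genes[pos][1]
            for rs in members
            if len(rs.genes) == len(vector) and rs.genes[pos][1] is not None
        }
        out.append(seen.pop() if len(seen) == 1 else None)
    return tuple(out)


# ---------------------------------------------------------------------------
# Genotyping


@dataclass
class Genotype:
    individual_id: str
    alleles: list           # each a tuple of candidate family vectors (len 1 = unambiguous)
    homozygous: bool
    status: str = "ok"      # "ok" | "undetermined" | "error"
    catalog: Optional[HaplotypeCatalog] = None


def genotype_individual(
    individual_id: str,
    read_structures: Sequence[ReadStructure],
    catalog: Optional[HaplotypeCatalog] = None,
) -> Genotype:
    """One or two haplotypes per individual from its informative reads.

    Distinct unambiguously-assigned haplotypes: 1 = homozygous, 2 =
    heterozygous, >2 = error (contamination or miscall).  Ambiguity sets
    (reads compatible with several catalog entries) are reported as candidate
    sets and never counted as additional distinct haplotypes.
    """
    if catalog is None:
        catalog = catalog_haplotypes(read_structures)
    if not catalog.entries:
        return Genotype(individual_id, [], False, status="undetermined", catalog=catalog)
    own_ids = {rs.read_id for rs in read_structures}
    own_assignments = [
        idxs for rid, idxs in catalog.assignments.items() if rid in own_ids
    ]
    distinct = sorted({i for idxs in own_assignments if len(idxs) == 1 for i in idxs})
    ambiguous_sets = {
        idxs
        for idxs in own_assignments
        if len(idxs) > 1 and not set(idxs) & set(distinct)
    }
    if len(distinct) > 2 or (len(distinct) == 2 and ambiguous_sets):
        status = "error"
    elif not distinct and not ambiguous_sets:
        return Genotype(individual_id, [], False, status="undetermined", catalog=catalog)
    else:
        status = "ok"
    vec = lambda i: catalog.entries[i].families
    alleles = [(vec(i),) for i in distinct]
    for idxs in sorted(ambiguous_sets):
        alleles.append(tuple(vec(i) for i in idxs))
    homozygous = status == "ok" and len(alleles) == 1 and len(alleles[0]) == 1
    return Genotype(individual_id, alleles, homozygous, status=status, catalog=catalog)


# ---------------------------------------------------------------------------
# Consensus polishing


@dataclass
class PolishConfig:
    max_dist_frac: float = 0.30   # accurate read vs backbone placement cutoff
    min_insert_support: float = 0.5
    rounds: int = 2               # consensus iterations (round 2 realigns to round 1)


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _align_to_backbone(read: str, backbone: str, max_dist: int):
    best = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        res = edlib.align(seq, backbone, mode="HW", task="path", k=max_dist)
        d = res["editDistance"]
        if d >= 0 and (best is None or d < best[0]):
            best = (d, strand, seq, res)
    return best


def polish_consensus(
    genotype: Genotype,
    noisy_full_reads: Sequence[str],
    accurate_reads: Sequence[str],
    index: TypingIndex,
    config: PolishConfig = PolishConfig(),
    typing_config: TypingConfig = TypingConfig(),
) -> AnnotatedLocus:
    """Majority-vote consensus of accurate reads laid over a noisy full-span
    backbone read (which supplies the overall organization).

    Requires a homozygous genotype: with two identical chromosomes all
    accurate reads describe the same haplotype.  Zero-coverage backbone
    columns are emitted as '-' with a warning.
    """
    if not genotype.homozygous:
        raise ValueError("polish_consensus requires a homozygous genotype")
    if not noisy_full_reads:
        raise ValueError("need at least one noisy full-span read as backbone")
    backbone = noisy_full_reads[0]
    if detect_flanks(backbone, index, typing_config).orientation == "reverse":
        backbone = revcomp(backbone)
    for _ in range(max(1, config.rounds)):
        backbone = _consensus_round(backbone, accurate_reads, config)
    features = _annotate(backbone, index, typing_config)
    return AnnotatedLocus(sequence=backbone, features=features)


def _consensus_round(
    backbone: str, accurate_reads: Sequence[str], config: PolishConfig
) -> str:
    L = len(backbone)
    base_votes = np.zeros((L, 4), dtype=np.int32)
    del_votes = np.zeros(L, dtype=np.int32)
    junction_cov = np.zeros(L + 1, dtype=np.int32)
    inserts: dict[int, Counter] = {}
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}

    for read in accurate_reads:
        hit = _align_to_backbone(read, backbone, int(len(read) * config.max_dist_frac))
        if hit is None:
            continue
        _d, _strand, seq, res = hit
        start = res["locations"][0][0]
        qpos, tpos = 0, start
        junction_cov[start : res["locations"][0][1] + 2] += 1
        for n, op in _CIG_RE.findall(res["cigar"]):
            n = int(n)
            if op in "=XM":
                for i in range(n):
                    b = lut.get(seq[qpos + i])
                    if b is not None:
                        base_votes[tpos + i, b] += 1
                qpos += n
                tpos += n
            elif op == "I":  # extra bases in the read: insertion vs backbone
                inserts.setdefault(tpos, Counter())[seq[qpos : qpos + n]] += 1
                qpos += n
            else:  # "D": backbone base absent from the read
                del_votes[tpos : tpos + n] += 1
                tpos += n

    pieces: list[str] = []
    uncovered = 0
    nts = "ACGT"
    for i in range(L):
        ins_here = inserts.get(i)
        if ins_here is not None and junction_cov[i] > 0:
            total = sum(ins_here.values())
            if total > config.min_insert_support * junction_cov[i]:
                pieces.append(ins_here.most_common(1)[0][0])
        cov = int(base_votes[i].sum() + del_votes[i])
        if cov == 0:
            pieces.append("-")
            uncovered += 1
            continue
        best_base = int(np.argmax(base_votes[i]))
        if del_votes[i] > base_votes[i, best_base]:
            continue  # majority deletion: drop the backbone base
        pieces.append(nts[best_base])
    if uncovered:
        warnings.warn(f"{uncovered} backbone columns had zero accurate coverage")
    return "".join(pieces)


def _annotate(sequence: str, index: TypingIndex, typing_config: TypingConfig) -> list[GeneFeature]:
    hits = scan_read("consensus", sequence, index, typing_config)
    features = []
    for i, h in enumerate(hits):
        s, e = h.span
        w0 = max(0, s - typing_config.window_pad)
        w1 = min(len(sequence), e + typing_config.window_pad)
        window = sequence[w0:w1]
        exon_spans = []
        key = (h.family, h.subtype) if (h.family, h.subtype) in index.exon_seqs else None
        if key is None:
            cands = [k for k in index.exon_seqs if k[0] == h.family]
            key = cands[0] if cands else None
        if key is not None:
            for exon in index.exon_seqs[key]:
                res = edlib.align(exon, window, mode="HW", task="locations")
                if res["editDistance"] >= 0:
                    a, b = res["locations"][0]
                    exon_spans.append((w0 + a, w0 + b + 1))
        exon_spans = [sp for sp in sorted(exon_spans)]
        # drop overlapping/out-of-order exon placements
        clean: list[tuple[int, int]] = []
        for sp in exon_spans:
            if not clean or sp[0] >= clean[-1][1]:
                clean.append(sp)
        features.append(
            GeneFeature(
                label=f"{h.family}{h.subtype or ''}_{i + 1}",
                family=h.family,
                subtype=h.subtype,
                strand=h.strand,
                span=(min(s, clean[0][0]) if clean else s, max(e, clean[-1][1]) if clean else e),
                exon_spans=clean,
            )
        )
    return features
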