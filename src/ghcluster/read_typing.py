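"""Detect GH-like gene occurrences in reads and type them to paralog family
(and, where the evidence allows, subtype).

Unit-cost edit distance is the single scoring currency throughout: it is
deterministic, indel-tolerant, and adequate at the divergences involved
(~8% between families, ~0.5% between subtypes).  Occurrences are located by
scanning reads with per-exon consensus templates (introns are never required
to match), then typed by exon-wise edit distance against every candidate
type.  Greedy non-overlap resolution is by ascending edit distance with ties
broken by leftmost read coordinate.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .core import revcomp
from .simulate import ParalogFamilies

Type = tuple[str, Optional[str]]


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def infix_distance(query: str, target: str, k: int = -1) -> int:
    """Best edit distance of ``query`` against any infix of ``target``; -1 if
    above ``k``."""
    return edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]


# ---------------------------------------------------------------------------
# Typing index


@dataclass
class TypingConfig:
    margin_min: int = 2               # family assignment margin (edit distance)
    subtype_margin_min: int = 1
    detect_max_dist_frac: float = 0.25
    min_detect_len: int = 100         # exons shorter than this locate poorly
    occurrence_gap: int = 3000        # > max intron, << min spacer
    window_pad: int = 600
    flank_max_dist_frac: float = 0.20
    flank_min_cov: float = 0.5


def _consensus(seqs: Sequence[str]) -> str:
    lengths = Counter(len(s) for s in seqs)
    modal = lengths.most_common(1)[0][0]
    rows = [s for s in seqs if len(s) == modal]
    return "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*rows)
    )


@dataclass
class TypingIndex:
    """Per-type exon sequences plus cross-family consensus detection
    templates and flank templates."""

    exon_seqs: dict            # Type -> list of 5 exon CDS chunks
    detection_templates: list  # consensus exon sequences used to locate genes
    flank5: str
    flank3: str
    families: list

    @classmethod
    def from_families(
        cls, families: ParalogFamilies, config: TypingConfig = TypingConfig()
    ) -> "TypingIndex":
        exon_seqs = {}
        for key, cds in families.cds.items():
            splits = families.exon_splits[key]
            chunks, pos = [], 0
            for ln in splits:
                chunks.append(cds[pos : pos + ln])
                pos += ln
            exon_seqs[key] = chunks
        n_exons = len(next(iter(exon_seqs.values())))
        templates = []
        for e in range(n_exons):
            cons = _consensus([v[e] for v in exon_seqs.values()])
            if len(cons) >= config.min_detect_len:
                templates.append(cons)
        return cls(
            exon_seqs=exon_seqs,
            detection_templates=templates,
            flank5=families.flank5,
            flank3=families.flank3,
            families=list(families.spec.families),
        )

    def types(self) -> list[Type]:
        return list(self.exon_seqs.keys())


# ---------------------------------------------------------------------------
# Gene hits


@dataclass
class GeneHit:
    read_id: str
    span: tuple[int, int]
    strand: str
    family: str
    subtype: Optional[str]
    score: int          # total exon-wise edit distance of the best type
    margin: int         # to the second-best family
    status: str         # "assigned" | "unassigned"


def _iter_template_hits(read: str, template: str, max_dist: int, max_hits: int = 128):
    """All non-overlapping infix matches of template in read, best first."""
    work = read
    for _ in range(max_hits):
        res = edlib.align(template, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            return
        start, end = res["locations"][0]
        end += 1  # edlib locations are inclusive
        yield start, end, res["editDistance"]
        work = work[:start] + "#" * (end - start) + work[end:]


def _locate_occurrences(read: str, index: TypingIndex, config: TypingConfig):
    """Cluster per-exon template hits into candidate gene occurrences."""
    hits = []  # (start, end, strand)
    for template in index.detection_templates:
        k = int(len(template) * config.detect_max_dist_frac)
        for strand, tpl in (("+", template), ("-", revcomp(template))):
            for s, e, _d in _iter_template_hits(read, tpl, k):
                hits.append((s, e, strand))
    occurrences = []
    for strand in "+-":
        strand_hits = sorted(h[:2] for h in hits if h[2] == strand)
        group: list[tuple[int, int]] = []
        for s, e in strand_hits:
            if group and s - group[-1][1] > config.occurrence_gap:
                occurrences.append((group[0][0], group[-1][1], strand))
                group = []
            group.append((s, e))
        if group:
            occurrences.append((group[0][0], group[-1][1], strand))
    return sorted(occurrences)


def _score_types(window: str, index: TypingIndex) -> dict:
    """Exon-wise summed edit distance of every type against a window."""
    scores = {}
    for typ, exons in index.exon_seqs.items():
        total = 0
        for exon in exons:
            d = infix_distance(exon, window)
            total += d if d >= 0 else len(exon)
        scores[typ] = total
    return scores


def scan_read(
    read_id: str,
    read: str,
    index: TypingIndex,
    config: TypingConfig = TypingConfig(),
) -> list[GeneHit]:
    """Locate and type every GH-like gene occurrence in a read.

    Family is assigned when the best family beats the second-best by at least
    ``margin_min`` total edit distance; subtype additionally requires a
    within-family margin of ``subtype_margin_min`` (subtype divergence is
    below long-read noise, so subtype is often None)."""
    if not read:
        return []
    hits: list[GeneHit] = []
    for start, end, strand in _locate_occurrences(read, index, config):
        w_start = max(0, start - config.window_pad)
        w_end = min(len(read), end + config.window_pad)
        window = read[w_start:w_end]
        if strand == "-":
            window = revcomp(window)
        scores = _score_types(window, index)
        fam_best: dict[str, int] = {}
        for (fam, _sub), s in scores.items():
            if fam not in fam_best or s < fam_best[fam]:
                fam_best[fam] = s
        ranked = sorted(fam_best.items(), key=lambda kv: kv[1])
        best_family, best_score = ranked[0]
        margin = (ranked[1][1] - best_score) if len(ranked) > 1 else best_score
        status = "assigned" if margin >= config.margin_min else "unassigned"
        sub_scores = sorted(
            (s, sub) for (fam, sub), s in scores.items() if fam == best_family
        )
        subtype = None
        if len(sub_scores) == 1:
            subtype = sub_scores[0][1]
        elif sub_scores[1][0] - sub_scores[0][0] >= config.subtype_margin_min:
            subtype = sub_scores[0][1]
        hits.append(
            GeneHit(
                read_id=read_id,
                span=(start, end),
                strand=strand,
                family=best_family,
                subtype=subtype if status == "assigned" else None,
                score=best_score,
                margin=margin,
                status=status,
            )
        )
    hits.sort(key=lambda h: (h.span[0], h.span[1]))
    # greedy non-overlap resolution: ascending score, ties leftmost
    chosen: list[GeneHit] = []
    for h in sorted(hits, key=lambda h: (h.score, h.span[0])):
        if all(h.span[1] <= c.span[0] or h.span[0] >= c.span[1] for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.span[0])
    return chosen


# ---------------------------------------------------------------------------
# Flank detection


@dataclass
class FlankResult:
    has_5prime: bool
    has_3prime: bool
    orientation: str  # "forward" | "reverse" | "ambiguous" | "unknown"


def _find_flank(read: str, template: str, config: TypingConfig):
    """Presence requires a local match of >= flank_min_cov of the template at
    <= flank_max_dist_frac edit distance; halves rescue truncated flanks."""
    half = len(template) // 2
    pieces = [template, template[:half], template[half:]]
    best = None  # (strand)
    for piece in pieces:
        if len(piece) < config.flank_min_cov * len(template):
            continue
        k = int(len(piece) * config.flank_max_dist_frac)
        for strand, tpl in (("+", piece), ("-", revcomp(piece))):
            if infix_distance(tpl, read, k=k) >= 0:
                return strand
    return best


def detect_flanks(
    read: str, index: TypingIndex, config: TypingConfig = TypingConfig()
) -> FlankResult:
    s5 = _find_flank(read, index.flank5, config)
    s3 = _find_flank(read, index.flank3, config)
    strands = {s for s in (s5, s3) if s is not None}
    if not strands:
        orientation = "unknown"
    elif len(strands) > 1:
        orientation = "ambiguous"
        warnings.warn("conflicting flank strands; orientation ambiguous")
    else:
        orientation = "forward" if strands == {"+"} else "reverse"
    return FlankResult(s5 is not None, s3 is not None, orientation)


# ---------------------------------------------------------------------------
# Discriminating probe design


@dataclass
class Probe:
    sequence: str
    offset: int  # 0-based offset in the homologized (reference) coordinates
    margin: int  # minimum edit distance to every other type's window


@dataclass
class ProbeSet:
    probe_len: int
    probes: dict                       # Type -> list[Probe]
    groups: list                       # lists of mutually indistinguishable types
    cds_by_type: dict = field(default_factory=dict)

    def group_of(self, typ: Type) -> tuple:
        for g in self.groups:
            if typ in g:
                return tuple(g)
        raise KeyError(typ)


def _homologize(cds_by_type: dict) -> dict:
    """Project every CDS onto the coordinates of the first one (deletions
    become '-', insertions relative to the reference are dropped)."""
    types = list(cds_by_type)
    ref = cds_by_type[types[0]]
    out = {}
    for t in types:
        seq = cds_by_type[t]
        if len(seq) == len(ref):
            out[t] = seq
            continue
        res = edlib.align(seq, ref, mode="NW", task="path")
        aligned = ["-"] * len(ref)
        qpos = rpos = 0
        import re

        for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            n = int(n)
            if op in "=XM":
                for i in range(n):
                    aligned[rpos + i] = seq[qpos + i]
                qpos += n
                rpos += n
            elif op == "I":  # present in query, absent in reference
                qpos += n
            else:  # deletion relative to reference
                rpos += n
        out[t] = "".join(aligned)
    return out


def design_discriminating_probes(
    cds_by_type: dict, probe_len: int = 80
) -> ProbeSet:
    """All length-``probe_len`` windows that separate each type from every
    other type by edit distance >= 1, annotated with the separation margin.

    Types with no discriminating window against some other type are merged
    into one indistinguishable group (quantified jointly downstream)."""
    if len(cds_by_type) < 2:
        raise ValueError("need at least 2 types to design discriminating probes")
    types = list(cds_by_type)
    hom = _homologize(cds_by_type)
    ref_len = len(next(iter(hom.values())))
    n_win = ref_len - probe_len + 1
    if n_win <= 0:
        raise ValueError("probe_len longer than the sequences")

    # pairwise window distances (degapped window strings)
    windows = {t: [hom[t][i : i + probe_len].replace("-", "") for i in range(n_win)] for t in types}
    probes: dict = {t: [] for t in types}
    indist_pairs = set()
    for a_i, a in enumerate(types):
        for i in range(n_win):
            wa = windows[a][i]
            margin = None
            for b in types:
                if b == a:
                    continue
                d = edit_distance(wa, windows[b][i])
                margin = d if margin is None else min(margin, d)
                if margin == 0:
                    break
            if margin and margin >= 1:
                probes[a].append(Probe(sequence=wa, offset=i, margin=margin))
        for b in types[a_i + 1 :]:
            if hom[a].replace("-", "") == hom[b].replace("-", ""):
                indist_pairs.add((a, b))

    # union-find over identical sequences
    parent = {t: t for t in types}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in indist_pairs:
        parent[find(a)] = find(b)
    # types that found no probes but are not literally identical to anything:
    # merge them with their closest type (no window separates them reliably)
    groups: dict = {}
    for t in types:
        groups.setdefault(find(t), []).append(t)
    if indist_pairs:
        warnings.warn(
            f"indistinguishable types merged into joint groups: "
            f"{[g for g in groups.values() if len(g) > 1]}"
        )
    return ProbeSet(
        probe_len=probe_len,
        probes=probes,
        groups=sorted(groups.values()),
        cds_by_type=dict(cds_by_type),
    )
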