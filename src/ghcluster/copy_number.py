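"""Per-family gene copy number from short-read hit counts, normalized to
single-copy anchor families.

A read votes for the family whose exon-5 reference it matches best (edit
distance), provided it meets minimum overlap and identity and beats the
second-best family by at least one edit; ties go to the unassigned class.
Counts are scaled so that the mean over the anchor families (GH, CSH1, CSH3
by default — each present exactly once per haplotype) equals 1, making the
scaled count per family an estimate of its copy number per haplotype.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .core import SeqRecord, revcomp

UNASSIGNED = "unassigned"
DEFAULT_ANCHORS = ("GH", "CSH1", "CSH3")


@dataclass
class CountConfig:
    min_overlap: int = 60
    min_identity: float = 0.90
    margin_min: int = 1
    prefilter_slack: float = 0.06


def _best_distance(read: str, reference: str) -> tuple[int, int]:
    """(edit distance, compared length) of the read against a reference,
    trying both strands; the shorter sequence is aligned as an infix of the
    longer one."""
    if len(read) <= len(reference):
        query_len = len(read)
        pairs = ((read, reference), (revcomp(read), reference))
    else:
        query_len = len(reference)
        pairs = ((reference, read), (reference, revcomp(read)))
    best = query_len
    for q, t in pairs:
        d = edlib.align(q, t, mode="HW", task="distance", k=best)["editDistance"]
        if 0 <= d < best:
            best = d
    return best, query_len


_N_EQUALITIES = [("N", c) for c in "ACGT"]


class _OverlapScorer:
    """Semi-global read-vs-reference scoring via edlib.

    The reference is padded with ``read_len - min_overlap`` wildcard Ns on
    each side (N matches any base at no cost), so a read may overhang either
    reference end freely while any alignment placement is forced to cover at
    least ``min_overlap`` real reference columns.  The edit distance then
    counts differences over the overlap only — the behavior of a local
    (BLAST-style) alignment, at edlib speed and uniform across families.
    """

    def __init__(self, ref: str, min_overlap: int):
        self.ref = ref
        self.min_overlap = min_overlap
        self._padded: dict[int, str] = {}

    def __call__(self, read: str) -> tuple[int, int]:
        """(edit distance over the overlap, overlap length); both strands."""
        pad = max(0, len(read) - self.min_overlap)
        padded = self._padded.get(pad)
        if padded is None:
            padded = "N" * pad + self.ref + "N" * pad
            self._padded[pad] = padded
        best_d, best_ov = len(read), 0
        ref_span = (pad, pad + len(self.ref))
        for seq in (read, revcomp(read)):
            res = edlib.align(
                seq, padded, mode="HW", task="locations",
                additionalEqualities=_N_EQUALITIES,
            )
            d = res["editDistance"]
            for s, e in res["locations"]:
                ov = min(e + 1, ref_span[1]) - max(s, ref_span[0])
                if ov >= self.min_overlap and (
                    best_ov == 0 or d / ov < best_d / best_ov
                ):
                    best_d, best_ov = d, ov
        return best_d, best_ov


def count_exon5_hits(
    short_reads: Sequence[SeqRecord],
    exon5_by_family: dict,
    config: CountConfig = CountConfig(),
) -> dict:
    """Per-family read hit counts plus an unassigned count.

    A read hits a family when its best local overlap with that family's
    exon-5 reference spans >= min_overlap nt at >= min_identity, and the
    best family beats the second best by >= margin_min edits.  Each read
    counts at most once; reads matching no family contribute nothing; reads
    without a clear best family count as unassigned.  A consensus prefilter
    rejects the non-GH-like bulk cheaply before per-family scoring.
    """
    from .read_typing import _consensus

    counts = {fam: 0 for fam in exon5_by_family}
    counts[UNASSIGNED] = 0
    prefilter = _OverlapScorer(_consensus(list(exon5_by_family.values())), config.min_overlap)
    scorers = {
        fam: _OverlapScorer(ref, config.min_overlap)
        for fam, ref in exon5_by_family.items()
    }
    for rec in short_reads:
        seq = rec.sequence if isinstance(rec, SeqRecord) else rec
        d, qlen = prefilter(seq)
        if qlen < config.min_overlap:
            continue
        if 1.0 - d / qlen < config.min_identity - config.prefilter_slack:
            continue
        scored = []
        for fam, scorer in scorers.items():
            d, qlen = scorer(seq)
            if qlen < config.min_overlap:
                continue
            scored.append((d, qlen, fam))
        if not scored:
            continue
        scored.sort()
        d1, qlen, fam1 = scored[0]
        if 1.0 - d1 / qlen < config.min_identity:
            continue
        if len(scored) > 1 and scored[1][0] - d1 < config.margin_min:
            counts[UNASSIGNED] += 1
        else:
            counts[fam1] += 1
    return counts


def normalize_copy_number(
    counts: dict, anchors: Sequence[str] = DEFAULT_ANCHORS
) -> dict:
    """Scale hit counts so the anchor-family mean is exactly 1.

    c_t = h_t / mean(h_a for a in anchors).  The unassigned count is carried
    through unchanged (reported, not normalized).
    """
    for a in anchors:
        if counts.get(a, 0) <= 0:
            raise ValueError(
                f"anchor family {a!r} has zero hits (insufficient coverage)"
            )
    anchor_mean = sum(counts[a] for a in anchors) / len(anchors)
    out = {
        fam: c / anchor_mean for fam, c in counts.items() if fam != UNASSIGNED
    }
    if UNASSIGNED in counts:
        out[UNASSIGNED] = counts[UNASSIGNED]
    return out


@dataclass
class ReplicateSummary:
    mean: dict          # family -> mean normalized estimate
    sem: dict           # family -> standard error of the mean
    n: int
    single_replicate: bool = False


def aggregate_replicates(estimate_tables: Sequence[dict]) -> ReplicateSummary:
    """Mean and SEM per family over replicate estimate tables.

    SEM = sample standard deviation (ddof=1) / sqrt(n); for a single
    replicate SEM is reported as 0 and the summary is flagged.
    """
    if not estimate_tables:
        raise ValueError("need at least one replicate")
    keys = [
        {k for k in t if k != UNASSIGNED} for t in estimate_tables
    ]
    if any(k != keys[0] for k in keys):
        raise ValueError("inconsistent family sets across replicates")
    n = len(estimate_tables)
    mean, sem = {}, {}
    for fam in sorted(keys[0]):
        vals = [t[fam] for t in estimate_tables]
        m = sum(vals) / n
        mean[fam] = m
        if n == 1:
            sem[fam] = 0.0
        else:
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))
            sem[fam] = sd / math.sqrt(n)
    return ReplicateSummary(mean=mean, sem=sem, n=n, single_replicate=(n == 1))


@dataclass
class GeneCountCall:
    copies: dict            # family -> rounded integer copies
    ambiguous: dict         # family -> (low, high) range for flagged estimates
    total: int
    total_range: tuple


def infer_gene_counts(
    mean_estimates: dict, ambiguity_band: float = 0.3
) -> GeneCountCall:
    """Round estimates to integer copies (half away from zero); estimates
    within ``ambiguity_band`` of a half-integer are additionally flagged and
    reported as a range (e.g. 3.57 -> 3-4)."""
    copies, ambiguous = {}, {}
    for fam, est in mean_estimates.items():
        if fam == UNASSIGNED:
            continue
        if est < 0:
            raise ValueError(f"negative estimate for {fam}")
        rounded = math.floor(est + 0.5)
        copies[fam] = rounded
        frac = est - math.floor(est)
        if abs(frac - 0.5) <= ambiguity_band:
            ambiguous[fam] = (math.floor(est), math.floor(est) + 1)
    total = sum(copies.values())
    low = sum(ambiguous.get(f, (c, c))[0] for f, c in copies.items())
    high = sum(ambiguous.get(f, (c, c))[1] for f, c in copies.items())
    return GeneCountCall(copies=copies, ambiguous=ambiguous, total=total,
                         total_range=(low, high))


@dataclass
class CopyNumberTable:
    """Full record of one copy-number experiment (shaped like a published
    per-species table: families x replicates, mean +/- SEM, inferred copies)."""

    raw_counts: list            # per-replicate hit-count dicts
    estimates: list             # per-replicate normalized estimates
    summary: ReplicateSummary
    call: GeneCountCall
    anchors: tuple = DEFAULT_ANCHORS


def copy_number_table(
    replicate_reads: Sequence[Sequence[SeqRecord]],
    exon5_by_family: dict,
    anchors: Sequence[str] = DEFAULT_ANCHORS,
    config: CountConfig = CountConfig(),
) -> CopyNumberTable:
    """End-to-end copy-number estimation over replicate read sets."""
    raw = [count_exon5_hits(reads, exon5_by_family, config) for reads in replicate_reads]
    est = [normalize_copy_number(c, anchors) for c in raw]
    summary = aggregate_replicates(est)
    call = infer_gene_counts(summary.mean)
    return CopyNumberTable(
        raw_counts=raw, estimates=est, summary=summary, call=call, anchors=tuple(anchors)
    )
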