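"""Paralog-type expression quantification in transcriptome read sets.

Reads are screened against the family coding sequences (>= 90% identity over
>= 60 nt makes a read "GH-like"), then assigned to the probe-distinguishable
group whose sequences beat all other groups by at least one edit; reads
without a clear winner form the unassigned class.  Groups default to the
paralog families (GH2a/b/c jointly, etc.) because recent subtypes differ at
too few positions for every read to separate them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .copy_number import _best_distance
from .core import SeqRecord
from .read_typing import ProbeSet, Type

UNASSIGNED = "unassigned"


def subsample_reads(
    reads: Sequence[SeqRecord],
    n: int,
    seed: int = 0,
    mode: str = "first",
) -> list[SeqRecord]:
    """Take the first n reads or a uniform random n (deterministic per seed).

    Transcriptome screens are typically run on a bounded subsample (100 000
    reads by default elsewhere in this package) because highly expressed
    genes make exhaustive search unnecessary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    reads = list(reads)
    if n >= len(reads):
        if n > len(reads):
            warnings.warn(f"requested {n} reads, only {len(reads)} available")
        return reads
    if mode == "first":
        return reads[:n]
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=n, replace=False)
        return [reads[i] for i in sorted(idx)]
    raise ValueError(f"unknown subsample mode {mode!r}")


@dataclass
class AssignConfig:
    min_overlap: int = 60
    min_identity: float = 0.90
    margin_min: int = 1
    prefilter_slack: float = 0.10


def _gh_like(seq: str, consensus: str, config: AssignConfig) -> bool:
    """Cheap family-consensus screen rejecting the non-GH-like bulk."""
    d, qlen = _best_distance(seq, consensus)
    return qlen >= config.min_overlap and (
        1.0 - d / qlen >= config.min_identity - config.prefilter_slack
    )


def _family_groups(probe_set: ProbeSet) -> dict:
    """Group types by family, merging any probe-indistinguishable groups that
    span families (none do for realistically divergent families)."""
    groups: dict[str, list[Type]] = {}
    for typ in probe_set.cds_by_type:
        groups.setdefault(typ[0], []).append(typ)
    return {_group_label(v): tuple(v) for v in groups.values()}


def _group_label(types: Sequence[Type]) -> str:
    fams = sorted({f for f, _ in types})
    if len(fams) == 1:
        subs = sorted(s for _, s in types if s is not None)
        return fams[0] + (",".join([""] + subs) if subs else "")
    return "+".join(fams)


def assign_transcript_reads(
    reads: Sequence[SeqRecord],
    probe_set: ProbeSet,
    config: AssignConfig = AssignConfig(),
    groups: Optional[dict] = None,
) -> tuple[dict, int]:
    """Per-group GH-like hit counts plus the unassigned count.

    Returns ``(counts, unassigned)``; counts keys are group labels such as
    ``"GH2a,b,c"``.  Conservation: sum(counts) + unassigned = total GH-like
    reads, always.
    """
    if not probe_set.cds_by_type:
        raise ValueError("empty probe set")
    if groups is None:
        groups = _family_groups(probe_set)
    counts = {label: 0 for label in groups}
    unassigned = 0
    from .read_typing import _consensus

    consensus = _consensus(list(probe_set.cds_by_type.values()))
    for rec in reads:
        seq = rec.sequence if isinstance(rec, SeqRecord) else rec
        if not _gh_like(seq, consensus, config):
            continue
        group_scores = []
        for label, members in groups.items():
            best = None
            for typ in members:
                d, qlen = _best_distance(seq, probe_set.cds_by_type[typ])
                if qlen < config.min_overlap:
                    continue
                if best is None or d < best[0]:
                    best = (d, qlen)
            if best is not None:
                group_scores.append((best[0], best[1], label))
        if not group_scores:
            continue
        group_scores.sort()
        d1, qlen, label1 = group_scores[0]
        if 1.0 - d1 / qlen < config.min_identity:
            continue
        if len(group_scores) > 1 and group_scores[1][0] - d1 < config.margin_min:
            unassigned += 1
        else:
            counts[label1] += 1
    return counts, unassigned


@dataclass
class ExpressionRow:
    group: str
    hits: int
    pct_of_all_reads: float
    pct_of_gh_like: float
    display: str  # "< floor" for zero-hit groups


@dataclass
class ExpressionTable:
    total_reads: int
    rows: list
    unassigned: int
    unassigned_pct_of_gh_like: float
    total_hits: int
    total_pct_of_all_reads: float
    detection_floor_pct: float

    def as_dict(self) -> dict:
        return {r.group: r.pct_of_gh_like for r in self.rows}


def expression_report(counts: dict, unassigned: int, total_reads: int) -> ExpressionTable:
    """Percentages of all reads and of the GH-like total, with a detection
    floor of 100/total_reads percent: zero-hit groups are reported as below
    the floor rather than as zero."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    total_hits = sum(counts.values()) + unassigned
    floor = 100.0 / total_reads
    rows = []
    for group in counts:
        h = counts[group]
        rows.append(
            ExpressionRow(
                group=group,
                hits=h,
                pct_of_all_reads=100.0 * h / total_reads,
                pct_of_gh_like=(100.0 * h / total_hits) if total_hits else 0.0,
                display=(f"< {floor:.5g}" if h == 0 else f"{100.0 * h / total_reads:.4g}"),
            )
        )
    return ExpressionTable(
        total_reads=total_reads,
        rows=rows,
        unassigned=unassigned,
        unassigned_pct_of_gh_like=(100.0 * unassigned / total_hits) if total_hits else 0.0,
        total_hits=total_hits,
        total_pct_of_all_reads=100.0 * total_hits / total_reads,
        detection_floor_pct=floor,
    )


def subtype_share(
    reads: Sequence[SeqRecord],
    probe_set: ProbeSet,
    family: str,
    config: AssignConfig = AssignConfig(),
) -> tuple[dict, int]:
    """Secondary estimator: apportion a family's reads among its subtypes by
    discriminating-position votes, counting only reads that separate a unique
    best subtype (coverage caveat: many reads cover no discriminating
    position and cast no vote).  Returns (shares, n_informative)."""
    members = [t for t in probe_set.cds_by_type if t[0] == family]
    if len(members) < 2:
        raise ValueError(f"family {family!r} has fewer than 2 subtypes")
    votes = {t: 0 for t in members}
    from .read_typing import _consensus

    consensus = _consensus(list(probe_set.cds_by_type.values()))
    for rec in reads:
        seq = rec.sequence if isinstance(rec, SeqRecord) else rec
        if not _gh_like(seq, consensus, config):
            continue
        # the read must belong to the target family, not merely resemble it:
        # nearby families sit within the identity threshold of each other
        fam_best: dict[str, int] = {}
        qlen1 = 0
        for typ, cds in probe_set.cds_by_type.items():
            d, qlen = _best_distance(seq, cds)
            if qlen < config.min_overlap:
                continue
            if typ[0] not in fam_best or d < fam_best[typ[0]]:
                fam_best[typ[0]] = d
                if typ[0] == family:
                    qlen1 = qlen
        if family not in fam_best:
            continue
        d_fam = fam_best[family]
        if 1.0 - d_fam / max(qlen1, 1) < config.min_identity:
            continue
        others = [d for f, d in fam_best.items() if f != family]
        if others and min(others) - d_fam < config.margin_min:
            continue
        scored = sorted(
            (_best_distance(seq, probe_set.cds_by_type[t])[0], t) for t in members
        )
        if len(scored) > 1 and scored[1][0] - scored[0][0] >= 1:
            votes[scored[0][1]] += 1
    n_informative = sum(votes.values())
    shares = {
        t: (v / n_informative if n_informative else 0.0) for t, v in votes.items()
    }
    return shares, n_informative
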