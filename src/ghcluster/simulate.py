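"""Synthetic GH-cluster loci, diploid individuals, reads, transcriptome
mixtures and codon alignments with known ground truth.

The generator emulates the structure of the macaque growth-hormone locus: a
~150 kb tandem array of 11-14 five-exon GH-like genes drawn from six paralog
families (GH, CSH1, GH2, CSH2, CSH3, CSH4), with recent within-family
duplicates (subtypes a/b/c) that are nearly identical (~0.5% pairwise
divergence) while families remain clearly distinguishable (~8% pairwise
divergence).  The cluster is flanked by unique anchor genes, CD79B (5')
and TCAM1P (3').  CSH3 is generated as a pseudogene, carrying a 1-nt
frameshift deletion in exon 5 and a premature stop codon.

Every generator takes an explicit seed; the same seed gives byte-identical
output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon import (
    CodonPropagator,
    STOP_CODONS,
    codons_to_indices,
    f3x4,
    indices_to_cds,
    translate,
)
from .core import AnnotatedLocus, GeneFeature, LabeledTree, SeqRecord, revcomp

NT = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default five-exon gene model: CDS split across exons, fixed intron lengths.
EXON_CDS_SPLITS = (24, 140, 120, 162, 208)  # sums to 654 nt (217 codons + stop)
INTRON_LENS = (260, 210, 190, 280)
FLANK5_NAME, FLANK3_NAME = "CD79B", "TCAM1P"
FLANK_LEN = 2000
OUTER_MARGIN = 2000

DEFAULT_FAMILY_ORDER = ("GH", "CSH1", "GH2", "CSH2", "CSH3", "CSH4")
DEFAULT_SUBTYPE_COUNTS = {"GH": 1, "CSH1": 1, "GH2": 3, "CSH2": 3, "CSH3": 1, "CSH4": 3}
ANCHOR_FAMILIES = ("GH", "CSH1", "CSH3")  # single-copy in every haplotype


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def random_dna(n: int, rng: np.random.Generator) -> str:
    return rng.choice(NT, size=n).tobytes().decode()


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS of ``n_codons`` sense codons plus a TAA stop."""
    codons = []
    while len(codons) < n_codons:
        c = random_dna(3, rng)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons) + "TAA"


def evolve_cds(cds: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``divergence``.

    Substitutions that would create an internal stop codon are resampled; the
    terminal stop codon is never touched.  Expected number of differences from
    the input is Binomial(len - 3, divergence).
    """
    body, stop = cds[:-3], cds[-3:]
    arr = np.frombuffer(body.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    for pos in hits:
        old = arr[pos]
        codon_start = 3 * (pos // 3)
        for _ in range(10):
            new = NT[rng.integers(4)]
            if new == old:
                continue
            arr[pos] = new
            codon = arr[codon_start : codon_start + 3].tobytes().decode()
            if codon not in STOP_CODONS:
                break
            arr[pos] = old
    return arr.tobytes().decode() + stop


def evolve_neutral(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Neutral i.i.d. substitution (introns, spacers)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    shift = rng.integers(1, 4, size=hits.size)
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    for pos, s in zip(hits, shift):
        arr[pos] = NT[(lut[arr[pos]] + s) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Family specification and realization


@dataclass
class PseudogeneSpec:
    """Coordinates (0-based, CDS) of injected inactivating mutations."""

    frameshift_deletion: int = 570  # inside the exon-5 portion of the CDS
    premature_stop_codon: int = 150  # codon index rewritten to TGA


@dataclass
class FamilySpec:
    families: tuple[str, ...] = DEFAULT_FAMILY_ORDER
    subtype_counts: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS))
    between_divergence: float = 0.08   # expected pairwise, family vs family
    within_divergence: float = 0.005   # expected pairwise, subtype vs subtype
    intron_rate_factor: float = 2.0    # introns evolve faster than CDS
    pseudogenes: dict = field(default_factory=lambda: {"CSH3": PseudogeneSpec()})
    anchor_families: tuple[str, ...] = ANCHOR_FAMILIES

    def __post_init__(self) -> None:
        if not (0 <= self.within_divergence < self.between_divergence <= 0.5):
            raise ValueError(
                "require 0 <= within_divergence < between_divergence <= 0.5"
            )
        if not set(self.anchor_families) <= set(self.families):
            raise ValueError("anchor families must be declared families")


def _subtype_letters(n: int) -> list[Optional[str]]:
    if n == 1:
        return [None]
    return [chr(ord("a") + i) for i in range(n)]


@dataclass
class ParalogFamilies:
    """Realized paralog family sequences with full ground truth."""

    spec: FamilySpec
    ancestor_cds: str
    cds: dict  # (family, subtype|None) -> CDS string
    introns: dict  # (family, subtype|None) -> tuple of 4 intron strings
    exon_splits: dict  # (family, subtype|None) -> tuple of 5 CDS chunk lengths
    proteins: dict  # (family, subtype|None) -> protein (pseudogenes excluded)
    pseudogene_truth: dict  # family -> PseudogeneSpec
    flank5: str
    flank3: str

    def types(self) -> list[tuple[str, Optional[str]]]:
        return list(self.cds.keys())

    def families(self) -> list[str]:
        return list(self.spec.families)

    def subtypes_of(self, family: str) -> list[Optional[str]]:
        return [s for (f, s) in self.cds if f == family]

    def gene_sequence(self, family: str, subtype: Optional[str]) -> str:
        """Genomic gene: five exons interleaved with introns."""
        key = (family, subtype)
        cds, splits, introns = self.cds[key], self.exon_splits[key], self.introns[key]
        exons, pos = [], 0
        for ln in splits:
            exons.append(cds[pos : pos + ln])
            pos += ln
        parts = [exons[0]]
        for i in range(4):
            parts.append(introns[i])
            parts.append(exons[i + 1])
        return "".join(parts)

    def exon_genomic_spans(self, family: str, subtype: Optional[str]) -> list[tuple[int, int]]:
        splits = self.exon_splits[(family, subtype)]
        spans, pos = [], 0
        for i, ln in enumerate(splits):
            spans.append((pos, pos + ln))
            pos += ln
            if i < 4:
                pos += INTRON_LENS[i]
        return spans

    def exon5_by_family(self) -> dict:
        """Representative exon-5 CDS chunk per family (first subtype)."""
        out = {}
        for (fam, sub), cds in self.cds.items():
            if fam in out:
                continue
            splits = self.exon_splits[(fam, sub)]
            out[fam] = cds[sum(splits[:4]) :]
        return out

    def cds_by_type(self, include_pseudogenes: bool = True) -> dict:
        return {
            k: v
            for k, v in self.cds.items()
            if include_pseudogenes or k[0] not in self.pseudogene_truth
        }


def make_paralog_families(
    ancestor_cds: Optional[str] = None,
    spec: Optional[FamilySpec] = None,
    seed: int = 0,
) -> ParalogFamilies:
    """Evolve a set of paralog families (and near-identical subtypes) from a
    common ancestral CDS.

    Families diverge from the ancestor at ``between_divergence / 2`` per
    lineage (so family-vs-family pairwise divergence matches the spec value);
    subtypes diverge from their family sequence at ``within_divergence / 2``.
    Introns evolve ``intron_rate_factor`` times faster.  Pseudogene families
    then receive their injected frameshift and premature stop.
    """
    spec = spec or FamilySpec()
    rng = _rng(seed)
    if ancestor_cds is None:
        ancestor_cds = random_cds(217, rng)
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor CDS length must be divisible by 3")
    ancestor_introns = tuple(random_dna(n, rng) for n in INTRON_LENS)

    d_fam = spec.between_divergence / 2
    d_sub = spec.within_divergence / 2
    intron_f = spec.intron_rate_factor

    cds, introns, splits, proteins, pseudo_truth = {}, {}, {}, {}, {}
    for family in spec.families:
        fam_cds = evolve_cds(ancestor_cds, d_fam, rng)
        fam_introns = tuple(
            evolve_neutral(i, min(0.49, d_fam * intron_f), rng) for i in ancestor_introns
        )
        pg = spec.pseudogenes.get(family)
        if pg is not None:
            fam_cds = _inject_pseudogene(fam_cds, pg)
            pseudo_truth[family] = pg
        for sub in _subtype_letters(spec.subtype_counts.get(family, 1)):
            key = (family, sub)
            if pg is None:
                sub_cds = evolve_cds(fam_cds, d_sub, rng)
                proteins[key] = translate(sub_cds)[:-1]  # drop trailing stop
            else:
                sub_cds = evolve_neutral(fam_cds, d_sub, rng)
            cds[key] = sub_cds
            introns[key] = tuple(
                evolve_neutral(i, min(0.49, d_sub * intron_f), rng) for i in fam_introns
            )
            last = len(sub_cds) - sum(EXON_CDS_SPLITS[:4])
            splits[key] = EXON_CDS_SPLITS[:4] + (last,)

    flank5 = random_dna(FLANK_LEN, rng)
    flank3 = random_dna(FLANK_LEN, rng)
    return ParalogFamilies(
        spec=spec,
        ancestor_cds=ancestor_cds,
        cds=cds,
        introns=introns,
        exon_splits=splits,
        proteins=proteins,
        pseudogene_truth=pseudo_truth,
        flank5=flank5,
        flank3=flank3,
    )


def _inject_pseudogene(cds: str, pg: PseudogeneSpec) -> str:
    stop_nt = 3 * pg.premature_stop_codon
    out = cds[:stop_nt] + "TGA" + cds[stop_nt + 3 :]
    out = out[: pg.frameshift_deletion] + out[pg.frameshift_deletion + 1 :]
    return out


# ---------------------------------------------------------------------------
# Haplotype structures and loci


@dataclass(frozen=True)
class HaplotypeStructure:
    """Ordered gene content of one cluster haplotype (5' -> 3')."""

    name: str
    genes: tuple  # tuple of (family, subtype|None)

    def __post_init__(self) -> None:
        if self.genes and self.genes[0][0] != "GH":
            raise ValueError("first gene in the cluster must be GH")

    def families(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.genes)

    def copy_numbers(self) -> dict:
        out: dict[str, int] = {}
        for f, _ in self.genes:
            out[f] = out.get(f, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.genes)


def _pairs(*subs: str) -> list[tuple[str, Optional[str]]]:
    out = []
    for s in subs:
        out += [("GH2", s), ("CSH2", s)]
    return out


def cluster_structures() -> dict[str, HaplotypeStructure]:
    """The five canonical M. fascicularis cluster arrangements (11/12/13/14/13
    genes).  The 11-gene form is the base; the others add a CSH4 copy, a
    GH2-CSH2 pair, both, or a lone extra GH2."""
    head = [("GH", None), ("CSH1", None)]
    tail2 = [("CSH3", None), ("CSH4", "a"), ("CSH4", "b")]
    tail3 = tail2 + [("CSH4", "c")]
    base = head + _pairs("a", "b", "c")
    s = {
        "I": base + tail2,
        "II": base + tail3,
        "III": head + _pairs("a", "b", "c", "c") + tail2,
        "IV": head + _pairs("a", "b", "c", "c") + tail3,
        "V": head + _pairs("a", "b") + [("GH2", "b")] + _pairs("c") + tail3,
    }
    return {k: HaplotypeStructure(name=k, genes=tuple(v)) for k, v in s.items()}


def build_haplotype(
    structure: HaplotypeStructure,
    families: ParalogFamilies,
    spacer_range: tuple[int, int] = (6000, 13000),
    seed: int = 0,
) -> AnnotatedLocus:
    """Assemble a locus: outer margin, CD79B, the gene array with random
    spacers, TCAM1P, outer margin.  All genes on the plus strand."""
    for fam, sub in structure.genes:
        if (fam, sub) not in families.cds:
            raise KeyError(f"structure names unknown gene type {(fam, sub)}")
    rng = _rng(seed)
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        span = (pos, pos + len(seq))
        pos += len(seq)
        return span

    emit(random_dna(OUTER_MARGIN, rng))
    span = emit(families.flank5)
    features.append(GeneFeature(FLANK5_NAME, FLANK5_NAME, None, "+", span))
    emit(random_dna(int(rng.integers(*spacer_range)), rng))
    for i, (fam, sub) in enumerate(structure.genes):
        gene = families.gene_sequence(fam, sub)
        span = emit(gene)
        exon_spans = [
            (span[0] + s, span[0] + e) for s, e in families.exon_genomic_spans(fam, sub)
        ]
        label = f"{fam}{sub or ''}_{i + 1}"
        features.append(GeneFeature(label, fam, sub, "+", span, exon_spans))
        emit(random_dna(int(rng.integers(*spacer_range)), rng))
    span = emit(families.flank3)
    features.append(GeneFeature(FLANK3_NAME, FLANK3_NAME, None, "+", span))
    emit(random_dna(OUTER_MARGIN, rng))
    return AnnotatedLocus(sequence="".join(parts), features=features)


@dataclass
class DiploidIndividual:
    id: str
    structures: tuple[HaplotypeStructure, HaplotypeStructure]
    loci: tuple[AnnotatedLocus, AnnotatedLocus]

    @property
    def homozygous(self) -> bool:
        return self.structures[0].genes == self.structures[1].genes


def make_individual(
    individual_id: str,
    structure_a: HaplotypeStructure,
    structure_b: HaplotypeStructure,
    families: ParalogFamilies,
    spacer_range: tuple[int, int] = (6000, 13000),
    seed: int = 0,
) -> DiploidIndividual:
    """Homozygotes carry two copies of one locus realization (the two
    chromosomes are identical); heterozygotes get independent realizations."""
    rng = _rng(seed)
    locus_a = build_haplotype(structure_a, families, spacer_range, _sub_seed(rng))
    if structure_a.genes == structure_b.genes:
        locus_b = locus_a
    else:
        locus_b = build_haplotype(structure_b, families, spacer_range, _sub_seed(rng))
    return DiploidIndividual(individual_id, (structure_a, structure_b), (locus_a, locus_b))


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ErrorProfile:
    """Per-base i.i.d. error rates and read-length model.

    ``read_len_mean`` None means full-span reads (the whole locus).  The
    default ONT-like profile is indel dominated, as in real very long nanopore
    reads over this locus.
    """

    sub: float = 0.02
    ins: float = 0.015
    dele: float = 0.025
    read_len_mean: Optional[int] = None
    read_len_sd: int = 0

    def __post_init__(self) -> None:
        rates = (self.sub, self.ins, self.dele)
        if any(not (0 <= r < 1) for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be in [0,1) and sum < 0.5")

    @property
    def total(self) -> float:
        return self.sub + self.ins + self.dele

    @classmethod
    def ont(cls, **kw) -> "ErrorProfile":
        return cls(sub=0.02, ins=0.015, dele=0.025, **kw)

    @classmethod
    def accurate(cls, read_len_mean: Optional[int] = 25000, read_len_sd: int = 3000) -> "ErrorProfile":
        """PacBio-like: >20 kb reads, total error <= 0.005."""
        return cls(sub=0.002, ins=0.0015, dele=0.0015,
                   read_len_mean=read_len_mean, read_len_sd=read_len_sd)

    @classmethod
    def perfect(cls, **kw) -> "ErrorProfile":
        return cls(sub=0.0, ins=0.0, dele=0.0, **kw)


_NT_LUT = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_LUT[_b] = _i


def apply_errors(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions, single-base insertions and deletions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if profile.ins > 0:
        ins_pos = np.nonzero(rng.random(arr.size) < profile.ins)[0]
        if ins_pos.size:
            arr = np.insert(arr, ins_pos, NT[rng.integers(4, size=ins_pos.size)])
    n = arr.size
    if profile.sub > 0:
        sub_pos = np.nonzero(rng.random(n) < profile.sub)[0]
        if sub_pos.size:
            shift = rng.integers(1, 4, size=sub_pos.size)
            arr[sub_pos] = NT[(_NT_LUT[arr[sub_pos]] + shift) % 4]
    if profile.dele > 0:
        keep = rng.random(arr.size) >= profile.dele
        arr = arr[keep]
    return arr.tobytes().decode()


def simulate_long_reads(
    individual: DiploidIndividual,
    n_reads: int,
    profile: ErrorProfile = ErrorProfile(),
    seed: int = 0,
) -> tuple[list[SeqRecord], list[dict]]:
    """Long reads from random haplotypes/strands, with a truth table.

    Full-span mode (``read_len_mean`` None) emits reads covering the entire
    haplotype.  Truth rows record haplotype index, span and strand.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = _rng(seed)
    locus_len = min(len(l.sequence) for l in individual.loci)
    if profile.read_len_mean is not None and profile.read_len_mean < locus_len:
        warnings.warn(
            "read length distribution is shorter than the locus; "
            "full-span reads will be rare"
        )
    records, truth = [], []
    for i in range(n_reads):
        hap = int(rng.integers(2))
        seq = individual.loci[hap].sequence
        if profile.read_len_mean is None:
            start, end = 0, len(seq)
        else:
            ln = max(200, int(rng.normal(profile.read_len_mean, profile.read_len_sd or 1)))
            ln = min(ln, len(seq))
            start = int(rng.integers(0, len(seq) - ln + 1))
            end = start + ln
        frag = seq[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        read = apply_errors(frag, profile, rng)
        rid = f"{individual.id}_read{i:04d}"
        records.append(SeqRecord(id=rid, sequence=read))
        truth.append(
            {"read_id": rid, "hap_index": hap, "start": start, "end": end, "strand": strand}
        )
    return records, truth


def simulate_short_reads(
    individual: DiploidIndividual,
    coverage: float,
    read_len: int = 150,
    seed: int = 0,
    sub_rate: float = 0.001,
) -> list[SeqRecord]:
    """Uniform-coverage short reads; ``coverage`` is per-haplotype depth."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (50 <= read_len <= 300):
        raise ValueError("read_len must be within [50, 300]")
    rng = _rng(seed)
    records = []
    err = ErrorProfile(sub=sub_rate, ins=0.0, dele=0.0)
    for hap, locus in enumerate(individual.loci):
        L = len(locus.sequence)
        if read_len > L:
            raise ValueError("read_len exceeds locus length")
        n = int(round(L * coverage / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n)
        strands = rng.random(n) < 0.5
        for i, (s, fwd) in enumerate(zip(starts, strands)):
            frag = locus.sequence[s : s + read_len]
            if not fwd:
                frag = revcomp(frag)
            if sub_rate > 0:
                frag = apply_errors(frag, err, rng)
            records.append(
                SeqRecord(id=f"{individual.id}_h{hap}_sr{i:06d}", sequence=frag)
            )
    return records


# ---------------------------------------------------------------------------
# Transcriptome mixtures


@dataclass
class ExpressionProfile:
    """Per-type fraction of all transcripts plus a background fraction."""

    fractions: dict  # (family, subtype|None) -> fraction of all reads
    background: float

    def __post_init__(self) -> None:
        vals = list(self.fractions.values()) + [self.background]
        if any(v < 0 for v in vals):
            raise ValueError("fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("fractions plus background must sum to 1")


def pituitary_profile(gh_fraction: float = 0.01) -> ExpressionProfile:
    """Pituitary-like: GH ~1% of all transcripts, nothing else GH-like."""
    return ExpressionProfile(
        fractions={("GH", None): gh_fraction}, background=1.0 - gh_fraction
    )


def day140_profile(total_gh_like: float = 0.00473) -> ExpressionProfile:
    """Late-gestation placenta-like mixture: GH-like reads are ~0.47% of all
    transcripts, split CSH1 21% / GH2 52% / CSH2 27% of the GH-like total,
    with GH2a carrying 60% of the GH2 share."""
    shares = {
        ("CSH1", None): 0.21,
        ("GH2", "a"): 0.52 * 0.60,
        ("GH2", "b"): 0.52 * 0.25,
        ("GH2", "c"): 0.52 * 0.15,
        ("CSH2", "a"): 0.27 * 0.40,
        ("CSH2", "b"): 0.27 * 0.35,
        ("CSH2", "c"): 0.27 * 0.25,
    }
    fractions = {k: v * total_gh_like for k, v in shares.items()}
    return ExpressionProfile(
        fractions=fractions, background=1.0 - sum(fractions.values())
    )


def simulate_transcriptome(
    profile: ExpressionProfile,
    families: ParalogFamilies,
    n_reads: int,
    read_len: int = 150,
    seed: int = 0,
) -> list[SeqRecord]:
    """Multinomial transcript mixture: GH-like reads are error-free fragments
    of the corresponding CDS; background reads are random sequence."""
    rng = _rng(seed)
    types = list(profile.fractions.keys())
    probs = np.array([profile.fractions[t] for t in types] + [profile.background])
    counts = rng.multinomial(n_reads, probs / probs.sum())
    records = []
    k = 0
    for t, c in zip(types, counts[:-1]):
        cds = families.cds[t]
        for _ in range(c):
            if len(cds) <= read_len:
                frag = cds
            else:
                s = int(rng.integers(0, len(cds) - read_len + 1))
                frag = cds[s : s + read_len]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            records.append(SeqRecord(id=f"tx{k:06d}", sequence=frag))
            k += 1
    for _ in range(counts[-1]):
        records.append(SeqRecord(id=f"tx{k:06d}", sequence=random_dna(read_len, rng)))
        k += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# Codon-alignment evolution


def simulate_codon_evolution(
    tree: LabeledTree,
    root_cds: str,
    kappa: float,
    omega_by_class: dict,
    seed: int = 0,
):
    """Evolve a stop-free CDS along a labeled tree under a GY94-style model.

    Branch lengths are expected substitutions/codon; each branch uses the
    omega of its class.  States are confined to sense codons, so internal
    stops can never arise.  Returns a CodonAlignment over the leaf taxa.
    """
    from .molevol import CodonAlignment

    if any(w < 0 for w in omega_by_class.values()):
        raise ValueError("omega must be >= 0")
    root_idx = codons_to_indices(root_cds)  # raises on stops / bad length
    pi = f3x4([root_cds])
    props = {c: CodonPropagator(kappa, w, pi) for c, w in omega_by_class.items()}
    rng = _rng(seed)

    states = {id(tree.root): root_idx}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        if node.cls not in props:
            raise KeyError(f"no omega supplied for branch class {node.cls}")
        if node.length <= 0:
            child = parent_states.copy()
        else:
            P = props[node.cls].transition_matrix(node.length)
            child = parent_states.copy()
            for s in np.unique(parent_states):
                mask = parent_states == s
                child[mask] = rng.choice(P.shape[1], size=int(mask.sum()), p=P[s])
        states[id(node)] = child

    leaves = tree.leaves()
    return CodonAlignment(
        names=[n.name for n in leaves],
        rows=[indices_to_cds(states[id(n)]) for n in leaves],
    )
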