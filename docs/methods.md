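# Methods

This note records the models, conventions and numerical choices behind
`ghcluster`, and what the synthetic-data generator does and does not
emulate.

## The synthetic locus generator

The generator produces tandem GH-like gene clusters with known ground
truth. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical output.

**Gene model.** Each gene is a 654-nt CDS (217 codons: a 26-residue signal
peptide, 191-residue mature protein, terminal stop) split over five exons
(24/140/120/162/208 nt of CDS) separated by fixed-length introns
(260/210/190/280 nt). Gene span ≈ 1.6 kb.

**Families and subtypes.** Six families (GH, CSH1, GH2, CSH2, CSH3, CSH4)
descend from one random ancestral CDS. Families diverge from the ancestor
at half the *between-family divergence* per lineage, so family-vs-family
pairwise divergence matches the nominal value (default 8%); subtypes
(a/b/c in GH2, CSH2, CSH4) diverge from their family sequence at half the
*within-family divergence* (default 0.5% — pairwise subtype identity
>99%). These defaults make family-level typing easy and subtype typing
hard, which is the character of the real locus. Substitutions that would
create internal stops are resampled; introns evolve at 2× the CDS rate.
CSH3 is generated as a pseudogene: a 1-nt deletion in the exon-5 portion
of the CDS plus a premature TGA, at recorded coordinates.

**Cluster arrangements.** Five canonical structures with 11/12/13/14/13
genes: the 12-gene form is GH, CSH1, (GH2,CSH2)×a/b/c, CSH3, CSH4×a/b/c;
the others remove a CSH4, add a GH2–CSH2 pair, do both, or insert one
extra GH2. The insertion point of the lone extra GH2 in the fifth
arrangement is this package's choice (after the b pair); only family-level
order matters to the caller and all five orders are pairwise distinct.
Loci place genes on the plus strand with uniform-random 6–13 kb spacers,
2 kb flank genes (CD79B 5′, TCAM1P 3′) and 2 kb outer margins; the 12-gene
locus is ~150 kb.

**Reads.** Errors are i.i.d. per base: substitution / single-base
insertion / deletion rates (ONT-like default 0.020/0.015/0.025,
indel-dominated; PacBio-like "accurate" 0.002/0.0015/0.0015 at 20–30 kb).
No homopolymer-aware or quality-score model — sufficient for testing
indel-robust typing, and deliberately the simplest defensible model. Short
reads have uniform start positions on both haplotypes; `coverage` is
per-haplotype depth. Transcriptome mixtures draw per-type read counts from
a multinomial; GH-like reads are error-free CDS fragments, background
reads random sequence. Homozygous individuals carry two copies of one
locus realization, as two identical chromosomes do.

**What passing tests do not show.** Real nanopore error is bursty and
homopolymer-biased; real clusters carry Alu repeats (~20% of the span) and
segmental near-duplications of spacers, which the random spacers do not
emulate. Typing accuracy and consensus quality on real data will be
somewhat worse than on this generator; the pipeline's margins (family
divergence ≈ 8% versus read error ≈ 6%) are what make the conclusions
robust, not the error model's details.

## Read typing and haplotype calling

Unit-cost edit distance (edlib) is the single scoring currency:
deterministic and indel-tolerant, and adequate at these divergences.
Candidate gene occurrences are located by iteratively matching per-exon
cross-family consensus templates (exons ≥100 nt; introns never need to
match) at ≤25% of template length, then grouping template hits separated
by ≤3 kb (greater than any intron, far less than any spacer). Each
occurrence is typed by the summed exon-wise edit distance of every
(family, subtype); the family must win by ≥2 edits (default) or the hit is
*unassigned*; the subtype must additionally win its within-family
comparison by ≥1 edit, else subtype is None. Ties in greedy non-overlap
resolution break by leftmost coordinate, for reproducibility.

Flank detection requires a local match covering ≥50% of the flank template
at ≤20% edit distance (template halves rescue truncated flanks). A read is
*full* when both flanks are present, *almost full* with exactly one flank
plus the terminal gene of the flankless side (GH at 5′, CSH4 at 3′ —
configurable). Orientation is normalized so CD79B is 5′.

The catalog collapses full structures by exact family-level order;
unassigned positions are wildcards that match anything (conservative
against noise-created "new" haplotypes). Almost-full structures are
assigned the compatibility set of entries they prefix/suffix-match; only
singleton assignments add support. Genotypes: one distinct unambiguous
haplotype = homozygous, two = heterozygous, more = error; ambiguity sets
are reported but never counted as distinct. Minimum support for an entry
is one read; the support column lets users filter.

**Polishing.** For homozygotes, a noisy full-span read (oriented by its
flanks) is the backbone; accurate reads are placed on it by infix
alignment, and per-column votes (base/deletion, plus insertion strings at
junctions with >50% support) give the consensus; two rounds by default.
Consensus accuracy is assessed over the anchored span (CD79B through
TCAM1P): simulated loci end abruptly, so the outermost margins see 1–2×
coverage — a boundary artifact with no analogue on a chromosome — while
the anchored span reaches full depth. At ≥20× accurate coverage the
consensus error over that span is ≤1e-4 (tested), with zero-coverage
columns emitted as '-' plus a warning.

## Copy number

A read hits a family when its best semi-global overlap with that family's
exon-5 reference covers ≥60 nt at ≥90% identity, and the best family beats
the second by ≥1 edit; otherwise it is unassigned (reads matching nothing
are not counted at all). Overlap scoring pads references with wildcard Ns
(edlib `additionalEqualities`), which reproduces local-alignment behavior
— reads may overhang either reference end freely — at edlib speed and
uniformly across families; pad length is read length − 60, forcing every
placement to cover ≥60 real columns. Normalization divides by the mean
anchor count (mean over {GH, CSH1, CSH3}; the mean rather than the median
is the estimator choice for three anchors), making the anchor mean exactly
1. SEM is sample SD/√n; n = 1 is flagged. Integer copies round half away
from zero; estimates within 0.3 of a half-integer are flagged and reported
as ranges, reproducing the convention of reporting "10 to 12 genes" where
the evidence is genuinely between integers.

Reads whose best two families tie within one edit (locally identical
exon-5 windows) fall into the unassigned class; multi-copy families lose
proportionally more such reads than anchors, so their estimates run a few
percent conservative. At 30× this never moved an integer call in testing.

## Expression

Reads are GH-like at ≥90% identity over ≥60 nt against any family CDS
(a family-consensus prefilter rejects the non-GH-like bulk cheaply).
Groups default to families because within-family subtypes differ at too
few positions for every read to separate them — GH2a/b/c are quantified
jointly, matching how such data can honestly be reported. Percentages are
computed against reads searched (post-subsampling; default cap 100 000
reads); zero-hit groups are reported as "< floor" with floor = 100/n %. A
secondary subtype-share estimator apportions a family's reads by
discriminating-position votes among reads that (a) belong to that family
by margin and (b) cover a discriminating difference; it is reported with
its informative-read count because coverage, not sampling, limits it.

Probe design enumerates every 80-nt window (after projecting all types
onto the first sequence's coordinates when lengths differ) and keeps
windows separated from every other type by ≥1 edit, recording the margin;
types with no separating window are merged into one indistinguishable
group and quantified jointly.

## Selection analysis

The codon model is GY94-structured: rate π_j · κ^[transition] ·
ω^[nonsynonymous] between sense codons one nucleotide apart, F3x4
frequencies from the alignment (floored at 1e-4 so every codon is
reachable), Q scaled to one expected substitution per codon per unit
branch length. Branch classes come from `#k` labels in the newick input;
each class has its own ω. Branch lengths, κ and all ω are estimated
jointly by L-BFGS-B in log space with ≥2–3 starts (ω starts spread from
0.1 to 10), which in practice enforces the nesting inequality
lnL(alt) ≥ lnL(null); gapped codon columns are removed (complete
deletion); pseudogene rows are excluded. ω is capped at 999 and flagged
when it hits the cap; per-branch expected nonsynonymous/synonymous counts
(t · L · ρ_N with ρ_N the nonsynonymous rate fraction of the fitted Q) are
always reported, because a branch with zero synonymous substitutions makes
ω itself meaningless. Branch lengths are re-estimated independently under
null and alternative models. The LRT statistic 2ΔlnL is floored at zero
(warning beyond 1e-6 of optimizer noise) and compared to χ² with df =
difference in ω-class counts.

**Parsimony change mapping.** Per alignment column, constrained Sankoff
dynamic programming (up/down passes) yields, exactly, the set of
(parent state, child state) pairs achievable on a target branch across
*all* most-parsimonious reconstructions; a change is *unequivocal* when
that set is a single ordered pair with parent ≠ child. This is the
deterministic, testable formalization of "forced under both ACCTRAN and
DELTRAN" (it is in fact stronger); a brute-force enumeration oracle
verifies it on small instances. Two-child roots are collapsed so the two
root edges behave as the single unrooted branch they are. Leaves with
gaps/X accept any state at zero cost; candidate states are restricted to
those observed in the column, which is lossless under unit costs.

**NG86.** Sites per codon use the standard per-position synonymous
fraction with mutations to stops excluded from the opportunity;
differences average over all mutational pathways that avoid stops;
Jukes–Cantor correction maps proportions to distances. It cross-checks the
ML machinery and is itself cross-checked against an independent
implementation in the tests.

**Pseudogene handling.** Diagnostics align the suspect CDS to a
translatable homolog globally with affine gap costs (BLASTN-like scoring,
via scikit-bio) — unit-cost alignment renders pairs of nearby
substitutions as spurious indel pairs and is unusable here. Indels of
length ≢ 0 (mod 3) are frameshifts; premature stops are read in the frame
restored after each frameshift. The alignability cutoff is 60% matched
columns: random nucleotide pairs align at ~48% by chance, so a lower
cutoff could never fire. `force_frame` inserts placeholder bases at stated
sites and translates with 'X' at placeholder codons and '*' at stops,
for display alongside intact homologs.

## Problem sizes used in the tests

Stochastic checks run at sizes chosen to exercise the full pipeline while
keeping the suite fast: haplotype-recovery replicates use 10 seeds
(full-scale condition: ≥95% of 50); polishing and copy-number property
tests use compact 4–5-gene loci (~35 kb) where the full ~150 kb locus adds
nothing; codon-model recovery uses 4 taxa × 900–1200 codons. The
acceptance script runs the two headline computations at the stated study
conditions (five full clusters with 3 full-span reads each; a full 12-gene
locus at 30×).

## Known limitations

- Subtype-level haplotype refinement reports a consensus only; no attempt
  to phase subtypes across reads disagreeing at noise level.
- The copy-number estimator assumes anchors are truly single-copy and
  equally mappable; GC/mappability correction is out of scope.
- The branch model has no among-site variation (no site or branch-site
  classes); ω is a branch-class property only.
- The polisher assumes a homozygous individual and one backbone read; it
  is not a general assembler.
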