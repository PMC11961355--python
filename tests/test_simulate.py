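import warnings

import edlib
import numpy as np
import pytest

from ghcluster.core import revcomp
from ghcluster.io import read_tree
from ghcluster.molevol import pairwise_identity
from ghcluster.simulate import (
    ErrorProfile,
    ExpressionProfile,
    FamilySpec,
    HaplotypeStructure,
    build_haplotype,
    cluster_structures,
    evolve_cds,
    make_individual,
    make_paralog_families,
    random_cds,
    simulate_codon_evolution,
    simulate_long_reads,
    simulate_short_reads,
    simulate_transcriptome,
)
from ghcluster.codon import (
    codons_to_indices,
    f3x4,
    nonsyn_rate_fraction,
    CODON_AA,
    SENSE_CODONS,
    translate,
)


class TestParalogFamilies:
    def test_zero_within_divergence_gives_identical_subtypes(self):
        spec = FamilySpec(within_divergence=0.0, pseudogenes={})
        fams = make_paralog_families(spec=spec, seed=3)
        for fam in ("GH2", "CSH2", "CSH4"):
            subs = fams.subtypes_of(fam)
            assert len({fams.cds[(fam, s)] for s in subs}) == 1

    def test_divergence_matches_binomial_expectation(self):
        # evolve at 2% over 651 coding positions: diffs ~ Binomial(651, 0.02)
        rng = np.random.default_rng(0)
        cds = random_cds(217, rng)
        n, p = 651, 0.02
        diffs = []
        for seed in range(100):
            out = evolve_cds(cds, p, np.random.default_rng(seed))
            diffs.append(sum(a != b for a, b in zip(cds, out)))
        mean = np.mean(diffs)
        se = np.sqrt(n * p * (1 - p) / len(diffs))
        assert abs(mean - n * p) < 3 * se

    def test_within_family_identity_exceeds_99_percent(self, families):
        prot_or_cds = families.cds
        for fam in ("GH2", "CSH2", "CSH4"):
            subs = families.subtypes_of(fam)
            for i, a in enumerate(subs):
                for b in subs[i + 1 :]:
                    ident = pairwise_identity(
                        prot_or_cds[(fam, a)], prot_or_cds[(fam, b)]
                    )
                    assert ident > 99.0

    def test_pseudogene_carries_injected_lesions(self, families):
        pg = families.pseudogene_truth["CSH3"]
        cds = families.cds[("CSH3", None)]
        assert len(cds) == 653  # one deleted base
        stop_nt = 3 * pg.premature_stop_codon
        assert cds[stop_nt : stop_nt + 3] == "TGA"

    def test_no_internal_stops_in_coding_families(self, families):
        for (fam, sub), cds in families.cds.items():
            if fam in families.pseudogene_truth:
                continue
            assert "*" not in translate(cds)[:-1]

    def test_unreachable_divergence_spec_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(between_divergence=0.01, within_divergence=0.02)


class TestHaplotypes:
    def test_canonical_structures_have_expected_gene_counts(self, structures):
        assert [len(structures[k]) for k in "I II III IV V".split()] == [11, 12, 13, 14, 13]
        vecs = {s.families() for s in structures.values()}
        assert len(vecs) == 5  # pairwise distinct at family level

    def test_first_gene_must_be_gh(self):
        with pytest.raises(ValueError):
            HaplotypeStructure(name="bad", genes=(("CSH1", None),))

    def test_locus_matches_structure_and_length(self, families, structures):
        locus = build_haplotype(structures["II"], families, seed=5)
        genes = [f for f in locus.features if f.family not in ("CD79B", "TCAM1P")]
        assert [(f.family, f.subtype) for f in genes] == list(structures["II"].genes)
        assert len(genes) == 12
        assert 120_000 < len(locus.sequence) < 185_000
        assert locus.features[0].family == "CD79B"
        assert locus.features[-1].family == "TCAM1P"

    def test_feature_extraction_round_trip(self, families, structures):
        locus = build_haplotype(structures["I"], families, seed=6)
        for f in locus.features:
            if f.family in ("CD79B", "TCAM1P"):
                continue
            assert locus.extract(f) == families.gene_sequence(f.family, f.subtype)
            assert locus.extract_cds(f) == families.cds[(f.family, f.subtype)]

    def test_empty_structure_gives_flanks_only(self, families):
        locus = build_haplotype(
            HaplotypeStructure(name="empty", genes=()), families, seed=7
        )
        assert [f.family for f in locus.features] == ["CD79B", "TCAM1P"]

    def test_unknown_label_rejected(self, families):
        bad = HaplotypeStructure(name="x", genes=(("GH", None), ("NOPE", None)))
        with pytest.raises(KeyError):
            build_haplotype(bad, families, seed=0)

    def test_homozygote_shares_one_realization(self, families, structures):
        ind = make_individual("a", structures["I"], structures["I"], families, seed=1)
        assert ind.homozygous
        assert ind.loci[0].sequence == ind.loci[1].sequence
        het = make_individual("b", structures["I"], structures["II"], families, seed=1)
        assert not het.homozygous


class TestLongReads:
    def test_zero_error_reads_are_exact_substrings(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        reads, truth = simulate_long_reads(ind, 4, ErrorProfile.perfect(), seed=3)
        for rec, row in zip(reads, truth):
            hap = ind.loci[row["hap_index"]].sequence
            frag = hap[row["start"]:row["end"]]
            assert rec.sequence in (frag, revcomp(frag))

    def test_ont_error_rate_within_tolerance(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        profile = ErrorProfile.ont()
        reads, truth = simulate_long_reads(ind, 6, profile, seed=4)
        total_edits = total_len = 0
        for rec, row in zip(reads, truth):
            hap = ind.loci[row["hap_index"]].sequence
            frag = hap[row["start"]:row["end"]]
            if row["strand"] == "-":
                frag = revcomp(frag)
            total_edits += edlib.align(rec.sequence, frag, mode="NW",
                                       task="distance")["editDistance"]
            total_len += len(frag)
        rate = total_edits / total_len
        expected = profile.total
        sigma = np.sqrt(expected * (1 - expected) / total_len)
        # edit distance undercounts stacked events slightly; allow 10% slack + 3 sigma
        assert abs(rate - expected) < 0.1 * expected + 3 * sigma

    def test_accurate_mode_contract(self):
        p = ErrorProfile.accurate()
        assert p.read_len_mean > 20_000
        assert p.total <= 0.005

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            ErrorProfile(sub=0.3, ins=0.2, dele=0.1)

    def test_short_read_length_warning_not_error(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        with pytest.warns(UserWarning, match="shorter than the locus"):
            simulate_long_reads(ind, 1, ErrorProfile(read_len_mean=5000, read_len_sd=500), seed=1)

    def test_seed_determinism(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        a, _ = simulate_long_reads(ind, 3, ErrorProfile.ont(), seed=9)
        b, _ = simulate_long_reads(ind, 3, ErrorProfile.ont(), seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestShortReads:
    def test_read_count_matches_coverage(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        L = len(ind.loci[0].sequence)
        reads = simulate_short_reads(ind, coverage=10, read_len=150, seed=3)
        assert len(reads) == 2 * round(L * 10 / 150)

    def test_degenerate_coverage_tolerated(self, families, small_structure):
        ind = make_individual("x", small_structure, small_structure, families,
                              spacer_range=(2000, 3000), seed=2)
        reads = simulate_short_reads(ind, coverage=0.001, read_len=150, seed=3)
        assert len(reads) >= 0  # downstream accepts possibly-empty input

    def test_read_len_longer_than_locus_rejected(self, families):
        locus = build_haplotype(HaplotypeStructure(name="e", genes=()), families,
                                spacer_range=(6000, 6001), seed=1)
        from ghcluster.simulate import DiploidIndividual
        tiny = DiploidIndividual("t", (HaplotypeStructure(name="e", genes=()),) * 2,
                                 (locus, locus))
        with pytest.raises(ValueError):
            simulate_short_reads(tiny, coverage=1, read_len=301, seed=0)


class TestTranscriptome:
    def test_multinomial_counts_recovered(self, families):
        profile = ExpressionProfile(fractions={("GH", None): 0.01}, background=0.99)
        reads = simulate_transcriptome(profile, families, 20_000, seed=5)
        gh = families.cds[("GH", None)]
        n_gh = sum(
            1 for r in reads
            if edlib.align(r.sequence, gh, mode="HW", task="distance", k=2)["editDistance"] >= 0
            or edlib.align(revcomp(r.sequence), gh, mode="HW", task="distance", k=2)["editDistance"] >= 0
        )
        expected, sigma = 200, np.sqrt(20_000 * 0.01 * 0.99)
        assert abs(n_gh - expected) < 3 * sigma

    def test_all_background_has_no_gh_reads(self, families):
        profile = ExpressionProfile(fractions={}, background=1.0)
        reads = simulate_transcriptome(profile, families, 5000, seed=6)
        gh = families.cds[("GH", None)]
        assert all(
            edlib.align(r.sequence, gh, mode="HW", task="distance", k=5)["editDistance"] < 0
            for r in reads
        )

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ExpressionProfile(fractions={("GH", None): 0.5}, background=0.4)


class TestCodonEvolution:
    def test_zero_length_tree_gives_identical_rows(self):
        rng = np.random.default_rng(1)
        root = random_cds(100, rng)[:-3]
        tree = read_tree("(A:0,B:0,C:0);")
        aln = simulate_codon_evolution(tree, root, 2.0, {0: 0.5}, seed=2)
        assert set(aln.rows) == {root}

    def test_neutral_nonsyn_proportion_matches_enumeration(self):
        # omega = 1: realized nonsyn fraction of substitutions should match
        # the rate-matrix opportunity computed by enumeration
        rng = np.random.default_rng(2)
        root = random_cds(400, rng)[:-3]
        tree = read_tree("(A:0.03,B:0.03);")
        pi = f3x4([root])
        expected = nonsyn_rate_fraction(2.0, 1.0, pi)
        n_nonsyn = n_total = 0
        for seed in range(30):
            aln = simulate_codon_evolution(tree, root, 2.0, {0: 1.0}, seed=seed)
            a, b = (codons_to_indices(r) for r in aln.rows)
            for ca, cb in zip(a, b):
                if ca != cb:
                    n_total += 1
                    if CODON_AA[ca] != CODON_AA[cb]:
                        n_nonsyn += 1
        frac = n_nonsyn / n_total
        sigma = np.sqrt(expected * (1 - expected) / n_total)
        # short branches: multiple hits are rare, single-change classification ok
        assert abs(frac - expected) < 3 * sigma + 0.02

    def test_no_stop_codons_ever(self):
        rng = np.random.default_rng(3)
        root = random_cds(200, rng)[:-3]
        tree = read_tree("((A:0.4,B:0.4):0.2,C:0.6);")
        aln = simulate_codon_evolution(tree, root, 2.0, {0: 2.0}, seed=4)
        for row in aln.rows:
            assert "*" not in translate(row)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        root = random_cds(50, rng)[:-3]
        tree = read_tree("(A:0.2,B:0.2);")
        a = simulate_codon_evolution(tree, root, 2.0, {0: 1.0}, seed=11)
        b = simulate_codon_evolution(tree, root, 2.0, {0: 1.0}, seed=11)
        assert a.rows == b.rows
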