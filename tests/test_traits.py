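"""Genomic-trait equations against brute-force oracles, plus encoder invariants."""

import math
import shutil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virhost.traits import (
    AMINO_ACIDS,
    CODON_TO_AA,
    DINUCLEOTIDES,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    CodingAnnotation,
    Gene,
    GenomicTraitEncoder,
    UNOBSERVED_FLOOR,
    amino_acid_usage,
    codon_pair_score,
    codon_usage,
    count_compositions,
    dinucleotide_preference,
    encode_traits,
    feature_names,
    normalize_and_log,
    nucleotide_preference,
    predict_coding_regions,
)

ORF = "ATG" + "AAA" * 200 + "TAA"
GENOME = "C" * 100 + ORF + "C" * 100


def make_gene(seq, start=1, strand="+"):
    body = seq[:-3] if seq[-3:] in STOP_CODONS else seq
    protein = "".join(CODON_TO_AA[body[i : i + 3]] for i in range(0, len(body), 3))
    return Gene(start, start + len(seq) - 1, strand, seq, protein)


class TestOrfCaller:
    def test_single_embedded_orf(self):
        ann = predict_coding_regions(GENOME)
        assert len(ann.genes) == 1
        g = ann.genes[0]
        assert len(g.nt_seq) == 606
        assert g.protein == "M" + "K" * 200
        assert (g.start, g.end, g.strand) == (101, 706, "+")

    def test_noncoding_input_yields_empty(self):
        rng = np.random.RandomState(0)
        # no ATG at all: alphabet restricted to C/G/T
        seq = "".join(rng.choice(list("CGT"), size=500))
        assert len(predict_coding_regions(seq)) == 0

    def test_reverse_complement_strand_symmetry(self):
        from Bio.Seq import Seq

        rc = str(Seq(GENOME).reverse_complement())
        fwd = predict_coding_regions(GENOME).genes[0]
        rev = predict_coding_regions(rc).genes[0]
        assert rev.strand == "-"
        assert rev.protein == fwd.protein
        # coordinates map to the same genome interval after mirroring
        assert (rev.start, rev.end) == (len(GENOME) - fwd.end + 1, len(GENOME) - fwd.start + 1)

    def test_partial_orf_fallback_on_fragment(self):
        # cut away start and stop: the complete-ORF scan fails but the
        # longest-open-frame fallback recovers the coding frame
        fragment = GENOME[150:550]
        assert len(predict_coding_regions(fragment)) == 0
        ann = predict_coding_regions(fragment, allow_partial=True)
        assert len(ann.genes) == 1
        assert ann.genes[0].partial
        assert set(ann.genes[0].protein) == {"K"}

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            predict_coding_regions("ATG" * 10)

    @pytest.mark.skipif(shutil.which("prodigal") is None, reason="prodigal not installed")
    def test_external_gene_caller_agrees_on_frame(self):
        ann = predict_coding_regions(GENOME, backend="external")
        assert len(ann.genes) >= 1
        assert "K" * 50 in ann.genes[0].protein


class TestCompositionCounts:
    def test_overlapping_dinucleotides(self):
        c = count_compositions("ACACACACAC")
        assert c.nt["A"] == 5 and c.nt["C"] == 5
        assert c.dinuc["AC"] == 5 and c.dinuc["CA"] == 4

    def test_codon_and_pair_hand_count(self):
        ann = CodingAnnotation([make_gene("AAAAAA")])
        c = count_compositions("AAAAAA", ann)
        assert c.codon["AAA"] == 2
        assert c.aa["K"] == 2
        assert c.codon_pair[("AAA", "AAA")] == 1
        assert c.aa_pair[("K", "K")] == 1

    def test_empty_annotation_zero_coding_counts(self):
        c = count_compositions("ACGTACGT", CodingAnnotation([]))
        assert sum(c.codon.values()) == 0
        assert sum(c.aa.values()) == 0
        assert sum(c.codon_pair.values()) == 0

    def test_ambiguous_bases_skipped(self):
        c = count_compositions("ACGNNACG")
        assert sum(c.nt.values()) == 6
        # windows touching N are not counted
        assert sum(c.dinuc.values()) == 4

    def test_segments_pooled_without_cross_boundary_windows(self):
        pooled = count_compositions(["AC", "GT"])
        assert sum(pooled.dinuc.values()) == 2
        assert pooled.dinuc["CG"] == 0

    @given(st.text(alphabet="ACGT", min_size=2, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_window_counts_match_naive_scan(self, seq):
        c = count_compositions(seq)
        for x in NUCLEOTIDES:
            assert c.nt[x] == seq.count(x)
        for d in DINUCLEOTIDES:
            naive = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == d)
            assert c.dinuc[d] == naive


class TestPreferenceEquations:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}),
            ("ACGT", {x: 0.25 for x in NUCLEOTIDES}),
            ("AACG", {"A": 0.5, "C": 0.25, "G": 0.25, "T": 0.0}),
        ],
    )
    def test_nucleotide_preference(self, seq, expected):
        assert nucleotide_preference(count_compositions(seq)) == pytest.approx(expected)

    def test_dinucleotide_odds_ratio(self):
        p = dinucleotide_preference(count_compositions("ACACACACAC"))
        assert p["AC"] == pytest.approx((5 / 9) / 0.25)
        assert p["AA"] == 0.0

    def test_dinucleotide_homopolymer(self):
        p = dinucleotide_preference(count_compositions("AAAA"))
        assert p["AA"] == pytest.approx(1.0)

    def test_dinucleotide_iid_uniform_near_one(self):
        rng = np.random.RandomState(7)
        counts = count_compositions(
            ["".join(rng.choice(list("ACGT"), size=100_000)) for _ in range(3)]
        )
        p = dinucleotide_preference(counts)
        assert all(abs(v - 1.0) < 0.05 for v in p.values())

    def test_codon_usage_single_synonym(self):
        gene = "CTG" * 10
        p = codon_usage(count_compositions(gene, CodingAnnotation([make_gene(gene)])))
        assert p["CTG"] == 1.0
        assert p["CTT"] == 0.0

    def test_codon_usage_split_synonyms(self):
        gene = "AAAAAG"
        p = codon_usage(count_compositions(gene, CodingAnnotation([make_gene(gene)])))
        assert p["AAA"] == pytest.approx(0.5)
        assert p["AAG"] == pytest.approx(0.5)

    def test_amino_acid_usage(self):
        gene = "ATGAAA"
        p = amino_acid_usage(count_compositions(gene, CodingAnnotation([make_gene(gene)])))
        assert p["M"] == pytest.approx(0.5)
        assert p["K"] == pytest.approx(0.5)

    def test_codon_pair_score_homopolymer(self):
        gene = "AAAAAAAAA"
        cps = codon_pair_score(count_compositions(gene, CodingAnnotation([make_gene(gene)])))
        assert cps[("AAA", "AAA")] == pytest.approx(1.0)

    def test_codon_pair_score_alternating_brute_force(self):
        gene = "AAAAAG" * 4  # AAA AAG AAA AAG ...
        counts = count_compositions(gene, CodingAnnotation([make_gene(gene)]))
        cps = codon_pair_score(counts)
        # brute-force oracle: enumerate the codon chain directly
        codons = [gene[i : i + 3] for i in range(0, len(gene), 3)]
        pairs = list(zip(codons, codons[1:]))
        n_pair = pairs.count(("AAA", "AAG"))
        n_kk = len(pairs)
        p_aaa = codons.count("AAA") / len(codons)
        p_aag = codons.count("AAG") / len(codons)
        assert cps[("AAA", "AAG")] == pytest.approx(n_pair / (n_kk * p_aaa * p_aag))
        # the reverse pair occurs once less in the chain (4 vs 3 occurrences)
        assert cps[("AAA", "AAG")] == pytest.approx(cps[("AAG", "AAA")] * 4 / 3)

    def test_single_codon_gene_no_pairs(self):
        gene = "ATG"
        cps = codon_pair_score(count_compositions(gene, CodingAnnotation([make_gene(gene)])))
        assert all(v == 0.0 for v in cps.values())

    def test_synonymous_codon_sum_and_aa_sum(self):
        rng = np.random.RandomState(3)
        codons = [SENSE_CODONS[i] for i in rng.randint(0, 61, size=300)]
        gene = "".join(codons)
        counts = count_compositions(gene, CodingAnnotation([make_gene(gene)]))
        usage = codon_usage(counts)
        for aa in AMINO_ACIDS:
            if counts.aa[aa] > 0:
                syn = sum(usage[c] for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
                assert syn == pytest.approx(1.0)
        assert sum(amino_acid_usage(counts).values()) == pytest.approx(1.0)
        assert sum(nucleotide_preference(counts).values()) == pytest.approx(1.0)


class TestNormalizeAndLog:
    @pytest.mark.parametrize("value,expected", [(1.0, 0.0), (2.0, 1.0), (0.0, math.log2(1e-4))])
    def test_values(self, value, expected):
        assert normalize_and_log({"k": value})["k"] == pytest.approx(expected)

    def test_floor_magnitude(self):
        assert normalize_and_log({"k": 0.0})["k"] == pytest.approx(-13.2877, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_log({"k": -0.5})


class TestTraitVector:
    def test_dimensions(self):
        assert len(feature_names("sbias")) == 137
        assert len(feature_names("bias")) == 137 + 3904
        assert encode_traits(GENOME).shape == (137,)
        assert encode_traits(GENOME, feature_set="bias").shape == (4041,)

    def test_deterministic_and_finite(self):
        v1 = encode_traits(GENOME)
        v2 = encode_traits(GENOME)
        assert np.array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_case_and_trailing_n_invariance(self):
        enc = GenomicTraitEncoder().fit([])
        base = enc.encode_one(GENOME)
        assert np.array_equal(base, enc.encode_one(GENOME.lower()))
        assert np.array_equal(base, enc.encode_one(GENOME + "NNNN"))

    def test_unobserved_entries_at_floor(self):
        names = feature_names("sbias")
        v = encode_traits(GENOME)
        vec = dict(zip(names, v))
        # GENOME holds a single G (in ATG), so GG never occurs, and no Phe codon
        assert vec["dinuc|GG"] == pytest.approx(math.log2(UNOBSERVED_FLOOR))
        assert vec["codon|TTT"] == pytest.approx(math.log2(UNOBSERVED_FLOOR))

    def test_transformer_batch_matches_single(self):
        enc = GenomicTraitEncoder().fit([])
        batch = enc.transform([GENOME, "A" * 600])
        assert batch.shape == (2, 137)
        assert np.array_equal(batch[0], enc.encode_one(GENOME))
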