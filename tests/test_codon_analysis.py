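"""Wobble model, codon usage, bias scoring and synonymous recoding."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from adatscan.codon_analysis import (
    ALL_CODONS,
    STOP_CODONS,
    BiasScore,
    CodingSequence,
    aggregate_usage,
    bias_score,
    build_adat_codon_model,
    codon_usage,
    dependent_fraction,
    recode_sequence,
    translate,
)
from adatscan.errors import ConfigurationError, SequenceError, UndefinedFoldError

# Independent hand-built wobble table: the dependent codon is the
# reverse-complement of anticodon positions 35-36 with C at the wobble-paired
# third position (I34:C pairing).
EXPECTED_DEPENDENT = {
    ("Leu", "AAG"): "CTC",
    ("Arg", "ACG"): "CGC",
    ("Ser", "AGA"): "TCC",
    ("Pro", "AGG"): "CCC",
    ("Ala", "AGC"): "GCC",
    ("Val", "AAC"): "GTC",
    ("Ile", "AAT"): "ATC",
    ("Thr", "AGT"): "ACC",
}


class TestWobbleModel:
    def test_eight_families_eight_dependent_codons(self, model):
        assert len(model.families) == 8
        assert len(model.dependent_codons) == 8
        assert all(c.endswith("C") for c in model.dependent_codons)

    def test_dependent_codons_match_hand_built_wobble_table(self, model):
        by_family = {(f.amino_acid, f.anticodon): f.dependent_codon for f in model.families}
        assert by_family == EXPECTED_DEPENDENT
        # cross-check via an independent reverse-complement route
        for fam in model.families:
            rc = str(Seq(fam.anticodon).reverse_complement())
            assert fam.dependent_codon == rc[:2] + "C"

    def test_family_codon_bijection(self, model):
        codons = [f.dependent_codon for f in model.families]
        assert len(set(codons)) == 8
        assert set(codons) == set(model.dependent_codons)
        assert set(codons) == {"TCC", "CTC", "CGC", "CCC", "GCC", "GTC", "ATC", "ACC"}

    def test_ser_aga_reads_tcc(self, model):
        fam = model.family_for_codon("TCC")
        assert (fam.amino_acid, fam.anticodon) == ("Ser", "AGA")

    def test_anticodons_have_wobble_a_first(self, model):
        assert all(f.anticodon[0] == "A" for f in model.families)

    def test_recode_map_is_synonymous_and_escapes_dependence(self, model):
        for old, new in model.recode_map.items():
            assert str(Seq(old).translate()) == str(Seq(new).translate())
            assert new not in model.dependent_codons
        assert set(model.recode_map) == set(model.dependent_codons)

    def test_codon_subset_restricts_scoring(self):
        m = build_adat_codon_model({"TCC", "CTC", "CGC"})
        assert m.scoring_subset == frozenset({"TCC", "CTC", "CGC"})
        assert len(m.dependent_codons) == 8  # model itself stays complete

    def test_invalid_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            build_adat_codon_model({"TCC", "AAA"})


class TestCodingSequence:
    def test_u_mapped_to_t_and_uppercased(self):
        seq = CodingSequence("g", "augUCC")
        assert seq.sequence == "ATGTCC"

    @pytest.mark.parametrize("bad", ["AT", "ATGCATG", "ATGNNN"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(SequenceError):
            CodingSequence("g", bad)


class TestCodonUsage:
    def test_direct_count(self):
        counts = codon_usage(CodingSequence("g", "ATGTCCTCC"))
        assert counts["ATG"] == 1 and counts["TCC"] == 2
        assert sum(counts.values()) == 3
        assert len(counts) == 64

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from(ALL_CODONS), min_size=1, max_size=300))
    def test_agrees_with_sliding_window_oracle(self, codon_list):
        seq = "".join(codon_list)
        counts = codon_usage(CodingSequence("g", seq))
        # independent 3-mer-stride tally
        oracle = {c: 0 for c in ALL_CODONS}
        for i in range(0, len(seq), 3):
            oracle[seq[i : i + 3]] += 1
        assert counts == oracle
        assert sum(counts.values()) == len(seq) // 3


class TestBiasScore:
    def test_arithmetic(self, model):
        # gene usage 0.30 vs background 0.15 -> fold 2.0, passes the 1.5 cut
        b = BiasScore("g", 0.30, 0.15, 0.30 / 0.15)
        assert b.fold_enrichment == pytest.approx(2.0)
        assert b.passes(1.5)

    def test_gene_identical_to_background_gives_fold_one(self, model):
        seq = CodingSequence("g", "ATGTCCGAA" * 10)
        score = bias_score(seq, codon_usage(seq), model)
        assert score.fold_enrichment == pytest.approx(1.0)

    def test_toy_set_matches_brute_force_oracle(self, model):
        rng = np.random.default_rng(42)
        non_dep = [c for c in ALL_CODONS if c not in model.dependent_codons and c not in STOP_CODONS]
        genes = []
        for i in range(10):
            n_dep = rng.integers(0, 40)
            codons = ["TCC"] * int(n_dep) + list(rng.choice(non_dep, 100 - int(n_dep)))
            rng.shuffle(codons)
            genes.append(CodingSequence(f"g{i}", "".join(codons)))
        background = aggregate_usage(genes)
        scores = {g.gene_id: bias_score(g, background, model) for g in genes}
        # brute-force fractions per gene
        total_dep = sum(1 for g in genes for c in g.codons if c in model.dependent_codons)
        total = sum(1 for g in genes for c in g.codons if c not in STOP_CODONS)
        bg_frac = total_dep / total
        for g in genes:
            dep = sum(1 for c in g.codons if c in model.dependent_codons)
            tot = sum(1 for c in g.codons if c not in STOP_CODONS)
            expected_fold = (dep / tot) / bg_frac
            assert scores[g.gene_id].fold_enrichment == pytest.approx(expected_fold)
            assert scores[g.gene_id].passes(1.5) == (expected_fold > 1.5)

    def test_scale_invariance_under_background_duplication(self, model):
        seqs = [CodingSequence("a", "ATGTCCCTCGAA"), CodingSequence("b", "ATGGAAGAAGAA")]
        bg1 = aggregate_usage(seqs)
        bg2 = aggregate_usage(seqs + seqs)
        for s in seqs:
            f1 = bias_score(s, bg1, model).fold_enrichment
            f2 = bias_score(s, bg2, model).fold_enrichment
            assert f1 == pytest.approx(f2)

    def test_zero_background_raises(self, model):
        seq = CodingSequence("g", "ATGGAAGAA")
        with pytest.raises(UndefinedFoldError, match="undefined"):
            bias_score(seq, codon_usage(seq), model)


class TestRecode:
    def test_single_codon_example(self, model):
        new, events = recode_sequence(CodingSequence("g", "ATGTCC"), model)
        assert new.sequence == "ATGTCG"
        assert str(Seq(new.sequence).translate()) == "MS"
        assert [(e.codon_index, e.old_codon, e.new_codon) for e in events] == [(1, "TCC", "TCG")]

    def test_fixed_point_when_no_dependent_codons(self, model):
        seq = CodingSequence("g", "ATGGAAAAATAA")
        new, events = recode_sequence(seq, model)
        assert new.sequence == seq.sequence
        assert events == []

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from(ALL_CODONS), min_size=1, max_size=100))
    def test_synonymy_completeness_idempotence(self, model, codon_list):
        seq = CodingSequence("g", "".join(codon_list))
        new, events = recode_sequence(seq, model)
        # synonymy, via the independent Biopython translation oracle
        assert str(Seq(new.sequence).translate()) == str(Seq(seq.sequence).translate())
        # completeness
        assert not set(new.codons) & model.dependent_codons
        # idempotence
        again, events2 = recode_sequence(new, model)
        assert again.sequence == new.sequence and events2 == []
        # the report accounts for every change
        assert len(events) == sum(1 for c in seq.codons if c in model.dependent_codons)
        for ev in events:
            assert seq.codons[ev.codon_index] == ev.old_codon
            assert new.codons[ev.codon_index] == ev.new_codon


def test_translate_matches_biopython_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join(rng.choice(ALL_CODONS, 30))
        assert translate(seq) == str(Seq(seq).translate())


def test_dependent_fraction_excludes_stops(model):
    counts = codon_usage(CodingSequence("g", "ATGTCCTAA"))
    # stop TAA excluded from the denominator: 1 dependent of 2 decoded codons
    assert dependent_fraction(counts, model.dependent_codons) == pytest.approx(0.5)
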