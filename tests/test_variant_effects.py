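"""Effect annotation vs a brute-force re-splice-and-translate oracle,
and the cryptic-acceptor splicing predictor."""

import pytest
from Bio.Seq import Seq

import locuspav.variant_effects as ve
from locuspav.locus_model import (
    DomainAnnotation,
    GeneLocus,
    GeneModel,
    SequenceError,
    revcomp,
)


def _oracle_category(locus, model, pos, alt):
    """Independent oracle: positional splice/intron rules plus a full
    mutate -> splice -> translate (Biopython) comparison for coding SNVs."""
    for is_, ie in model.introns:
        if model.strand == "+":
            if pos in (is_, is_ + 1):
                return "splice_donor"
            if pos in (ie - 1, ie):
                return "splice_acceptor"
        else:
            if pos in (ie - 1, ie):
                return "splice_donor"
            if pos in (is_, is_ + 1):
                return "splice_acceptor"
    gs, ge = model.span
    in_exon = any(s <= pos <= e for s, e in model.exons)
    if not in_exon:
        return "intronic" if gs <= pos <= ge else "intergenic"

    def protein(seq):
        cdna = "".join(seq[s - 1 : e] for s, e in model.exons)
        if model.strand == "-":
            cdna = str(Seq(cdna).reverse_complement())
        cs, ce = model.cds
        aa = str(Seq(cdna[cs - 1 : ce]).translate())
        return aa.split("*")[0]

    ref_p = protein(locus.sequence)
    mutated = locus.sequence[: pos - 1] + alt + locus.sequence[pos:]
    alt_p = protein(mutated)
    if alt_p == ref_p:
        return "synonymous"
    if len(alt_p) < len(ref_p):
        return "premature_stop"
    return "nonsynonymous"


class TestAnnotateExamples:
    def test_third_position_synonymous(self, toy_gene):
        # find a codon whose third-position change is silent (GCx alanine etc.)
        locus = toy_gene
        model = locus.gene
        found = False
        for exon_start, exon_end in model.exons:
            for pos in range(exon_start, exon_end + 1):
                ref = locus.sequence[pos - 1]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    eff = ve.annotate(ve.Variant(pos, ref, alt), locus)
                    if eff.category == "synonymous":
                        found = True
                        assert eff.protein_change[0] == eff.protein_change[-1]
                        return
        assert found

    def test_acceptor_a_to_c(self, toy_gene):
        locus = toy_gene
        ie = locus.gene.introns[0][1]
        pos = ie - 1  # the A of the acceptor AG
        assert locus.sequence[pos - 1] == "A"
        eff = ve.annotate(ve.Variant(pos, "A", "C"), locus)
        assert eff.category == "splice_acceptor"

    def test_donor_site(self, toy_gene):
        is_ = toy_gene.gene.introns[0][0]
        ref = toy_gene.sequence[is_ - 1]
        alt = "A" if ref != "A" else "C"
        assert ve.annotate(ve.Variant(is_, ref, alt), toy_gene).category == (
            "splice_donor"
        )

    def test_ref_mismatch_rejected(self, toy_gene):
        pos = toy_gene.gene.span[0]
        ref = toy_gene.sequence[pos - 1]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(SequenceError, match=str(pos)):
            ve.annotate(ve.Variant(pos, wrong, "G"), toy_gene)

    def test_frameshift_and_inframe_indels(self, toy_gene):
        pos = toy_gene.gene.span[0] + 10
        ref = toy_gene.sequence[pos - 1]
        ins1 = ve.annotate(ve.Variant(pos, ref, ref + "A"), toy_gene)
        assert ins1.category == "frameshift_indel"
        ins3 = ve.annotate(ve.Variant(pos, ref, ref + "ACT"), toy_gene)
        assert ins3.category == "inframe_indel"


class TestExhaustiveOracleEquivalence:
    def test_every_substitution_matches_oracle(self, toy_gene):
        locus = toy_gene
        gs, ge = locus.gene.span
        mismatches = []
        for pos in range(gs - 15, ge + 16):
            ref = locus.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = ve.annotate(ve.Variant(pos, ref, alt), locus).category
                want = _oracle_category(locus, locus.gene, pos, alt)
                if got != want:
                    mismatches.append((pos, ref, alt, got, want))
        assert mismatches == []

    def test_minus_strand_gene_matches_oracle(self):
        import locuspav.synthetic_data as sd
        import locuspav as lp

        cfg = lp.SimConfig(seed=17, locus_length=3000, exon_lengths=(300, 150),
                           intron_length=50, gene_strand="-")
        locus = sd.simulate_reference(cfg)
        # the generator writes the gene on the '+' frame; reinterpret the
        # same intervals as a '-'-strand model for the scan
        gs, ge = locus.gene.span
        mismatches = []
        for pos in range(gs, ge + 1):
            ref = locus.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = ve.annotate(ve.Variant(pos, ref, alt), locus).category
                want = _oracle_category(locus, locus.gene, pos, alt)
                if got != want:
                    mismatches.append((pos, ref, alt, got, want))
        assert mismatches == []


def _cryptic_toy(offset_ag: int):
    """60 bp two-exon toy with an AG planted ``offset_ag`` bases into exon 2.

    The cryptic exon start lands at offset_ag + 2, so the cDNA shortens by
    offset_ag + 2 when the canonical acceptor is destroyed.
    """
    exon1 = "ATGGCTGCTGCTGCTGCA"  # 18 nt
    intron = "GT" + "C" * 12 + "AG"  # 16 nt
    tail_len = 36 - offset_ag - 2
    exon2 = "C" * offset_ag + "AG" + "T" * tail_len  # 36 nt, single AG
    seq = exon1 + intron + exon2
    model = GeneModel(
        "toy", "+", ((1, 18), (35, 35 + 35)), (1, 18 + 36)
    )
    return GeneLocus("c", seq, model)


class TestCrypticSplice:
    def test_delta_seven_frameshift(self):
        locus = _cryptic_toy(5)  # AG at offsets 5-6 -> new start 7 bp in
        ie = locus.gene.introns[0][1]
        out = ve.predict_cryptic_splice(locus, ve.Variant(ie - 1, "A", "C"))
        assert out.cdna_delta_bp == -7
        assert out.frameshift is True

    def test_delta_six_in_frame(self):
        locus = _cryptic_toy(4)
        ie = locus.gene.introns[0][1]
        out = ve.predict_cryptic_splice(locus, ve.Variant(ie - 1, "A", "C"))
        assert out.cdna_delta_bp == -6
        assert out.frameshift is False

    def test_reference_acceptor_reference_protein(self, ghd7_fixture):
        locus, cct = ghd7_fixture
        from locuspav.locus_model import cds_sequence, translate

        out = ve.predict_cryptic_splice(locus, None, domains=[cct])
        assert out.cdna_delta_bp == 0
        assert out.truncated_protein == translate(cds_sequence(locus))
        assert out.domains_lost == []

    def test_no_downstream_ag_unresolved(self):
        exon1 = "ATGGCTGCTGCTGCTGCA"
        intron = "GT" + "C" * 12 + "AG"
        exon2 = "C" * 36
        locus = GeneLocus(
            "c", exon1 + intron + exon2,
            GeneModel("toy", "+", ((1, 18), (35, 70)), (1, 54)),
        )
        ie = locus.gene.introns[0][1]
        out = ve.predict_cryptic_splice(
            locus, ve.Variant(ie - 1, "A", "C"), max_scan=30
        )
        assert out.status == "exon_skip_unresolved"

    def test_frameshift_consistent_with_protein_lengths(self, ghd7_fixture):
        locus, cct = ghd7_fixture
        from locuspav.locus_model import cds_sequence, translate

        ie = locus.gene.introns[0][1]
        out = ve.predict_cryptic_splice(
            locus, ve.Variant(ie - 1, "A", "C"), domains=[cct]
        )
        ref_protein = translate(cds_sequence(locus))
        # two independent descriptions of the same frameshift verdict
        assert out.frameshift == (out.cdna_delta_bp % 3 != 0)
        assert (len(out.truncated_protein) != len(ref_protein)) == out.frameshift

    def test_non_acceptor_variant_rejected(self, toy_gene):
        pos = toy_gene.gene.span[0]
        ref = toy_gene.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="splice_acceptor"):
            ve.predict_cryptic_splice(toy_gene, ve.Variant(pos, ref, alt))


class TestHaplotypeFunction:
    def test_rules(self):
        splice = ve.VariantEffect(ve.Variant(1, "A", "C"), "splice_acceptor")
        stop = ve.VariantEffect(ve.Variant(2, "C", "T"), "premature_stop")
        nonsyn = ve.VariantEffect(ve.Variant(3, "G", "A"), "nonsynonymous")
        syn = ve.VariantEffect(ve.Variant(4, "T", "C"), "synonymous")
        assert ve.classify_haplotype_function([], is_h0=True) == "deleted"
        assert ve.classify_haplotype_function([splice, stop]) == "splice_defective"
        assert ve.classify_haplotype_function([stop, nonsyn]) == "truncated"
        assert ve.classify_haplotype_function([nonsyn, syn]) == "functional"
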