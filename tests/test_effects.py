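from __future__ import annotations

import itertools

import pytest
from Bio.Seq import Seq

from sweepscan import effects as fx
from sweepscan.effects import (
    GeneModel,
    VariantEffect,
    build_gene_model,
    classify_variant,
    is_putatively_functional,
    load_gene_models,
    most_severe,
)

# A small synthetic gene used across tests:
# chr coordinates 1..100; exon1 = 11..40 (UTR5 11..20, CDS 21..40),
# intron = 41..60, exon2 = 61..90 (CDS 61..70, UTR3 71..90).
# CDS (30 bp, 10 codons): ATG GAA GGA TGG GCT GCT GCT GCT GCT TAA
CDS_SEQ = "ATGGAAGGATGGGCTGCTGCTGCTGCTTAA"


def _plus_chrom() -> str:
    seq = list("T" * 100)
    seq[20:40] = CDS_SEQ[:20]
    seq[60:70] = CDS_SEQ[20:]
    return "".join(seq)


def _plus_model(chrom_seq: str | None = None) -> GeneModel:
    return build_gene_model(
        "geneA", "geneA.t1", "chr1", "+",
        exons=[(11, 40), (61, 90)],
        cds=[(21, 40), (61, 70)],
        chrom_seq=chrom_seq or _plus_chrom(),
    )


def _minus_mirror() -> tuple[GeneModel, str]:
    """The same transcript laid on the minus strand of a reverse-
    complemented chromosome; genomic position p maps to 101 - p."""
    rc = str(Seq(_plus_chrom()).reverse_complement())
    model = build_gene_model(
        "geneA", "geneA.t1", "chr1", "-",
        exons=[(101 - 40, 101 - 11), (101 - 90, 101 - 61)],
        cds=[(101 - 40, 101 - 21), (101 - 70, 101 - 61)],
        chrom_seq=rc,
    )
    return model, rc


class TestGeneModel:
    def test_utrs_derived_by_subtraction(self):
        m = _plus_model()
        assert m.utr5 == ((11, 20),)
        assert m.utr3 == ((71, 90),)

    def test_minus_strand_utr5_at_higher_coordinates(self):
        m, _ = _minus_mirror()
        assert m.utr5[0][0] > m.cds[-1][1]

    def test_cds_sequence_extracted_in_transcript_orientation(self):
        assert _plus_model().cds_seq == CDS_SEQ
        m, _ = _minus_mirror()
        assert m.cds_seq == CDS_SEQ

    def test_cds_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            build_gene_model(
                "g", "t", "chr1", "+", exons=[(1, 10)], cds=[(1, 10)],
                chrom_seq="A" * 20,
            )


def _one(effects, consequence):
    found = [e for e in effects if e.consequence == consequence]
    assert len(found) == 1, effects
    return found[0]


class TestClassifyVariant:
    MODEL = None

    @classmethod
    def setup_class(cls):
        cls.MODEL = _plus_model()

    def classify(self, pos, ref, alt):
        return classify_variant(("chr1", pos, ref, alt), [self.MODEL])

    def test_missense_first_codon_position(self):
        # codon 0: ATG -> GTG (M/V), genomic pos 21
        e = _one(self.classify(21, "A", "G"), fx.MISSENSE)
        assert e.aa_change == "M/V"

    def test_synonymous_third_position(self):
        # codon 2: GGA -> GGG at genomic pos 29
        e = _one(self.classify(29, "A", "G"), fx.SYNONYMOUS)
        assert e.aa_change == "G/G"

    def test_stop_gained_and_lost(self):
        # codon 3: TGG -> TGA at genomic pos 32
        assert _one(self.classify(32, "G", "A"), fx.STOP_GAINED).aa_change == "W/*"
        # final codon TAA -> CAA at genomic pos 68
        assert _one(self.classify(68, "T", "C"), fx.STOP_LOST).aa_change == "*/Q"

    def test_utr_membership(self):
        assert _one(self.classify(15, "T", "C"), fx.FIVE_PRIME_UTR)
        assert _one(self.classify(80, "T", "C"), fx.THREE_PRIME_UTR)

    def test_splice_region_five_bp_into_intron(self):
        e = self.classify(45, "T", "C")  # intron starts at 41
        assert [x.consequence for x in e] == [fx.SPLICE_REGION]

    def test_deep_intronic_is_non_functional(self):
        e = self.classify(50, "T", "C")  # 10 bp from either junction
        assert [x.consequence for x in e] == [fx.NON_FUNCTIONAL]

    def test_exonic_base_next_to_junction_also_splice_region(self):
        effects = self.classify(40, "C", "G")  # last CDS base of exon 1
        assert {e.consequence for e in effects} == {
            fx.MISSENSE, fx.SPLICE_REGION,
        }

    def test_intergenic_site_non_functional_with_no_gene(self):
        (e,) = self.classify(5, "T", "C")
        assert e.consequence == fx.NON_FUNCTIONAL and e.gene_id is None

    def test_unknown_chromosome_non_functional(self):
        (e,) = classify_variant(("chrZ", 21, "A", "G"), [self.MODEL])
        assert e.consequence == fx.NON_FUNCTIONAL

    def test_every_cds_snp_gets_exactly_one_coding_consequence(self):
        coding = {fx.MISSENSE, fx.SYNONYMOUS, fx.STOP_GAINED, fx.STOP_LOST}
        chrom = _plus_chrom()
        for pos in itertools.chain(range(21, 41), range(61, 71)):
            ref = chrom[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                effects = self.classify(pos, ref, alt)
                assert sum(e.consequence in coding for e in effects) == 1


class TestStrandSymmetry:
    def test_minus_strand_equals_reverse_complemented_plus(self):
        plus = _plus_model()
        minus, _ = _minus_mirror()
        chrom = _plus_chrom()
        for pos in range(11, 91):
            ref = chrom[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                fwd = classify_variant(("chr1", pos, ref, alt), [plus])
                comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
                rev = classify_variant(
                    ("chr1", 101 - pos, comp[ref], comp[alt]), [minus]
                )
                assert sorted((e.consequence, e.aa_change or "") for e in fwd) == \
                    sorted((e.consequence, e.aa_change or "") for e in rev)


class TestLoaderAndRecovery:
    def test_load_gene_models_from_synthetic_bundle(self, iid_run):
        _, bundle, _ = iid_run
        models = load_gene_models(bundle.gff3, bundle.fasta)
        assert len(models) == len(bundle.models)
        by_id = {m.transcript_id: m for m in models}
        for built in bundle.models:
            loaded = by_id[built.transcript_id]
            assert loaded.cds == built.cds
            assert loaded.utr5 == built.utr5
            assert loaded.utr3 == built.utr3
            assert loaded.cds_seq == built.cds_seq

    def test_missing_chromosome_fatal(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrZ\t.\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "chrZ\t.\tmRNA\t1\t30\t.\t+\t.\tID=t1;Parent=g1\n"
            "chrZ\t.\texon\t1\t30\t.\t+\t.\tParent=t1\n"
            "chrZ\t.\tCDS\t1\t30\t.\t+\t0\tParent=t1\n"
        )
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "A" * 30 + "\n")
        with pytest.raises(KeyError, match="chrZ"):
            load_gene_models(gff, fasta)

    def test_all_planted_consequences_recovered(self, iid_run):
        """On a genome where every consequence category is planted at a
        known position, the classifier recovers every (gene, consequence)
        label."""
        _, bundle, result = iid_run
        models = load_gene_models(bundle.gff3, bundle.fasta)
        truth = bundle.truth_frame()
        planted = truth[truth["kind"] == "fixed_variant"]
        assert set(planted["consequence"]) == {
            fx.MISSENSE, fx.SYNONYMOUS, fx.STOP_GAINED, fx.STOP_LOST,
            fx.FIVE_PRIME_UTR, fx.THREE_PRIME_UTR, fx.SPLICE_REGION,
        }
        for _, row in planted.iterrows():
            site = next(
                s for s in result.fst_sites
                if s.chrom == row["chrom"] and s.pos == int(row["pos"])
            )
            # ref/alt from the VCF via the pipeline's divergent sites
            d = next(
                d for d in result.divergent
                if d.chrom == row["chrom"] and d.pos == int(row["pos"])
            )
            labels = {(e.gene_id, e.consequence) for e in d.effects}
            assert (row["gene"], row["consequence"]) in labels


class TestFunctionalPredicate:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (fx.SYNONYMOUS, False),
            (fx.THREE_PRIME_UTR, True),
            (fx.FIVE_PRIME_UTR, True),
            (fx.MISSENSE, True),
            (fx.SPLICE_REGION, True),
            (fx.STOP_GAINED, True),
            (fx.NON_FUNCTIONAL, False),
        ],
    )
    def test_functional_category_membership(self, consequence, expected):
        e = VariantEffect("chr1", 1, "g", "t", consequence)
        assert is_putatively_functional(e) is expected

    def test_most_severe_ordering(self):
        effects = [
            VariantEffect("c", 1, "g", "t", fx.SYNONYMOUS),
            VariantEffect("c", 1, "g", "t", fx.STOP_GAINED),
            VariantEffect("c", 1, "g", "t", fx.MISSENSE),
        ]
        assert most_severe(effects).consequence == fx.STOP_GAINED
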