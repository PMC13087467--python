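"""Transcript models, spliced UTRs, coordinate maps, Kozak logic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from utr5var import (
    kozak_context,
    kozak_strength,
    load_reference,
    map_genomic_to_transcript,
    spliced_utr,
)
from utr5var.reference import CoordinateMap, KozakContext, SplicedUTR, reverse_complement

from helpers import make_two_exon_model


def _write_toy_annotation(tmp_path, mane_on_both=True):
    """One single-exon gene and one two-exon gene (CDS start in exon 2)."""
    fa = tmp_path / "g.fa"
    gtf = tmp_path / "g.gtf"
    # gene A (+): exon 1-30, UTR 1-10, CDS 11-25
    # gene B (+): exons 41-55 and 61-90; UTR = exon1 + 61-65, CDS 66-80
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=100))
    seq = seq[:10] + "ATG" + seq[13:65] + "ATG" + seq[68:]
    fa.write_text(">chrT\n" + seq + "\n")
    tagb = ' tag "MANE_Select";' if mane_on_both else ""
    lines = [
        'chrT\tt\tgene\t1\t30\t.\t+\t.\tgene_id "A"; transcript_id "A1"; gene_name "A"; tag "MANE_Select";',
        'chrT\tt\ttranscript\t1\t30\t.\t+\t.\tgene_id "A"; transcript_id "A1"; gene_name "A"; tag "MANE_Select";',
        'chrT\tt\texon\t1\t30\t.\t+\t.\tgene_id "A"; transcript_id "A1"; gene_name "A"; tag "MANE_Select";',
        'chrT\tt\tCDS\t11\t25\t.\t+\t.\tgene_id "A"; transcript_id "A1"; gene_name "A"; tag "MANE_Select";',
        f'chrT\tt\tgene\t41\t90\t.\t+\t.\tgene_id "B"; transcript_id "B1"; gene_name "B";{tagb}',
        f'chrT\tt\ttranscript\t41\t90\t.\t+\t.\tgene_id "B"; transcript_id "B1"; gene_name "B";{tagb}',
        f'chrT\tt\texon\t41\t55\t.\t+\t.\tgene_id "B"; transcript_id "B1"; gene_name "B";{tagb}',
        f'chrT\tt\texon\t61\t90\t.\t+\t.\tgene_id "B"; transcript_id "B1"; gene_name "B";{tagb}',
        f'chrT\tt\tCDS\t66\t80\t.\t+\t.\tgene_id "B"; transcript_id "B1"; gene_name "B";{tagb}',
    ]
    gtf.write_text("\n".join(lines) + "\n")
    return str(fa), str(gtf)


class TestLoadReference:
    def test_toy_catalog_geometry(self, tmp_path):
        fa, gtf = _write_toy_annotation(tmp_path)
        catalog = load_reference(fa, gtf, transcript_set="all")
        assert set(catalog) == {"A1", "B1"}
        assert catalog["A1"].start_exon_index == 1
        assert catalog["A1"].utr5_intervals == [(1, 10)]
        assert catalog["B1"].start_exon_index == 2
        assert catalog["B1"].utr5_intervals == [(41, 55), (61, 65)]
        assert catalog["B1"].utr5_length == 20

    def test_mane_filter_excludes_untagged(self, tmp_path):
        fa, gtf = _write_toy_annotation(tmp_path, mane_on_both=False)
        catalog = load_reference(fa, gtf, transcript_set="mane")
        assert set(catalog) == {"A1"}

    def test_cds_start_at_exon2_start_makes_exon1_all_utr(self):
        model, genome = make_two_exon_model("AAATTT", "GTAG", "", "ATGCCCTAA")
        assert model.utr5_intervals == [(1, 6)]
        assert spliced_utr(model, genome).sequence == "AAATTT"

    def test_malformed_annotation_line_reports_lineno(self, tmp_path):
        fa, gtf = _write_toy_annotation(tmp_path)
        bad = tmp_path / "bad.gtf"
        bad.write_text("chrT\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 1"):
            load_reference(fa, str(bad))

    def test_missing_contig_is_hard_error(self, tmp_path):
        fa, gtf = _write_toy_annotation(tmp_path)
        other = tmp_path / "other.fa"
        other.write_text(">chrZ\nACGTACGTACGT\n")
        with pytest.raises(KeyError, match="chrT"):
            load_reference(str(other), gtf, transcript_set="all")


class TestSplicedUTR:
    def test_plus_strand_two_exon_splice(self):
        # UTR exons [1-3] and [7-9] of AAATTTGGGCCC -> AAAGGG
        model, genome = make_two_exon_model("AAA", "TTT", "GGG", "ATGTAA")
        genome = {"chrT": "AAATTTGGGCCC" + genome["chrT"][12:]}
        assert spliced_utr(model, genome).sequence == "AAAGGG"

    def test_minus_strand_single_exon_reverse_complements(self):
        from utr5var.reference import TranscriptModel

        # genomic AACG on the minus strand reads CGTT
        genome = {"chrT": "CATTAACG"}  # CDS 1-3 is revcomp'd ATG at 3..1
        model = TranscriptModel(
            transcript_id="M1", gene_symbol="M", chrom="chrT", strand="-",
            exons=[(1, 8)], cds_start_genomic=4,
            cds_intervals=[(1, 4)], utr5_intervals=[(5, 8)], start_exon_index=1,
        )
        assert spliced_utr(model, genome).sequence == "CGTT"

    def test_single_exon_utr_is_identity_splice(self):
        model, genome = make_two_exon_model("ACGTACGT", "GTAG", "", "ATGTAA")
        assert spliced_utr(model, genome).sequence == "ACGTACGT"

    def test_out_of_bounds_interval_errors(self):
        model, genome = make_two_exon_model("AAA", "TTT", "GGG", "ATGTAA")
        genome = {"chrT": "AAATT"}
        with pytest.raises(ValueError, match="outside contig"):
            spliced_utr(model, genome)


class TestCoordinateMap:
    def test_first_utr_base_maps_to_offset_one(self, bundle):
        for model in bundle["catalog"].values():
            if model.utr5_intervals:
                assert map_genomic_to_transcript(model, model.utr5_start_genomic) == 1

    def test_intron_position_labeled_intronic(self):
        model, _ = make_two_exon_model("AAA", "TTT", "GGG", "ATGTAA")
        assert map_genomic_to_transcript(model, 5) == "intronic"
        assert map_genomic_to_transcript(model, 200) == "outside"

    def test_round_trip_identity_on_random_positions(self, bundle):
        rng = np.random.default_rng(7)
        checked = 0
        for model in bundle["catalog"].values():
            utr = spliced_utr(model, bundle["genome"])
            cmap = utr.coord_map
            for off in rng.integers(1, cmap.length + 1, size=10):
                off = int(off)
                assert cmap.to_transcript(cmap.to_genomic(off)) == off
                checked += 1
        assert checked >= 100


class TestKozak:
    def test_ninemer_assembly(self):
        ctx = kozak_context("GCCACCATGGC", 7)
        assert ctx.ninemer == "CACCATGGC"
        assert ctx.minus3 == "A" and ctx.plus4 == "G"
        assert ctx.strength == "Strong"

    def test_atg_at_offset_one_has_na_strength(self):
        ctx = kozak_context("ATGCCC", 1)
        assert ctx.ninemer.startswith("NNNN")
        assert ctx.strength == "NA"

    def test_partial_upstream_context(self):
        ctx = kozak_context("CATGCCC", 2)
        assert ctx.ninemer[0] == "N" and ctx.minus3 == "N"

    def test_not_an_atg_raises(self):
        with pytest.raises(ValueError, match="not an ATG"):
            kozak_context("GCCACCATGGC", 6)

    @pytest.mark.parametrize(
        "m3,p4,expected",
        [("A", "G", "Strong"), ("G", "G", "Strong"), ("T", "C", "Weak"),
         ("C", "G", "Adequate"), ("A", "C", "Adequate"), ("N", "G", "NA")],
    )
    def test_strength_table(self, m3, p4, expected):
        ctx = KozakContext(f"C{m3}CCATG{p4}C")
        assert kozak_strength(ctx) == expected

    @given(
        st.text(alphabet="ACGT", min_size=7, max_size=7),
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
    )
    def test_strength_depends_only_on_minus3_plus4(self, other, m3, p4):
        # positions -4,-2,-1,+5 and the ATG itself never matter
        ninemer = other[0] + m3 + other[1] + other[2] + "ATG" + p4 + other[3]
        variant = other[4] + m3 + other[5] + other[6] + "ATG" + p4 + other[0]
        assert kozak_strength(KozakContext(ninemer)) == kozak_strength(KozakContext(variant))


def test_strand_symmetry_of_spliced_utr(bundle):
    """A gene and its reverse-complement mirror image yield the same mature UTR."""
    from utr5var.reference import TranscriptModel

    for model in list(bundle["catalog"].values())[:5]:
        utr = spliced_utr(model, bundle["genome"])
        n = len(bundle["genome"][model.chrom])
        flipped_seq = reverse_complement(str(bundle["genome"][model.chrom][:]))
        flip = lambda iv: (n - iv[1] + 1, n - iv[0] + 1)
        mirrored = TranscriptModel(
            transcript_id=model.transcript_id, gene_symbol=model.gene_symbol,
            chrom=model.chrom, strand="-" if model.strand == "+" else "+",
            exons=[flip(e) for e in model.exons],
            cds_start_genomic=n - model.cds_start_genomic + 1,
            cds_intervals=[flip(e) for e in model.cds_intervals],
            utr5_intervals=[flip(e) for e in model.utr5_intervals],
            start_exon_index=model.start_exon_index,
        )
        mirrored_utr = spliced_utr(mirrored, {model.chrom: flipped_seq})
        assert mirrored_utr.sequence == utr.sequence
        assert mirrored_utr.downstream_cds_sequence == utr.downstream_cds_sequence
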