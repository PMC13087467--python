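"""Consequence calling: re-scan diff, effect direction, output schema."""

import numpy as np
import pandas as pd
import pytest

from utr5var import (
    Variant,
    apply_variant,
    diff_uorf_landscape,
    predict_translation_effect,
    read_variants,
    scan_uorfs,
)
from utr5var.annotate import (
    BOX1_COLUMNS,
    CONSEQUENCES,
    ConsequenceCall,
    EditMap,
    SkipVariant,
    call_mkozak,
)
from utr5var.reference import SplicedUTR
from utr5var.uorf import N_TERMINAL, NON_OVERLAPPING, OVERLAPPING, UORF

from helpers import make_utr


def _diff_for_variant(utr, variant):
    mut_full, mut_cds, anchor = apply_variant(utr, variant)
    mut = SplicedUTR(mut_full[: mut_cds - 1], mut_full[mut_cds - 1 :], utr.coord_map)
    calls = diff_uorf_landscape(scan_uorfs(utr), scan_uorfs(mut), anchor)
    mk = call_mkozak(utr.full_sequence, utr.cds_start_offset, mut_full, mut_cds)
    if mk is not None:
        calls.append(mk)
    return calls


class TestApplyVariant:
    def test_snv_preserves_length(self):
        utr = make_utr("CCCATACCCC", "ATGAATAAGGG")
        mut, cds_off, anchor = apply_variant(utr, Variant("chrT", 6, ".", "A", "G"))
        assert len(mut) == len(utr.full_sequence)
        assert cds_off == utr.cds_start_offset
        assert mut[:10] == "CCCATGCCCC"

    def test_deletion_shifts_downstream_anchors(self):
        utr = make_utr("CCCATACCCC", "ATGAATAAGGG")
        mut, cds_off, anchor = apply_variant(utr, Variant("chrT", 4, ".", "ATAC", "A"))
        assert cds_off == utr.cds_start_offset - 3
        assert anchor.map(9) == 6 and anchor.map(3) == 3 and anchor.map(6) is None

    def test_minus_strand_edit_is_reverse_complemented(self):
        # genomic: CDS(revcomp) then UTR(revcomp); transcript UTR = CGTT
        from utr5var.reference import CoordinateMap

        genome_utr = "AACG"      # revcomp -> CGTT
        cmap = CoordinateMap("chrT", "-", [(5, 8), (1, 4)])
        utr = SplicedUTR("CGTT", "ATGC", cmap)
        # transcript offset 2 (G) is genomic pos 7 (base C); alt A -> transcript T
        mut, _, _ = apply_variant(utr, Variant("chrT", 7, ".", "C", "A"))
        assert mut[:4] == "CTTT"

    def test_intronic_and_mismatch_variants_are_skipped(self):
        utr = make_utr("CCCATACCCC", "ATGAATAAGGG")
        with pytest.raises(SkipVariant, match="outside"):
            apply_variant(utr, Variant("chrT", 400, ".", "A", "G"))
        with pytest.raises(SkipVariant, match="mismatch"):
            apply_variant(utr, Variant("chrT", 6, ".", "T", "G"))

    def test_edit_overlapping_main_start_is_skipped(self):
        utr = make_utr("CCCATACCCC", "ATGAATAAGGG")
        with pytest.raises(SkipVariant, match="main start"):
            apply_variant(utr, Variant("chrT", 10, ".", "CAT", "C"))


class TestDiff:
    def test_ustart_gain_overlapping(self):
        utr = make_utr("CCCATACCCC", "ATGAATAAGGG")
        calls = _diff_for_variant(utr, Variant("chrT", 6, ".", "A", "G"))
        (call,) = calls
        assert call.csq == "uStart_gain"
        assert call.mutant_uorf.type == OVERLAPPING
        assert call.translation == "decreased"

    def test_ustop_loss_to_nterminal_extension(self):
        utr = make_utr("CATGTGACCC", "ATGAATAAGGG")
        calls = _diff_for_variant(utr, Variant("chrT", 5, ".", "T", "C"))
        (call,) = calls
        assert call.csq == "uStop_loss"
        assert call.mutant_uorf.type == N_TERMINAL
        assert call.translation == "N-terminal extension"

    def test_identical_landscapes_yield_no_calls(self):
        utr = make_utr("CCCCCACCCC", "ATGAATAAGGG")
        assert _diff_for_variant(utr, Variant("chrT", 6, ".", "A", "G")) == []

    def test_ustart_loss(self):
        utr = make_utr("CCATGTAACC", "ATGAATAAGGG")
        calls = _diff_for_variant(utr, Variant("chrT", 3, ".", "A", "C"))
        assert [c.csq for c in calls] == ["uStart_loss"]
        assert calls[0].translation == "increased"

    def test_ustop_gain_shortens_uorf(self):
        # uORF ATG AAA CAA TAA; SNV C->T makes TAA at the second codon
        utr = make_utr("CATGAAACAATAACC", "ATGAATAAGGG")
        calls = _diff_for_variant(utr, Variant("chrT", 8, ".", "C", "T"))
        assert [c.csq for c in calls] == ["uStop_gain"]
        assert calls[0].translation == "increased"

    def test_ukozak_strength_change(self):
        # uAUG at 5 with -3=A, +4=G (Strong); -3 A->T makes Adequate
        utr = make_utr("AACCATGGCATAACC", "ATGAATAAGGG")
        calls = _diff_for_variant(utr, Variant("chrT", 2, ".", "A", "T"))
        # -3 of uAUG at offset 5 is offset 2
        ukozak = [c for c in calls if c.csq == "uKozak"]
        assert len(ukozak) == 1
        assert ukozak[0].kozak_transition[0] != ukozak[0].kozak_transition[1]

    def test_mkozak_weakening_decreases_translation(self):
        # main CDS Kozak: -3 = offset L-2; make it A->T (Strong->Adequate if +4=G)
        utr = make_utr("CCCCCCCACC", "ATGGATAAGG")
        calls = _diff_for_variant(utr, Variant("chrT", 8, ".", "A", "T"))
        (call,) = calls
        assert call.csq == "mKozak"
        assert call.translation == "decreased"

    def test_reversibility_gains_and_losses_swap(self):
        rng = np.random.default_rng(21)
        utr_seq = "".join(rng.choice(list("ACGT"), size=150))
        cds = "ATGAATAAGGGTGA"
        utr = make_utr(utr_seq, cds)
        wild = scan_uorfs(utr)
        for _ in range(40):
            q = int(rng.integers(1, 151))
            ref = utr_seq[q - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            mut_full, mut_cds, anchor = apply_variant(utr, Variant("chrT", q, ".", ref, alt))
            mut = SplicedUTR(mut_full[: mut_cds - 1], mut_full[mut_cds - 1 :], utr.coord_map)
            mutant = scan_uorfs(mut)
            fwd = diff_uorf_landscape(wild, mutant, anchor)
            rev = diff_uorf_landscape(mutant, wild, anchor)
            swap = {"uStart_gain": "uStart_loss", "uStart_loss": "uStart_gain",
                    "uStop_gain": "uStop_loss", "uStop_loss": "uStop_gain",
                    "uKozak": "uKozak"}
            assert sorted(swap[c.csq] for c in fwd) == sorted(c.csq for c in rev)

    def test_no_uaug_yields_both_gain_and_loss(self):
        """A single anchored uAUG never produces uStart_gain and uStart_loss."""
        rng = np.random.default_rng(33)
        utr_seq = "".join(rng.choice(list("ACGT"), size=120))
        utr = make_utr(utr_seq, "ATGAATAAGGG")
        for _ in range(40):
            q = int(rng.integers(1, 121))
            ref = utr_seq[q - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            calls = _diff_for_variant(utr, Variant("chrT", q, ".", ref, alt))
            gains = {c.mutant_uorf.uorf_start for c in calls if c.csq == "uStart_gain"}
            losses = {c.wild_uorf.uorf_start for c in calls if c.csq == "uStart_loss"}
            assert not gains & losses


class TestPredictTranslationEffect:
    @pytest.mark.parametrize(
        "csq,mut_type,transition,expected",
        [
            ("uStart_gain", OVERLAPPING, None, "decreased"),
            ("uStart_gain", N_TERMINAL, None, "N-terminal extension"),
            ("uStart_loss", None, None, "increased"),
            ("uStop_gain", NON_OVERLAPPING, None, "increased"),
            ("uStop_loss", OVERLAPPING, None, "decreased"),
            ("uStop_loss", NON_OVERLAPPING, None, "decreased"),
            ("uKozak", None, ("Weak", "Strong"), "decreased"),
            ("uKozak", None, ("Strong", "Weak"), "increased"),
            ("mKozak", None, ("Weak", "Strong"), "increased"),
            ("mKozak", None, ("Strong", "Adequate"), "decreased"),
        ],
    )
    def test_decision_table(self, csq, mut_type, transition, expected):
        from utr5var.reference import KozakContext

        mu = None
        if mut_type is not None:
            mu = UORF(1, 9, mut_type, "TAA", KozakContext("NNNNATGNN"), 9, 2)
        call = ConsequenceCall(csq, "", mutant_uorf=mu, kozak_transition=transition)
        assert predict_translation_effect(call) == expected


class TestReadVariants:
    def test_multiallelic_split_and_symbolic_skip(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\trs1\tA\tT,C\t.\tPASS\tAF=0.1,0.2\n"
            "chr1\t20\t.\tG\t<DEL>\t.\tPASS\t.\n"
        )
        variants, skipped = read_variants(str(vcf))
        assert [(v.pos, v.alt, v.maf) for v in variants] == [(10, "T", pytest.approx(0.1)), (10, "C", pytest.approx(0.2))]
        assert skipped["symbolic_alt"] == 1

    def test_fixture_round_trip_preserves_positions(self, bundle):
        variants, _ = read_variants(bundle["paths"]["vcf"])
        labels = pd.read_csv(bundle["paths"]["labels"], sep="\t")
        assert sorted(v.pos for v in variants) == sorted(labels["pos"])


class TestRecords:
    def test_schema_and_value_domains(self, bundle):
        from helpers import annotate_bundle

        df = annotate_bundle(bundle)
        assert list(df.columns) == BOX1_COLUMNS
        assert set(df["CSQ"]) <= set(CONSEQUENCES)
        assert set(df["Translation"]) <= {"increased", "decreased", "N-terminal extension"}
        assert set(df["STRAND"]) <= {"+", "-"}
        assert (df["5UTR_LENGTH"].astype(int) > 0).all()
        uorf_rows = df[df["uORF_TYPE"] != "NA"]
        assert set(uorf_rows["uORF_TYPE"]) <= {NON_OVERLAPPING, OVERLAPPING, N_TERMINAL}
        assert set(uorf_rows["uSTOP_CODON"]) <= {"TAA", "TGA", "TAG", "NA"}
        # mKozak rows carry no uORF detail
        assert (df.loc[df["CSQ"] == "mKozak", "uORF_TYPE"] == "NA").all()

    def test_variant_outside_all_utrs_yields_no_records(self, bundle):
        from utr5var import annotate

        v = Variant("chr1", 5, ".", "N", "A")
        records, counts = annotate([v], bundle["catalog"], bundle["genome"])
        assert records == [] and counts["no_utr_overlap"] == 1

    def test_new_uorf_flagged_in_ribo_seq_column(self, bundle):
        from helpers import annotate_bundle

        df = annotate_bundle(bundle)
        gains = df[df["CSQ"] == "uStart_gain"]
        assert (gains["Ribo_seq"] == "New uORF").all()
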