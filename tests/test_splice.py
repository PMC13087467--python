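"""Splice-prediction loading and 5' UTR reconstruction."""

import pandas as pd
import pytest

from utr5var.annotate import SkipVariant, Variant, build_context
from utr5var.splice import (
    SpliceEvent,
    annotate_splice_variant,
    load_splice_predictions,
    reconstruct_utr,
)

from helpers import make_two_exon_model


def _write_predictions(path, rows):
    cols = "chrom pos ref alt DS_AG DS_AL DS_DG DS_DL POS_AG POS_AL POS_DG POS_DL".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


class TestLoader:
    def test_below_cutoff_filtered(self, tmp_path):
        p = tmp_path / "s.tsv"
        _write_predictions(p, [("chr1", 10, "A", "G", 0.05, 0.05, 0.05, 0.05, 1, 1, 1, 1)])
        assert load_splice_predictions(str(p)) == []

    def test_donor_loss_above_cutoff_kept(self, tmp_path):
        p = tmp_path / "s.tsv"
        _write_predictions(p, [("chr1", 10, "G", "C", 0.0, 0.0, 0.0, 0.8, 0, 0, 0, 9)])
        (ev,) = load_splice_predictions(str(p))
        assert ev.site_kind == "donor_loss"
        assert ev.delta_score == pytest.approx(0.8)
        assert ev.predicted_site_pos == 9

    def test_threshold_override(self, tmp_path):
        p = tmp_path / "s.tsv"
        _write_predictions(p, [("chr1", 10, "G", "C", 0.3, 0.0, 0.0, 0.0, 9, 0, 0, 0)])
        assert len(load_splice_predictions(str(p), threshold=0.2)) == 1
        assert load_splice_predictions(str(p), threshold=0.5) == []

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "s.tsv"
        _write_predictions(p, [("chr1", "oops", "G", "C", 0, 0, 0, 0, 0, 0, 0, 0)])
        with pytest.raises(ValueError, match="line 2"):
            load_splice_predictions(str(p))


class TestReconstruction:
    def test_full_intron_retention(self):
        # exon1 AAA, intron GGG, exon2 TTT: donor loss -> AAAGGGTTT
        model, genome = make_two_exon_model("AAA", "GGG", "TTT", "ATGCCCTAA")
        ev = SpliceEvent(Variant("chrT", 4, ".", "G", "C"), "donor_loss", 0.8, 3)
        altered, recipe, anchor = reconstruct_utr(model, ev, genome)
        assert altered.sequence == "AAAGGGTTT"
        assert recipe.edit_kind == "full_intron_retention"
        assert len(altered.sequence) == 6 + 3
        assert anchor.map(4) == 7  # first exon2 base shifts by the intron length

    def test_exonic_deletion_from_new_donor(self):
        # new donor 2 nt upstream of the canonical donor: exon1 -> "A"
        model, genome = make_two_exon_model("AAA", "GGG", "TTT", "ATGCCCTAA")
        ev = SpliceEvent(Variant("chrT", 2, ".", "A", "G"), "donor_gain", 0.6, 1)
        altered, recipe, _ = reconstruct_utr(model, ev, genome)
        assert altered.sequence == "ATTT"
        assert recipe.edit_kind == "exonic_deletion"
        assert recipe.size == 2

    def test_partial_retention_from_intronic_acceptor(self):
        intron = "GT" + "C" * 96 + "AG"  # 100 nt
        model, genome = make_two_exon_model("AAA", intron, "TTT", "ATGCCCTAA")
        # new acceptor 70 nt from the intron end: retained = last 70 intron bases
        site = 3 + 100 - 70 + 1
        ev = SpliceEvent(Variant("chrT", site, ".", "C", "T"), "acceptor_gain", 0.5, site)
        altered, recipe, _ = reconstruct_utr(model, ev, genome)
        assert recipe.edit_kind == "partial_intron_retention"
        assert recipe.size == 70
        assert len(altered.sequence) == 6 + 70

    def test_event_deleting_cds_start_rejected(self):
        model, genome = make_two_exon_model("AAA", "GGG", "TTT", "ATGCCCTAA")
        # acceptor gain downstream of the UTR piece would delete into the CDS
        ev = SpliceEvent(Variant("chrT", 8, ".", "T", "A"), "donor_gain", 0.6, 8)
        with pytest.raises(SkipVariant):
            reconstruct_utr(model, ev, genome)

    def test_length_bookkeeping_on_fixture_events(self, bundle):
        events = load_splice_predictions(bundle["paths"]["splice"])
        assert events, "fixture bundle should contain splice events"
        checked = 0
        for ev in events:
            for model in bundle["catalog"].values():
                if len(model.utr5_intervals) < 2 or model.chrom != ev.variant.chrom:
                    continue
                lo = min(x[0] for x in model.exons)
                hi = max(x[1] for x in model.exons)
                if not lo <= ev.variant.pos <= hi:
                    continue
                wild_len = model.utr5_length
                altered, recipe, _ = reconstruct_utr(model, ev, bundle["genome"])
                if recipe.edit_kind.endswith("retention"):
                    assert len(altered.sequence) == wild_len + recipe.size
                else:
                    assert len(altered.sequence) == wild_len - recipe.size
                checked += 1
        assert checked >= 1


class TestSpliceAnnotation:
    def test_retention_with_intronic_uaug_is_ustart_gain(self):
        model, genome = make_two_exon_model("AAA", "GTATGGCAG", "TTT", "ATGCCCTAA")
        ctx = build_context(model, genome, None, None, None)
        ev = SpliceEvent(Variant("chrT", 4, ".", "G", "C"), "donor_loss", 0.9, 3)
        records = annotate_splice_variant(Variant("chrT", 4, ".", "G", "C"), ctx, ev, genome)
        assert any(r["CSQ"] == "uStart_gain" for r in records)
        assert all(r["Splicing_CSQ"] != "NA" for r in records)
        assert all("donor_loss" in r["SpliceAI"] for r in records)

    def test_splice_annotation_is_deterministic(self):
        model, genome = make_two_exon_model("AAA", "GTATGGCAG", "TTT", "ATGCCCTAA")
        ctx = build_context(model, genome, None, None, None)
        ev = SpliceEvent(Variant("chrT", 4, ".", "G", "C"), "donor_loss", 0.9, 3)
        v = Variant("chrT", 4, ".", "G", "C")
        a = annotate_splice_variant(v, ctx, ev, genome)
        b = annotate_splice_variant(v, ctx, ev, genome)
        assert a and a == b

    def test_overlapping_uorf_converted_to_nterminal_extension(self):
        # wild: uAUG at 2 out of frame, stop inside the CDS (Overlapping);
        # retaining a 4-nt intron brings it in frame with no stop -> NTE
        model, genome = make_two_exon_model("CATGC", "GTCA", "C", "ATGCTAATAA")
        ctx = build_context(model, genome, None, None, None)
        wild = {u.uorf_start: u.type for u in ctx.wild_uorfs}
        assert wild == {2: "Overlapping"}
        ev = SpliceEvent(Variant("chrT", 6, ".", "G", "C"), "donor_loss", 0.9, 5)
        records = annotate_splice_variant(Variant("chrT", 6, ".", "G", "C"), ctx, ev, genome)
        nte = [r for r in records if r["Translation"] == "N-terminal extension"]
        assert nte and nte[0]["CSQ"] == "uStop_loss"
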