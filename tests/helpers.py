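"""Shared constructors for transcript-space test objects."""

import pandas as pd

from utr5var.reference import CoordinateMap, SplicedUTR, TranscriptModel


def make_utr(utr_seq: str, cds_seq: str, chrom: str = "chrT", strand: str = "+") -> SplicedUTR:
    """A single-exon SplicedUTR laid out at genomic position 1."""
    n = len(utr_seq) + len(cds_seq)
    cmap = CoordinateMap(chrom, strand, [(1, n)])
    return SplicedUTR(utr_seq, cds_seq, cmap)


def make_two_exon_model(
    exon1_utr: str, intron: str, exon2_utr: str, cds: str, trail: str = ""
):
    """Plus-strand two-exon toy: exon1 is all UTR; exon2 = UTR piece + CDS."""
    e1 = (1, len(exon1_utr))
    i_lo = e1[1] + 1
    i_hi = i_lo + len(intron) - 1
    e2_lo = i_hi + 1
    utr2 = (e2_lo, e2_lo + len(exon2_utr) - 1) if exon2_utr else None
    cds_lo = e2_lo + len(exon2_utr)
    cds_iv = (cds_lo, cds_lo + len(cds) - 1)
    e2 = (e2_lo, cds_iv[1] + len(trail))
    genome = {"chrT": exon1_utr + intron + exon2_utr + cds + trail}
    model = TranscriptModel(
        transcript_id="TXT", gene_symbol="GENET", chrom="chrT", strand="+",
        exons=[e1, e2], cds_start_genomic=cds_lo, cds_intervals=[cds_iv],
        utr5_intervals=[e1] + ([utr2] if utr2 else []), start_exon_index=2,
        mane_id="NM_1.1",
    )
    return model, genome


def annotate_bundle(bundle, with_splice: bool = True) -> pd.DataFrame:
    """Run the full annotation pipeline over the fixture bundle."""
    from utr5var import annotate, read_variants
    from utr5var.annotate import BOX1_COLUMNS, build_context
    from utr5var.splice import annotate_splice_variant, load_splice_predictions

    variants, _ = read_variants(bundle["paths"]["vcf"])
    records, _ = annotate(
        variants, bundle["catalog"], bundle["genome"],
        bundle["evidence"], bundle["conservation"], bundle["constraint"],
    )
    if with_splice:
        events = load_splice_predictions(bundle["paths"]["splice"])
        by_key = {
            (e.variant.chrom, e.variant.pos, e.variant.ref, e.variant.alt): e
            for e in events
        }
        ctxs = {}
        for v in variants:
            ev = by_key.get((v.chrom, v.pos, v.ref, v.alt))
            if ev is None:
                continue
            for tid, model in bundle["catalog"].items():
                lo = min(x[0] for x in model.exons)
                hi = max(x[1] for x in model.exons)
                if model.chrom != v.chrom or not lo <= v.pos <= hi:
                    continue
                if tid not in ctxs:
                    ctxs[tid] = build_context(
                        model, bundle["genome"], bundle["evidence"],
                        bundle["conservation"], bundle["constraint"],
                    )
                records.extend(
                    annotate_splice_variant(
                        v, ctxs[tid], ev, bundle["genome"],
                        bundle["evidence"], bundle["conservation"],
                    )
                )
    return pd.DataFrame(records, columns=BOX1_COLUMNS)
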