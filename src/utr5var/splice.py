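"""Splice-aware 5' UTR reconstruction.

Precomputed splice-alteration predictions (four delta scores for acceptor/
donor gain/loss, with predicted site positions) are filtered at a
sensitivity cutoff (default 0.2) and converted into insertions or deletions
relative to the wild-type mature transcript:

* donor/acceptor **loss** -> full retention of the affected 5' UTR intron;
* donor/acceptor **gain inside an exon** -> exonic deletion of the span
  between the new and the canonical site;
* donor/acceptor **gain inside an intron** -> partial retention of the span
  between the canonical site and the new site.

Site position conventions (genomic, 1-based): a donor site is the last
exonic base of the exon it terminates; an acceptor site is the first exonic
base of the exon it opens. Only the single highest-delta event per variant
is reconstructed; all above-threshold deltas are listed in the SpliceAI
output column. The reconstructed 5' UTR is re-annotated through the standard
uORF diff engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotate import (
    AnnotationContext,
    ConsequenceCall,
    EditMap,
    SkipVariant,
    Variant,
    call_mkozak,
    diff_uorf_landscape,
    record_for_call,
)
from .reference import CoordinateMap, SplicedUTR, TranscriptModel, reverse_complement
from .uorf import attach_evidence, rank_and_distances, scan_uorfs

logger = logging.getLogger(__name__)

KINDS = {"AG": "acceptor_gain", "AL": "acceptor_loss", "DG": "donor_gain", "DL": "donor_loss"}


@dataclass
class SpliceEvent:
    variant: Variant
    site_kind: str          # donor_gain | donor_loss | acceptor_gain | acceptor_loss
    delta_score: float
    predicted_site_pos: int
    all_scores: str = ""    # printable summary of every above-threshold delta


@dataclass
class ReconstructionRecipe:
    edit_kind: str                             # exonic_deletion | full_intron_retention | partial_intron_retention
    removed_or_inserted_interval: tuple[int, int]
    splicing_csq: str

    @property
    def size(self) -> int:
        lo, hi = self.removed_or_inserted_interval
        return hi - lo + 1


def load_splice_predictions(path: str, threshold: float = 0.2) -> list[SpliceEvent]:
    """Load SpliceAI-style predictions from a TSV.

    Expected columns: chrom, pos, ref, alt, DS_AG, DS_AL, DS_DG, DS_DL,
    POS_AG, POS_AL, POS_DG, POS_DL (header line expected). The POS_* columns
    in this dialect carry absolute genomic site positions. Only the single
    highest-delta event per variant is retained, provided it reaches
    ``threshold``; all deltas at/above threshold are echoed in
    ``all_scores``.
    """
    events: list[SpliceEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom, pos, ref, alt = parts[0], int(parts[1]), parts[2], parts[3]
                scores = {k: float(parts[idx[f"DS_{k}"]]) for k in KINDS}
                positions = {k: int(parts[idx[f"POS_{k}"]]) for k in KINDS}
            except (ValueError, IndexError, KeyError) as e:
                raise ValueError(f"malformed splice prediction line {lineno} in {path}: {e}")
            best = max(scores, key=lambda k: scores[k])
            if scores[best] < threshold:
                continue
            above = [f"{k}={scores[k]:.2f}" for k in KINDS if scores[k] >= threshold]
            events.append(
                SpliceEvent(
                    Variant(chrom, pos, ".", ref, alt),
                    KINDS[best],
                    scores[best],
                    positions[best],
                    all_scores=";".join(above),
                )
            )
    return events


def _utr_introns(model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic (lo, hi) intervals of introns between 5' UTR exon pieces,
    ordered in transcript orientation."""
    introns = []
    pieces = model.utr5_intervals
    for (a_lo, a_hi), (b_lo, b_hi) in zip(pieces, pieces[1:]):
        if model.strand == "+":
            introns.append((a_hi + 1, b_lo - 1))
        else:
            introns.append((b_hi + 1, a_lo - 1))
    return introns


def _piece_offset(model: TranscriptModel, piece_idx: int, pos: int) -> int:
    """1-based transcript offset of genomic ``pos`` inside UTR piece ``piece_idx``."""
    off = sum(hi - lo + 1 for lo, hi in model.utr5_intervals[:piece_idx])
    lo, hi = model.utr5_intervals[piece_idx]
    within = pos - lo if model.strand == "+" else hi - pos
    return off + within + 1


def reconstruct_utr(
    model: TranscriptModel, event: SpliceEvent, genome
) -> tuple[SplicedUTR, ReconstructionRecipe, EditMap]:
    """Reconstruct the altered mature 5' UTR implied by ``event``.

    Returns the altered SplicedUTR (with a genuine genomic coordinate map
    over the altered exon structure), the recipe, and an anchor map from
    wild-type to altered transcript offsets. Raises SkipVariant for events
    that cannot be realized upstream of the CDS start.
    """
    pieces = model.utr5_intervals
    introns = _utr_introns(model)
    if not pieces:
        raise SkipVariant("transcript has no 5' UTR")
    p = event.predicted_site_pos
    plus = model.strand == "+"
    kind = event.site_kind

    in_intron = next((i for i, (lo, hi) in enumerate(introns) if lo <= p <= hi), None)
    in_piece = next((j for j, (lo, hi) in enumerate(pieces) if lo <= p <= hi), None)

    new_pieces = [list(x) for x in pieces]
    anchor = EditMap()

    if kind in ("donor_loss", "acceptor_loss"):
        if not introns:
            raise SkipVariant("no 5' UTR intron to retain")
        if in_intron is None:
            # site sits on the canonical boundary: pick the nearest intron edge
            dists = []
            for i, (lo, hi) in enumerate(introns):
                dists.append((min(abs(p - lo), abs(p - hi)), i))
            d, in_intron = min(dists)
            if d > 100:
                raise SkipVariant("predicted site not within 100 nt of a 5' UTR intron")
        lo, hi = introns[in_intron]
        ins_len = hi - lo + 1
        q = sum(h - l + 1 for l, h in pieces[: in_intron + 1])
        new_pieces.insert(in_intron + 1, [lo, hi])
        anchor.add(q + 1, q, ins_len)
        recipe = ReconstructionRecipe(
            "full_intron_retention", (lo, hi),
            f"full retention of 5'UTR intron {in_intron + 1} (+{ins_len} nt)",
        )
    elif in_intron is not None:  # gain inside an intron -> partial retention
        lo, hi = introns[in_intron]
        if kind == "donor_gain":
            # retained 5' part of the intron, through the new donor
            kept = (lo, p) if plus else (p, hi)
        else:
            # acceptor_gain: retained 3' part, from the new acceptor on
            kept = (p, hi) if plus else (lo, p)
        ins_len = kept[1] - kept[0] + 1
        q = sum(h - l + 1 for l, h in pieces[: in_intron + 1])
        new_pieces.insert(in_intron + 1, list(kept))
        anchor.add(q + 1, q, ins_len)
        recipe = ReconstructionRecipe(
            "partial_intron_retention", kept,
            f"partial retention of 5'UTR intron {in_intron + 1} (+{ins_len} nt)",
        )
    elif in_piece is not None:  # gain inside an exon -> exonic deletion
        lo, hi = pieces[in_piece]
        if kind == "donor_gain":
            if in_piece >= len(introns):
                raise SkipVariant("new donor in the CDS-start exon has no downstream intron")
            deleted = (p + 1, hi) if plus else (lo, p - 1)
            new_pieces[in_piece] = [lo, p] if plus else [p, hi]
        else:
            if in_piece == 0:
                raise SkipVariant("new acceptor in the first exon has no upstream intron")
            deleted = (lo, p - 1) if plus else (p + 1, hi)
            new_pieces[in_piece] = [p, hi] if plus else [lo, p]
        if deleted[1] < deleted[0]:
            raise SkipVariant("degenerate zero-length exonic deletion")
        del_len = deleted[1] - deleted[0] + 1
        a = _piece_offset(model, in_piece, deleted[0] if plus else deleted[1])
        anchor.add(a, a + del_len - 1, -del_len)
        recipe = ReconstructionRecipe(
            "exonic_deletion", deleted, f"exonic deletion in the 5'UTR (-{del_len} nt)"
        )
    else:
        raise SkipVariant("predicted site outside the 5' UTR exon/intron structure")

    lo, hi = recipe.removed_or_inserted_interval
    if lo <= model.cds_start_genomic <= hi:
        raise SkipVariant("reconstruction would remove the CDS start")

    new_pieces_t = [tuple(x) for x in new_pieces]
    cmap = CoordinateMap(model.chrom, model.strand, new_pieces_t + model.cds_intervals)

    def splice(intervals):
        parts = []
        for l, h in intervals:
            s = str(genome[model.chrom][l - 1 : h]).upper()
            parts.append(reverse_complement(s) if model.strand == "-" else s)
        return "".join(parts)

    altered = SplicedUTR(splice(new_pieces_t), splice(model.cds_intervals), cmap)
    return altered, recipe, anchor


def annotate_splice_variant(
    v: Variant,
    ctx: AnnotationContext,
    event: SpliceEvent,
    genome,
    evidence=None,
    conservation=None,
) -> list[dict]:
    """Reconstruct the altered 5' UTR for ``event``, apply the ALT allele,
    and diff the result against the wild-type landscape.

    Emitted records carry the SpliceAI and Splicing_CSQ columns.
    """
    altered, recipe, anchor = reconstruct_utr(ctx.model, event, genome)

    # apply the variant's ALT allele where it is exonic in the altered transcript
    full = altered.full_sequence
    cds_off = altered.cds_start_offset
    offsets = [altered.coord_map.to_transcript(pos) for pos in range(v.pos, v.end + 1)]
    if all(isinstance(t, int) for t in offsets):
        t1, t2 = min(offsets), max(offsets)
        minus = ctx.model.strand == "-"
        alt_t = reverse_complement(v.alt) if minus else v.alt
        ref_t = reverse_complement(v.ref) if minus else v.ref
        if t2 < cds_off and full[t1 - 1 : t2] == ref_t.upper():
            full = full[: t1 - 1] + alt_t.upper() + full[t2:]
            delta = len(alt_t) - (t2 - t1 + 1)
            cds_off += delta
            anchor.add(t1, t2, delta)

    mut_utr = SplicedUTR(full[: cds_off - 1], full[cds_off - 1 :], altered.coord_map)
    mut_uorfs = scan_uorfs(mut_utr)
    rank_and_distances(mut_uorfs, cds_off - 1)
    attach_evidence(mut_uorfs, evidence, conservation, ctx.model.transcript_id, altered.coord_map)

    if mut_utr.sequence == ctx.utr.sequence:
        return []
    calls = diff_uorf_landscape(ctx.wild_uorfs, mut_uorfs, anchor)
    mk = call_mkozak(ctx.utr.full_sequence, ctx.utr.cds_start_offset, full, cds_off)
    if mk is not None:
        calls.append(mk)

    spliceai = f"{event.site_kind}:{event.delta_score:.2f}@{ctx.model.chrom}:{event.predicted_site_pos}"
    if event.all_scores:
        spliceai += f" ({event.all_scores})"
    records = []
    for call in calls:
        records.append(
            record_for_call(
                v, ctx, call, anchor=None, conservation=conservation,
                spliceai=spliceai, splicing_csq=recipe.splicing_csq,
            )
        )
    return records
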