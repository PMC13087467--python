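"""Variant consequence annotation on mature 5' UTRs.

Each variant intersecting a 5' UTR is applied to the spliced UTR+CDS string,
the mutant sequence is re-scanned for uORFs, and the wild-type and mutant
uORF landscapes are diffed. This re-scan strategy treats SNVs, small indels
and large indels uniformly. Six consequence categories are called:

* uStart_gain  — a mutant uAUG with no anchored wild-type counterpart
* uStart_loss  — a wild-type uAUG with no mutant counterpart
* uStop_gain   — an anchored uORF whose stop moves strictly upstream
* uStop_loss   — an anchored uORF whose stop moves downstream or disappears
* uKozak       — an anchored uAUG whose Kozak strength category changes
* mKozak       — the CDS start Kozak strength category changes

One variant may yield several calls (one row each). The predicted direction
of the translational effect follows ribosome-scanning logic: new or
strengthened uORFs divert scanning ribosomes and decrease CDS translation;
removed or weakened uORFs increase it; a strengthened main-CDS Kozak
increases translation; in-frame stop-free uORFs produce N-terminal
extensions of the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from cyvcf2 import VCF

from .reference import (
    SplicedUTR,
    TranscriptModel,
    CoordinateMap,
    kozak_context,
    kozak_strength,
    reverse_complement,
    spliced_utr,
)
from .uorf import (
    N_TERMINAL,
    NON_OVERLAPPING,
    OVERLAPPING,
    UORF,
    attach_evidence,
    rank_and_distances,
    scan_uorfs,
    transcript_uorf_summary,
)

logger = logging.getLogger(__name__)

#: Output schema: variant identity, then the full annotation block, then the
#: two splice-module columns (NA for direct-UTR records).
BOX1_COLUMNS = [
    "CHROM", "POS", "ID", "REF", "ALT",
    "CSQ", "Translation", "5ULTRA_Score", "GENE", "TRANSCRIPT", "MANE",
    "5UTR_START", "5UTR_END", "STRAND", "5UTR_LENGTH", "START_EXON",
    "mKOZAK", "mKOZAK_STRENGTH",
    "uORF_count", "Overlapping_count", "Nterminal_count", "NonOverlapping_count",
    "uORF_START", "uORF_END", "Ribo_seq",
    "uSTART_mSTART_DIST", "uSTART_CAP_DIST", "uSTOP_CODON", "uORF_TYPE",
    "uKOZAK", "uKOZAK_STRENGTH", "uORF_LENGTH", "uORF_AA_LENGTH", "uORF_rank",
    "uSTART_PHYLOP", "uSTART_PHASTCONS", "pLI", "LOEUF",
    "SpliceAI", "Splicing_CSQ",
]

CONSEQUENCES = ["uStart_gain", "uStart_loss", "uStop_gain", "uStop_loss", "uKozak", "mKozak"]

_STRENGTH_ORDER = {"Weak": 0, "Adequate": 1, "Strong": 2}


class SkipVariant(Exception):
    """Raised when a variant cannot be evaluated on a transcript; logged, never fatal."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class Variant:
    chrom: str
    pos: int           # 1-based genomic position of the first REF base
    id: str
    ref: str
    alt: str
    maf: Optional[float] = None

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class ConsequenceCall:
    csq: str
    translation: str
    wild_uorf: Optional[UORF] = None
    mutant_uorf: Optional[UORF] = None
    kozak_transition: Optional[tuple[str, str]] = None

    @property
    def affected_uorf(self) -> Optional[UORF]:
        """Mutant-side uORF for gains, wild-type-side for losses."""
        if self.csq in ("uStart_gain", "uStop_gain"):
            return self.mutant_uorf
        return self.wild_uorf


class EditMap:
    """Maps wild-type transcript offsets to mutant offsets across one or more
    sequential edits. Offsets inside an edited span map to None."""

    def __init__(self):
        self.edits: list[tuple[int, int, int]] = []  # (t1, t2, delta) in wild coords of that step

    def add(self, t1: int, t2: int, delta: int) -> None:
        self.edits.append((t1, t2, delta))

    def map(self, offset: int) -> Optional[int]:
        for t1, t2, delta in self.edits:
            if offset < t1:
                continue
            if offset > t2:
                offset += delta
            else:
                return None
        return offset

    @property
    def span(self) -> tuple[int, int, int]:
        """(t1, t2, delta) of the first edit (single-edit maps)."""
        return self.edits[0]


def read_variants(vcf_path: str, maf_key: str = "AF") -> tuple[list[Variant], dict[str, int]]:
    """Read a VCF into Variant records.

    Multi-allelic rows are split into one Variant per ALT; symbolic ALTs
    (<DEL>, breakends, '*') are skipped and counted. MAF is read from the
    INFO field named ``maf_key`` when present.
    """
    variants: list[Variant] = []
    skipped = {"symbolic_alt": 0}
    for rec in VCF(vcf_path):
        info_af = rec.INFO.get(maf_key)
        for i, alt in enumerate(rec.ALT):
            if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                skipped["symbolic_alt"] += 1
                logger.info("skipping symbolic ALT %s at %s:%d", alt, rec.CHROM, rec.POS)
                continue
            maf = None
            if info_af is not None:
                maf = float(info_af[i]) if isinstance(info_af, tuple) else float(info_af)
            variants.append(
                Variant(rec.CHROM, rec.POS, rec.ID or ".", rec.REF, alt, maf)
            )
    return variants, skipped


def apply_variant(utr: SplicedUTR, v: Variant) -> tuple[str, int, EditMap]:
    """Apply ``v`` to the concatenated UTR+CDS string of ``utr``.

    Returns (mutant full sequence, mutant CDS start offset, anchor map from
    wild offsets to mutant offsets). Raises SkipVariant for variants whose
    REF spans intronic bases, does not intersect the 5' UTR, mismatches the
    spliced sequence, or overlaps the main start codon.
    """
    cmap = utr.coord_map
    full = utr.full_sequence
    L = len(utr.sequence)
    cds_off = utr.cds_start_offset

    offsets = []
    for pos in range(v.pos, v.end + 1):
        t = cmap.to_transcript(pos)
        if not isinstance(t, int):
            raise SkipVariant(f"REF base at {v.chrom}:{pos} is {t} for this transcript")
        offsets.append(t)
    t1, t2 = min(offsets), max(offsets)
    if t2 - t1 + 1 != len(offsets):
        raise SkipVariant("REF interval is not contiguous on the transcript")
    if t1 > L:
        raise SkipVariant("REF interval does not intersect the 5' UTR")

    minus = cmap.strand == "-"
    ref_t = reverse_complement(v.ref) if minus else v.ref
    alt_t = reverse_complement(v.alt) if minus else v.alt
    if full[t1 - 1 : t2] != ref_t.upper():
        raise SkipVariant(
            f"REF mismatch: expected {full[t1 - 1 : t2]} on transcript, VCF gives {ref_t}"
        )
    if t2 >= cds_off:
        raise SkipVariant("edit overlaps the main start codon")

    mutant = full[: t1 - 1] + alt_t.upper() + full[t2:]
    delta = len(alt_t) - (t2 - t1 + 1)
    anchor = EditMap()
    anchor.add(t1, t2, delta)
    return mutant, cds_off + delta, anchor


def _strength_change(old: str, new: str) -> Optional[str]:
    """'strengthened' / 'weakened' when both categories are defined and differ."""
    if old == new or "NA" in (old, new):
        return None
    return "strengthened" if _STRENGTH_ORDER[new] > _STRENGTH_ORDER[old] else "weakened"


def diff_uorf_landscape(
    wild: list[UORF],
    mutant: list[UORF],
    anchors: EditMap,
) -> list[ConsequenceCall]:
    """Diff wild-type and mutant uORF landscapes into consequence calls.

    uAUGs are matched by anchored offset outside the edited span; unanchored
    uAUGs inside the span are paired greedily by nearest relative offset.
    mKozak is not handled here (it needs the CDS contexts; see
    ``call_mkozak``).
    """
    t1, t2, delta = anchors.span
    mut_span_end = t2 + delta  # last mutant offset of the edited region
    mut_by_start = {m.uorf_start: m for m in mutant}
    pairs: list[tuple[UORF, UORF]] = []
    unpaired_wild: list[UORF] = []
    paired_mut_ids = set()

    for w in wild:
        mw = anchors.map(w.uorf_start)
        if mw is not None and mw in mut_by_start:
            pairs.append((w, mut_by_start[mw]))
            paired_mut_ids.add(id(mut_by_start[mw]))
        else:
            unpaired_wild.append(w)

    # nearest-offset pairing inside the edited span
    in_span_wild = [w for w in unpaired_wild if t1 <= w.uorf_start <= t2]
    in_span_mut = [
        m for m in mutant
        if id(m) not in paired_mut_ids and t1 <= m.uorf_start <= max(mut_span_end, t1)
    ]
    for w in sorted(in_span_wild, key=lambda u: u.uorf_start):
        if not in_span_mut:
            break
        best = min(in_span_mut, key=lambda m: abs((m.uorf_start - t1) - (w.uorf_start - t1)))
        pairs.append((w, best))
        paired_mut_ids.add(id(best))
        in_span_mut.remove(best)
        unpaired_wild.remove(w)

    calls: list[ConsequenceCall] = []
    for m in mutant:
        if id(m) not in paired_mut_ids:
            calls.append(ConsequenceCall("uStart_gain", "", mutant_uorf=m))
    for w in unpaired_wild:
        calls.append(ConsequenceCall("uStart_loss", "", wild_uorf=w))

    for w, m in pairs:
        w_has_stop = w.ustop_codon != "NA"
        m_has_stop = m.ustop_codon != "NA"
        if w_has_stop and m_has_stop:
            exp_end = anchors.map(w.uorf_end)
            if exp_end is None:
                exp_end = w.uorf_end if w.uorf_end < t1 else w.uorf_end + delta
            if m.uorf_end < exp_end:
                calls.append(ConsequenceCall("uStop_gain", "", wild_uorf=w, mutant_uorf=m))
            elif m.uorf_end > exp_end:
                calls.append(ConsequenceCall("uStop_loss", "", wild_uorf=w, mutant_uorf=m))
        elif w_has_stop and not m_has_stop:
            calls.append(ConsequenceCall("uStop_loss", "", wild_uorf=w, mutant_uorf=m))
        elif not w_has_stop and m_has_stop:
            calls.append(ConsequenceCall("uStop_gain", "", wild_uorf=w, mutant_uorf=m))

        change = _strength_change(w.ukozak.strength, m.ukozak.strength)
        if change is not None:
            calls.append(
                ConsequenceCall(
                    "uKozak", "", wild_uorf=w, mutant_uorf=m,
                    kozak_transition=(w.ukozak.strength, m.ukozak.strength),
                )
            )

    for c in calls:
        c.translation = predict_translation_effect(c)
    return calls


def call_mkozak(wild_full: str, wild_cds_off: int, mut_full: str, mut_cds_off: int) -> Optional[ConsequenceCall]:
    """Compare main-CDS Kozak strength between wild and mutant sequences."""
    old = kozak_strength(kozak_context(wild_full, wild_cds_off))
    if mut_full[mut_cds_off - 1 : mut_cds_off + 2] != "ATG":
        return None
    new = kozak_strength(kozak_context(mut_full, mut_cds_off))
    if _strength_change(old, new) is None:
        return None
    call = ConsequenceCall("mKozak", "", kozak_transition=(old, new))
    call.translation = predict_translation_effect(call)
    return call


def predict_translation_effect(call: ConsequenceCall) -> str:
    """Decision table mapping a consequence call to its predicted direction."""
    if call.csq == "uStart_gain":
        if call.mutant_uorf is not None and call.mutant_uorf.type == N_TERMINAL:
            return "N-terminal extension"
        return "decreased"
    if call.csq == "uStart_loss":
        return "increased"
    if call.csq == "uStop_gain":
        return "increased"
    if call.csq == "uStop_loss":
        m = call.mutant_uorf
        if m is not None and m.type == N_TERMINAL:
            return "N-terminal extension"
        return "decreased"
    if call.csq in ("uKozak", "mKozak"):
        old, new = call.kozak_transition
        strengthened = _STRENGTH_ORDER[new] > _STRENGTH_ORDER[old]
        if call.csq == "uKozak":
            return "decreased" if strengthened else "increased"
        return "increased" if strengthened else "decreased"
    raise ValueError(f"unknown consequence {call.csq}")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _inverse_map(anchor: EditMap, offset: int) -> Optional[int]:
    """Map a mutant offset back to a wild offset (None inside the edit)."""
    t1, t2, delta = anchor.span
    if offset < t1:
        return offset
    if offset > t2 + delta:
        return offset - delta
    # inside the edited region: genomically resolvable only for substitutions
    if delta == 0 and offset <= t2:
        return offset
    return None


@dataclass
class AnnotationContext:
    """Per-transcript wild-type annotation shared by all records."""

    model: TranscriptModel
    utr: SplicedUTR
    wild_uorfs: list[UORF]
    summary: dict[str, int]
    pli: Optional[float]
    loeuf: Optional[float]


def build_context(model, genome, evidence, conservation, constraint) -> AnnotationContext:
    utr = spliced_utr(model, genome)
    uorfs = scan_uorfs(utr)
    rank_and_distances(uorfs, len(utr.sequence))
    attach_evidence(uorfs, evidence, conservation, model.transcript_id, utr.coord_map)
    pli, loeuf = (constraint.get(model.gene_symbol) if constraint is not None else (None, None))
    return AnnotationContext(model, utr, uorfs, transcript_uorf_summary(uorfs), pli, loeuf)


def record_for_call(
    v: Variant,
    ctx: AnnotationContext,
    call: ConsequenceCall,
    anchor: Optional[EditMap] = None,
    conservation=None,
    spliceai: str = "NA",
    splicing_csq: str = "NA",
) -> dict:
    """Assemble one output row (Box-1 style schema) for a consequence call."""
    model, utr = ctx.model, ctx.utr
    mkozak_ctx = kozak_context(utr.full_sequence, utr.cds_start_offset)
    row = {
        "CHROM": v.chrom, "POS": v.pos, "ID": v.id, "REF": v.ref, "ALT": v.alt,
        "CSQ": call.csq, "Translation": call.translation, "5ULTRA_Score": "NA",
        "GENE": model.gene_symbol, "TRANSCRIPT": model.transcript_id,
        "MANE": model.mane_id or "NA",
        "5UTR_START": model.utr5_start_genomic, "5UTR_END": model.utr5_end_genomic,
        "STRAND": model.strand, "5UTR_LENGTH": model.utr5_length,
        "START_EXON": model.start_exon_index,
        "mKOZAK": mkozak_ctx.ninemer, "mKOZAK_STRENGTH": mkozak_ctx.strength,
        **ctx.summary,
        "SpliceAI": spliceai, "Splicing_CSQ": splicing_csq,
    }
    u = call.affected_uorf
    ufields = dict.fromkeys(
        ["uORF_START", "uORF_END", "Ribo_seq", "uSTART_mSTART_DIST", "uSTART_CAP_DIST",
         "uSTOP_CODON", "uORF_TYPE", "uKOZAK", "uKOZAK_STRENGTH", "uORF_LENGTH",
         "uORF_AA_LENGTH", "uORF_rank", "uSTART_PHYLOP", "uSTART_PHASTCONS"], None)
    if u is not None:
        mutant_side = u is call.mutant_uorf
        g_start, g_end = u.genomic_start, u.genomic_end
        ribo = u.ribo_seq
        phylop, phastcons = u.phylop_ustart, u.phastcons_ustart
        if mutant_side and call.csq == "uStart_gain":
            ribo = "New uORF"
        if mutant_side and anchor is not None:
            # mutant offsets have no direct genomic meaning; map back through the edit
            w_start = _inverse_map(anchor, u.uorf_start)
            w_end = _inverse_map(anchor, u.uorf_end)
            g_start = utr.coord_map.to_genomic(w_start) if w_start and w_start <= utr.coord_map.length else None
            g_end = utr.coord_map.to_genomic(w_end) if w_end and w_end <= utr.coord_map.length else None
            if conservation is not None and w_start is not None:
                pos3 = []
                for i in range(3):
                    wo = _inverse_map(anchor, u.uorf_start + i)
                    if wo is None or wo > utr.coord_map.length:
                        pos3 = None
                        break
                    pos3.append(utr.coord_map.to_genomic(wo))
                if pos3:
                    vals_p = [conservation.phylop.get(utr.coord_map.chrom, p) for p in pos3]
                    vals_c = [conservation.phastcons.get(utr.coord_map.chrom, p) for p in pos3]
                    phylop = None if any(x is None for x in vals_p) else sum(vals_p) / 3
                    phastcons = None if any(x is None for x in vals_c) else sum(vals_c) / 3
        ufields.update({
            "uORF_START": g_start, "uORF_END": g_end, "Ribo_seq": ribo,
            "uSTART_mSTART_DIST": u.dist_to_cds, "uSTART_CAP_DIST": u.dist_to_cap,
            "uSTOP_CODON": u.ustop_codon, "uORF_TYPE": u.type,
            "uKOZAK": u.ukozak.ninemer, "uKOZAK_STRENGTH": u.ukozak.strength,
            "uORF_LENGTH": u.length_nt, "uORF_AA_LENGTH": u.length_aa,
            "uORF_rank": u.rank,
            "uSTART_PHYLOP": phylop, "uSTART_PHASTCONS": phastcons,
        })
    row.update(ufields)
    row["pLI"] = ctx.pli
    row["LOEUF"] = ctx.loeuf
    return {k: _fmt(row[k]) for k in BOX1_COLUMNS}


def annotate(
    variants: list[Variant],
    catalog: dict[str, TranscriptModel],
    genome,
    evidence=None,
    conservation=None,
    constraint=None,
) -> tuple[list[dict], dict[str, int]]:
    """Annotate variants against every transcript whose 5' UTR they intersect.

    Returns (records, manifest counts). Per-variant failures are logged and
    counted, never fatal. Records are dicts keyed by BOX1_COLUMNS.
    """
    contexts: dict[str, AnnotationContext] = {}
    records: list[dict] = []
    counts = {"variants_in": len(variants), "annotated": 0, "no_utr_overlap": 0, "skipped": 0}

    for v in variants:
        hit_any = False
        for tid, model in catalog.items():
            if model.chrom != v.chrom or not model.utr5_intervals:
                continue
            if not any(lo <= v.end and v.pos <= hi for lo, hi in model.utr5_intervals):
                continue
            hit_any = True
            if tid not in contexts:
                contexts[tid] = build_context(model, genome, evidence, conservation, constraint)
            ctx = contexts[tid]
            try:
                mut_full, mut_cds_off, anchor = apply_variant(ctx.utr, v)
            except SkipVariant as e:
                logger.warning("skipping %s on %s: %s", v.key, tid, e.reason)
                counts["skipped"] += 1
                continue
            mut_utr_obj = SplicedUTR(
                mut_full[: mut_cds_off - 1], mut_full[mut_cds_off - 1 :], ctx.utr.coord_map
            )
            mut_uorfs = scan_uorfs(mut_utr_obj)
            rank_and_distances(mut_uorfs, mut_cds_off - 1)
            # carry wild-type evidence/conservation through the anchor for anchored uAUGs
            for m in mut_uorfs:
                w_off = _inverse_map(anchor, m.uorf_start)
                if w_off is not None:
                    for w in ctx.wild_uorfs:
                        if w.uorf_start == w_off:
                            m.ribo_seq = w.ribo_seq
                            m.phylop_ustart = w.phylop_ustart
                            m.phastcons_ustart = w.phastcons_ustart
                            break
            calls = diff_uorf_landscape(ctx.wild_uorfs, mut_uorfs, anchor)
            mk = call_mkozak(ctx.utr.full_sequence, ctx.utr.cds_start_offset, mut_full, mut_cds_off)
            if mk is not None:
                calls.append(mk)
            for call in calls:
                records.append(record_for_call(v, ctx, call, anchor, conservation))
                counts["annotated"] += 1
        if not hit_any:
            counts["no_utr_overlap"] += 1
    return records, counts


def write_records(records: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BOX1_COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(rec[c] for c in BOX1_COLUMNS) + "\n")
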