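"""Enumeration and characterization of ATG-initiated upstream ORFs.

Every ATG whose A lies within the mature 5' UTR opens one candidate uORF
(overlapping ATGs are each counted; uORFs sharing a stop but differing in
start are kept distinct). The stop search walks codons from the uAUG through
the UTR and on into the CDS. Types:

* ``Non-overlapping`` — the stop codon ends at or before the last UTR base;
* ``Overlapping`` — the uAUG is out of frame with the CDS and the first
  in-frame stop lies within the CDS (or, for stop-free out-of-frame walks,
  nowhere in the annotated CDS; then the stop codon is NA);
* ``N-terminal extension`` — the uAUG is in frame with the CDS and no stop
  intervenes before the CDS start, so translation runs into the main ORF.

For uORFs with a stop, length_nt runs from the uAUG through the stop codon
inclusive and length_aa excludes the stop (length_nt = 3*(length_aa+1)).
For N-terminal extensions length_nt is the uAUG-to-CDS distance (a multiple
of 3 by the in-frame condition) and uorf_end is the last 5' UTR base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .reference import STOP_CODONS, KozakContext, SplicedUTR, kozak_context

NON_OVERLAPPING = "Non-overlapping"
OVERLAPPING = "Overlapping"
N_TERMINAL = "N-terminal extension"


@dataclass
class UORF:
    uorf_start: int                      # transcript offset of the A of the uAUG
    uorf_end: int                        # offset of last base of stop / CDS-entry point
    type: str                            # Non-overlapping | Overlapping | N-terminal extension
    ustop_codon: str                     # TAA | TGA | TAG | NA
    ukozak: KozakContext
    length_nt: int
    length_aa: int
    genomic_start: Optional[int] = None
    genomic_end: Optional[int] = None
    rank: Optional[int] = None
    dist_to_cds: Optional[int] = None
    dist_to_cap: Optional[int] = None
    ribo_seq: str = "False"              # True | False | New uORF
    phylop_ustart: Optional[float] = None
    phastcons_ustart: Optional[float] = None


def scan_uorfs(utr: SplicedUTR) -> list[UORF]:
    """Enumerate all ATG-initiated uORFs in a spliced 5' UTR, sorted by start."""
    full = utr.full_sequence
    L = len(utr.sequence)
    cds_off = utr.cds_start_offset
    out: list[UORF] = []
    for s in range(1, L + 1):
        if full[s - 1 : s + 2] != "ATG":
            continue
        in_frame = (cds_off - s) % 3 == 0
        ctx = kozak_context(full, s)
        if in_frame:
            stop_at = None
            for c in range(s, cds_off - 2, 3):
                if full[c - 1 : c + 2] in STOP_CODONS:
                    stop_at = c
                    break
            if stop_at is not None:
                end = stop_at + 2
                nt = end - s + 1
                u = UORF(s, end, NON_OVERLAPPING, full[stop_at - 1 : stop_at + 2],
                         ctx, nt, nt // 3 - 1)
            else:
                nt = cds_off - s
                u = UORF(s, L, N_TERMINAL, "NA", ctx, nt, nt // 3)
        else:
            stop_at = None
            for c in range(s, len(full) - 2 + 1, 3):
                if full[c - 1 : c + 2] in STOP_CODONS:
                    stop_at = c
                    break
            if stop_at is not None:
                end = stop_at + 2
                nt = end - s + 1
                utype = NON_OVERLAPPING if end <= L else OVERLAPPING
                u = UORF(s, end, utype, full[stop_at - 1 : stop_at + 2],
                         ctx, nt, nt // 3 - 1)
            else:
                # out of frame, no stop anywhere in the annotated CDS
                n_codons = (len(full) - s + 1) // 3
                end = s + 3 * n_codons - 1
                nt = end - s + 1
                u = UORF(s, end, OVERLAPPING, "NA", ctx, nt, nt // 3)
        try:
            u.genomic_start = utr.coord_map.to_genomic(u.uorf_start)
            u.genomic_end = utr.coord_map.to_genomic(u.uorf_end)
        except IndexError:
            pass
        out.append(u)
    return out


def rank_and_distances(uorfs: list[UORF], utr_length: int) -> list[UORF]:
    """Fill rank (1 = uAUG closest to the CDS start) and the two distances.

    dist_to_cap = uorf_start - 1 (nt from the 5' cap to the uAUG);
    dist_to_cds = utr_length - uorf_start + 1. Rank ties (impossible for
    distinct starts) would break toward the smaller start offset.
    """
    for u in uorfs:
        if u.uorf_start > utr_length:
            raise ValueError("uORF start beyond the 5' UTR")
        u.dist_to_cap = u.uorf_start - 1
        u.dist_to_cds = utr_length - u.uorf_start + 1
    order = sorted(uorfs, key=lambda u: (u.dist_to_cds, u.uorf_start))
    for r, u in enumerate(order, start=1):
        u.rank = r
    return uorfs


def _mean_over_start(track, chrom: str, positions: list[int]) -> Optional[float]:
    vals = [track.get(chrom, p) for p in positions]
    if any(v is None for v in vals):
        return None
    return sum(vals) / len(vals)


def attach_evidence(
    uorfs: list[UORF],
    catalog,           # EvidenceCatalog or None
    cons,              # ConservationTrack or None
    transcript_id: str,
    coord_map,
) -> list[UORF]:
    """Attach ribo-seq translation evidence and uAUG conservation means.

    Conservation means cover the 3 uAUG bases; if any base lacks a score the
    mean is missing (None), never zero.
    """
    for u in uorfs:
        try:
            pos3 = [coord_map.to_genomic(u.uorf_start + i) for i in range(3)]
        except IndexError:
            pos3 = None
        if pos3 is not None:
            if catalog is not None and (transcript_id, pos3[0]) in catalog:
                u.ribo_seq = "True"
            if cons is not None:
                u.phylop_ustart = _mean_over_start(cons.phylop, coord_map.chrom, pos3)
                u.phastcons_ustart = _mean_over_start(cons.phastcons, coord_map.chrom, pos3)
    return uorfs


def transcript_uorf_summary(uorfs: list[UORF]) -> dict[str, int]:
    counts = {
        "uORF_count": len(uorfs),
        "Overlapping_count": sum(1 for u in uorfs if u.type == OVERLAPPING),
        "Nterminal_count": sum(1 for u in uorfs if u.type == N_TERMINAL),
        "NonOverlapping_count": sum(1 for u in uorfs if u.type == NON_OVERLAPPING),
    }
    return counts
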