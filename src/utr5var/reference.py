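"""Transcript models, spliced 5' UTR sequences, and Kozak context logic.

Coordinates follow the annotation conventions: GTF and VCF positions are
1-based inclusive genomic; internal transcript offsets are 1-based and
increase 5'->3' in transcript orientation. Exons of minus-strand transcripts
are stored in transcript orientation (descending genomic coordinate) and all
sequences are reverse-complemented so that downstream code only ever sees the
mature mRNA sense strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = ("TAA", "TGA", "TAG")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KozakContext:
    """The 9-mer covering positions -4..+5 around an ATG.

    ``ninemer`` holds, in order, positions -4,-3,-2,-1 then A,T,G then +4,+5.
    Positions outside the transcript are padded with ``N``. Strength is
    decided by the -3 and +4 positions alone: Strong when -3 is A/G and +4 is
    G (the (A/G)CCAUGG consensus), Adequate when exactly one of the two
    matches, Weak when neither, NA when either position is unavailable.
    """

    ninemer: str

    @property
    def minus3(self) -> str:
        return self.ninemer[1]

    @property
    def plus4(self) -> str:
        return self.ninemer[7]

    @property
    def strength(self) -> str:
        return kozak_strength(self)


def kozak_context(sequence: str, atg_offset: int) -> KozakContext:
    """Assemble the -4..+5 Kozak 9-mer around the ATG at 1-based ``atg_offset``.

    ``sequence`` is a transcript-scale string (typically the mature mRNA,
    5' UTR + CDS, so that contexts near the UTR/CDS boundary are complete).
    Flanks that fall outside the sequence are padded with ``N``.
    """
    if sequence[atg_offset - 1 : atg_offset + 2] != "ATG":
        raise ValueError(f"not an ATG at offset {atg_offset}")
    chars = []
    for off in range(atg_offset - 4, atg_offset + 5):
        if 1 <= off <= len(sequence):
            chars.append(sequence[off - 1])
        else:
            chars.append("N")
    return KozakContext("".join(chars))


def kozak_strength(context: KozakContext) -> str:
    m3, p4 = context.minus3, context.plus4
    if m3 == "N" or p4 == "N":
        return "NA"
    hits = int(m3 in "AG") + int(p4 == "G")
    return {2: "Strong", 1: "Adequate", 0: "Weak"}[hits]


class CoordinateMap:
    """Bijection between 1-based transcript offsets and genomic positions.

    Built from genomic intervals listed in transcript orientation. For
    minus-strand transcripts each interval is still stored as
    (low, high) genomic, but is traversed high->low.
    """

    def __init__(self, chrom: str, strand: str, intervals: list[tuple[int, int]]):
        self.chrom = chrom
        self.strand = strand
        self.intervals = list(intervals)
        self._cumlens = []
        total = 0
        for lo, hi in self.intervals:
            total += hi - lo + 1
            self._cumlens.append(total)
        self.length = total

    def to_genomic(self, offset: int) -> int:
        if not 1 <= offset <= self.length:
            raise IndexError(f"transcript offset {offset} outside 1..{self.length}")
        prev = 0
        for (lo, hi), cum in zip(self.intervals, self._cumlens):
            if offset <= cum:
                within = offset - prev - 1
                return lo + within if self.strand == "+" else hi - within
            prev = cum
        raise AssertionError("unreachable")

    def to_transcript(self, pos: int) -> Union[int, str]:
        """Map a genomic position to a transcript offset, or 'intronic'/'outside'."""
        prev = 0
        for (lo, hi), cum in zip(self.intervals, self._cumlens):
            if lo <= pos <= hi:
                within = pos - lo if self.strand == "+" else hi - pos
                return prev + within + 1
            prev = cum
        lo_all = min(lo for lo, _ in self.intervals)
        hi_all = max(hi for _, hi in self.intervals)
        if lo_all <= pos <= hi_all:
            return "intronic"
        return "outside"


@dataclass
class TranscriptModel:
    """Exon structure and 5' UTR geometry of one protein-coding transcript.

    ``exons`` and ``utr5_intervals`` are (low, high) 1-based inclusive genomic
    intervals ordered 5'->3' in transcript orientation. ``cds_start_genomic``
    is the genomic position of the first CDS base (the A of the main ATG).
    ``start_exon_index`` is the 1-based ordinal, in transcript orientation, of
    the exon containing the CDS start.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_genomic: int
    cds_intervals: list[tuple[int, int]]
    utr5_intervals: list[tuple[int, int]]
    start_exon_index: int
    mane_id: Optional[str] = None

    @property
    def utr5_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.utr5_intervals)

    @property
    def utr5_start_genomic(self) -> Optional[int]:
        """Genomic position of the first (cap-proximal) 5' UTR base."""
        if not self.utr5_intervals:
            return None
        lo, hi = self.utr5_intervals[0]
        return lo if self.strand == "+" else hi

    @property
    def utr5_end_genomic(self) -> Optional[int]:
        if not self.utr5_intervals:
            return None
        lo, hi = self.utr5_intervals[-1]
        return hi if self.strand == "+" else lo


@dataclass
class SplicedUTR:
    """The mature (post-splicing) 5' UTR plus its downstream CDS.

    ``sequence`` is the exon-concatenated, strand-corrected 5' UTR;
    ``downstream_cds_sequence`` the spliced CDS. ``coord_map`` covers the
    concatenated UTR+CDS so that overlapping-uORF stops inside the CDS remain
    genomically resolvable; transcript offset ``len(sequence)+1`` is the CDS
    start.
    """

    sequence: str
    downstream_cds_sequence: str
    coord_map: CoordinateMap

    @property
    def full_sequence(self) -> str:
        return self.sequence + self.downstream_cds_sequence

    @property
    def cds_start_offset(self) -> int:
        return len(self.sequence) + 1


def _fetch(genome: Fasta, chrom: str, lo: int, hi: int) -> str:
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} missing from reference FASTA")
    rec = genome[chrom]
    if hi > len(rec):
        raise ValueError(f"interval {chrom}:{lo}-{hi} outside contig bounds (len {len(rec)})")
    return str(rec[lo - 1 : hi]).upper()


def spliced_utr(model: TranscriptModel, genome: Fasta) -> SplicedUTR:
    """Splice the 5' UTR (and CDS) of ``model`` out of ``genome``."""
    if not model.utr5_intervals:
        raise ValueError(f"{model.transcript_id} has no 5' UTR")

    def splice(intervals: list[tuple[int, int]]) -> str:
        parts = []
        for lo, hi in intervals:
            s = _fetch(genome, model.chrom, lo, hi)
            parts.append(reverse_complement(s) if model.strand == "-" else s)
        return "".join(parts)

    utr_seq = splice(model.utr5_intervals)
    cds_seq = splice(model.cds_intervals)
    cmap = CoordinateMap(model.chrom, model.strand, model.utr5_intervals + model.cds_intervals)
    return SplicedUTR(utr_seq, cds_seq, cmap)


def map_genomic_to_transcript(model: TranscriptModel, pos: int) -> Union[int, str]:
    """Map a genomic position into 1-based 5' UTR transcript offsets.

    Returns the offset for exonic 5' UTR positions, ``'intronic'`` for
    positions between 5' UTR exons, and ``'outside'`` otherwise.
    """
    if not model.utr5_intervals:
        return "outside"
    cmap = CoordinateMap(model.chrom, model.strand, model.utr5_intervals)
    return cmap.to_transcript(pos)


def _validate_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"malformed annotation line {lineno} in {path}")


def _transcript_model(db, tx, mane_tag: str) -> Optional[TranscriptModel]:
    """Build a TranscriptModel from a gffutils transcript feature, or None."""
    tid = tx.id
    exons = sorted(
        [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
    )
    cds = sorted([(f.start, f.end) for f in db.children(tx, featuretype="CDS")])
    if not cds:
        logger.info("skipping %s: no annotated CDS", tid)
        return None
    tags = tx.attributes.get("tag", [])
    if "cds_start_NF" in tags or "cds_end_NF" in tags:
        logger.info("skipping %s: CDS flagged incomplete", tid)
        return None
    strand = tx.strand
    if strand == "+":
        cds_start = cds[0][0]
        tx_exons = exons
        tx_cds = cds
    else:
        cds_start = cds[-1][1]
        tx_exons = exons[::-1]
        tx_cds = cds[::-1]

    utr5 = []
    start_exon_index = None
    for i, (lo, hi) in enumerate(tx_exons, start=1):
        if strand == "+":
            if hi < cds_start:
                utr5.append((lo, hi))
            elif lo <= cds_start <= hi:
                if cds_start > lo:
                    utr5.append((lo, cds_start - 1))
                start_exon_index = i
                break
        else:
            if lo > cds_start:
                utr5.append((lo, hi))
            elif lo <= cds_start <= hi:
                if cds_start < hi:
                    utr5.append((cds_start + 1, hi))
                start_exon_index = i
                break
    if start_exon_index is None:
        logger.warning("skipping %s: CDS start not contained in any exon", tid)
        return None

    gene = tx.attributes.get("gene_name", [tid])[0]
    mane_id = tx.attributes.get("mane_id", [None])[0]
    if mane_id is None and mane_tag in tags:
        mane_id = tid
    return TranscriptModel(
        transcript_id=tid,
        gene_symbol=gene,
        chrom=tx.seqid,
        strand=strand,
        exons=tx_exons,
        cds_start_genomic=cds_start,
        cds_intervals=tx_cds,
        utr5_intervals=utr5,
        start_exon_index=start_exon_index,
        mane_id=mane_id,
    )


def load_reference(
    fasta_path: str,
    annotation_path: str,
    transcript_set: str = "mane",
    mane_tag: str = "MANE_Select",
) -> dict[str, TranscriptModel]:
    """Parse a genome FASTA + GENCODE-style GTF into transcript models.

    ``transcript_set='mane'`` keeps only transcripts carrying the MANE tag
    (attribute ``tag "MANE_Select"`` or a ``mane_id`` attribute);
    ``'all'`` keeps every protein-coding transcript with an annotated CDS.
    Transcripts with a zero-length 5' UTR are retained in the catalog (they
    simply yield no annotations); transcripts without a CDS, with incomplete
    CDS tags, are skipped with a logged reason.
    """
    if transcript_set not in ("mane", "all"):
        raise ValueError("transcript_set must be 'mane' or 'all'")
    _validate_gtf(annotation_path)
    genome = Fasta(fasta_path)
    db = gffutils.create_db(
        annotation_path,
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    catalog: dict[str, TranscriptModel] = {}
    for tx in db.features_of_type("transcript", order_by="start"):
        model = _transcript_model(db, tx, mane_tag)
        if model is None:
            continue
        if transcript_set == "mane" and model.mane_id is None:
            logger.info("excluding %s: no MANE tag", model.transcript_id)
            continue
        if model.chrom not in genome:
            raise KeyError(f"contig {model.chrom!r} missing from reference FASTA")
        if not model.utr5_intervals:
            logger.info("%s has zero-length 5' UTR; retained but will not be annotated",
                        model.transcript_id)
        catalog[model.transcript_id] = model
    return catalog
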