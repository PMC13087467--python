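"""Synthetic desk-scale inputs: toy genome, annotation, conservation,
uORF evidence, labeled variants, and splice predictions.

The generator emulates the shapes of the real resources (GENCODE-style GTF
with MANE tags, gnomAD-style VCF with allele frequencies, Ribo-uORF-style
evidence TSV, per-base conservation TSVs, SpliceAI-style prediction TSV) at
a scale where full pipeline runs complete in seconds. Defaults mirror the
observed human 5' UTR geometry: lengths 50-300 nt with median near 136 nt,
and roughly 38% of transcripts with the CDS start downstream of exon 1.

Every fixture ships a machine-readable truth sidecar: planted uORFs are
enumerated by a local brute-force codon walk that is fully independent of
the package's scanning engine, planted variants record their intended
consequence, and conservation is baseline noise N(0, 0.5) phyloP with
+3 phyloP / +0.8 PhastCons bumps at uAUGs carrying translation evidence, so
the prioritization model has a learnable planted signal.

All randomness flows from the single config seed; regeneration is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .reference import CoordinateMap, reverse_complement

_STOPS = ("TAA", "TGA", "TAG")
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class FixtureConfig:
    seed: int
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 3)
    utr5_length_range: tuple[int, int] = (50, 300)
    utr5_length_median: int = 136
    uorf_density: float = 2.0              # expected planted uORFs per UTR
    fraction_multi_exon_utr: float = 0.38
    cds_codons_range: tuple[int, int] = (20, 50)
    intron_length_range: tuple[int, int] = (40, 90)
    chrom: str = "chr1"

    def __post_init__(self):
        if self.utr5_length_range[0] < 20:
            raise ValueError("UTR length range too short to host planted uORFs")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


def brute_force_uorfs(utr_seq: str, cds_seq: str) -> list[dict]:
    """Independent exhaustive uORF enumerator (oracle).

    Triple loop: every UTR position is tested for ATG; the codon walk
    proceeds one codon at a time through UTR then CDS. In-frame starts with
    no stop before the CDS are N-terminal extensions; out-of-frame walks
    continue into the CDS (Overlapping) and report NA when no stop exists.
    """
    full = utr_seq + cds_seq
    L = len(utr_seq)
    cds_off = L + 1
    found = []
    for s in range(1, L + 1):
        if full[s - 1] != "A" or full[s : s + 2] != "TG":
            continue
        in_frame = (cds_off - s) % 3 == 0
        stop = None
        c = s
        while c + 2 <= len(full):
            if in_frame and c >= cds_off:
                break
            codon = full[c - 1 : c + 2]
            if codon in _STOPS:
                stop = c
                break
            c += 3
        if stop is not None:
            end = stop + 2
            found.append({
                "start": s, "end": end,
                "type": "Non-overlapping" if end <= L else "Overlapping",
                "ustop": full[stop - 1 : stop + 2],
                "length_nt": end - s + 1,
            })
        elif in_frame:
            found.append({
                "start": s, "end": L, "type": "N-terminal extension",
                "ustop": "NA", "length_nt": cds_off - s,
            })
        else:
            n_codons = (len(full) - s + 1) // 3
            found.append({
                "start": s, "end": s + 3 * n_codons - 1, "type": "Overlapping",
                "ustop": "NA", "length_nt": 3 * n_codons,
            })
    return found


def _kozak_category(full: str, s: int) -> str:
    """Local Kozak strength rule (generator-side copy, -3/+4 only)."""
    m3 = full[s - 4] if s - 4 >= 0 else "N"
    p4 = full[s + 2] if s + 2 < len(full) else "N"
    if m3 == "N" or p4 == "N":
        return "NA"
    return {2: "Strong", 1: "Adequate", 0: "Weak"}[int(m3 in "AG") + int(p4 == "G")]


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _build_gene(rng: np.random.Generator, cfg: FixtureConfig, idx: int) -> dict:
    strand = "+" if rng.random() < 0.5 else "-"
    L = int(np.clip(
        round(rng.lognormal(np.log(cfg.utr5_length_median), 0.4)),
        *cfg.utr5_length_range,
    ))
    multi = bool(rng.random() < cfg.fraction_multi_exon_utr)
    if multi:
        n_pieces = int(rng.integers(2, cfg.exons_per_gene[1] + 1))
        # last piece (in the CDS-start exon) may be empty: the CDS then
        # starts precisely at the first base of its exon
        last_empty = bool(rng.random() < 0.2)
        inner = n_pieces - 1 if last_empty else n_pieces
        while True:
            cuts = np.sort(rng.integers(12, max(13, L - 12), size=inner - 1)) if inner > 1 else np.array([], dtype=int)
            lens = np.diff(np.concatenate([[0], cuts, [L]])).tolist()
            if all(x >= 10 for x in lens):
                break
        piece_lens = lens + ([0] if last_empty else [])
    else:
        piece_lens = [L]

    utr = list(_random_seq(rng, L))
    # plant uAUGs (a stop is planted downstream in-frame for most of them)
    for _ in range(rng.poisson(cfg.uorf_density)):
        if L < 15:
            break
        s = int(rng.integers(1, L - 10))
        utr[s - 1 : s + 2] = "ATG"
        if rng.random() < 0.6:
            max_j = (L - s - 4) // 3
            if max_j >= 1:
                j = int(rng.integers(1, max_j + 1))
                c = s + 3 * j
                utr[c - 1 : c + 2] = str(rng.choice(_STOPS))
    utr = "".join(utr)

    n_codons = int(rng.integers(*cfg.cds_codons_range))
    cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=n_codons)) + str(rng.choice(_STOPS))
    trail = _random_seq(rng, 12)

    introns = []
    for _ in range(len(piece_lens) - 1):
        ilen = int(rng.integers(*cfg.intron_length_range))
        body = list(_random_seq(rng, ilen - 4))
        # plant an intronic ATG so intron retention creates a new uORF
        mid = (ilen - 4) // 2
        if mid >= 4:
            body[mid : mid + 5] = "ATGGC"
        introns.append("GT" + "".join(body) + "AG")

    # assemble pre-mRNA and transcript-space feature spans
    pre = []
    exon_spans = []      # transcript-space (1-based) spans of exons
    cursor = 0
    pieces = []
    off = 0
    for plen in piece_lens:
        pieces.append(utr[off : off + plen])
        off += plen
    for i, p in enumerate(pieces[:-1] if len(pieces) > 1 else []):
        pre.append(p)
        exon_spans.append((cursor + 1, cursor + len(p)))
        cursor += len(p)
        pre.append(introns[i])
        cursor += len(introns[i])
    last_exon_seq = pieces[-1] + cds + trail
    pre.append(last_exon_seq)
    cds_start_t = cursor + len(pieces[-1]) + 1
    exon_spans.append((cursor + 1, cursor + len(last_exon_seq)))
    cursor += len(last_exon_seq)
    pre = "".join(pre)
    cds_span_t = (cds_start_t, cds_start_t + len(cds) - 1)

    return {
        "idx": idx, "strand": strand, "pre": pre,
        "exon_spans": exon_spans, "cds_span": cds_span_t,
        "utr_seq": utr, "cds_seq": cds,
        "piece_lens": piece_lens, "multi": len(exon_spans) > 1,
    }


def _to_genomic_span(span_t: tuple[int, int], gene_start: int, gene_len: int, strand: str) -> tuple[int, int]:
    a, b = span_t
    if strand == "+":
        return gene_start + a - 1, gene_start + b - 1
    return gene_start + (gene_len - b), gene_start + (gene_len - a)


def generate_reference(cfg: FixtureConfig, out_dir) -> dict[str, str]:
    """Write genome FASTA, GTF, conservation TSVs, evidence, constraint, and
    the truth sidecar. Returns a dict of paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = [_build_gene(rng, cfg, i) for i in range(cfg.n_genes)]
    genome_parts = []
    gtf_lines = []
    truth = {}
    cons_rows = []      # (pos, phylop, phastcons)
    evidence_rows = []
    constraint_rows = []
    cursor = 1  # next free genomic position

    for g in genes:
        pad = _random_seq(rng, 100)
        genome_parts.append(pad)
        cursor += len(pad)
        gene_start = cursor
        gene_len = len(g["pre"])
        gene_seq = g["pre"] if g["strand"] == "+" else reverse_complement(g["pre"])
        genome_parts.append(gene_seq)
        cursor += gene_len

        tid = f"TX{g['idx']:04d}"
        gname = f"GENE{g['idx']}"
        mane = f"NM_{900000 + g['idx']}.1"
        exon_g = [_to_genomic_span(s, gene_start, gene_len, g["strand"]) for s in g["exon_spans"]]
        cds_g = _to_genomic_span(g["cds_span"], gene_start, gene_len, g["strand"])
        lo = min(x[0] for x in exon_g)
        hi = max(x[1] for x in exon_g)
        attrs = (
            f'gene_id "{gname}"; transcript_id "{tid}"; gene_name "{gname}"; '
            f'tag "basic"; tag "MANE_Select"; mane_id "{mane}";'
        )
        st = g["strand"]
        gtf_lines.append((lo, f"{cfg.chrom}\ttoy\tgene\t{lo}\t{hi}\t.\t{st}\t.\t{attrs}"))
        gtf_lines.append((lo, f"{cfg.chrom}\ttoy\ttranscript\t{lo}\t{hi}\t.\t{st}\t.\t{attrs}"))
        for e_lo, e_hi in sorted(exon_g):
            gtf_lines.append((e_lo, f"{cfg.chrom}\ttoy\texon\t{e_lo}\t{e_hi}\t.\t{st}\t.\t{attrs}"))
        gtf_lines.append((cds_g[0], f"{cfg.chrom}\ttoy\tCDS\t{cds_g[0]}\t{cds_g[1]}\t.\t{st}\t.\t{attrs}"))

        # 5' UTR genomic pieces in transcript orientation, for the coordinate map
        utr_pieces_t = []
        off = 0
        for plen in g["piece_lens"]:
            if plen:
                utr_pieces_t.append((off + 1, off + plen))
            off += plen
        # transcript-space offsets -> pre-mRNA coords -> genomic
        pre_spans = []
        t_cursor = 0
        for span, plen in zip(g["exon_spans"], g["piece_lens"]):
            if plen:
                pre_spans.append((span[0], span[0] + plen - 1))
        utr_intervals = [
            _to_genomic_span(s, gene_start, gene_len, g["strand"]) for s in pre_spans
        ]
        cmap = CoordinateMap(cfg.chrom, g["strand"], utr_intervals)

        uorfs = brute_force_uorfs(g["utr_seq"], g["cds_seq"])
        ribo_starts = []
        for u in uorfs:
            if rng.random() < 0.5:
                ribo_starts.append(u["start"])
        real_positions = set()
        for s in ribo_starts:
            gpos = cmap.to_genomic(s)
            evidence_rows.append((tid, cfg.chrom, gpos, "riboseq"))
            for i in range(3):
                real_positions.add(cmap.to_genomic(s + i))
        # baseline conservation over every UTR base, bumps at evidenced uAUGs
        for t in range(1, len(g["utr_seq"]) + 1):
            gpos = cmap.to_genomic(t)
            phy = rng.normal(0.0, 0.5)
            pc = float(np.clip(rng.normal(0.1, 0.05), 0, 1))
            if gpos in real_positions:
                phy += 3.0
                pc = float(np.clip(pc + 0.8, 0, 1))
            cons_rows.append((gpos, phy, pc))

        pli = float(np.round(rng.beta(0.5, 0.5), 3))
        loeuf = float(np.round(rng.uniform(0.1, 1.8), 3))
        constraint_rows.append((gname, pli, loeuf))

        truth[tid] = {
            "gene": gname, "strand": g["strand"], "chrom": cfg.chrom,
            "utr5_length": len(g["utr_seq"]),
            "multi_exon_utr": g["multi"],
            "start_exon_index": len(g["exon_spans"]),
            "utr_seq": g["utr_seq"], "cds_seq": g["cds_seq"],
            "utr_intervals": [list(x) for x in utr_intervals],
            "cds_start_genomic": cds_g[0] if g["strand"] == "+" else cds_g[1],
            "uorfs": uorfs,
            "ribo_starts": ribo_starts,
        }

    genome_parts.append(_random_seq(rng, 100))
    genome = "".join(genome_parts)

    paths = {
        "fasta": str(out / "genome.fa"),
        "gtf": str(out / "annotation.gtf"),
        "phylop": str(out / "phylop.tsv"),
        "phastcons": str(out / "phastcons.tsv"),
        "evidence": str(out / "uorf_evidence.tsv"),
        "constraint": str(out / "constraint.tsv"),
        "truth": str(out / "truth.json"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i : i + 60] + "\n")
    with open(paths["gtf"], "w") as fh:
        for _, line in sorted(gtf_lines, key=lambda t: t[0]):
            fh.write(line + "\n")
    with open(paths["phylop"], "w") as fh:
        for pos, phy, _ in sorted(cons_rows):
            fh.write(f"{cfg.chrom}\t{pos}\t{phy:.4f}\n")
    with open(paths["phastcons"], "w") as fh:
        for pos, _, pc in sorted(cons_rows):
            fh.write(f"{cfg.chrom}\t{pos}\t{pc:.4f}\n")
    with open(paths["evidence"], "w") as fh:
        fh.write("transcript_id\tchrom\tgenomic_uAUG_pos\tsource\n")
        for row in sorted(evidence_rows):
            fh.write("\t".join(map(str, row)) + "\n")
    with open(paths["constraint"], "w") as fh:
        fh.write("gene\tpLI\tLOEUF\n")
        for row in constraint_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

def _atg_starts(utr_seq: str) -> set[int]:
    return {
        i for i in range(1, len(utr_seq) + 1)
        if utr_seq[i - 1 : i + 2] == "ATG"
    }


def _walk_end(full: str, cds_off: int, s: int) -> Optional[int]:
    """Offset of the last stop-codon base for the uORF starting at s, or None."""
    in_frame = (cds_off - s) % 3 == 0
    c = s
    while c + 2 <= len(full):
        if in_frame and c >= cds_off:
            return None
        if full[c - 1 : c + 2] in _STOPS:
            return c + 2
        c += 3
    return None


class _Tx:
    """Planting context for one transcript (transcript-space view)."""

    def __init__(self, tid: str, info: dict, genome: Fasta):
        self.tid = tid
        self.gene = info["gene"]
        self.chrom = info["chrom"]
        self.strand = info["strand"]
        self.utr = info["utr_seq"]
        self.cds = info["cds_seq"]
        self.full = self.utr + self.cds
        self.L = len(self.utr)
        self.cds_off = self.L + 1
        self.uorfs = info["uorfs"]
        self.utr_intervals = [tuple(x) for x in info["utr_intervals"]]
        self.cmap = CoordinateMap(self.chrom, self.strand, self.utr_intervals)
        self.genome = genome

    # --- transcript-space edit -> VCF row -------------------------------
    def snv_row(self, q: int, alt_base: str) -> tuple[int, str, str]:
        g = self.cmap.to_genomic(q)
        ref_g = str(self.genome[self.chrom][g - 1]).upper()
        alt_g = alt_base if self.strand == "+" else reverse_complement(alt_base)
        return g, ref_g, alt_g

    def deletion_row(self, d1: int, d2: int) -> Optional[tuple[int, str, str]]:
        """Plus-strand only; anchor base is the one before the deleted span."""
        if self.strand != "+" or d1 < 2:
            return None
        g = [self.cmap.to_genomic(t) for t in range(d1 - 1, d2 + 1)]
        if g != list(range(g[0], g[0] + len(g))):
            return None  # span crosses an exon boundary
        seq = str(self.genome[self.chrom][g[0] - 1 : g[-1]]).upper()
        return g[0], seq, seq[0]

    def insertion_row(self, t: int, ins: str) -> Optional[tuple[int, str, str]]:
        """Insert ``ins`` after transcript offset ``t`` (plus-strand only)."""
        if self.strand != "+" or t < 1 or t >= self.L:
            return None
        g = self.cmap.to_genomic(t)
        if self.cmap.to_genomic(t + 1) != g + 1:
            return None  # at an exon boundary
        ref_g = str(self.genome[self.chrom][g - 1]).upper()
        return g, ref_g, ref_g + ins


def _try_snv(tx: _Tx, q: int, alt: str):
    """Mutant UTR string after a transcript-space SNV (no validity checks)."""
    return tx.utr[: q - 1] + alt + tx.utr[q:]


def _plant_ustart_gain_snv(tx: _Tx, rng) -> Optional[dict]:
    order = rng.permutation(np.arange(5, max(6, tx.L - 2)))
    wild_starts = _atg_starts(tx.utr)
    for s in order:
        s = int(s)
        codon = tx.utr[s - 1 : s + 2]
        if len(codon) < 3 or codon == "ATG":
            continue
        diff = [i for i in range(3) if codon[i] != "ATG"[i]]
        if len(diff) != 1:
            continue
        q = s + diff[0]
        mut = _try_snv(tx, q, "ATG"[diff[0]])
        if _atg_starts(mut) == wild_starts | {s}:
            return {"q": q, "alt": "ATG"[diff[0]], "csq": "uStart_gain"}
    return None


def _plant_ustart_loss_snv(tx: _Tx, rng) -> Optional[dict]:
    wild_starts = _atg_starts(tx.utr)
    for s in rng.permutation(sorted(wild_starts)).tolist():
        s = int(s)
        for i, alt in [(0, "C"), (1, "G"), (2, "C"), (0, "T")]:
            q = s + i
            if tx.utr[q - 1] == alt:
                continue
            mut = _try_snv(tx, q, alt)
            if _atg_starts(mut) == wild_starts - {s}:
                return {"q": q, "alt": alt, "csq": "uStart_loss"}
    return None


def _plant_ustop_gain_snv(tx: _Tx, rng) -> Optional[dict]:
    wild_starts = _atg_starts(tx.utr)
    cands = [u for u in tx.uorfs if u["ustop"] != "NA" and u["length_nt"] >= 12]
    for u in rng.permutation(np.arange(len(cands))).tolist():
        u = cands[int(u)]
        s, end = u["start"], u["end"]
        for c in range(s + 3, min(end - 5, tx.L - 2) + 1, 3):
            codon = tx.utr[c - 1 : c + 2]
            for stop in _STOPS:
                diff = [i for i in range(3) if codon[i] != stop[i]]
                if len(diff) != 1:
                    continue
                q = c + diff[0]
                mut = _try_snv(tx, q, stop[diff[0]])
                if _atg_starts(mut) != wild_starts:
                    continue
                new_end = _walk_end(mut + tx.cds, tx.cds_off, s)
                if new_end is not None and new_end < end:
                    return {"q": q, "alt": stop[diff[0]], "csq": "uStop_gain"}
    return None


def _plant_ustop_loss_snv(tx: _Tx, rng) -> Optional[dict]:
    wild_starts = _atg_starts(tx.utr)
    cands = [u for u in tx.uorfs if u["type"] == "Non-overlapping"]
    for u in rng.permutation(np.arange(len(cands))).tolist():
        u = cands[int(u)]
        s, end = u["start"], u["end"]
        stop_start = end - 2
        codon = tx.utr[stop_start - 1 : stop_start + 2]
        for i in range(3):
            for alt in _BASES:
                if alt == codon[i]:
                    continue
                new_codon = codon[:i] + alt + codon[i + 1 :]
                if new_codon in _STOPS:
                    continue
                q = stop_start + i
                mut = _try_snv(tx, q, alt)
                if _atg_starts(mut) != wild_starts:
                    continue
                new_end = _walk_end(mut + tx.cds, tx.cds_off, s)
                if new_end is None or new_end > end:
                    return {"q": q, "alt": alt, "csq": "uStop_loss"}
    return None


def _flip_kozak_alts(base: str) -> list[str]:
    return ["C", "T"] if base in "AG" else ["A", "G"]


def _plant_ukozak_snv(tx: _Tx, rng) -> Optional[dict]:
    wild_starts = _atg_starts(tx.utr)
    cands = [u for u in tx.uorfs if u["start"] >= 4]
    for u in rng.permutation(np.arange(len(cands))).tolist():
        u = cands[int(u)]
        s = u["start"]
        if _kozak_category(tx.full, s) == "NA":
            continue
        q = s - 3
        for alt in _flip_kozak_alts(tx.utr[q - 1]):
            mut = _try_snv(tx, q, alt)
            if _atg_starts(mut) != wild_starts:
                continue
            if _kozak_category(mut + tx.cds, s) != _kozak_category(tx.full, s):
                return {"q": q, "alt": alt, "csq": "uKozak"}
    return None


def _plant_mkozak_snv(tx: _Tx, rng) -> Optional[dict]:
    if tx.L < 3:
        return None
    wild_starts = _atg_starts(tx.utr)
    q = tx.cds_off - 3
    old = _kozak_category(tx.full, tx.cds_off)
    if old == "NA":
        return None
    for alt in _flip_kozak_alts(tx.utr[q - 1]):
        mut = _try_snv(tx, q, alt)
        if _atg_starts(mut) != wild_starts:
            continue
        if _kozak_category(mut + tx.cds, tx.cds_off) != old:
            return {"q": q, "alt": alt, "csq": "mKozak"}
    return None


def _plant_ustart_gain_ins(tx: _Tx, rng) -> Optional[dict]:
    """Insert 'ATG' after a random UTR offset (frame-preserving 3-nt indel)."""
    wild_starts = _atg_starts(tx.utr)
    for t in rng.permutation(np.arange(5, max(6, tx.L - 5))).tolist():
        t = int(t)
        row = tx.insertion_row(t, "ATG")
        if row is None:
            return None
        mut = tx.utr[:t] + "ATG" + tx.utr[t:]
        expected = {x if x <= t else x + 3 for x in wild_starts} | {t + 1}
        if _atg_starts(mut) == expected:
            return {"indel": row, "csq": "uStart_gain"}
    return None


def _plant_ustart_loss_del(tx: _Tx, rng, long: bool) -> Optional[dict]:
    """Delete a uAUG (3 nt) or a whole uORF (frame-preserving, <= 50 nt)."""
    wild_starts = _atg_starts(tx.utr)
    cands = [u for u in tx.uorfs if u["start"] >= 2]
    if long:
        cands = [u for u in cands if u["type"] == "Non-overlapping"
                 and u["length_nt"] <= 48 and u["end"] <= tx.L]
    for u in rng.permutation(np.arange(len(cands))).tolist():
        u = cands[int(u)]
        s = u["start"]
        d1, d2 = (s, u["end"]) if long else (s, s + 2)
        row = tx.deletion_row(d1, d2)
        if row is None:
            continue
        n = d2 - d1 + 1
        mut = tx.utr[: d1 - 1] + tx.utr[d2:]
        expected = {x if x < d1 else x - n for x in wild_starts if not d1 <= x <= d2}
        if s in {x for x in wild_starts if d1 <= x <= d2} and _atg_starts(mut) == expected:
            return {"indel": row, "csq": "uStart_loss"}
    return None


def _plant_ustop_loss_del(tx: _Tx, rng) -> Optional[dict]:
    """Delete the 3-nt stop codon of a non-overlapping uORF."""
    wild_starts = _atg_starts(tx.utr)
    cands = [u for u in tx.uorfs if u["type"] == "Non-overlapping" and u["end"] - 2 >= 2]
    for u in rng.permutation(np.arange(len(cands))).tolist():
        u = cands[int(u)]
        s, end = u["start"], u["end"]
        d1, d2 = end - 2, end
        row = tx.deletion_row(d1, d2)
        if row is None:
            continue
        mut = tx.utr[: d1 - 1] + tx.utr[d2:]
        expected = {x if x < d1 else x - 3 for x in wild_starts if not d1 <= x <= d2}
        if _atg_starts(mut) != expected:
            continue
        new_end = _walk_end(mut + tx.cds, tx.cds_off - 3, s)
        if new_end is None or new_end > end - 3:
            return {"indel": row, "csq": "uStop_loss"}
    return None


def _plant_negative_snv(tx: _Tx, rng) -> Optional[dict]:
    """SNV verified (by brute force) to leave the uORF landscape and every
    Kozak strength category unchanged."""
    wild = brute_force_uorfs(tx.utr, tx.cds)
    wild_sig = [(u["start"], u["end"], u["type"]) for u in wild]
    wild_koz = [_kozak_category(tx.full, u["start"]) for u in wild]
    wild_mk = _kozak_category(tx.full, tx.cds_off)
    for q in rng.permutation(np.arange(1, tx.L + 1)).tolist():
        q = int(q)
        alt = str(rng.choice([b for b in _BASES if b != tx.utr[q - 1]]))
        mut = _try_snv(tx, q, alt)
        m = brute_force_uorfs(mut, tx.cds)
        if [(u["start"], u["end"], u["type"]) for u in m] != wild_sig:
            continue
        if [_kozak_category(mut + tx.cds, u["start"]) for u in m] != wild_koz:
            continue
        if _kozak_category(mut + tx.cds, tx.cds_off) != wild_mk:
            continue
        return {"q": q, "alt": alt, "csq": "none"}
    return None


def _plant_splice_gain(tx_info: dict, tid: str, genome: Fasta) -> Optional[dict]:
    """Donor-loss SNV at a 5' UTR intron whose retention adds a planted
    intronic uAUG (plus strand, multi-exon UTR only)."""
    if tx_info["strand"] != "+" or len(tx_info["utr_intervals"]) < 2:
        return None
    chrom = tx_info["chrom"]
    p1 = tx_info["utr_intervals"][0]
    p2 = tx_info["utr_intervals"][1]
    intron = (p1[1] + 1, p2[0] - 1)
    intron_seq = str(genome[chrom][intron[0] - 1 : intron[1]]).upper()
    if "ATG" not in intron_seq:
        return None
    pos = intron[0]  # first intron base: the canonical donor G of GT
    ref = str(genome[chrom][pos - 1]).upper()
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": "C",
        "kind": "DL", "delta": 0.8, "site_pos": p1[1],
        "csq": "uStart_gain", "tid": tid,
    }


DEFAULT_MIX = {
    "uStart_gain": 5, "uStart_loss": 5, "uStop_gain": 5,
    "uStop_loss": 5, "uKozak": 5, "mKozak": 5, "negative": 10,
}


def generate_variants(ref_paths: dict, mix: Optional[dict] = None, seed: int = 0) -> dict[str, str]:
    """Plant labeled variants with known intended consequences.

    Per consequence class the plant list mixes SNVs with frame-preserving
    indels (ATG insertion, uAUG/stop-codon/whole-uORF deletions up to 48 nt)
    and, for uStart_gain, donor-loss splice events whose intron retention
    introduces a planted intronic uAUG. Negatives are brute-force-verified
    no-consequence SNVs and draw a population allele frequency > 0.05.

    Writes variants.vcf, variant_truth.tsv and splice_predictions.tsv next
    to the reference files; returns their paths.
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    rng = np.random.default_rng(seed)
    out = Path(ref_paths["fasta"]).parent
    genome = Fasta(ref_paths["fasta"])
    with open(ref_paths["truth"]) as fh:
        truth = json.load(fh)

    txs = {tid: _Tx(tid, info, genome) for tid, info in truth.items()}
    tids = sorted(txs)

    rows = []        # (chrom, pos, ref, alt, maf, csq, route, label, tid)
    splice_events = []
    used_sites = set()

    def take(csq: str, n: int, planters):
        planted = 0
        order = [tids[i] for i in rng.permutation(len(tids))]
        for planter in planters:
            for tid in order:
                if planted >= n:
                    return planted
                tx = txs[tid]
                res = planter(tx, rng)
                if res is None:
                    continue
                if "indel" in res:
                    pos, ref, alt = res["indel"]
                else:
                    pos, ref, alt = tx.snv_row(res["q"], res["alt"])
                key = (tx.chrom, pos, ref, alt)
                if key in used_sites:
                    continue
                used_sites.add(key)
                rows.append((tx.chrom, pos, ref, alt, 0.0, csq, "direct", 1, tid))
                planted += 1
        return planted

    for csq, n in mix.items():
        if n <= 0:
            continue
        if csq == "uStart_gain":
            n_splice = min(2, n - 1) if n >= 3 else 0
            n_ins = 1 if n - n_splice >= 2 else 0
            n_snv = n - n_splice - n_ins
            take(csq, n_snv, [_plant_ustart_gain_snv])
            take(csq, n_ins, [lambda tx, r: _plant_ustart_gain_ins(tx, r)])
            planted = 0
            for tid in sorted(t for t in tids if truth[t]["strand"] == "+"):
                if planted >= n_splice:
                    break
                ev = _plant_splice_gain(truth[tid], tid, genome)
                if ev is None:
                    continue
                key = (ev["chrom"], ev["pos"], ev["ref"], ev["alt"])
                if key in used_sites:
                    continue
                used_sites.add(key)
                rows.append((ev["chrom"], ev["pos"], ev["ref"], ev["alt"], 0.0,
                             "uStart_gain", "splice", 1, tid))
                splice_events.append(ev)
                planted += 1
        elif csq == "uStart_loss":
            n_del3 = 1 if n >= 3 else 0
            n_long = 1 if n >= 4 else 0
            take(csq, n - n_del3 - n_long, [_plant_ustart_loss_snv])
            take(csq, n_del3, [lambda tx, r: _plant_ustart_loss_del(tx, r, long=False)])
            take(csq, n_long, [lambda tx, r: _plant_ustart_loss_del(tx, r, long=True)])
        elif csq == "uStop_gain":
            take(csq, n, [_plant_ustop_gain_snv])
        elif csq == "uStop_loss":
            n_del = 1 if n >= 3 else 0
            take(csq, n - n_del, [_plant_ustop_loss_snv])
            take(csq, n_del, [lambda tx, r: _plant_ustop_loss_del(tx, r)])
        elif csq == "uKozak":
            take(csq, n, [_plant_ukozak_snv])
        elif csq == "mKozak":
            take(csq, n, [_plant_mkozak_snv])
        elif csq == "negative":
            planted = 0
            order = [tids[i] for i in rng.permutation(len(tids))]
            for tid in order:
                if planted >= n:
                    break
                res = _plant_negative_snv(txs[tid], rng)
                if res is None:
                    continue
                tx = txs[tid]
                pos, ref, alt = tx.snv_row(res["q"], res["alt"])
                key = (tx.chrom, pos, ref, alt)
                if key in used_sites:
                    continue
                used_sites.add(key)
                maf = float(np.round(rng.uniform(0.051, 0.5), 4))
                rows.append((tx.chrom, pos, ref, alt, maf, "none", "direct", 0, tid))
                planted += 1
        else:
            raise ValueError(f"unknown mix class {csq}")

    paths = {
        "vcf": str(out / "variants.vcf"),
        "labels": str(out / "variant_truth.tsv"),
        "splice": str(out / "splice_predictions.tsv"),
    }
    contig_len = len(genome[list(genome.keys())[0]])
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={rows[0][0] if rows else 'chr1'},length={contig_len}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, maf, *_ in sorted(rows, key=lambda r: (r[0], r[1], r[3])):
            info = f"AF={maf:.4f}" if maf > 0 else "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tintended_csq\troute\tlabel\tmaf\ttranscript_id\n")
        for chrom, pos, ref, alt, maf, csq, route, label, tid in sorted(
            rows, key=lambda r: (r[0], r[1], r[3])
        ):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{csq}\t{route}\t{label}\t{maf:.4f}\t{tid}\n")
    generate_splice_predictions(ref_paths, splice_events, seed, paths["splice"])
    return paths


def generate_splice_predictions(
    ref_paths: dict, events: list[dict], seed: int, out_path: Optional[str] = None
) -> str:
    """Write a SpliceAI-style prediction TSV for the requested events plus
    deterministic below-threshold decoy rows."""
    rng = np.random.default_rng(seed + 1)
    out_path = out_path or str(Path(ref_paths["fasta"]).parent / "splice_predictions.tsv")
    with open(ref_paths["truth"]) as fh:
        truth = json.load(fh)
    multi = [t for t, info in truth.items() if len(info["utr_intervals"]) > 1]
    if events and not multi:
        raise ValueError("no multi-exon 5' UTR available for splice events")
    cols = ["chrom", "pos", "ref", "alt", "DS_AG", "DS_AL", "DS_DG", "DS_DL",
            "POS_AG", "POS_AL", "POS_DG", "POS_DL"]
    with open(out_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            ds = {"AG": 0.0, "AL": 0.0, "DG": 0.0, "DL": 0.0}
            pos_ = {"AG": 0, "AL": 0, "DG": 0, "DL": 0}
            ds[ev["kind"]] = ev["delta"]
            pos_[ev["kind"]] = ev["site_pos"]
            fh.write(
                f"{ev['chrom']}\t{ev['pos']}\t{ev['ref']}\t{ev['alt']}\t"
                f"{ds['AG']:.2f}\t{ds['AL']:.2f}\t{ds['DG']:.2f}\t{ds['DL']:.2f}\t"
                f"{pos_['AG']}\t{pos_['AL']}\t{pos_['DG']}\t{pos_['DL']}\n"
            )
        # below-threshold decoys at arbitrary UTR positions
        for tid in sorted(truth)[:3]:
            info = truth[tid]
            lo, hi = info["utr_intervals"][0]
            p = int(rng.integers(lo, hi + 1))
            d = float(np.round(rng.uniform(0.01, 0.19), 2))
            fh.write(f"{info['chrom']}\t{p}\tA\tG\t{d:.2f}\t0.00\t0.00\t0.00\t{p}\t0\t0\t0\n")
    return out_path


# ---------------------------------------------------------------------------
# planted-signal training data for the prioritization model
# ---------------------------------------------------------------------------

def generate_training_records(
    n_pos: int = 300, n_neg: int = 300, seed: int = 42
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic labeled annotation records with a planted signal.

    Positives emulate disease-causing uORF variants: highly conserved uAUGs
    (phyloP ~ N(4,1), PhastCons ~ Beta(8,2)), constrained genes (high pLI,
    low LOEUF), few uORFs per transcript, translation evidence. Negatives
    emulate common population variants with the opposite tendencies. The
    remaining features are drawn from overlapping distributions so the
    planted signal dominates feature importance.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in ((1, n_pos), (0, n_neg)):
        for _ in range(n):
            utr_len = int(np.clip(rng.lognormal(np.log(136), 0.5), 30, 2000))
            dist_cds = int(rng.integers(1, utr_len + 1))
            if label:
                phylop = rng.normal(4.0, 1.0)
                phastcons = rng.beta(8, 2)
                pli = rng.beta(5, 2)
                loeuf = rng.uniform(0.1, 1.0)
                count = int(rng.poisson(1.0)) + 1
                ribo = "True" if rng.random() < 0.7 else "False"
            else:
                phylop = rng.normal(0.0, 1.0)
                phastcons = rng.beta(2, 8)
                pli = rng.beta(2, 5)
                loeuf = rng.uniform(0.3, 1.6)
                count = int(rng.poisson(3.0)) + 1
                ribo = "True" if rng.random() < 0.3 else "False"
            rows.append({
                "CSQ": str(rng.choice(["uStart_gain", "uStart_loss", "uStop_gain",
                                       "uStop_loss", "uKozak"])),
                "5UTR_LENGTH": utr_len,
                "uSTART_mSTART_DIST": dist_cds,
                "uSTART_CAP_DIST": utr_len - dist_cds,
                "uORF_rank": int(rng.integers(1, count + 1)),
                "uORF_LENGTH": int(rng.integers(9, 301)) // 3 * 3,
                "uORF_AA_LENGTH": 0,
                "uSTART_PHYLOP": phylop,
                "uSTART_PHASTCONS": phastcons,
                "pLI": pli, "LOEUF": loeuf, "uORF_count": count,
                "uORF_TYPE": str(rng.choice(["Non-overlapping", "Overlapping",
                                             "N-terminal extension"])),
                "uSTOP_CODON": str(rng.choice(["TAA", "TGA", "TAG", "NA"])),
                "uKOZAK_STRENGTH": str(rng.choice(["Weak", "Adequate", "Strong"])),
                "Ribo_seq": ribo,
                "mKOZAK_STRENGTH": str(rng.choice(["Weak", "Adequate", "Strong"])),
                "Splicing_CSQ": "NA",
                "label": label,
            })
    df = pd.DataFrame(rows)
    df["uORF_AA_LENGTH"] = df["uORF_LENGTH"] // 3 - 1
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    return df.drop(columns="label"), df["label"].to_numpy()
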