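"""Auxiliary per-base and per-gene resources.

Conservation: phyloP (signed -log p of a neutral-evolution test) and
PhastCons (probability in [0,1] of belonging to a conserved element), read
from plain 3-column TSVs (chrom, pos, score) or bigWig files. Missing
positions yield missing values, never zeros.

Evidence: a catalog of (transcript_id, genomic uAUG position) pairs with
ribosome-profiling support of translation.

Constraint: per-gene pLI and LOEUF intolerance metrics.
"""

from __future__ import annotations

from typing import Optional


class _BaseTrack:
    def __init__(self, scores: dict):
        self._scores = scores

    def get(self, chrom: str, pos: int) -> Optional[float]:
        return self._scores.get((chrom, pos))


class _BigWigTrack:
    def __init__(self, path: str):
        import pyBigWig  # optional dependency

        self._bw = pyBigWig.open(path)

    def get(self, chrom: str, pos: int) -> Optional[float]:
        if chrom not in self._bw.chroms():
            return None
        val = self._bw.values(chrom, pos - 1, pos)[0]
        import math

        return None if val is None or math.isnan(val) else float(val)


def _load_track(path: str):
    if path.endswith((".bw", ".bigWig", ".bigwig")):
        return _BigWigTrack(path)
    scores = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed conservation line {lineno} in {path}")
            scores[(parts[0], int(parts[1]))] = float(parts[2])
    return _BaseTrack(scores)


class ConservationTrack:
    """Paired per-base phyloP and PhastCons tracks."""

    def __init__(self, phylop, phastcons):
        self.phylop = phylop
        self.phastcons = phastcons

    @classmethod
    def from_files(cls, phylop_path: str, phastcons_path: str) -> "ConservationTrack":
        return cls(_load_track(phylop_path), _load_track(phastcons_path))

    @classmethod
    def empty(cls) -> "ConservationTrack":
        return cls(_BaseTrack({}), _BaseTrack({}))


class EvidenceCatalog:
    """Set of (transcript_id, genomic uAUG position) pairs flagged as translated."""

    def __init__(self, pairs: set[tuple[str, int]]):
        self._pairs = set(pairs)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_tsv(cls, path: str) -> "EvidenceCatalog":
        """TSV columns: transcript_id, chrom, genomic_uAUG_pos (1-based), source."""
        pairs = set()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                tid, _chrom, pos = line.rstrip("\n").split("\t")[:3]
                pairs.add((tid, int(pos)))
        return cls(pairs)


class GeneConstraint:
    """Per-gene pLI (probability in [0,1]) and LOEUF (positive real)."""

    def __init__(self, table: dict[str, tuple[Optional[float], Optional[float]]]):
        self._table = table

    def get(self, gene: str) -> tuple[Optional[float], Optional[float]]:
        return self._table.get(gene, (None, None))

    @classmethod
    def from_tsv(cls, path: str) -> "GeneConstraint":
        """TSV columns: gene, pLI, LOEUF (header line expected)."""
        table = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                gene, pli, loeuf = line.rstrip("\n").split("\t")[:3]
                table[gene] = (
                    float(pli) if pli not in ("", "NA") else None,
                    float(loeuf) if loeuf not in ("", "NA") else None,
                )
        return cls(table)

    @classmethod
    def empty(cls) -> "GeneConstraint":
        return cls({})
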