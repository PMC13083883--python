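"""Genomic coordinate system, domain types and interval algebra.

All coordinates are 0-based half-open (BED convention) on named contigs.
GTF input (1-based closed) is converted on ingest by :mod:`b2gate.io`.
Strand ``"."`` behaves like ``"+"`` for sequence retrieval; read tags and
binding clusters always carry an explicit strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a contig.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> float:
        """End-to-start distance in bp; 0 when overlapping, inf across contigs."""
        if self.contig != other.contig:
            return math.inf
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def shifted(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.contig, self.start + delta, self.end + delta, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS/TES and a sorted, non-overlapping exon chain."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.contig != self.interval.contig:
                raise ValueError(f"{self.gene_id}: exon on wrong contig")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first transcribed base)."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (0-based position of the last transcribed base)."""
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


TE_FAMILIES = ("SINE", "LINE", "LTR", "other")


@dataclass(frozen=True)
class TEInstance:
    """One annotated transposable-element copy (e.g. a B2_Mm1a locus)."""

    interval: GenomicInterval
    subfamily: str
    family: str

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")
        if self.family not in TE_FAMILIES:
            raise ValueError(f"family must be one of {TE_FAMILIES}, got {self.family!r}")


@dataclass
class GenomeAnnotation:
    """Genes plus TE instances on a shared set of contigs."""

    contig_lengths: Dict[str, int]
    genes: List[GeneModel] = field(default_factory=list)
    tes: List[TEInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            self._check_within(g.interval, g.gene_id)
        for te in self.tes:
            self._check_within(te.interval, te.subfamily)

    def _check_within(self, iv: GenomicInterval, label: str) -> None:
        if iv.contig not in self.contig_lengths:
            raise ValueError(f"{label}: unknown contig {iv.contig}")
        if iv.end > self.contig_lengths[iv.contig]:
            raise ValueError(
                f"{label}: interval [{iv.start},{iv.end}) exceeds length of {iv.contig}"
            )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def te_instances(self, subfamily_prefix: str | None = None) -> List[TEInstance]:
        if subfamily_prefix is None:
            return list(self.tes)
        return [t for t in self.tes if t.subfamily.startswith(subfamily_prefix)]

    @property
    def subfamilies(self) -> List[str]:
        return sorted({t.subfamily for t in self.tes})


def nearest_distance(query: GenomicInterval, targets: Sequence[GenomicInterval]) -> float:
    """Distance in bp from ``query`` to the closest target interval.

    Returns 0 on overlap, the end-to-start gap otherwise (strand ignored), and
    ``inf`` when no target shares the query's contig.  Raises on an empty
    target list.
    """
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    best = math.inf
    for t in targets:
        d = query.gap_to(t)
        if d < best:
            best = d
            if best == 0:
                break
    return best


def nearest_distances(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Vectorized :func:`nearest_distance` for many queries.

    Uses per-contig sorted target coordinates; half-open interval arithmetic
    makes the overlap count exactly ``#(start < q.end) - #(end <= q.start)``.
    """
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    by_contig: Dict[str, list] = {}
    for t in targets:
        by_contig.setdefault(t.contig, []).append(t)
    sorted_coords = {}
    for contig, ts in by_contig.items():
        starts = np.sort(np.array([t.start for t in ts]))
        ends = np.sort(np.array([t.end for t in ts]))
        sorted_coords[contig] = (starts, ends)

    out = np.full(len(queries), math.inf)
    for i, q in enumerate(queries):
        if q.contig not in sorted_coords:
            continue
        starts, ends = sorted_coords[q.contig]
        n_start_lt = int(np.searchsorted(starts, q.end, side="left"))
        n_end_le = int(np.searchsorted(ends, q.start, side="right"))
        if n_start_lt > n_end_le:  # at least one overlapping target
            out[i] = 0
            continue
        d = math.inf
        if n_end_le > 0:
            d = min(d, q.start - int(ends[n_end_le - 1]))
        if n_start_lt < len(starts):
            d = min(d, int(starts[n_start_lt]) - q.end)
        out[i] = d
    return out


class SequenceStore:
    """In-memory uppercase DNA sequences keyed by contig."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {}
        for contig, seq in sequences.items():
            s = str(seq).upper()
            if set(s) - set("ACGTN"):
                bad = sorted(set(s) - set("ACGTN"))
                raise ValueError(f"{contig}: non-DNA characters {bad}")
            self._seqs[contig] = s

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def fetch(self, interval: GenomicInterval) -> str:
        """Stranded sequence of ``interval``; ``-`` returns the reverse complement."""
        if interval.contig not in self._seqs:
            raise KeyError(f"unknown contig {interval.contig}")
        seq = self._seqs[interval.contig]
        if interval.start < 0 or interval.end > len(seq):
            raise ValueError(
                f"interval [{interval.start},{interval.end}) out of bounds for "
                f"{interval.contig} (length {len(seq)})"
            )
        s = seq[interval.start : interval.end]
        return reverse_complement(s) if interval.strand == "-" else s

    def fetch_clipped(self, interval: GenomicInterval) -> str:
        """Like :meth:`fetch` but silently clips the window at contig edges."""
        L = len(self._seqs[interval.contig])
        start = max(0, interval.start)
        end = min(L, interval.end)
        if start >= end:
            return ""
        return self.fetch(GenomicInterval(interval.contig, start, end, interval.strand))

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self._seqs):
                fh.write(f">{contig}\n")
                seq = self._seqs[contig]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union-merge intervals (bookended intervals are joined); strand is dropped."""
    by_contig: Dict[str, list] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for contig in sorted(by_contig):
        spans = sorted(by_contig[contig])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(contig, cur_s, cur_e))
    return merged
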