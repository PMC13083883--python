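"""Readers and writers for the standard formats the pipeline touches.

GTF is read/written through pyranges (1-based closed on disk, converted to
0-based half-open in memory).  BED6, bedGraph and count tables are plain
tab-separated files handled with pandas.  The repeat BED dialect stores
``subfamily:family`` in the name column.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInstance,
)

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# GTF

def read_gtf_genes(path) -> List[GeneModel]:
    """Parse gene and exon features from a GTF into :class:`GeneModel` objects."""
    import pyranges as pr

    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise ParseError(f"failed to parse GTF {path}: {exc}") from exc
    if df.empty:
        return []
    required = {"Chromosome", "Start", "End", "Strand", "Feature", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"GTF {path} lacks columns {sorted(missing)}")

    genes: List[GeneModel] = []
    gene_rows = df[df.Feature == "gene"]
    exon_rows = df[df.Feature == "exon"]
    exons_by_gene: Dict[str, list] = {}
    for row in exon_rows.itertuples():
        exons_by_gene.setdefault(row.gene_id, []).append(
            GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand))
        )
    for row in gene_rows.itertuples():
        iv = GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand))
        exons = sorted(exons_by_gene.get(row.gene_id, []), key=lambda e: e.start)
        try:
            genes.append(GeneModel(gene_id=str(row.gene_id), interval=iv, exons=exons))
        except ValueError as exc:
            raise ParseError(f"GTF {path}: {exc}") from exc
    genes.sort(key=lambda g: (g.interval.contig, g.interval.start, g.gene_id))
    return genes


def write_gtf(genes: Sequence[GeneModel], path, source: str = "b2gate") -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.contig, g.interval.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            iv = g.interval
            fh.write(
                f"{iv.contig}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.contig}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED6 / repeat BED

def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame with 0-based half-open coordinates."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=BED6_COLUMNS,
            dtype={"contig": str, "name": str, "strand": str},
        )
    except Exception as exc:
        raise ParseError(f"failed to parse BED {path}: {exc}") from exc
    bad = df.index[(df.start < 0) | (df.start >= df.end)]
    if len(bad):
        raise ParseError(f"BED {path}: invalid interval at line {int(bad[0]) + 1}")
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_repeat_bed(path) -> List[TEInstance]:
    """Repeat annotation BED6 with name ``subfamily:family``."""
    df = read_bed6(path)
    tes: List[TEInstance] = []
    for i, row in enumerate(df.itertuples(), start=1):
        parts = str(row.name).split(":")
        if len(parts) != 2:
            raise ParseError(
                f"repeat BED {path} line {i}: name {row.name!r} is not 'subfamily:family'"
            )
        subfamily, family = parts
        try:
            tes.append(
                TEInstance(
                    interval=GenomicInterval(row.contig, int(row.start), int(row.end), row.strand),
                    subfamily=subfamily,
                    family=family,
                )
            )
        except ValueError as exc:
            raise ParseError(f"repeat BED {path} line {i}: {exc}") from exc
    return tes


def write_repeat_bed(tes: Sequence[TEInstance], path) -> None:
    rows = [
        {
            "contig": t.interval.contig,
            "start": t.interval.start,
            "end": t.interval.end,
            "name": f"{t.subfamily}:{t.family}",
            "score": 0,
            "strand": t.interval.strand,
        }
        for t in sorted(tes, key=lambda t: (t.interval.contig, t.interval.start))
    ]
    write_bed6(pd.DataFrame(rows, columns=BED6_COLUMNS), path)


def read_annotation(gtf_path, repeat_bed_path, contig_lengths: Dict[str, int] | None = None) -> GenomeAnnotation:
    """Load genes (GTF) and TE instances (repeat BED) into one annotation.

    When ``contig_lengths`` is not supplied it is inferred as the maximal
    feature end per contig (sufficient for validation of internal data).
    """
    genes = read_gtf_genes(gtf_path)
    tes = read_repeat_bed(repeat_bed_path)
    if contig_lengths is None:
        contig_lengths = {}
        for iv in [g.interval for g in genes] + [t.interval for t in tes]:
            contig_lengths[iv.contig] = max(contig_lengths.get(iv.contig, 0), iv.end)
    return GenomeAnnotation(contig_lengths=dict(contig_lengths), genes=genes, tes=tes)


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, contig_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base float arrays."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["contig", "start", "end", "value"], dtype={"contig": str},
        )
    except Exception as exc:
        raise ParseError(f"failed to parse bedGraph {path}: {exc}") from exc
    data = {c: np.zeros(L, dtype=float) for c, L in contig_lengths.items()}
    unknown = set(df.contig.unique()) - set(data)
    if unknown:
        raise ParseError(f"bedGraph {path}: unknown contig {sorted(unknown)[0]}")
    for contig, sub in df.groupby("contig", sort=False):
        starts = sub.start.to_numpy(np.int64)
        lengths = sub.end.to_numpy(np.int64) - starts
        # vectorized expansion of disjoint runs into the dense array
        offsets = np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
        idx = np.repeat(starts, lengths) + offsets
        data[contig][idx] = np.repeat(sub.value.to_numpy(float), lengths)
    return data


def write_bedgraph(data: Dict[str, np.ndarray], path, precision: int = 6) -> None:
    """Run-length encode dense per-base arrays as bedGraph (zero runs skipped)."""
    frames = []
    for contig in sorted(data):
        arr = np.asarray(data[contig], dtype=float)
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        vals = arr[starts]
        keep = vals != 0
        frames.append(
            pd.DataFrame(
                {"contig": contig, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contig", "start", "end", "value"]
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format=f"%.{precision}g")


# ---------------------------------------------------------------------------
# Count tables

def read_counts(path) -> pd.DataFrame:
    """Feature x sample count table, first column = feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"count table {path} has no sample columns")
    return df


def write_counts(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_sample_table(path) -> pd.DataFrame:
    """Sample metadata TSV indexed by sample id (columns e.g. condition, stage)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
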