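"""Reader binding-site calling from LACE-seq read 5'-end tags.

LACE-seq maps an RNA-binding protein's crosslink positions as read 5' ends.
The caller reproduces the post-alignment logic used for YTHDF ("DF") reader
profiling in early embryos:

1. single-linkage merging of 5'-end positions closer than 100 bp, per
   (contig, strand);
2. clusters kept only with more than 10 unique reads; the summit is the
   position with the highest read-end coverage;
3. tag-density enrichment of the cluster over a 500-bp background window
   centred on the summit;
4. subtraction of a methyltransferase-inhibited (STM2457) negative control
   by a library-normalized ratio;
5. removal of clusters whose sequence context (cluster span plus 30 nt
   upstream) lacks the m6A consensus DRACH (D=G/A/T, R=A/G, H=A/T/C).

Surviving clusters are annotated to genes (exon/intron), TE subfamilies and
intergenic space, and aggregated to a target-gene set at the non-intronic
(exonic) level.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, GenomicInterval, SequenceStore
from .io import BED6_COLUMNS

DRACH_REGEX = re.compile(r"[GAT][AG]AC[ATC]")

#: All pentamers matching the DRACH consensus (3 * 2 * 1 * 1 * 3 = 18).
DRACH_PENTAMERS = tuple(
    d + r + "AC" + h for d in "GAT" for r in "AG" for h in "ATC"
)


@dataclass
class TagSet:
    """Deduplicated read 5'-end positions for one sample.

    ``tags`` holds one row per unique read with columns ``contig`` (str),
    ``pos`` (0-based 5'-end) and ``strand`` (+/-).
    """

    sample_id: str
    condition: str  # "control" or "inhibitor"
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"contig", "pos", "strand"} - set(self.tags.columns)
        if missing:
            raise ValueError(f"tag table lacks columns {sorted(missing)}")

    @property
    def library_size(self) -> int:
        return len(self.tags)

    @classmethod
    def from_bed(cls, path, sample_id: str, condition: str) -> "TagSet":
        from .io import read_bed6

        df = read_bed6(path)
        tags = pd.DataFrame(
            {"contig": df.contig, "pos": df.start.astype(int), "strand": df.strand}
        )
        return cls(sample_id=sample_id, condition=condition, tags=tags)

    def to_bed(self, path) -> None:
        from .io import write_bed6

        df = self.tags.sort_values(["contig", "pos", "strand"], kind="mergesort")
        out = pd.DataFrame(
            {
                "contig": df.contig,
                "start": df.pos,
                "end": df.pos + 1,
                "name": [f"{self.sample_id}_{i}" for i in range(len(df))],
                "score": 1,
                "strand": df.strand,
            },
            columns=BED6_COLUMNS,
        )
        write_bed6(out, path)


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the binding-site caller (defaults as used here)."""

    merge_distance: int = 100  # merge 5' ends with gap strictly below this
    min_unique_reads: int = 10  # keep clusters with strictly more reads
    background_halfwidth: int = 250  # 500-bp window centred on the summit
    upstream_extension: int = 30  # motif search window extension, nt
    control_fold: float = 2.0  # min treatment/control library-normalized ratio
    motif: str = "DRACH"

    def __post_init__(self) -> None:
        if self.merge_distance <= 0 or self.background_halfwidth <= 0:
            raise ValueError("distances must be positive")
        if self.upstream_extension < 0:
            raise ValueError("upstream_extension must be >= 0")


@dataclass
class BindingCluster:
    """A merged 5'-end cluster and its summary statistics."""

    interval: GenomicInterval
    summit: int
    unique_reads: int
    signal_enrichment: float = math.nan
    control_ratio: float = math.nan
    drach_pass: bool | None = None
    background_window: GenomicInterval | None = None

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# Clustering

def cluster_tags(tags: TagSet, params: CallerParams = CallerParams()) -> List[BindingCluster]:
    """Merge 5'-end positions into clusters, per (contig, strand).

    Consecutive sorted positions are joined while the gap is strictly smaller
    than ``merge_distance`` (single linkage).  Clusters with
    ``unique_reads <= min_unique_reads`` are discarded.  Summit ties are
    broken toward the 5' side of the cluster strand.
    """
    clusters: List[BindingCluster] = []
    if tags.tags.empty:
        return clusters
    for (contig, strand), grp in tags.tags.groupby(["contig", "strand"], sort=True):
        positions, counts = np.unique(grp["pos"].to_numpy(int), return_counts=True)
        breaks = np.flatnonzero(np.diff(positions) >= params.merge_distance) + 1
        for seg_pos, seg_cnt in zip(np.split(positions, breaks), np.split(counts, breaks)):
            n = int(seg_cnt.sum())
            if n <= params.min_unique_reads:
                continue
            best = seg_cnt.max()
            tie_idx = np.flatnonzero(seg_cnt == best)
            summit = int(seg_pos[tie_idx[-1]] if strand == "-" else seg_pos[tie_idx[0]])
            clusters.append(
                BindingCluster(
                    interval=GenomicInterval(contig, int(seg_pos[0]), int(seg_pos[-1]) + 1, strand),
                    summit=summit,
                    unique_reads=n,
                )
            )
    clusters.sort(key=lambda c: (c.contig, c.strand, c.interval.start))
    return clusters


def _count_in(tags: pd.DataFrame, interval: GenomicInterval, stranded: bool = True) -> int:
    m = (
        (tags.contig == interval.contig)
        & (tags.pos >= interval.start)
        & (tags.pos < interval.end)
    )
    if stranded:
        m &= tags.strand == interval.strand
    return int(m.sum())


def score_enrichment(
    cluster: BindingCluster,
    all_tags: TagSet,
    params: CallerParams = CallerParams(),
    contig_lengths: Dict[str, int] | None = None,
) -> BindingCluster:
    """Tag-density ratio of the cluster span over its 500-bp background.

    Background is the window ``summit +/- background_halfwidth`` (clipped at
    contig edges) with the cluster span itself excluded, so a sharp cluster
    cannot inflate its own background.  Zero background density yields
    ``inf``.
    """
    hw = params.background_halfwidth
    lo = max(0, cluster.summit - hw)
    hi = cluster.summit + hw
    if contig_lengths is not None:
        hi = min(hi, contig_lengths[cluster.contig])
    if hi <= lo:
        raise ValueError("background window fully clipped away")
    window = GenomicInterval(cluster.contig, lo, hi, cluster.strand)

    span = cluster.interval
    n_cluster = _count_in(all_tags.tags, span)
    n_window = _count_in(all_tags.tags, window)
    ov_lo, ov_hi = max(lo, span.start), min(hi, span.end)
    overlap_len = max(0, ov_hi - ov_lo)
    n_bg = n_window - _count_in(
        all_tags.tags, GenomicInterval(cluster.contig, ov_lo, ov_hi, cluster.strand)
    ) if overlap_len else n_window
    bg_len = window.length - overlap_len

    cluster_density = n_cluster / span.length
    bg_density = (n_bg / bg_len) if bg_len > 0 else 0.0
    enrichment = math.inf if bg_density == 0 else cluster_density / bg_density
    return replace(cluster, signal_enrichment=enrichment, background_window=window)


def subtract_control(
    clusters: Sequence[BindingCluster],
    treatment: TagSet,
    control: TagSet,
    params: CallerParams = CallerParams(),
) -> List[BindingCluster]:
    """Filter clusters by ratio over a negative-control library.

    ``control_ratio = (t / T) / ((c + 1) / C)`` where t, c are tag counts in
    the cluster interval and T, C the library sizes (pseudocount 1 on the
    control count).  Clusters with ratio below ``control_fold`` are removed.
    The exact arithmetic of control mitigation is a documented policy of this
    implementation, not a published formula.
    """
    T, C = treatment.library_size, control.library_size
    if T == 0 or C == 0:
        raise ValueError("zero-size library")
    kept: List[BindingCluster] = []
    for cl in clusters:
        t = _count_in(treatment.tags, cl.interval)
        c = _count_in(control.tags, cl.interval)
        ratio = (t / T) / ((c + 1) / C)
        cl = replace(cl, control_ratio=ratio)
        if ratio >= params.control_fold:
            kept.append(cl)
    return kept


def drach_search_window(cluster: BindingCluster, params: CallerParams) -> GenomicInterval:
    """Cluster span extended ``upstream_extension`` nt on the 5' side."""
    iv = cluster.interval
    ext = params.upstream_extension
    if iv.strand == "-":
        return GenomicInterval(iv.contig, iv.start, iv.end + ext, iv.strand)
    return GenomicInterval(iv.contig, max(0, iv.start - ext), iv.end, iv.strand)


def has_drach(seq: str) -> bool:
    return DRACH_REGEX.search(seq) is not None


def drach_filter(
    clusters: Sequence[BindingCluster],
    store: SequenceStore,
    params: CallerParams = CallerParams(),
) -> List[BindingCluster]:
    """Keep clusters whose stranded search window contains a DRACH pentamer.

    Windows running off the contig are clipped.  Any window containing N
    cannot match (the consensus alphabet is ACGT only), a conservative call.
    """
    kept: List[BindingCluster] = []
    for cl in clusters:
        window = drach_search_window(cl, params)
        seq = store.fetch_clipped(window)
        ok = has_drach(seq)
        cl = replace(cl, drach_pass=ok)
        if ok:
            kept.append(cl)
    return kept


# ---------------------------------------------------------------------------
# Annotation

def annotate_clusters(
    clusters: Sequence[BindingCluster], ann: GenomeAnnotation
) -> pd.DataFrame:
    """Assign each cluster (by summit) to gene/feature-class/TE subfamily.

    Precedence for ``feature_class`` is exon > intron > intergenic; a summit
    inside a TE instance is labelled with the subfamily regardless of genic
    status.  Gene assignment requires matching strand (tags derive from the
    transcript); TE overlap is positional.
    """
    rows = []
    for i, cl in enumerate(clusters):
        gene_id = ""
        feature_class = "intergenic"
        for g in ann.genes:
            iv = g.interval
            if iv.contig != cl.contig or iv.strand != cl.strand:
                continue
            if iv.start <= cl.summit < iv.end:
                gene_id = g.gene_id
                in_exon = any(e.start <= cl.summit < e.end for e in g.exons)
                feature_class = "exon" if in_exon else "intron"
                break
        te_subfamily = ""
        for te in ann.tes:
            iv = te.interval
            if iv.contig == cl.contig and iv.start <= cl.summit < iv.end:
                te_subfamily = te.subfamily
                break
        rows.append(
            {
                "cluster_id": i,
                "contig": cl.contig,
                "start": cl.interval.start,
                "end": cl.interval.end,
                "strand": cl.strand,
                "summit": cl.summit,
                "unique_reads": cl.unique_reads,
                "signal_enrichment": cl.signal_enrichment,
                "control_ratio": cl.control_ratio,
                "gene_id": gene_id,
                "feature_class": feature_class,
                "te_subfamily": te_subfamily,
            }
        )
    cols = [
        "cluster_id", "contig", "start", "end", "strand", "summit",
        "unique_reads", "signal_enrichment", "control_ratio",
        "gene_id", "feature_class", "te_subfamily",
    ]
    return pd.DataFrame(rows, columns=cols)


def target_gene_set(annotated: pd.DataFrame) -> Set[str]:
    """Genes with at least one retained exonic cluster (non-intronic level)."""
    mask = (annotated.feature_class == "exon") & (annotated.gene_id != "")
    return set(annotated.loc[mask, "gene_id"])


def reciprocal_overlap(a: Set[str], b: Set[str]) -> Tuple[float, float]:
    """(|A∩B|/|A|, |A∩B|/|B|); 0 for empty sets."""
    inter = len(a & b)
    return (inter / len(a) if a else 0.0, inter / len(b) if b else 0.0)


def call_binding_sites(
    treatment: TagSet,
    control: TagSet,
    store: SequenceStore,
    params: CallerParams = CallerParams(),
) -> List[BindingCluster]:
    """Full caller: cluster, score, control-subtract, DRACH-filter."""
    contig_lengths = store.contig_lengths
    clusters = cluster_tags(treatment, params)
    clusters = [score_enrichment(c, treatment, params, contig_lengths) for c in clusters]
    clusters = subtract_control(clusters, treatment, control, params)
    clusters = drach_filter(clusters, store, params)
    for cl in clusters:  # post-filter invariant: every window has a motif hit
        assert has_drach(store.fetch_clipped(drach_search_window(cl, params)))
    return clusters


def clusters_to_bed(clusters: Sequence[BindingCluster], path) -> None:
    """Write clusters as BED6+ (extra columns: summit, enrichment, ratio, drach)."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters):
            enr = "inf" if math.isinf(cl.signal_enrichment) else f"{cl.signal_enrichment:.6g}"
            ratio = "nan" if math.isnan(cl.control_ratio) else f"{cl.control_ratio:.6g}"
            fh.write(
                f"{cl.contig}\t{cl.interval.start}\t{cl.interval.end}\t"
                f"cluster_{i}\t{cl.unique_reads}\t{cl.strand}\t"
                f"{cl.summit}\t{enr}\t{ratio}\t{int(bool(cl.drach_pass))}\n"
            )
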