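"""Polymerase CUT&Tag coverage analytics.

Per-base coverage tracks (bedGraph-backed dense arrays at toy scale) feed
TSS/TES metagene profiles, the promoter-proximal pausing index, merged-
region differential binding, B2-distance-stratified Pol II fold changes,
and length-scaled repeat-locus metagenes.

The pausing index is the ratio of Pol II signal density in a promoter
window (default TSS-50..TSS+300, transcript-oriented) to density in the
remaining gene body (+300..TES); windows follow common pausing-index
practice and are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decay import PSEUDOCOUNT, size_factors
from .genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInstance,
    merge_intervals,
    nearest_distances,
)

#: Fig-style distance bin edges (kb) to the nearest B2 locus.
DEFAULT_DISTANCE_BINS_KB = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0)


@dataclass
class CoverageTrack:
    """Dense per-base polymerase signal per contig."""

    data: Dict[str, np.ndarray]
    polymerase: str = "PolII"
    condition: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        for contig, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{contig}: coverage must be finite and non-negative")
            self.data[contig] = arr

    @property
    def library_size(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def cpm(self) -> "CoverageTrack":
        """Counts-per-million scaled copy (library size -> 1e6)."""
        total = self.library_size
        if total == 0:
            raise ValueError("empty track")
        scale = 1e6 / total
        return CoverageTrack(
            {c: arr * scale for c, arr in self.data.items()},
            polymerase=self.polymerase,
            condition=self.condition,
            sample_id=self.sample_id,
        )

    def region_sum(self, iv: GenomicInterval) -> float:
        return float(self.data[iv.contig][iv.start : iv.end].sum())

    def region_mean(self, iv: GenomicInterval) -> float:
        return self.region_sum(iv) / iv.length

    @classmethod
    def from_bedgraph(cls, path, contig_lengths: Dict[str, int], **meta) -> "CoverageTrack":
        from .io import read_bedgraph

        return cls(read_bedgraph(path, contig_lengths), **meta)

    def to_bedgraph(self, path) -> None:
        from .io import write_bedgraph

        write_bedgraph(self.data, path)


def _oriented_window(gene: GeneModel, rel_start: int, rel_end: int) -> GenomicInterval:
    """Genomic interval for transcript coordinates [rel_start, rel_end)."""
    if gene.strand == "-":
        # transcript position t maps to genomic tss - t
        start = gene.tss - rel_end + 1
        end = gene.tss - rel_start + 1
    else:
        start = gene.tss + rel_start
        end = gene.tss + rel_end
    return GenomicInterval(gene.interval.contig, start, end, gene.strand)


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    anchor: str = "TSS",
    flank: int = 2000,
    n_bins: int = 100,
) -> Tuple[pd.DataFrame, int]:
    """Strand-oriented mean CPM profile around TSS or TES anchors.

    Genes whose full window runs off the contig are excluded; the count of
    exclusions is returned.  Upstream is always on the left.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be TSS or TES")
    cpm = track.cpm()
    width = 2 * flank
    bin_edges = np.linspace(0, width, n_bins + 1).astype(int)
    rows = []
    excluded = 0
    for g in genes:
        pos = g.tss if anchor == "TSS" else g.tes
        contig = g.interval.contig
        L = len(cpm.data[contig])
        start, end = pos - flank, pos + flank
        if start < 0 or end > L:
            excluded += 1
            continue
        window = cpm.data[contig][start:end]
        if g.strand == "-":
            window = window[::-1]
        binned = [window[a:b].mean() for a, b in zip(bin_edges[:-1], bin_edges[1:])]
        rows.append(binned)
    if not rows:
        raise ValueError("no usable genes for metagene profile")
    mat = np.asarray(rows)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2 - flank
    profile = pd.DataFrame(
        {
            "position": centers,
            "mean": mat.mean(axis=0),
            "sem": mat.std(axis=0, ddof=1) / math.sqrt(len(mat)) if len(mat) > 1 else 0.0,
            "n_genes": len(mat),
        }
    )
    return profile, excluded


@dataclass
class PausingIndex:
    gene_id: str
    promoter_density: float
    body_density: float

    @property
    def pi(self) -> float:
        return self.promoter_density / self.body_density


def pausing_index(
    track: CoverageTrack,
    gene: GeneModel,
    promoter_window: Tuple[int, int] = (-50, 300),
    body_start: int = 300,
    min_gene_length: int = 600,
) -> PausingIndex | None:
    """Promoter/body signal-density ratio for one gene.

    Returns ``None`` (excluded) for genes shorter than ``min_gene_length``
    or with zero body density.  Densities are mean per-base signal over
    transcript-oriented windows; the ratio is scale-invariant, so raw or
    CPM tracks give identical values.
    """
    if gene.length <= min_gene_length:
        return None
    promoter = _oriented_window(gene, promoter_window[0], promoter_window[1])
    body = _oriented_window(gene, body_start, gene.length)
    if promoter.start < 0 or body.start < 0:
        return None
    L = len(track.data[gene.interval.contig])
    if promoter.end > L or body.end > L:
        return None
    prom_d = track.region_mean(promoter)
    body_d = track.region_mean(body)
    if body_d == 0:
        return None
    return PausingIndex(gene.gene_id, prom_d, body_d)


def pausing_index_table(track: CoverageTrack, genes: Sequence[GeneModel], **kwargs) -> pd.DataFrame:
    rows = []
    for g in genes:
        res = pausing_index(track, g, **kwargs)
        if res is not None:
            rows.append(
                {"gene_id": res.gene_id, "promoter_density": res.promoter_density,
                 "body_density": res.body_density, "pausing_index": res.pi}
            )
    return pd.DataFrame(rows, columns=["gene_id", "promoter_density", "body_density", "pausing_index"]).set_index("gene_id")


def merge_peak_sets(peak_sets: Sequence[Sequence[GenomicInterval]]) -> List[GenomicInterval]:
    """Union-merge peak intervals from all replicates (bookended joined)."""
    all_peaks = [iv for peaks in peak_sets for iv in peaks]
    if not all_peaks:
        raise ValueError("no peaks to merge")
    return merge_intervals(all_peaks)


def region_counts(
    tracks: Dict[str, CoverageTrack], regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-region raw signal sums, region x sample."""
    index = [f"{iv.contig}:{iv.start}-{iv.end}" for iv in regions]
    data = {
        sample: [track.region_sum(iv) for iv in regions]
        for sample, track in tracks.items()
    }
    return pd.DataFrame(data, index=index)


def differential_regions(
    tracks: Dict[str, CoverageTrack],
    peak_sets: Sequence[Sequence[GenomicInterval]],
    conditions: pd.Series,
    kd_condition: str = "kd",
    ctrl_condition: str = "control",
) -> Tuple[pd.DataFrame, List[GenomicInterval]]:
    """Merged-region differential binding (Welch t stand-in, BH-adjusted).

    Peaks from all replicates are union-merged, per-region signal is
    quantified per sample, normalized by median-of-ratios, and tested on
    log2 normalized counts.
    """
    kd = [s for s in tracks if conditions.get(s) == kd_condition]
    ctrl = [s for s in tracks if conditions.get(s) == ctrl_condition]
    if len(kd) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 replicates per condition")
    regions = merge_peak_sets(peak_sets)
    counts = region_counts(tracks, regions)
    factors = size_factors(counts)
    norm = counts / factors
    log_norm = np.log2(norm + PSEUDOCOUNT)
    lfc = np.log2(norm[kd].mean(axis=1) + PSEUDOCOUNT) - np.log2(
        norm[ctrl].mean(axis=1) + PSEUDOCOUNT
    )
    pvals = []
    for region in counts.index:
        a = log_norm.loc[region, kd].to_numpy(float)
        b = log_norm.loc[region, ctrl].to_numpy(float)
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
            pvals.append(1.0)
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        pvals.append(1.0 if np.isnan(p) else float(p))
    out = pd.DataFrame({"log2fc": lfc, "p": pvals}, index=counts.index)
    out["q"] = multipletests(out.p.to_numpy(), method="fdr_bh")[1]
    return out, regions


def assign_distance_bins(
    regions: Sequence[GenomicInterval],
    ann: GenomeAnnotation,
    bin_edges_kb: Sequence[float] = DEFAULT_DISTANCE_BINS_KB,
    subfamily_prefix: str = "B2",
) -> pd.Series:
    """Bin regions by nearest distance to any B2-subfamily instance.

    Bins: overlap (0 kb), then half-open (edge_i, edge_{i+1}] kb, then
    > last-edge kb.  Every region lands in exactly one bin.
    """
    b2 = [t.interval for t in ann.te_instances(subfamily_prefix)]
    if not b2:
        raise ValueError(f"no TE instances with subfamily prefix {subfamily_prefix!r}")
    dist = nearest_distances(list(regions), b2)
    edges_bp = [e * 1000 for e in bin_edges_kb]
    labels = []
    for d in dist:
        if d == 0:
            labels.append("0 kb")
            continue
        placed = False
        for lo, hi in zip(edges_bp[:-1], edges_bp[1:]):
            if lo < d <= hi:
                labels.append(f"({int(lo/1000)},{int(hi/1000)}] kb")
                placed = True
                break
        if not placed:
            labels.append(f">{int(edges_bp[-1]/1000)} kb")
    index = [f"{iv.contig}:{iv.start}-{iv.end}" for iv in regions]
    return pd.Series(labels, index=index, name="distance_bin")


def distance_bin_order(bin_edges_kb: Sequence[float] = DEFAULT_DISTANCE_BINS_KB) -> List[str]:
    edges = list(bin_edges_kb)
    out = ["0 kb"]
    out += [f"({int(lo)},{int(hi)}] kb" for lo, hi in zip(edges[:-1], edges[1:])]
    out.append(f">{int(edges[-1])} kb")
    return out


def b2_distance_stratification(
    region_scores: pd.Series,
    regions: Sequence[GenomicInterval],
    ann: GenomeAnnotation,
    bin_edges_kb: Sequence[float] = DEFAULT_DISTANCE_BINS_KB,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-distance-bin fold-change summaries plus adjacent-bin KS tests.

    ``region_scores`` holds per-region log2 fold changes in the same order
    as ``regions`` (as produced by :func:`differential_regions`).
    """
    if len(region_scores) != len(regions):
        raise ValueError("region_scores and regions must have equal length")
    bins = assign_distance_bins(regions, ann, bin_edges_kb)
    order = distance_bin_order(bin_edges_kb)
    scores = np.asarray(region_scores, dtype=float)
    bin_labels = bins.to_numpy()
    summary_rows = []
    values: Dict[str, np.ndarray] = {}
    for label in order:
        v = scores[bin_labels == label]
        v = v[~np.isnan(v)]
        values[label] = v
        summary_rows.append(
            {
                "distance_bin": label,
                "n": len(v),
                "median_log2fc": float(np.median(v)) if len(v) else math.nan,
                "mean_log2fc": float(v.mean()) if len(v) else math.nan,
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("distance_bin")

    ks_rows = []
    for a, b in zip(order[:-1], order[1:]):
        va, vb = values[a], values[b]
        if len(va) >= 5 and len(vb) >= 5:
            res = stats.ks_2samp(va, vb, method="asymp")
            ks_rows.append({"bin_a": a, "bin_b": b, "ks_d": float(res.statistic), "ks_p": float(res.pvalue)})
    return summary, pd.DataFrame(ks_rows, columns=["bin_a", "bin_b", "ks_d", "ks_p"])


def repeat_locus_metagene(
    track: CoverageTrack,
    instances: Sequence[TEInstance],
    flank: int = 1000,
    body_bins: int = 30,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Length-scaled meta-profile over TE instances with absolute-bp flanks.

    Each instance body is rescaled to ``body_bins`` bins; flanks are binned
    in absolute coordinates.  Minus-strand instances are flipped so upstream
    is left.
    """
    if not instances:
        raise ValueError("no TE instances supplied")
    cpm = track.cpm()
    profiles = []
    for te in instances:
        iv = te.interval
        arr = cpm.data[iv.contig]
        left = arr[max(0, iv.start - flank) : iv.start]
        body = arr[iv.start : iv.end]
        right = arr[iv.end : min(len(arr), iv.end + flank)]
        if len(left) < flank or len(right) < flank:
            continue
        def _bin(x: np.ndarray, nb: int) -> np.ndarray:
            edges = np.linspace(0, len(x), nb + 1).astype(int)
            return np.array([x[a:b].mean() if b > a else 0.0 for a, b in zip(edges[:-1], edges[1:])])
        prof = np.concatenate([_bin(left, flank_bins), _bin(body, body_bins), _bin(right, flank_bins)])
        if iv.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no instances with full flanks on contig")
    mat = np.asarray(profiles)
    n = flank_bins + body_bins + flank_bins
    segment = ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    return pd.DataFrame(
        {"bin": np.arange(n), "segment": segment, "mean": mat.mean(axis=0), "n_instances": len(mat)}
    )
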