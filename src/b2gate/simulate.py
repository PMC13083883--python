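"""Synthetic embryo multi-omics generator with planted ground truth.

Builds a toy genome with genes and TE instances (B2/MERVL/LINE1
subfamilies), plants DRACH-anchored m6A sites on designated transcripts and
B2 copies, and emits every input the analysis modules consume: reader 5'-end
tag sets (methyltransferase-inhibited condition as negative control),
negative-binomial count matrices with a planted stabilization shift under
knockdown + transcription inhibition, stage-wise expression programs drawn
from the 13 shipped class templates, and polymerase coverage with promoter
pausing and a B2-proximal cis effect under knockdown.

Every random draw derives from the config seed, so identical configs give
byte-identical outputs; the :class:`GroundTruth` records all plantings so
downstream recovery metrics (sensitivity, FDR, shift recovery, class
accuracy) never need to re-read the genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cuttag import CoverageTrack
from .genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
    TEInstance,
    nearest_distances,
    reverse_complement,
)
from .lace import DRACH_PENTAMERS, TagSet
from .stages import STAGES, default_templates

#: (subfamily, family, copy length) of the simulated TE complement.
TE_SUBFAMILIES = (
    ("B2_Mm1a", "SINE", 180),
    ("B2_Mm1t", "SINE", 180),
    ("B2_Mm2", "SINE", 180),
    ("MERVL-int", "LTR", 500),
    ("L1Md_A", "LINE", 1000),
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset (defaults = study-like toy scale)."""

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 1_000_000
    n_genes: int = 300
    te_copies: Dict[str, int] = field(
        default_factory=lambda: {
            "B2_Mm1a": 120, "B2_Mm1t": 80, "B2_Mm2": 60, "MERVL-int": 60, "L1Md_A": 80,
        }
    )
    b2_zone_fraction: float = 0.3  # B2 copies concentrated in this leading contig fraction
    b2_island_position: float = 0.55  # secondary B2 island (fraction of contig)
    b2_island_copy_fraction: float = 0.3  # share of B2 copies in the island
    stages: Tuple[str, ...] = STAGES
    # m6A / reader-target structure
    fraction_m6a: float = 0.5
    fraction_df_target_given_m6a: float = 0.5
    sites_per_target: int = 2
    n_b2_m6a: int = 50  # m6A-marked (reader-bound) B2_Mm1a copies
    m6a_peak_halfwidth: int = 50
    # reader tag model
    lambda_signal: float = 30.0  # expected tags per planted bound site
    background_rate: float = 0.005  # genome-wide tags per bp (both strands)
    tag_jitter_sd: float = 10.0
    # count model
    decay_shift_log2: float = 0.5  # stabilization of targets under kd+DRB
    te_kd_log2fc: float = 1.0  # B2/MERVL accumulation under kd
    nb_dispersion: float = 0.1  # per-gene counts
    te_nb_dispersion: float = 0.01  # subfamily aggregates over ~10^2 copies
    n_replicates: int = 3
    library_size_range: Tuple[float, float] = (0.5, 2.0)
    # stage-profile model
    noise_sd: float = 0.3
    stage_amplitude: float = 1.5
    # coverage model
    pol2_pausing_factor: float = 5.0
    gene_coverage_density: float = 10.0  # mean Pol II per-base body signal
    b2_cis_effect_log2: float = -0.5
    b2_cis_range: int = 50_000
    pol3_b2_enrichment: float = 20.0
    coverage_background: float = 0.1
    coverage_noise: bool = True
    n_coverage_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("fraction_m6a", "fraction_df_target_given_m6a", "b2_zone_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lambda_signal < 0 or self.background_rate <= 0:
            raise ValueError("tag rates must be positive (lambda_signal may be 0)")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["library_size_range"] = list(d["library_size_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "library_size_range" in d:
            d["library_size_range"] = tuple(d["library_size_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything that was planted, sufficient for all recovery metrics."""

    sites: pd.DataFrame  # contig, summit, strand, feature_id, kind, bound
    genes: pd.DataFrame  # index gene_id: m6a_modified, df_target, stage_class, base_mean
    m6a_peaks: List[GenomicInterval]
    b2_m6a_copies: List[int]  # indices into annotation.tes


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _spread_intervals(
    rng: np.random.Generator,
    region: Tuple[int, int],
    lengths: Sequence[int],
    margin: int = 400,
) -> List[Tuple[int, int]]:
    """Place non-overlapping spans in ``region`` by random gap allocation.

    Deterministically feasible whenever total length (plus margins) fits;
    raises otherwise.
    """
    lo, hi = region
    lengths = [int(L) for L in lengths]
    need = sum(lengths) + margin * max(0, len(lengths) - 1)
    free = (hi - lo) - need
    if free < 0:
        raise ValueError("infeasible packing: requested features exceed genome capacity")
    if not lengths:
        return []
    offsets = np.sort(rng.uniform(0, free, size=len(lengths)))
    placed = []
    cursor = lo
    for off_prev, off, L in zip(np.concatenate([[0.0], offsets[:-1]]), offsets, lengths):
        cursor += int(off - off_prev)
        placed.append((cursor, cursor + L))
        cursor += L + margin
    return placed


def _place_intervals(
    rng: np.random.Generator,
    occupied: List[Tuple[int, int]],
    region: Tuple[int, int],
    n: int,
    lengths: Sequence[int],
    margin: int = 100,
    max_tries_per: int = 2000,
) -> List[Tuple[int, int]]:
    """Rejection-sample ``n`` non-overlapping spans inside ``region``."""
    placed: List[Tuple[int, int]] = []
    lo, hi = region
    for i in range(n):
        L = int(lengths[i])
        ok = False
        for _ in range(max_tries_per):
            start = int(rng.integers(lo, hi - L))
            end = start + L
            if all(end + margin <= s or e + margin <= start for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end))
                ok = True
                break
        if not ok:
            raise ValueError(
                "infeasible packing: requested features exceed genome capacity"
            )
    return placed


def _gene_exons(
    rng: np.random.Generator, contig: str, start: int, end: int, strand: str
) -> List[GenomicInterval]:
    """Split a gene span into 2-4 exons with intervening introns."""
    L = end - start
    k = int(rng.integers(2, 5))
    min_exon, min_intron = 200, 100
    while k * min_exon + (k - 1) * min_intron > L:
        k -= 1
    n_seg = 2 * k - 1
    mins = np.array([min_exon if i % 2 == 0 else min_intron for i in range(n_seg)])
    spare = L - mins.sum()
    extra = rng.multinomial(spare, np.full(n_seg, 1 / n_seg))
    seg_lengths = mins + extra
    exons = []
    pos = start
    for i, sl in enumerate(seg_lengths):
        if i % 2 == 0:
            exons.append(GenomicInterval(contig, pos, pos + int(sl), strand))
        pos += int(sl)
    return exons


def simulate_genome(
    cfg: SimulationConfig,
) -> Tuple[SequenceStore, GenomeAnnotation, GroundTruth]:
    """Random genome with genes, TE copies and planted DRACH-anchored sites."""
    rng = _rng(cfg, 1)
    contigs = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    seqs = {
        c: rng.choice(list("ACGT"), size=cfg.contig_length) for c in contigs
    }

    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    fam_of = {s: f for s, f, _ in TE_SUBFAMILIES}
    len_of = {s: L for s, _, L in TE_SUBFAMILIES}

    # Genes first, via guaranteed gap allocation across the contig.
    genes: List[GeneModel] = []
    per_contig = np.diff(np.linspace(0, cfg.n_genes, cfg.n_contigs + 1).astype(int))
    gi = 0
    for contig, n in zip(contigs, per_contig):
        lengths = rng.integers(2400, 6000, size=int(n))
        spans = _spread_intervals(rng, (2500, cfg.contig_length - 2500), lengths)
        occupied[contig].extend(spans)
        for s, e in spans:
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _gene_exons(rng, contig, s, e, strand)
            genes.append(
                GeneModel(f"gene{gi:04d}", GenomicInterval(contig, s, e, strand), exons)
            )
            gi += 1
    genes.sort(key=lambda g: (g.interval.contig, g.interval.start))

    # TE copies.  B2 copies concentrate in a leading zone plus a mid-contig
    # island and may fall inside genes (intronic B2), so that distances of
    # gene loci to the nearest B2 span 0 to hundreds of kb; other TE
    # families are intergenic.
    tes: List[TEInstance] = []
    te_occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    L = cfg.contig_length
    b2_zone = (0, int(L * cfg.b2_zone_fraction))
    island_w = max(20_000, len_of["B2_Mm1a"] * 4)
    b2_island = (int(L * cfg.b2_island_position), int(L * cfg.b2_island_position) + island_w)
    for subfamily, n_total in sorted(cfg.te_copies.items()):
        if subfamily not in fam_of:
            raise ValueError(f"unknown TE subfamily {subfamily}")
        per = np.diff(np.linspace(0, n_total, cfg.n_contigs + 1).astype(int))
        for contig, n in zip(contigs, per):
            n = int(n)
            if subfamily.startswith("B2"):
                n_island = round(n * cfg.b2_island_copy_fraction)
                batches = [(b2_zone, n - n_island), (b2_island, n_island)]
                obstacle = te_occupied[contig]  # genes allowed, other TEs not
            else:
                batches = [((0, L), n)]
                obstacle = occupied[contig]
            for region, n_batch in batches:
                spans = _place_intervals(
                    rng, obstacle, region, n_batch, [len_of[subfamily]] * n_batch
                )
                if obstacle is te_occupied[contig]:
                    occupied[contig].extend(spans)  # later non-B2 TEs avoid B2 too
                else:
                    te_occupied[contig].extend(spans)
                for s, e in spans:
                    strand = "+" if rng.random() < 0.5 else "-"
                    tes.append(
                        TEInstance(GenomicInterval(contig, s, e, strand), subfamily, fam_of[subfamily])
                    )
    tes.sort(key=lambda t: (t.interval.contig, t.interval.start))

    # gene labels
    template_names = list(default_templates().index)
    n_m6a = round(cfg.n_genes * cfg.fraction_m6a)
    n_target = round(n_m6a * cfg.fraction_df_target_given_m6a)
    gene_ids = [g.gene_id for g in genes]
    m6a_ids = sorted(rng.choice(gene_ids, size=n_m6a, replace=False)) if n_m6a else []
    target_ids = sorted(rng.choice(m6a_ids, size=n_target, replace=False)) if n_target else []
    m6a_set, target_set = set(m6a_ids), set(target_ids)
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "m6a_modified": [g in m6a_set for g in gene_ids],
            "df_target": [g in target_set for g in gene_ids],
            "stage_class": rng.choice(template_names, size=len(gene_ids)),
            "base_mean": np.exp(rng.normal(np.log(100), 0.7, size=len(gene_ids))),
        }
    ).set_index("gene_id")

    # plant DRACH sites in m6A genes (bound only when the gene is a target)
    site_rows = []
    gene_by_id = {g.gene_id: g for g in genes}
    for gid in m6a_ids:
        g = gene_by_id[gid]
        exon_lens = np.array([e.length for e in g.exons], dtype=float)
        for _ in range(cfg.sites_per_target):
            ex = g.exons[int(rng.choice(len(g.exons), p=exon_lens / exon_lens.sum()))]
            summit = int(rng.integers(ex.start + 40, ex.end - 45))
            _plant_drach(rng, seqs[g.interval.contig], summit, g.strand)
            site_rows.append(
                {"contig": g.interval.contig, "summit": summit, "strand": g.strand,
                 "feature_id": gid, "kind": "gene", "bound": gid in target_set}
            )

    # m6A-marked B2 copies (reader-bound retrotransposon RNAs)
    b2_idx = [i for i, t in enumerate(tes) if t.subfamily == "B2_Mm1a"]
    n_b2 = min(cfg.n_b2_m6a, len(b2_idx))
    b2_m6a = sorted(rng.choice(b2_idx, size=n_b2, replace=False)) if n_b2 else []
    for i in b2_m6a:
        te = tes[i]
        mid = (te.interval.start + te.interval.end) // 2
        _plant_drach(rng, seqs[te.interval.contig], mid, te.interval.strand)
        site_rows.append(
            {"contig": te.interval.contig, "summit": mid, "strand": te.interval.strand,
             "feature_id": f"{te.subfamily}@{te.interval.contig}:{te.interval.start}",
             "kind": "te", "bound": True}
        )

    sites = pd.DataFrame(
        site_rows, columns=["contig", "summit", "strand", "feature_id", "kind", "bound"]
    )
    peaks = [
        GenomicInterval(
            r.contig,
            max(0, r.summit - cfg.m6a_peak_halfwidth),
            min(cfg.contig_length, r.summit + cfg.m6a_peak_halfwidth),
            r.strand,
        )
        for r in sites.itertuples()
    ]

    store = SequenceStore({c: "".join(s) for c, s in seqs.items()})
    ann = GenomeAnnotation(
        contig_lengths={c: cfg.contig_length for c in contigs}, genes=genes, tes=tes
    )
    truth = GroundTruth(sites=sites, genes=gene_table, m6a_peaks=peaks, b2_m6a_copies=list(b2_m6a))
    return store, ann, truth


def _plant_drach(rng: np.random.Generator, seq: np.ndarray, summit: int, strand: str) -> None:
    """Write a random DRACH pentamer at the summit on the given strand."""
    pent = DRACH_PENTAMERS[int(rng.integers(len(DRACH_PENTAMERS)))]
    if strand == "-":
        pent = reverse_complement(pent)
        seq[summit - 4 : summit + 1] = list(pent)
    else:
        seq[summit : summit + 5] = list(pent)


# ---------------------------------------------------------------------------
# Reader tags

def simulate_tags(
    cfg: SimulationConfig, truth: GroundTruth, contig_lengths: Dict[str, int],
    reader: str = "DF",
) -> Dict[str, TagSet]:
    """Reader 5'-end tag sets for control and inhibitor conditions.

    Control tags pile up at planted bound summits (Poisson(lambda_signal)
    per site, Gaussian positional jitter) on top of uniform background;
    the m6A-inhibitor condition carries background only.
    """
    rng = _rng(cfg, 2)
    out = {}
    for condition in ("control", "inhibitor"):
        rows = []
        if condition == "control" and cfg.lambda_signal > 0:
            bound = truth.sites[truth.sites.bound]
            for r in bound.itertuples():
                n = int(rng.poisson(cfg.lambda_signal))
                if n == 0:
                    continue
                jitter = np.rint(rng.normal(0, cfg.tag_jitter_sd, size=n)).astype(int)
                pos = np.clip(r.summit + jitter, 0, contig_lengths[r.contig] - 1)
                rows.append(pd.DataFrame({"contig": r.contig, "pos": pos, "strand": r.strand}))
        for contig in sorted(contig_lengths):
            L = contig_lengths[contig]
            for strand in "+-":
                n = int(rng.poisson(cfg.background_rate / 2 * L))
                if n == 0:
                    continue
                pos = rng.integers(0, L, size=n)
                rows.append(pd.DataFrame({"contig": contig, "pos": pos, "strand": strand}))
        tags = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["contig", "pos", "strand"])
        )
        tags = tags.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        out[condition] = TagSet(sample_id=f"{reader}_{condition}", condition=condition, tags=tags)
    return out


# ---------------------------------------------------------------------------
# Counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(int)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    cfg: SimulationConfig, truth: GroundTruth
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene + TE-subfamily count matrix over the four-arm decay design.

    Conditions: control, kd (reader knockdown), control_drb, kd_drb.  Under
    kd+DRB, reader-target genes and the m6A-marked B2 subfamily gain mean
    factor 2^decay_shift_log2 (planted stabilization); under kd, B2 and
    MERVL subfamilies gain 2^te_kd_log2fc (retrotransposon accumulation).
    """
    rng = _rng(cfg, 3)
    subfams = sorted({s for s, _, _ in TE_SUBFAMILIES})
    te_base = pd.Series(
        np.exp(rng.normal(np.log(500), 0.5, size=len(subfams))), index=subfams
    )
    features = list(truth.genes.index) + subfams
    base = np.concatenate([truth.genes.base_mean.to_numpy(), te_base.to_numpy()])
    is_target = np.concatenate(
        [truth.genes.df_target.to_numpy(), np.zeros(len(subfams), bool)]
    )
    is_te_up = np.array([False] * len(truth.genes) + [s in ("B2_Mm1a", "MERVL-int") for s in subfams])
    is_b2_m6a = np.array([False] * len(truth.genes) + [s == "B2_Mm1a" for s in subfams])

    conditions = ["control", "kd", "control_drb", "kd_drb"]
    counts = {}
    meta = []
    lo, hi = cfg.library_size_range
    for cond in conditions:
        for rep in range(1, cfg.n_replicates + 1):
            lib = rng.uniform(lo, hi)
            mean = base.copy()
            if cond in ("kd", "kd_drb"):
                mean = mean * np.where(is_te_up, 2.0 ** cfg.te_kd_log2fc, 1.0)
            if cond == "kd_drb":
                shift = 2.0 ** cfg.decay_shift_log2
                mean = mean * np.where(is_target | is_b2_m6a, shift, 1.0)
            sample = f"{cond}_rep{rep}"
            n_g = len(truth.genes)
            gene_part = _nb_draw(rng, mean[:n_g] * lib, cfg.nb_dispersion)
            te_part = _nb_draw(rng, mean[n_g:] * lib, cfg.te_nb_dispersion)
            counts[sample] = np.concatenate([gene_part, te_part])
            meta.append({"sample": sample, "condition": cond, "replicate": rep})
    counts_df = pd.DataFrame(counts, index=features)
    samples = pd.DataFrame(meta).set_index("sample")
    return counts_df, samples


def simulate_stage_counts(
    cfg: SimulationConfig, truth: GroundTruth
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-series counts (9 stages x replicates) following class templates.

    Each gene's stage mean is ``base * 2^(amplitude * (template_z + eps))``
    with per-gene profile noise eps ~ N(0, noise_sd) fixed across replicates.
    """
    rng = _rng(cfg, 4)
    templates = default_templates()
    z = templates.loc[truth.genes.stage_class].to_numpy()  # gene x stage
    eps = rng.normal(0, cfg.noise_sd, size=z.shape)
    log_profile = cfg.stage_amplitude * (z + eps)
    mean = truth.genes.base_mean.to_numpy()[:, None] * 2.0 ** log_profile

    counts = {}
    meta = []
    for j, stage in enumerate(cfg.stages):
        for rep in range(1, cfg.n_replicates + 1):
            sample = f"{stage}_rep{rep}"
            counts[sample] = _nb_draw(rng, mean[:, j], cfg.nb_dispersion)
            meta.append({"sample": sample, "stage": stage, "replicate": rep})
    counts_df = pd.DataFrame(counts, index=truth.genes.index)
    samples = pd.DataFrame(meta).set_index("sample")
    return counts_df, samples


def simulate_profiles(
    cfg: SimulationConfig, n_genes_per_class: int = 100
) -> Tuple[pd.DataFrame, pd.Series]:
    """Noisy z-profiles drawn directly from the 13 class templates.

    Returns (profiles, true class labels); the direct route for measuring
    classification accuracy without the count layer.
    """
    rng = _rng(cfg, 5)
    templates = default_templates()
    rows, labels, ids = [], [], []
    for cls in templates.index:
        t = templates.loc[cls].to_numpy()
        noisy = t + rng.normal(0, cfg.noise_sd, size=(n_genes_per_class, len(t)))
        noisy = (noisy - noisy.mean(1, keepdims=True)) / noisy.std(1, keepdims=True)
        for i in range(n_genes_per_class):
            ids.append(f"{cls}_{i:03d}")
            rows.append(noisy[i])
            labels.append(cls)
    profiles = pd.DataFrame(rows, index=ids, columns=templates.columns)
    return profiles, pd.Series(labels, index=ids, name="true_class")


# ---------------------------------------------------------------------------
# Coverage

def _gene_signal_windows(gene: GeneModel) -> Tuple[GenomicInterval, GenomicInterval]:
    """(promoter, body) windows used by the coverage generator; matches the
    pausing-index defaults (-50..+300 / +300..TES, transcript-oriented)."""
    from .cuttag import _oriented_window

    promoter = _oriented_window(gene, -50, 300)
    body = _oriented_window(gene, 300, gene.length)
    return promoter, body


def simulate_coverage(
    cfg: SimulationConfig, truth: GroundTruth, ann: GenomeAnnotation
) -> Tuple[Dict[str, CoverageTrack], Dict[str, List[GenomicInterval]], pd.DataFrame]:
    """Polymerase coverage tracks plus per-sample peak sets.

    Pol II: per-gene body density with the promoter window multiplied by
    the pausing factor; under knockdown, genes within ``b2_cis_range`` of a
    B2 locus are depressed by ``2^b2_cis_effect_log2``.  Pol III: signal
    concentrated on B2 bodies (enrichment over a uniform floor), reduced
    under knockdown.  With ``coverage_noise`` the per-base values are
    Poisson-sampled; otherwise tracks are exact (closed-form checks).
    """
    rng = _rng(cfg, 6)
    contig_lengths = ann.contig_lengths
    b2 = [t.interval for t in ann.te_instances("B2")]
    gene_ivs = [g.interval for g in ann.genes]
    dist = nearest_distances(gene_ivs, b2) if b2 else np.full(len(gene_ivs), np.inf)
    near_b2 = dist <= cfg.b2_cis_range
    gene_density = np.exp(rng.normal(np.log(cfg.gene_coverage_density), 0.4, size=len(ann.genes)))

    def pol2_base(condition: str) -> Dict[str, np.ndarray]:
        data = {c: np.full(L, cfg.coverage_background) for c, L in contig_lengths.items()}
        for g, d, near in zip(ann.genes, gene_density, near_b2):
            scale = 2.0 ** cfg.b2_cis_effect_log2 if (condition == "kd" and near) else 1.0
            promoter, body = _gene_signal_windows(g)
            data[body.contig][body.start : body.end] = d * scale
            data[promoter.contig][promoter.start : promoter.end] = (
                cfg.pol2_pausing_factor * d * scale
            )
        return data

    def pol3_base(condition: str) -> Dict[str, np.ndarray]:
        data = {c: np.full(L, cfg.coverage_background) for c, L in contig_lengths.items()}
        scale = 0.5 if condition == "kd" else 1.0  # reduced Pol III B2 output under kd
        for iv in b2:
            data[iv.contig][iv.start : iv.end] = (
                cfg.coverage_background * cfg.pol3_b2_enrichment * scale
            )
        return data

    tracks: Dict[str, CoverageTrack] = {}
    peaks: Dict[str, List[GenomicInterval]] = {}
    peak_regions = [
        GenomicInterval(
            g.interval.contig,
            max(0, g.interval.start - 50),
            min(ann.contig_lengths[g.interval.contig], g.interval.end + 50),
        )
        for g in ann.genes
    ]
    for condition in ("control", "kd"):
        base2 = pol2_base(condition)
        for rep in range(1, cfg.n_coverage_replicates + 1):
            name = f"PolII_{condition}_rep{rep}"
            data = {
                c: (rng.poisson(arr).astype(float) if cfg.coverage_noise else arr.copy())
                for c, arr in base2.items()
            }
            tracks[name] = CoverageTrack(data, polymerase="PolII", condition=condition, sample_id=name)
            peaks[name] = list(peak_regions)
        base3 = pol3_base(condition)
        name = f"PolIII_{condition}_rep1"
        data = {
            c: (rng.poisson(arr).astype(float) if cfg.coverage_noise else arr.copy())
            for c, arr in base3.items()
        }
        tracks[name] = CoverageTrack(data, polymerase="PolIII", condition=condition, sample_id=name)

    region_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in ann.genes],
            "distance_to_b2": dist,
            "true_log2_effect": np.where(near_b2, cfg.b2_cis_effect_log2, 0.0),
        }
    ).set_index("gene_id")
    return tracks, peaks, region_truth


# ---------------------------------------------------------------------------
# Dataset export

def write_dataset(cfg: SimulationConfig, outdir) -> Dict[str, str]:
    """Simulate everything and write the on-disk dataset; returns paths."""
    import os

    from . import io as bio

    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    store, ann, truth = simulate_genome(cfg)
    store.to_fasta(p("genome.fa"))
    bio.write_gtf(ann.genes, p("genes.gtf"))
    bio.write_repeat_bed(ann.tes, p("repeats.bed"))

    peaks_df = pd.DataFrame(
        {
            "contig": [iv.contig for iv in truth.m6a_peaks],
            "start": [iv.start for iv in truth.m6a_peaks],
            "end": [iv.end for iv in truth.m6a_peaks],
            "name": [f"m6a_peak_{i}" for i in range(len(truth.m6a_peaks))],
            "score": 0,
            "strand": [iv.strand for iv in truth.m6a_peaks],
        }
    )
    bio.write_bed6(peaks_df, p("m6a_peaks.bed"))
    truth.sites.to_csv(p("truth_sites.tsv"), sep="\t", index=False)
    truth.genes.to_csv(p("truth_genes.tsv"), sep="\t", float_format="%.6g")

    tags = simulate_tags(cfg, truth, ann.contig_lengths)
    tags["control"].to_bed(p("tags_DF_control.bed"))
    tags["inhibitor"].to_bed(p("tags_DF_inhibitor.bed"))

    counts, samples = simulate_counts(cfg, truth)
    bio.write_counts(counts, p("counts.tsv"))
    bio.write_sample_table(samples, p("samples.tsv"))

    stage_counts, stage_samples = simulate_stage_counts(cfg, truth)
    bio.write_counts(stage_counts, p("stage_counts.tsv"))
    bio.write_sample_table(stage_samples, p("stage_samples.tsv"))

    tracks, peak_sets, region_truth = simulate_coverage(cfg, truth, ann)
    for name, track in sorted(tracks.items()):
        track.to_bedgraph(p(f"coverage_{name}.bedGraph"))
    region_truth.to_csv(p("truth_regions.tsv"), sep="\t", float_format="%.6g")
    any_polii = next(s for s in sorted(peak_sets))
    peak_df = pd.DataFrame(
        {
            "contig": [iv.contig for iv in peak_sets[any_polii]],
            "start": [iv.start for iv in peak_sets[any_polii]],
            "end": [iv.end for iv in peak_sets[any_polii]],
            "name": [f"peak_{i}" for i in range(len(peak_sets[any_polii]))],
            "score": 0,
            "strand": ".",
        }
    )
    bio.write_bed6(peak_df, p("polii_peaks.bed"))
    return paths
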