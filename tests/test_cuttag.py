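"""Coverage tracks, metagenes, pausing index, differential regions, B2 bins."""

import numpy as np
import pandas as pd
import pytest

from b2gate.cuttag import (
    CoverageTrack,
    assign_distance_bins,
    b2_distance_stratification,
    differential_regions,
    distance_bin_order,
    merge_peak_sets,
    metagene_profile,
    pausing_index,
    pausing_index_table,
    region_counts,
    repeat_locus_metagene,
)
from b2gate.genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInstance,
)


def uniform_track(value=2.0, length=20_000, contig="c"):
    return CoverageTrack({contig: np.full(length, float(value))})


def plus_gene(gene_id="g", start=5000, end=9000, contig="c"):
    return GeneModel(gene_id, GenomicInterval(contig, start, end, "+"))


class TestCoverageTrack:
    def test_negative_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            CoverageTrack({"c": np.array([1.0, -1.0])})
        with pytest.raises(ValueError):
            CoverageTrack({"c": np.array([np.inf])})

    def test_cpm_scales_to_million(self):
        track = uniform_track(2.0, 1000)
        assert track.cpm().library_size == pytest.approx(1e6)

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        track = CoverageTrack({"c": rng.poisson(3.0, size=2000).astype(float)})
        path = tmp_path / "t.bedGraph"
        track.to_bedgraph(path)
        back = CoverageTrack.from_bedgraph(path, {"c": 2000})
        np.testing.assert_array_equal(back.data["c"], track.data["c"])


class TestMetagene:
    def test_uniform_coverage_gives_flat_profile(self):
        track = uniform_track(2.0)
        profile, excluded = metagene_profile(track, [plus_gene()], flank=2000, n_bins=40)
        expected_cpm = 1e6 / 20_000
        np.testing.assert_allclose(profile["mean"], expected_cpm, rtol=1e-9)
        assert excluded == 0

    def test_impulse_at_tss_hits_anchor_bin(self):
        data = np.zeros(20_000)
        data[5000] = 100.0
        track = CoverageTrack({"c": data})
        profile, _ = metagene_profile(track, [plus_gene()], flank=2000, n_bins=100)
        assert profile["mean"].idxmax() == 50  # first bin right of the anchor

    def test_minus_strand_gene_is_flipped(self):
        data = np.zeros(20_000)
        gene = GeneModel("m", GenomicInterval("c", 5000, 9000, "-"))
        data[8000:8999] = 10.0  # downstream of the TSS at 8999 (upstream in genome)
        track = CoverageTrack({"c": data})
        profile, _ = metagene_profile(track, [gene], flank=2000, n_bins=100)
        # signal covers transcript positions 0..+1000 -> right half of profile
        assert profile["mean"][:49].sum() == 0
        assert profile["mean"][50:].sum() > 0

    def test_clipped_genes_excluded_and_counted(self):
        track = uniform_track(1.0, 3000)
        gene_edge = plus_gene("edge", 100, 800)
        with pytest.raises(ValueError):
            metagene_profile(track, [gene_edge], flank=2000)


class TestPausingIndex:
    def test_uniform_coverage_gives_unit_index(self):
        res = pausing_index(uniform_track(), plus_gene())
        assert res.pi == pytest.approx(1.0)

    def test_scale_invariance_under_track_doubling(self):
        track = uniform_track(2.0)
        doubled = CoverageTrack({c: a * 2 for c, a in track.data.items()})
        gene = plus_gene()
        assert pausing_index(track, gene).pi == pytest.approx(
            pausing_index(doubled, gene).pi
        )

    def test_short_gene_and_zero_body_excluded(self):
        short = GeneModel("s", GenomicInterval("c", 5000, 5500, "+"))
        assert pausing_index(uniform_track(), short) is None
        data = np.zeros(20_000)
        data[4950:5300] = 5.0  # promoter only
        assert pausing_index(CoverageTrack({"c": data}), plus_gene()) is None

    def test_noise_free_planted_pausing_factor_is_exact(self):
        data = np.full(20_000, 0.0)
        gene = plus_gene()
        data[5300:9000] = 3.0
        data[4950:5300] = 15.0  # 5x the body density
        res = pausing_index(CoverageTrack({"c": data}), gene)
        assert abs(res.pi - 5.0) < 1e-12

    def test_minus_strand_windows(self):
        data = np.zeros(20_000)
        gene = GeneModel("m", GenomicInterval("c", 5000, 9000, "-"))
        # promoter: transcript -50..+300 from TSS at 8999 -> genomic [8700,9050)
        data[8700:9050] = 10.0
        data[5000:8700] = 2.0
        res = pausing_index(CoverageTrack({"c": data}), gene)
        assert res.pi == pytest.approx(5.0)


class TestDifferentialRegions:
    def _tracks(self, rng, effect_region=None, log2fc=0.0):
        genes = [(1000, 2000), (4000, 5500), (8000, 9000)]
        tracks = {}
        cond = {}
        for c, shift in (("control", 0.0), ("kd", log2fc)):
            for rep in range(3):
                data = np.full(12_000, 0.1)
                for i, (s, e) in enumerate(genes):
                    v = 20.0
                    if effect_region == i:
                        v *= 2.0 ** shift
                    data[s:e] = v
                name = f"{c}_{rep}"
                tracks[name] = CoverageTrack({"c": rng.poisson(data).astype(float)})
                cond[name] = c
        peaks = [GenomicInterval("c", s, e) for s, e in genes]
        return tracks, [peaks] * 6, pd.Series(cond)

    def test_identical_peak_sets_union_is_idempotent(self):
        peaks = [GenomicInterval("c", 0, 100), GenomicInterval("c", 300, 400)]
        merged = merge_peak_sets([peaks, peaks, peaks])
        assert [(m.start, m.end) for m in merged] == [(0, 100), (300, 400)]

    def test_overlapping_peaks_merge(self):
        merged = merge_peak_sets(
            [[GenomicInterval("c", 0, 100)], [GenomicInterval("c", 50, 150)]]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 150)]

    def test_region_counts_match_per_base_sum(self):
        rng = np.random.default_rng(8)
        data = rng.poisson(2.0, 1000).astype(float)
        track = CoverageTrack({"c": data})
        regions = [GenomicInterval("c", 100, 250), GenomicInterval("c", 600, 601)]
        counts = region_counts({"s": track}, regions)
        assert counts.loc["c:100-250", "s"] == data[100:250].sum()
        assert counts.loc["c:600-601", "s"] == data[600]

    def test_planted_depletion_recovered(self):
        rng = np.random.default_rng(12)
        tracks, peak_sets, cond = self._tracks(rng, effect_region=1, log2fc=-1.0)
        table, regions = differential_regions(tracks, peak_sets, cond)
        assert table.loc["c:4000-5500", "log2fc"] == pytest.approx(-1.0, abs=0.2)
        assert table.loc["c:4000-5500", "q"] < 0.05
        others = table.drop(index="c:4000-5500")
        assert others.log2fc.abs().max() < 0.2

    def test_too_few_replicates_rejected(self):
        track = uniform_track()
        with pytest.raises(ValueError):
            differential_regions(
                {"a": track, "b": track},
                [[GenomicInterval("c", 0, 10)]] * 2,
                pd.Series({"a": "control", "b": "kd"}),
            )


class TestDistanceBins:
    @pytest.fixture()
    def b2_ann(self):
        tes = [
            TEInstance(GenomicInterval("c", 10_000, 10_180, "+"), "B2_Mm1a", "SINE"),
            TEInstance(GenomicInterval("c", 200_000, 200_180, "+"), "B2_Mm2", "SINE"),
            TEInstance(GenomicInterval("c", 5_000, 5_500, "+"), "MERVL-int", "LTR"),
        ]
        return GenomeAnnotation(contig_lengths={"c": 500_000}, tes=tes)

    def test_overlap_and_gap_binning(self, b2_ann):
        regions = [
            GenomicInterval("c", 10_100, 10_300),  # overlaps a B2 copy
            GenomicInterval("c", 13_180, 13_280),  # 3,000 bp away
            GenomicInterval("c", 28_000, 28_100),  # 17,820 bp
            GenomicInterval("c", 320_000, 320_100),  # 119,820 bp
        ]
        bins = assign_distance_bins(regions, b2_ann)
        assert list(bins) == ["0 kb", "(0,5] kb", "(10,20] kb", ">100 kb"]

    def test_mervl_does_not_count_as_b2(self, b2_ann):
        regions = [GenomicInterval("c", 5_100, 5_200)]  # inside MERVL
        assert assign_distance_bins(regions, b2_ann).iloc[0] != "0 kb"

    def test_bins_partition_all_regions(self, b2_ann):
        rng = np.random.default_rng(3)
        regions = [
            GenomicInterval("c", int(s), int(s) + 100)
            for s in rng.integers(0, 499_000, size=200)
        ]
        bins = assign_distance_bins(regions, b2_ann)
        assert len(bins) == len(regions)
        assert set(bins).issubset(set(distance_bin_order()))

    def test_no_b2_instances_raises(self):
        ann = GenomeAnnotation(contig_lengths={"c": 1000}, tes=[])
        with pytest.raises(ValueError):
            assign_distance_bins([GenomicInterval("c", 0, 10)], ann)

    def test_stratification_summary_and_ks(self, b2_ann):
        rng = np.random.default_rng(5)
        regions = [
            GenomicInterval("c", int(s), int(s) + 100)
            for s in rng.integers(0, 499_000, size=300)
        ]
        scores = pd.Series(
            rng.normal(0, 0.05, len(regions)),
            index=[f"{r.contig}:{r.start}-{r.end}" for r in regions],
        )
        summary, ks = b2_distance_stratification(scores, regions, b2_ann)
        assert summary.n.sum() == len(regions)
        assert (ks.ks_p > 0.01).all()  # same null distribution in every bin


class TestRepeatMetagene:
    def test_uniform_coverage_flat_profile(self):
        track = uniform_track(3.0, 50_000)
        tes = [
            TEInstance(GenomicInterval("c", 10_000, 10_180, "+"), "B2_Mm1a", "SINE"),
            TEInstance(GenomicInterval("c", 30_000, 30_180, "-"), "B2_Mm1a", "SINE"),
        ]
        prof = repeat_locus_metagene(track, tes)
        np.testing.assert_allclose(prof["mean"], prof["mean"].iloc[0], rtol=1e-9)

    def test_body_only_coverage_has_zero_flanks(self):
        data = np.zeros(50_000)
        data[10_000:10_180] = 4.0
        track = CoverageTrack({"c": data})
        tes = [TEInstance(GenomicInterval("c", 10_000, 10_180, "+"), "B2_Mm1a", "SINE")]
        prof = repeat_locus_metagene(track, tes)
        assert prof.loc[prof.segment != "body", "mean"].sum() == 0
        assert (prof.loc[prof.segment == "body", "mean"] > 0).all()

    def test_pol3_enrichment_matches_generator_on_sparse_copies(self):
        from b2gate.simulate import SimulationConfig, simulate_coverage, simulate_genome

        cfg = SimulationConfig(
            seed=3, n_contigs=1, contig_length=400_000, n_genes=10,
            te_copies={"B2_Mm1a": 8, "MERVL-int": 4, "L1Md_A": 4},
            b2_zone_fraction=0.9, b2_island_copy_fraction=0.0,
            n_b2_m6a=4, coverage_noise=False, n_coverage_replicates=1,
        )
        _, ann, truth = simulate_genome(cfg)
        tracks, _, _ = simulate_coverage(cfg, truth, ann)
        prof = repeat_locus_metagene(
            tracks["PolIII_control_rep1"], ann.te_instances("B2")
        )
        body = prof.loc[prof.segment == "body", "mean"].mean()
        flank = prof.loc[prof.segment != "body", "mean"].mean()
        assert body / flank == pytest.approx(cfg.pol3_b2_enrichment, rel=0.10)
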