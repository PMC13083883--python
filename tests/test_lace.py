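"""Binding-site caller: clustering, enrichment, control and motif filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from b2gate.genome import GenomicInterval, SequenceStore
from b2gate.lace import (
    CallerParams,
    DRACH_PENTAMERS,
    TagSet,
    annotate_clusters,
    call_binding_sites,
    cluster_tags,
    drach_filter,
    drach_search_window,
    has_drach,
    reciprocal_overlap,
    score_enrichment,
    subtract_control,
    target_gene_set,
)


from oracles import brute_force_partition


class TestClusterTags:
    def test_threshold_and_merge_worked_example(self, tagset_factory):
        # 6 tags at 100, 4 at 150 (gap 50 < 100: merged, 10 reads, not >10),
        # 2 at 260 (gap 110: separate) -> everything discarded
        tags = tagset_factory([100] * 6 + [150] * 4 + [260] * 2)
        assert cluster_tags(tags) == []

    def test_single_position_cluster_retained(self, tagset_factory):
        clusters = cluster_tags(tagset_factory([500] * 12))
        assert len(clusters) == 1
        cl = clusters[0]
        assert (cl.interval.start, cl.interval.end) == (500, 501)
        assert cl.summit == 500
        assert cl.unique_reads == 12

    def test_empty_tagset_gives_empty_list(self, tagset_factory):
        assert cluster_tags(tagset_factory([])) == []

    def test_summit_tie_breaks_toward_five_prime(self, tagset_factory):
        plus = cluster_tags(
            tagset_factory([100] * 6 + [130] * 6, strand="+"),
            CallerParams(min_unique_reads=5),
        )
        minus = cluster_tags(
            tagset_factory([100] * 6 + [130] * 6, strand="-"),
            CallerParams(min_unique_reads=5),
        )
        assert plus[0].summit == 100
        assert minus[0].summit == 130

    def test_matches_transitive_closure_oracle(self, tagset_factory):
        rng = np.random.default_rng(42)
        params = CallerParams(min_unique_reads=0)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            positions = rng.integers(0, 10_000, size=n)
            clusters = cluster_tags(tagset_factory(positions), params)
            got = sorted(tuple(sorted(
                p for p in positions if c.interval.start <= p < c.interval.end
            )) for c in clusters)
            assert got == brute_force_partition(positions, params.merge_distance)

    def test_invariant_to_tag_order_and_finer_merge_distance(self, tagset_factory):
        rng = np.random.default_rng(7)
        positions = rng.integers(0, 5000, size=200)
        params = CallerParams(min_unique_reads=0)
        a = cluster_tags(tagset_factory(positions), params)
        b = cluster_tags(tagset_factory(rng.permutation(positions)), params)
        assert [(c.interval.start, c.interval.end, c.summit) for c in a] == [
            (c.interval.start, c.interval.end, c.summit) for c in b
        ]
        finer = cluster_tags(tagset_factory(positions), CallerParams(merge_distance=30, min_unique_reads=0))
        assert len(finer) >= len(a)  # lowering merge distance never merges more

    def test_raising_read_threshold_only_removes(self, tagset_factory):
        rng = np.random.default_rng(8)
        tags = tagset_factory(np.repeat(rng.integers(0, 3000, 40), rng.integers(1, 6, 40)))
        loose = {c.interval for c in cluster_tags(tags, CallerParams(min_unique_reads=2))}
        strict = {c.interval for c in cluster_tags(tags, CallerParams(min_unique_reads=6))}
        assert strict <= loose


class TestEnrichment:
    def test_worked_density_ratio(self, tagset_factory):
        # 12 tags spanning [1000,1010), 5 background tags elsewhere in the
        # 500-bp window -> (12/10) / (5/490) = 117.6
        cluster_pos = [1000, 1000, 1001, 1001] + list(range(1002, 1010))
        bg_pos = [870, 871, 872, 1150, 1151]
        tags = tagset_factory(cluster_pos + bg_pos)
        clusters = cluster_tags(tags)
        (cl,) = [c for c in clusters if c.unique_reads == 12]
        scored = score_enrichment(cl, tags)
        assert scored.signal_enrichment == pytest.approx((12 / 10) / (5 / 490))
        assert scored.background_window.length == 500

    def test_uniform_tags_give_enrichment_near_one(self, tagset_factory):
        from b2gate.lace import BindingCluster

        tags = tagset_factory(list(range(0, 2000)))  # one tag per bp
        cluster = BindingCluster(
            interval=GenomicInterval("chr1", 980, 1020, "+"), summit=1000, unique_reads=40
        )
        scored = score_enrichment(cluster, tags)
        assert scored.signal_enrichment == pytest.approx(1.0, rel=0.05)

    def test_zero_background_is_inf(self, tagset_factory):
        tags = tagset_factory([500] * 12)
        scored = score_enrichment(cluster_tags(tags)[0], tags)
        assert math.isinf(scored.signal_enrichment)


class TestControlSubtraction:
    def test_zero_control_pseudocount_ratio(self, tagset_factory):
        treatment = tagset_factory([500] * 20, sample_id="t")
        control = tagset_factory([9000] * 20, sample_id="c", condition="inhibitor")
        clusters = cluster_tags(treatment)
        kept = subtract_control(clusters, treatment, control)
        assert len(kept) == 1
        assert kept[0].control_ratio == pytest.approx(20.0)

    def test_self_control_removes_everything(self, tagset_factory):
        tags = tagset_factory([500] * 20)
        clusters = cluster_tags(tags)
        assert subtract_control(clusters, tags, tags) == []

    def test_zero_fold_keeps_everything(self, tagset_factory):
        tags = tagset_factory([500] * 20)
        clusters = cluster_tags(tags)
        kept = subtract_control(clusters, tags, tags, CallerParams(control_fold=0.0))
        assert len(kept) == len(clusters)

    def test_empty_library_raises(self, tagset_factory):
        tags = tagset_factory([500] * 20)
        with pytest.raises(ValueError):
            subtract_control(cluster_tags(tags), tags, tagset_factory([]))


class TestDrach:
    def test_exactly_18_pentamers_match(self):
        matches = [
            "".join(p) for p in itertools.product("ACGT", repeat=5) if has_drach("".join(p))
        ]
        assert len(matches) == 18
        assert sorted(matches) == sorted(DRACH_PENTAMERS)

    def test_canonical_instance_and_negatives(self):
        assert has_drach("TTGGACTTT")
        assert not has_drach("CCCCCCCC")
        assert not has_drach("GGNCT")  # N never matches

    def test_search_window_extends_upstream_by_strand(self, tagset_factory):
        # motif sits 20 nt upstream of the cluster on each strand
        seq = ["T"] * 600
        seq[470:475] = list("GGACT")  # upstream of + cluster at [495, 506)
        store_plus = SequenceStore({"chr1": "".join(seq)})
        tags = tagset_factory([495] * 6 + [505] * 6, strand="+")
        clusters = cluster_tags(tags)
        assert drach_filter(clusters, store_plus)[0].drach_pass

        seq = ["T"] * 600
        seq[521:526] = list(  # reverse complement of GGACT, upstream on -
            "AGTCC"
        )
        store_minus = SequenceStore({"chr1": "".join(seq)})
        tags_m = tagset_factory([495] * 6 + [505] * 6, strand="-")
        clusters_m = cluster_tags(tags_m)
        assert drach_filter(clusters_m, store_minus)[0].drach_pass
        # and the + strand caller must NOT see the minus-strand motif
        assert drach_filter(clusters, store_minus) == []

    def test_window_clipped_at_contig_edge(self, tagset_factory):
        # cluster 10 bp from the contig start: the 30-nt upstream extension
        # is clipped at 0 instead of erroring, and the motif inside the
        # clipped window is still found
        store = SequenceStore({"chr1": "TTTGGACTT" + "T" * 100})
        tags = tagset_factory([10] * 12, strand="+")
        clusters = cluster_tags(tags)
        window = drach_search_window(clusters[0], CallerParams())
        assert window.start == 0  # clipped at the contig edge
        assert drach_filter(clusters, store)[0].drach_pass


class TestAnnotation:
    def test_precedence_exon_over_te(self, toy_annotation, tagset_factory):
        tags = tagset_factory([1250] * 12, strand="+")  # in geneA exon1 and B2 copy
        clusters = cluster_tags(tags)
        table = annotate_clusters(clusters, toy_annotation)
        row = table.iloc[0]
        assert (row.gene_id, row.feature_class, row.te_subfamily) == ("geneA", "exon", "B2_Mm1a")

    def test_intron_and_intergenic(self, toy_annotation, tagset_factory):
        intron = annotate_clusters(
            cluster_tags(tagset_factory([1800] * 12, strand="+")), toy_annotation
        ).iloc[0]
        assert (intron.gene_id, intron.feature_class) == ("geneA", "intron")
        inter = annotate_clusters(
            cluster_tags(tagset_factory([4000] * 12, strand="+")), toy_annotation
        ).iloc[0]
        assert (inter.gene_id, inter.feature_class) == ("", "intergenic")

    def test_gene_assignment_requires_matching_strand(self, toy_annotation, tagset_factory):
        table = annotate_clusters(
            cluster_tags(tagset_factory([1250] * 12, strand="-")), toy_annotation
        )
        assert table.iloc[0].gene_id == ""  # geneA is on +

    def test_target_set_is_exonic_only(self, toy_annotation, tagset_factory):
        exonic = cluster_tags(tagset_factory([2500] * 12, strand="+"))
        intronic = cluster_tags(tagset_factory([1800] * 12, strand="+"))
        table = annotate_clusters(exonic + intronic, toy_annotation)
        assert target_gene_set(table) == {"geneA"}

    def test_reciprocal_overlap_extremes(self):
        assert reciprocal_overlap({"a", "b"}, {"a", "b"}) == (1.0, 1.0)
        assert reciprocal_overlap({"a"}, {"b"}) == (0.0, 0.0)


class TestPlantedRecovery:
    def test_clusters_annotate_to_planted_targets(self, sim_bundle, sim_clusters):
        ann, truth = sim_bundle["ann"], sim_bundle["truth"]
        table = annotate_clusters(sim_clusters, ann)
        genic = table[table.gene_id != ""]
        planted = set(truth.genes.index[truth.genes.df_target])
        frac = (genic.gene_id.isin(planted)).mean()
        assert frac >= 0.9

    def test_target_gene_jaccard(self, sim_bundle, sim_clusters):
        truth = sim_bundle["truth"]
        called = target_gene_set(annotate_clusters(sim_clusters, sim_bundle["ann"]))
        planted = set(truth.genes.index[truth.genes.df_target])
        jaccard = len(called & planted) / len(called | planted)
        assert jaccard >= 0.8
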