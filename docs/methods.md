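# Methods

This note documents the models and procedures implemented in `b2gate`, the
assumptions behind them, the defaults that matter, and what the synthetic
data do and do not establish about real data.

## Binding-site calling from read 5′ ends

LACE-seq marks an RNA-binding protein's crosslink positions as the 5′ ends
of sequenced reads. After upstream trimming, alignment and UMI
deduplication (out of scope here; tags arrive as BED6), the caller works
per (contig, strand):

1. **Clustering.** Sorted unique 5′-end positions are merged by single
   linkage while the gap between successive positions is strictly smaller
   than `merge_distance` (default 100 bp). "Shorter than 100 bp" is read
   as a strict inequality; the transitive-closure equivalence of this rule
   is oracle-tested against an O(n²) union-find.
2. **Read threshold.** Clusters are kept only with strictly more than
   `min_unique_reads` (default 10) tags.
3. **Summit.** The position with the highest read-end coverage; ties break
   toward the 5′ side of the cluster strand so output is deterministic.
4. **Enrichment.** Tag density in the cluster span divided by tag density
   in the 500-bp window centred on the summit (`background_halfwidth` 250)
   with the cluster span excluded from the background, so a sharp cluster
   cannot inflate its own background. Zero background density yields an
   `inf` sentinel rather than an error. Enrichment is recorded as a
   statistic; it is not itself a filter by default.
5. **Negative-control subtraction.** With an m⁶A-methyltransferase-
   inhibited (STM2457) library as negative control, the cluster ratio is
   `(t/T) / ((c+1)/C)` — treatment and control tag counts in the cluster
   interval, library-normalized, with pseudocount 1 on the control count —
   and clusters below `control_fold` (default 2.0) are removed. The
   arithmetic of this mitigation is a policy of this implementation (the
   underlying study states the intent, not a formula); it is configurable.
6. **DRACH filter.** The cluster span extended 30 nt upstream on the
   cluster strand must contain at least one DRACH pentamer
   (`[GAT][AG]AC[ATC]`, 18 of the 1024 pentamers). Windows are clipped at
   contig edges; any window containing N cannot match, a conservative
   choice. The post-filter invariant — every retained cluster's window has
   a match — is asserted on every pipeline run.

Clusters are annotated by summit position with precedence
exon > intron > intergenic; gene assignment requires a matching strand
(tags derive from transcripts), while TE-subfamily labels are positional
and attached regardless of genic status. The target-gene set is the set of
genes with at least one exonic cluster ("non-intronic gene level").

## TE quantification

Multi-mapper handling uses fractional weights: a read with k genomic hits
contributes 1/k per hit, split evenly across the distinct subfamilies
overlapping the hit position. This replaces EM redistribution
(TEtranscripts-style) deliberately: it is desk-scale, exactly
oracle-testable (weight conservation: total assigned + unassigned equals
the summed read weights), and has the same qualitative behaviour at
subfamily level, which is the only level this package reports on.
Binding enrichment per subfamily is
`log2(observed fraction / expected fraction)` with the expectation taken
from the genomic subfamily footprint (default) or a matched input tag set;
zeros are guarded with pseudofraction `1/(2·total)`. Note that with
overlapping repeat annotations the even-split rule makes a uniformly
covered nested subfamily legitimately depart from its naive genomic
expectation — enrichment scores are interpretable relative to the same
weighting scheme, as in any multi-mapper-aware counter.

## Normalization and decay statistics

Library size factors are DESeq-style median-of-ratios: over features
positive in all samples, `s_j = median_i(k_ij / gm_i)` with `gm_i` the
geometric mean across samples. The median is taken on the linear ratios
(taking it in log space differs whenever the number of usable features is
even). Two exactness properties hold and are tested: agreement with an
independently coded oracle to 1e-12, and exact c-fold movement of the
*relative* factor when one sample is scaled by c (the geometric-mean
reference moves with the sample, so the absolute factor moves by
c^(1−1/m); normalized counts change only by one global constant).

Fold changes are `log2((mean normalized A + 0.5)/(mean normalized B + 0.5))`;
the 0.5 pseudocount bounds log-fold-changes on zero counts. Genes are
stratified by (i) presence of an m⁶A peak overlapping the exonic span —
intronic peaks do not count, matching the non-intronic treatment of
targets — and (ii) membership in the caller's target set. Strata are
compared with the two-sided two-sample Kolmogorov–Smirnov test (asymptotic
p), requiring n ≥ 5 per stratum.

A property of median-of-ratios worth knowing when many features change in
one direction: the factors absorb part of a one-sided global shift, so
absolute per-stratum fold-change locations are compressed toward zero
while the *difference* between strata is preserved. The decay readout is
therefore reported as the between-strata ECDF shift
(median(target) − median(non-target)), which recovers the planted effect;
DESeq2 itself behaves the same way. Differential testing, where needed
(TE subfamilies, CUT&Tag regions), is Welch's t on log₂ normalized counts
with Benjamini–Hochberg adjustment — a documented simplification standing
in for a negative-binomial GLM, adequate because the headline outputs are
ECDF shifts and KS statistics, not per-feature significance calls.

## Stage-pattern classification

Counts with stage metadata are normalized, averaged per stage over the
nine stages MII…BL, and z-scored per gene (constant genes are excluded
with a log message). Genes are clustered by average linkage on
1 − Pearson correlation; the tree is cut at height 0.2, and modules whose
mean z-profiles ("eigenpatterns") correlate above 0.8 are merged
iteratively, most-correlated pair first — a deterministic, dependency-free
approximation of dynamic tree cutting plus close-module merging. The cut
height sits in the middle of a wide plateau (0.05–0.3 recover the 13
planted modules on template-drawn data; 0.4 merges the two most-correlated
classes).

Each module is assigned to the best-correlated of 13 shipped class
templates — maternal, maternal-early-decay, minor ZGA, major ZGA, 2-cell
transient, MGA, LGA-morula, LGA-blastocyst, biphasic, mid-decay,
late-decay, constitutive, others — falling back to "others" below
correlation 0.5. The template *shapes* are a declared convention of this
package: the class names follow standard MZT usage, but no authoritative
vector definitions exist for all 13, so they are shipped as an explicit
versioned table (`b2gate.stages.default_templates()`), designed so that
all pairwise correlations stay below the 0.8 merge threshold (max 0.74).
A strictly flat "constitutive" profile cannot be z-scored, so that class
is encoded as a low-amplitude alternating drift, and "others" as an
explicit zigzag in addition to serving as the fallback. Users with their
own definitions can supply a custom template table.

Overlap of a gene set with each class is scored by one-sided Fisher's
exact test (equivalently the hypergeometric upper tail, verified by
enumeration on small universes), BH-adjusted across classes.

## Polymerase coverage analytics

Coverage is held as dense per-base arrays per contig (bedGraph-backed; the
toy scale makes this cheap) and normalized to counts-per-million where a
scale-free view is needed. Metagene profiles are strand-oriented (upstream
left), binned means over TSS- or TES-anchored windows (default ±2 kb, 100
bins); genes whose window leaves the contig are excluded and counted.

The pausing index of a gene is mean promoter density over mean body
density with transcript-oriented windows TSS−50..+300 and +300..TES —
common pausing-index practice; the windows are configurable, genes shorter
than 600 bp or with zero body density are excluded with a log. The ratio
is invariant to any global scaling of the track.

Differential binding union-merges the peak regions of all replicates
(bookended intervals joined), sums raw signal per region and sample,
normalizes by median-of-ratios and tests with Welch + BH. Regions are then
assigned to distance bins by nearest-gap distance to any B2-subfamily
instance — 0 (overlap), (0,5], (5,10], (10,20], (20,50], (50,100], >100 kb
— with per-bin medians and adjacent-bin KS tests; the bins partition the
region set by construction. Repeat-locus metagenes rescale each instance
body to a fixed bin count with absolute-bp flanks.

## The synthetic-data generator

The generator plants everything the analyses are supposed to find, under
one seed that fixes every draw end-to-end (two runs of the writer are
byte-identical).

**Genome.** Default two 1-Mb contigs of uniform random sequence; 300
non-overlapping genes (2.4–6 kb, 2–4 exons, both strands) placed by random
gap allocation (guaranteed-feasible; an impossible request raises);
400 TE copies of subfamilies B2_Mm1a/B2_Mm1t/B2_Mm2 (180 bp, SINE),
MERVL-int (500 bp, LTR) and L1Md_A (1 kb, LINE). B2 copies concentrate in
a leading 30 % zone plus a mid-contig island and may fall inside genes
(intronic copies), so gene loci sample the full range of distances to the
nearest B2 — every Fig-style distance bin is populated at toy scale, as in
the real genome where most regions lie within 50 kb of a B2 element.

**m⁶A and binding.** Half the genes are m⁶A-marked; half of those are
reader targets; each marked gene carries two planted DRACH pentamers
inside exons, and 50 B2_Mm1a copies carry one each — 200 bound sites in
total, all recorded in `GroundTruth` with ±50-bp m⁶A peaks.

**Tags.** Control libraries draw Poisson(λ=30) tags per bound site with
discretized Gaussian jitter (sd 10 bp, well within the 100-bp merge
distance) over uniform background at 0.005 tags/bp genome-wide; the
inhibitor condition carries background only.

**Counts.** Negative binomial, dispersion 0.1 per gene; subfamily
aggregate rows use dispersion 0.01, since a subfamily sums ~10² largely
independent copies and per-aggregate overdispersion at 0.1 would leave a
single-subfamily fold change with an SE near 0.4 at n = 3+3, swamping any
planted effect of that size. Conditions are control / kd / control+DRB /
kd+DRB at 3 replicates with library factors uniform in [0.5, 2]; under
kd+DRB, target genes and the m⁶A-marked B2 subfamily gain 2^0.5 (the
planted stabilization), and under kd the B2 and MERVL subfamilies gain
2^1 (retrotransposon accumulation). Dispersion 0 degenerates exactly to
rounded means.

**Stage programs.** Gene stage means follow the gene's class template with
per-gene profile noise (sd 0.3 on the z scale) and amplitude 1.5 in log₂;
a direct profile generator (`simulate_profiles`) emits noisy z-profiles
for classification-accuracy measurements without the count layer.

**Coverage.** Pol II gene-body density is lognormal around 10 per bp with
the promoter window multiplied by the pausing factor (default 5); under
knockdown, genes within 50 kb of a B2 locus are depressed by 2^−0.5.
Depth matters: per-region counting noise sets the bias floor of
median-of-ratios under the one-sided contamination described above, and at
this depth the far-bin medians sit within ±0.03 of zero. With
`coverage_noise` off the tracks are exact, giving closed-form checks
(pausing index exactly 5.0). Pol III signal is a uniform floor multiplied
by 20 on B2 bodies, halved under knockdown.

**What passing does not show.** The generator emulates the *structure* of
the study's data, not its biology: uniform random sequence (no isochores,
no repeat-derived motif background beyond the ~1.8 %/bp chance DRACH
rate), independent genes, no mappability artefacts, no fragment-length or
crosslink-bias modelling, idealized negative controls with identical
background rates, and planted effects that are homogeneous within their
class. Recovery at the stated thresholds demonstrates the correctness and
calibration of the *computations*; it does not validate the upstream
experimental pipeline or guarantee the same sensitivity on real embryo
libraries.

## Problem sizes and numerical choices

The default simulation (the scale all recovery figures refer to) is
2 × 1 Mb, 300 genes, 400 TE copies, ~16 k tags per library, 12-sample
count matrices, 27-sample stage series and eight coverage tracks; the full
pipeline runs in well under a minute on one CPU. Caller-oracle equivalence
is checked on 1000 random tag sets of ≤50 tags; decay calibration on 50
independent null simulations; size-factor exactness on 30 random matrices.
Ties in summit calling break toward the transcript 5′ end; module
renumbering and merge order are fixed by deterministic rules; `inf` and
exclusion sentinels are used (and logged) rather than silent drops
wherever a ratio is undefined.
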