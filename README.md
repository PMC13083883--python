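# b2gate

Analysis toolkit for the regulatory axis in which the cytoplasmic m⁶A
reader proteins YTHDF1/2/3 ("DF1/2/3") degrade m⁶A-marked transcripts —
prominently SINE/B2 retrotransposon RNAs — and B2 abundance in turn gates
RNA polymerase II transcription in preimplantation mouse embryos.

It is written for computational biologists who need the bespoke post-
alignment analyses of this kind of study as tested, reusable components
rather than one-off scripts:

- **Reader binding-site calling** from LACE-seq read 5′ ends: single-linkage
  merging of crosslink positions closer than 100 bp per (contig, strand),
  retention of clusters with more than 10 unique reads, summit at the
  position of maximal read-end coverage, tag-density enrichment over a
  500-bp background window, subtraction of an
  STM2457 (METTL3-inhibited) negative control, and removal of clusters whose
  span + 30 nt upstream lacks the m⁶A consensus **DRACH**
  (D∈{G,A,T}, R∈{A,G}, then A·C, H∈{A,T,C}; exactly 18 pentamers).
- **TE-subfamily quantification**: fractional 1/k multi-mapper counting,
  per-subfamily binding enrichment log₂(observed/expected), and a
  simplified differential test (Welch *t* + Benjamini–Hochberg on log₂
  median-of-ratios-normalized counts).
- **Transcript-stability statistics** under DRB transcription inhibition:
  median-of-ratios size factors
  *ŝⱼ = medianᵢ (kᵢⱼ / (∏ⱼ kᵢⱼ)^(1/m))*, pseudocounted log₂ fold changes,
  stratification of genes by exonic m⁶A peaks and reader binding, and
  two-sample Kolmogorov–Smirnov comparison of the stratum ECDFs.
- **Developmental stage-pattern classification** across the nine stages
  MII → Zygote → E2C → M2C → L2C → 4C → 8C → MO → BL: per-gene z-scored
  stage profiles, average-linkage clustering on 1 − Pearson *r*, and
  assignment of modules to 13 stage-related classes (maternal, minor/major
  ZGA, 2-cell transient, MGA, LGA, …) by template correlation, plus
  Fisher-exact overlap enrichment.
- **Polymerase CUT&Tag analytics**: TSS/TES metagenes, the pausing index
  *PI = promoter density / gene-body density* (windows TSS−50..+300 and
  +300..TES), merged-region differential binding, length-scaled repeat-locus
  metagenes, and Pol II fold changes stratified by genomic distance to the
  nearest B2 locus (bins 0, (0,5], (5,10], (10,20], (20,50], (50,100],
  >100 kb).
- **A fully seeded synthetic-data generator** that emulates the study's
  data structure — planted DRACH-anchored binding sites, m⁶A peak BEDs,
  negative-binomial counts with a planted stabilization shift under
  knockdown + DRB, stage-template expression programs, and Pol II/Pol III
  coverage with promoter pausing and a B2-proximal cis effect — with a
  `GroundTruth` object sufficient to score every recovery metric.

All coordinates are 0-based half-open; GTF input is converted on ingest.
Standard formats are consumed and produced throughout: FASTA, GTF, BED6
(repeat dialect `subfamily:family` in the name field), bedGraph and TSV.

## Worked example

Simulate the default toy study (2 × 1 Mb contigs, 300 genes, 400 TE
copies, 200 planted reader-bound DRACH sites), call binding sites against
the inhibitor control, and test whether reader targets are stabilized when
the readers are depleted under DRB:

```python
from b2gate.simulate import SimulationConfig, simulate_genome, simulate_tags, simulate_counts
from b2gate.lace import call_binding_sites, annotate_clusters, target_gene_set
from b2gate.decay import stability_report

cfg = SimulationConfig(seed=1)
store, ann, truth = simulate_genome(cfg)
tags = simulate_tags(cfg, truth, ann.contig_lengths)

clusters = call_binding_sites(tags["control"], tags["inhibitor"], store)
targets = target_gene_set(annotate_clusters(clusters, ann))
print(f"retained clusters: {len(clusters)}")
print(f"reader target genes (exonic): {len(targets)}")

counts, samples = simulate_counts(cfg, truth)
table, results, ecdfs = stability_report(counts, samples, ann, truth.m6a_peaks, targets)
for r in results:
    print(f"{r.comparison}: D={r.ks_d:.3f} p={r.ks_p:.2e} "
          f"median shift={r.median_shift:+.3f} (n={r.n_a} vs {r.n_b})")
```

Output:

```
retained clusters: 195
reader target genes (exonic): 79
m6a_modified_vs_unmodified: D=0.270 p=2.60e-05 median shift=+0.253 (n=159 vs 141)
target_vs_nontarget: D=0.426 p=4.31e-10 median shift=+0.389 (n=79 vs 221)
```

The 195 retained clusters recover the 200 planted sites (nearby site pairs
merge); 75 of the 79 called target genes are planted targets. The KS shifts
are positive — reader targets are stabilized under knockdown + DRB — and
the m⁶A stratum shows roughly half the target shift because only half the
m⁶A-marked genes are reader-bound in the simulation.

The same pipeline runs end to end from the shell, writing every
intermediate in standard formats plus a provenance manifest:

```bash
b2gate run --seed 1 --out-dir out/
```

Subcommands `simulate`, `lace-call`, `te-quant`, `te-enrich`,
`decay-report`, `stage-classify` and `polii-report` expose each stage
individually on files.

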