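# chromopos

Misexpression clustering and 3D chromosome-territory analysis for
laminopathy studies.

Mutations in *LMNA*, the gene encoding the nuclear-lamina proteins lamin
A/C, cause cardiomyopathy and muscular dystrophy. Because the lamina
anchors peripheral chromatin, a mutant lamina can reposition whole
chromosomal domains and misregulate the genes they carry. `chromopos`
reimplements, as a tested and reusable pipeline, the computational
workflow used to link the cardiomyopathic *LMNA* E161K mutation to
chromosome-13 mispositioning and gene misexpression:

1. **Differential expression from a single mutant/control pair** —
   probesets are ranked by fold change with the rank-products statistic
   (RP of probeset *g* = geometric mean of its ranks across comparisons,
   (∏ᵢ rᵢ,g)^{1/k}) under two independent normalization variants; the
   top-K over- and under-expressed lists of the two variants are
   intersected and collapsed to unique genes.
2. **Genomic clustering** — a 500 kb window slides in 100 kb steps over
   the chip's gene map; a window qualifies when misexpressed genes are
   ≥ 75% of its chip genes and number ≥ 2; overlapping qualifying
   windows merge into clusters. Significance comes from an empirical
   null: cluster counts for random probeset lists of the same size, with
   the upper-tail p-value (b+1)/(N+1).
3. **Per-chromosome enrichment** — percentage of misexpressed genes per
   chromosome, χ² goodness-of-fit against the chip's chromosomal
   composition (χ² = Σ(O−E)²/E, df = #chromosomes − 1), and cross-tissue
   shared-gene analysis.
4. **3D immuno-FISH quantification** — hybrid-median despeckling,
   threshold segmentation, per-slice Euclidean distance maps of the DAPI
   mask evaluated under the territory mask in x-y and (after reslicing)
   x-z to get the territory's minimum distance to the nuclear edge;
   inter-locus distances √(Δx²+Δy²+Δz²) from signal centroids; binary
   lamina-contact scoring; nucleus-normalized territory volumes; Ki-67
   proliferation classification.
5. **Statistics and reporting** — Welch t-tests from raw data or from
   published mean ± SEM/n summaries, t-tests on binary contact scores,
   and tabular report assembly.

Every stage is driven by a synthetic-data module (gene maps, paired
expression tables with planted effects, multi-channel nucleus stacks
with analytically known geometry), so the full pipeline is testable
without any external downloads.

## Worked example

Plant three genomic clusters plus 30 scattered misexpressed genes in a
synthetic 3-chromosome chip, call DE genes through the dual-normalization
rank-products route, scan for clusters and test their significance:

```python
import chromopos as cp

uni = cp.make_gene_map(n_chromosomes=3, chrom_lengths=25_000_000,
                       genes_per_mb=8, seed=11)
truth = cp.plan_expression_truth(uni, n_de_genes=30, n_clusters=3,
                                 noise_sd=0.1, normalization_corr=0.95, seed=12)
tab_a, tab_b, truth = cp.make_expression(uni, truth)
k = len(truth.planted_de_probesets)
de = cp.call_de_probesets(tab_a, tab_b, k=k, universe=uni)
clusters = cp.merge_windows(cp.scan_windows(uni, de))
null = cp.null_cluster_distribution(uni, list_size=k, n_sims=1000, seed=13)
print(f"DE genes called: {de.n_genes} ({de.n_over} over, {de.n_under} under)")
print(f"clusters found: {len(clusters)} (planted: {len(truth.planted_clusters)})")
print(f"null over 1000 random lists of {k}: mean {null.mean:.1f}, "
      f"range {null.min}-{null.max}")
print(f"empirical P: {cp.empirical_p(len(clusters), null).rendered}")
```

prints

```
DE genes called: 52 (25 over, 27 under)
clusters found: 3 (planted: 3)
null over 1000 random lists of 31: mean 0.2, range 0-3
empirical P: 0.001998
```

All three planted clusters are recovered with no spurious hits, and
three clusters essentially never arise from random lists of the same
size, so the planted clustering is significant at P ≈ 0.002.

The published worked examples ship with the package
(`chromopos.datasets`): for instance the two chromosome-13 cluster start
coordinates give

```python
mb, mb_int = cp.locus_separation_mb(cp.datasets.CLUSTER_13A_START_HG17,
                                    cp.datasets.CLUSTER_13B_START_HG17)
res = cp.welch_t_from_summary(cp.datasets.PAIR_DISTANCE_E161K,
                              cp.datasets.PAIR_DISTANCE_NORMAL)
print(f"13A-13B separation: {mb_int} Mb")
print(f"pair-distance Welch t-test: t={res.t:.2f}, df={res.df:.0f}, p={res.p:.4f}")
```

```
13A-13B separation: 21 Mb
pair-distance Welch t-test: t=3.10, df=117, p=0.0024
```

i.e. the two clusters sit 21 Mb apart in the genome, yet their FISH
signals are significantly *further* apart in mutant nuclei (1.778 ± 0.096
µm, n = 56) than in normal nuclei (1.401 ± 0.075 µm, n = 94) — reduced
compaction of the intervening chromatin.

A `chromopos` console script exposes the same pipeline as subcommands
(`simulate-genemap`, `simulate-expression`, `simulate-nucleus`, `de`,
`scan`, `null`, `enrich`, `fish-measure`); run `chromopos --help`.

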