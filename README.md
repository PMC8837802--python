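# rhizometa

Paired rhizosphere-vs-bulk-soil bacteriome analysis as a tested, reusable
pipeline. The package is aimed at microbial ecologists synthesising 16S rRNA
amplicon surveys across many independent studies, where each study contributes
a matched pair of sample groups — soil under the direct influence of living
roots (rhizosphere) versus root-free bulk soil — and the question is which
community properties the rhizosphere consistently changes.

It covers five analysis stages plus a synthetic data generator:

1. **Diversity** — rarefaction to a common depth, observed richness, Shannon
   H (nats), Pielou J = H/ln S, Faith's phylogenetic diversity, Bray–Curtis
   ordination (PCoA) and PERMANOVA with permutations restricted within study.
2. **Differential abundance** — compositional testing on centered log-ratio
   (CLR) transformed Dirichlet(counts + 0.5) Monte-Carlo instances (128 by
   default), Wilcoxon rank-sum per taxon, Benjamini–Hochberg FDR, and a
   scale-free standardized effect size; aggregation to any taxonomic rank.
3. **Co-occurrence networks** — Spearman correlations on taxa above 0.02%
   mean relative abundance, a random-matrix-theory (RMT) correlation
   threshold, greedy Newman modularity, within-module degree z-score (Zi) and
   participation coefficient (Pi) keystone roles, spectral natural
   connectivity, and betweenness-ordered node-removal robustness curves.
4. **Community-weighted traits** — NSTI > 2 prediction-quality filter,
   community-weighted mean rRNA operon copy number (copiotrophy proxy),
   toxin–antitoxin and sporulation dormancy gene abundances, and
   taxonomy-rule function abundances.
5. **Meta-analysis** — the log response ratio per study and variable,

       lnRR = ln(X_t / X_c),   v = S_t²/(n_t X_t²) + S_c²/(n_c X_c²),

   pooled under a random-effects model with DerSimonian–Laird τ², weights
   w = 1/(v + τ²), 999-iteration bootstrap percentile CIs, percent-change
   back-conversion (e^lnRR − 1)·100%, Q_T = Q_W + Q_B subgroup heterogeneity
   partition (subgroups with k < 10 excluded), Egger's regression and
   Duval–Tweedie trim-and-fill publication-bias diagnostics, and all-subsets
   AICc Akaike-weight predictor importance (0.8 cutoff).

The `synth` module generates multi-study paired datasets with fully known
ground truth (per-taxon log-fold effects, between-study variance τ², trait
couplings, tree, taxonomy, function map), so every downstream stage is
testable without any external download.

## Worked example

```python
from rhizometa import synth, pipeline as pl

bundle = synth.generate_study_set(synth.SynthConfig(seed=42))
res = pl.run_pipeline(bundle, pl.PipelineConfig(), seed=42)
for s in res["meta_summaries"]:
    if not s.variable.startswith("fn_"):
        print(f"{s.variable:20s} {s.k:2d}  {s.pct_change:9.2f}"
              f"   ({s.pct_ci_low:7.2f}, {s.pct_ci_high:7.2f})   {s.significant}")
```

prints (12 synthetic studies, 5 paired samples per compartment, 300 taxa):

```
richness             12      -1.59   (  -2.50,   -0.81)   True
shannon              12      -1.98   (  -3.19,   -0.93)   True
pielou               12      -1.70   (  -2.85,   -0.66)   True
faith_pd             12      -0.30   (  -0.55,   -0.07)   True
operon_cwm           12       8.82   (   6.79,   10.58)   True
toxin_antitoxin      12      14.61   (  10.53,   18.92)   True
sporulation          12     -14.09   ( -16.61,  -11.37)   True
```

Each row is the pooled percent change in the rhizosphere relative to bulk
soil with its bootstrap 95% CI: diversity is depleted, the community-weighted
operon copy number and toxin–antitoxin dormancy loading are enriched
(copiotroph selection), and sporulation-based dormancy is depleted — the
directional signature the generator implants. The same run yields PERMANOVA
pseudo-F = 18.4 (p = 0.001) between compartments and per-compartment
networks of ~240–260 nodes with modularity Q ≈ 0.88.

The same stages are available from the shell:

```bash
rhizometa simulate --out fixture/ --seed 7
rhizometa pipeline --fixture fixture/ --out results/ --seed 7
rhizometa diversity --counts fixture/counts.tsv --tree fixture/tree.nwk \
    --metadata fixture/metadata.tsv --out div/
```

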