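# Methods

This note documents the statistical models, the synthetic data generator, the
numerical choices, and the known limitations of `rhizometa`.

## The meta-analytic model

Each study contributes, per variable, the natural-log response ratio of the
rhizosphere (treatment) group mean to the bulk-soil (control) group mean,

    lnRR = ln(X_t / X_c),

with within-study variance from the delta method,

    v = S_t² / (n_t X_t²) + S_c² / (n_c X_c²),

where S are sample standard deviations (n−1 denominator) and n group sizes.
Records with a non-positive group mean are skipped (the log is undefined);
single-sample groups contribute S = 0 and are flagged. Studies are pooled
under a random-effects model: between-study variance τ² is estimated by
DerSimonian–Laird, floored at zero, and studies weighted by w = 1/(v + τ²).
Confidence intervals are nonparametric: 999 bootstrap resamples of studies
with replacement, re-estimating τ² inside every resample, percentile method.
Resampling is at the study level (not of effect sizes within groups), the
natural unit of independence in a multi-study synthesis. The pooled effect is
reported as a percent change, (e^lnRR − 1)·100%, applied to the mean and both
CI bounds; an effect is called significant when the CI excludes zero.

**Subgroup heterogeneity.** For a categorical moderator, total heterogeneity
is partitioned as Q_T = Q_W + Q_B, with subgroup and grand means computed
under a common weight vector so the identity is exact. The weights are
mixed-model weights 1/(v + τ²_w), with τ²_w the DerSimonian–Laird estimate
pooled across within-group Q statistics. Pure fixed-effect weights (1/v)
would make Q_B grossly anticonservative whenever true between-study
heterogeneity exists (empirically ~44% rejection at the 5% level under a
null with τ² = 0.02); with mixed weights the test holds its level (~6%).
Q_B is referred to chi-square with (groups − 1) df. Subgroups with fewer
than 10 studies are excluded before the partition.

**Publication bias.** Egger's test regresses the standardized effect
lnRR/SE on precision 1/SE and t-tests the intercept (k − 2 df).
Trim-and-fill follows Duval & Tweedie: iteratively trim the k₀ most extreme
studies on the overrepresented funnel side, re-estimate the centre by the
fixed-effect mean of the trimmed set, re-estimate k₀ until stable, then
impute k₀ mirror-image studies and re-pool with random effects. Two k₀
estimators are provided: the rank-sum mass estimator L0 (default) and the
rightmost-run estimator R0, which is the appropriate choice when the *most
extreme* studies on one side are suspected suppressed — pure tail censoring
is nearly invisible to L0 (both this implementation and the reference R
implementation estimate k₀ ≈ 0 there) because re-centring at the trimmed
mean cancels the rank-sum asymmetry that L0 measures. The deficient side is
chosen by the sign of Egger's intercept unless forced.

**Predictor importance.** All 2^m subsets of up to six study-level
covariates are fit by variance-weighted least squares (weights 1/(v + τ²)),
ranked by AICc, converted to Akaike weights, and each predictor scored by
the summed weight of models containing it, with 0.8 as the importance
cutoff. AICc rather than AIC because study counts per variable are modest.
Collinear predictor pairs (|r| ≈ 1) are rejected by name.

## Diversity

Counts are rarefied once (seed-controlled) to a fixed depth — 10,000 reads
by default — by exact multivariate-hypergeometric subsampling without
replacement; samples below the depth are dropped and logged, not resampled.
Shannon H is in nats so Pielou J = H/ln S holds exactly; J is undefined at
S ≤ 1. Faith PD sums the branch lengths of the union of root paths of the
observed tips; inclusion of the root chain is the default and switchable
(`include_root=False` gives the crown subtree). PCoA is classical scaling of
the double-centred squared-distance matrix; negative eigenvalues are
reported, never adjusted. PERMANOVA uses Anderson's pseudo-F computed from
the within/between partition of squared distances, with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); when study identifiers are
supplied, labels are permuted only within studies, respecting the paired
multi-study design. Note that permutations recreating the observed partition
tie F exactly, so the attainable p floor for a two-group design is
2/(n_perm + 1).

## Differential abundance

Zeros are handled by sampling per-sample compositions from
Dirichlet(counts + 0.5) — 128 instances by default — and CLR-transforming
each instance (natural log; results are reported in log2 units where the
field convention expects them). Per instance, a two-sided Wilcoxon rank-sum
p-value is computed per taxon (Welch's t by flag); p-values are averaged
arithmetically over instances and then BH-corrected across taxa. The
standardized effect size is, per instance, the difference of one random
cross-group pair of CLR values divided by the larger of the two within-group
random-pair dispersions, summarised by the median over instances. The random
pair indices are drawn from a stream keyed on each group's own sorted sample
ids, which makes the estimator exactly antisymmetric under swapping the
group labels.

## Networks

Taxa below 0.02% mean relative abundance are removed; pairwise Spearman ρ
and p are computed and BH-corrected over all retained pairs. An edge is kept
iff q < 0.05 and |ρ| ≥ ρ*, with ρ* chosen by the random-matrix-theory
transition: for each candidate threshold the surviving correlation matrix's
eigenvalue staircase is unfolded with a cubic smoothing spline and the
nearest-neighbour spacing distribution tested by chi-square (20 bins on
[0, 3], open tail) against the Poisson law e^−s. The smallest candidate
whose spacings are Poisson-consistent is returned. Two guards make the scan
well-defined on small problems: a candidate is accepted outright when the
thresholded graph has fragmented into components of ≤ 20 nodes (the sparse
limit, trivially Poisson), and a chi-square verdict is only trusted when at
least 80 distinct eigenvalues support it — below that the test has no power
and a still-connected graph is not accepted. All constants are arguments.

Modules are found by greedy agglomerative maximisation of Newman's Q on the
unweighted graph (deterministic ordering; |ρ| weights by flag). Node roles
use Zi (z-score of within-module degree among module members; 0 when the
spread is zero) and Pi = 1 − Σ_s (k_is/k_i)², classified at Zi = 2.5 and
Pi = 0.62 with boundary equality resolved to the peripheral side, since the
defining inequalities are strict in both directions. Natural connectivity is
ln((1/N) Σ e^λi) over adjacency eigenvalues (computed via logsumexp).
Robustness curves compute betweenness once on the intact graph, remove nodes
in ascending betweenness order (ties broken by node id; `desc` and `random`
orders available for sensitivity analysis) until 80% are gone, recording
natural connectivity at every step including step 0. Ascending order —
low-betweenness nodes first — is deliberate: it reproduces the published
procedure this implements, even though it is the opposite of a targeted
attack.

## Community-weighted traits

Taxa with NSTI > 2.0 (strict) or missing from the trait table are excluded.
The community-weighted mean operon copy number is Σ p_i c_i on relative
abundances; dormancy gene abundances are Σ p_i g_i. Copy-number correction
(dividing counts by per-taxon operon copies before normalising) defaults ON
for dormancy and function abundances and OFF for the operon CWM itself,
which would otherwise be partially self-referential; both are switchable.
Dormancy abundances are per-read community-weighted means (matching the
community-aggregated-trait reading), not totals. Function abundances follow
a simplified rule dialect — one function per stanza, `Rank:value` inclusion
lines, `-Rank:value` exclusions — with a strict parser; a taxon matches when
any inclusion rule hits its lineage and no exclusion does, and may match
several functions.

## The synthetic generator

The generator is a stylised stand-in for observational multi-study survey
data — the data it emulates are not generated by any published mechanism, so
all distributional choices here are declared, not inferred:

* **Base composition**: log-normal relative abundances (σ = 1.5), giving the
  steep rank-abundance curve of real 16S data and making the 0.02% network
  filter meaningful.
* **Compartment effects**: 20% of taxa differential, |log-fold| uniform on
  [0.8, 2.0], 70% of them rhizosphere-enriched. These defaults place the
  declared truths in the empirically observed regime for this kind of
  comparison — richness depleted by a few percent, CWM operon enriched
  ~+10%, toxin–antitoxin enriched ~+25%, sporulation depleted — with signs
  stable across seeds.
* **Heterogeneity**: a study-level random effect u_j ~ N(0, τ²), τ² = 0.05
  by default, added to each differential taxon's effect magnitude on the
  log-ratio scale, matching the random-effects model under test.
* **Co-occurrence structure**: per-sample latent noise (σ = 0.6) is
  block-correlated (10 blocks, within-block correlation 0.7); the phylum
  tracks the block so co-occurring taxa share coarse taxonomy.
* **Counts**: multinomial at a negative-binomial depth (mean 15,000,
  dispersion 20, floored at 500), so row sums equal drawn depths exactly.
* **Traits**: operon copies = 1 + lognormal(0.3, 0.35) + 1.0·max(Δ, 0) plus
  small noise (copiotroph coupling); toxin–antitoxin ~ Poisson(1 + 1.2·up);
  sporulation ~ Poisson(1 + 2.0·down); NSTI ~ Exp(0.5), putting ~2% of taxa
  above the 2.0 cutoff. The low-variance operon base keeps the
  copiotroph–operon link sign-stable for any seed.
* **Tree**: random coalescent topology with exponential waiting-time branch
  lengths — a valid Faith-PD input, not a model of 16S phylogenies.
* **Declared truths**: per-study true lnRRs are computed analytically from
  the expected compartment compositions (softmax of log base + effects):
  Shannon and the CWM traits exactly; expected richness and PD at the
  nominal depth through per-taxon detection probabilities
  1 − (1 − p)^D (a with-replacement approximation).

What the generator does **not** emulate: sequencing error, chimeras, primer
or copy-number bias in the reads themselves, phylogenetically clustered
effects, non-compositional absolute-abundance shifts, and covariate
structure beyond a study-level ecosystem label and two continuous dummies.
Passing tests therefore demonstrate correctness and calibration of the
estimators under a known, well-behaved generative model — not robustness to
every artifact of real amplicon data.

## Calibration experiments (problem sizes)

The validation suite runs entirely from the generator: bootstrap CI coverage
and τ² recovery use truth lnRR = ln 0.95, τ² = 0.01, k = 40 studies of 5+5
samples over 200 replicates; type-I error of PERMANOVA (12 iid samples, 199
permutations), the Q_B test (40 studies in 3 equivalent subgroups) and
Egger's test (30 null studies) use 500 replicates each; trim-and-fill
recovery censors the 5 most negative of 40 studies over 200 replicates and
uses the R0 estimator, the one designed for extreme-study suppression. The
Egger null uses 10 samples per group: with 5, the sampling noise of the
estimated group SDs alone inflates rejection to ~0.10 — a property of the
test at small n, not of this implementation (it is nominal, 0.057, when
variances are known). The end-to-end direction test runs the full pipeline
on the default 12-study bundle. Everything completes in well under a minute
on one CPU.

## Known limitations

* The RMT threshold on very small taxon sets (< ~100 after filtering) is
  decided mostly by the fragmentation guard; the spacing test needs ≥ 80
  distinct eigenvalues to speak.
* The ALDEx2-style effect size uses one random pair per instance rather than
  the full pair distribution; it is unbiased for direction and scale-free,
  but noisier than the reference estimator at very small n_mc.
* Trim-and-fill assumes symmetric suppression around a common centre; under
  strong heterogeneity k₀ is known to be unstable for any estimator.
* Expected-richness truths use a with-replacement approximation to
  rarefaction; at depths ≫ taxon counts the discrepancy is negligible.
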