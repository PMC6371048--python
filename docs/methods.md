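# Methods

This note documents the statistical models, defaults and design choices
behind `lncsig`, and what the synthetic-data tests do and do not establish.

## Count model and differential expression

Counts are modelled as negative binomial with mean μ and dispersion α,
Var = μ + α·μ². Library depth enters through median-of-ratios size factors
(per sample, the median over all-nonzero genes of the ratio to the
per-gene geometric mean; total-count ratios as a warned fallback), used as
multiplicative offsets: E[count_gs] = sf_s · m_{g,level(s)}.

**Dispersion.** Per-gene method-of-moments on normalized counts,
α̂ = max(0, (pooled within-group variance − mean)/mean²), floored at 1e-8.
With the default design (3 timepoints × 4 replicates, 9 residual df) the
raw estimate is noisy enough that downstream chi-square tests become
anticonservative: in our null simulations the raw-estimate LRT rejected at
~0.10 at α = 0.05 and the BH-selected set carried an empirical FDR near
0.27. We therefore shrink log α̂ towards the across-gene median with prior
weight `prior_df = 10` residual df — the same moderation idea standard
count-model frameworks use. With shrinkage the null rejection drops to
~0.07 and the empirical FDR of padj < 0.05 selection to ≤ 0.15.
`prior_df = 0` restores the raw estimator.

**Tests.** The Wald test compares two groups on
log₂FC = log₂((μ_B + ε)/(μ_A + ε)) with ε = 0.5 (zero-group safety), using
a delta-method standard error from the NB variance of each group mean; the
statistic is referred to the standard normal. The LRT fits one NB mean per
factor level (fixed-point iteration on the score equation, offsets = size
factors) and refers 2·ΔlogL to chi-square with df = extra levels; a
reduced factor identical to the full one yields stat 0, p 1 by convention.
All-zero genes report log₂FC 0, p 1. BH adjustment is step-up with
monotonicity enforcement; NaN p-values propagate.

Asymptotically (α → 0, large counts, known dispersion) the Wald p matches
an exact Poisson likelihood-ratio computation to < 0.01 log₁₀ units in the
moderate-p regime; in deep tails (|z| ≳ 6) normal and chi-square tails
diverge by construction, which is why the oracle test conditions on
p > 0.01.

**Transforms.** `vst` is log₂(normalized count + 1) — a monotone
variance-flattening stand-in, not a parametric VST; every downstream
consumer (z-scores, Spearman, networks) needs only monotone flattening.
FPKM uses transcript length and raw column totals.

**Thresholds** (as configured in `PipelineConfig`): time course
padj < 0.05 (strict, as printed); cohort contrasts log₂FC ≥ 0.58 and
p ≤ 0.05, inclusive at the boundary; expression filter mean FPKM > 2 in at
least one condition.

## Kinetic classes

Per-gene vst means at (t0, 1.5 h, 4 h) are z-scored (population sd;
zero-variance genes flagged and left unclassified). With d1 = z(1.5)−z(0)
and d2 = z(4)−z(0), delta = 0.5 z-units:

* early: |d1| ≥ delta, |d2| ≥ 0.75·|d1|, same sign;
* early_transient: |d1| ≥ delta, |d2| < 0.5·|d1|;
* late: |d1| < delta, |d2| ≥ delta;
* otherwise unclassified.

The 0.75/0.5 persistence ratios make the three verbal definitions mutually
exclusive; profiles decaying to 50–75% of their 1.5 h change fall in the
deliberate gap and stay unclassified. K-means (k = 3, 10 seeded restarts)
runs separately within up- and down-regulated genes: mirror-image
z-profiles of opposite directions would otherwise share clusters and the
centroid rule would see their average. Classes attach to centroids, so k
only refines the partition.

## Enrichment and candidate selection

One-sided hypergeometric over-representation, p = P(X ≥ k), BH FDR across
terms. The universe is all genes passing the expression filter (standard
expression-matched background; the choice matters more than the test).
IFN/antiviral terms are selected from significant terms (FDR ≤ 0.05) by
case-insensitive keyword match ("interferon", "type I IFN", "virus",
"viral", "defense response") — a proxy for a curated list.

Spearman correlation uses average ranks and the two-sided t-approximation
on n−2 df (|rho| = 1 maps to p = 0); the matrix version is rank +
standardized inner product and matches `scipy.stats.spearmanr` pairwise.
All lncRNA × ISG-PCG pairs with p ≤ 0.05 are kept, both signs — the
selection is agnostic about activation versus repression, while cohort
replication later requires up-regulation specifically.

The cis filter pairs gene *bodies* (not TSS): gap =
max(0, max(starts) − min(ends) − 1) on 1-based inclusive coordinates,
0 for overlap, retained when gap ≤ 150,000 inclusive, strand ignored. A
candidate needs at least one PCG that is simultaneously correlated and in
cis; its supporting PCGs and best pair (largest |rho|) are reported.

The IFN score of a sample is the mean over the six signature genes of
(vst − HC mean)/HC sd (sd with ddof = 1); genes missing or degenerate in
controls are dropped with a warning. The exact historical formula behind
the published score is not reproduced here; this reconstruction preserves
its content (control-referenced mean ISG z-score) and is what the tests
exercise.

## Co-expression networks

Signed adjacency a_ij = ((1 + cor)/2)^β on Pearson correlations of vst
(constant genes treated as uncorrelated), diagonal 0 for connectivity.
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
Modules are average-linkage clusters of 1 − TOM with a *static* cut at
0.995 and minimum sizes 20 (time course) / 10 (cohort); smaller clusters
get label 0, the "grey" role. The published dynamic tree-cut algorithm has
unreported parameters, so module *recovery* — not label identity or module
counts — is the tested surface; with near-zero background TOM the static
cut separates planted structure cleanly. β defaults are 18 (time course)
and 13 (cohort), the values used for these two data types; the scale-free
R² diagnostic is reported but not used to choose β automatically.

## Synthetic world

Defaults state the emulated designs: 200 PCGs, 80 lncRNAs, 10 pseudogenes
on 5 chromosomes; 3 timepoints × 4 replicates (sequencing pools treated as
replicates); planted effect 2.0 log₂ units; dispersion 0.1; library sizes
log-uniform in [2e5, 5e5]; cohort groups HC 12 / ncSSc 17 / lcSSc 11 /
dcSSc 7 (case-group sizes of a definite-SSc cohort; its control count is
not printed anywhere, 12 is a realistic match). 30% of lncRNAs are
modulated with kinetic classes drawn (0.50, 0.25, 0.25) ~ the reported
early / early-transient / late shares; half of them are placed in cis
(gap ∈ [1, 100] kb) of an induced ISG partner, and all other neighbours
are > 150 kb apart so the planted pairs are the only cis pairs. The ISG
set is the six signature genes plus a 30-gene planted module; cis-paired
lncRNAs and all ISGs are early (co-induced), giving each pair matched
kinetics. The term map contains one "response to type I interferon"-like
term holding exactly the planted ISGs plus ≥ 12 keyword-free background
terms.

Two latent factors create realistic covariance:

* **time course** — a per-sample stimulation strength s ~ N(0, 0.3) scales
  every planted effect as 2^(lfc·k(t)·(1+s)). Without it, replicate noise
  is conditionally independent and co-regulated pairs barely correlate at
  n = 12 — the opposite of what co-expression analysis assumes. Its cost:
  timepoint means wobble coherently, so in occasional seeds a whole
  K-means centroid drifts into the unclassified gap; kinetic recovery is
  therefore assessed pooled across seeds (≈ 0.88 pooled, ≥ 0.7 required).
* **cohort** — per-sample IFN activity a ~ N(shift, 1), shift 0 in HC and
  2.0 in case groups; signature genes, the planted module and the
  NRIR-like lncRNA are scaled by 2^(1.0·a), producing both the score
  correlation and the module structure.

Not emulated: batch effects, donor pairing, per-gene effect-size
distributions, group-specific effect sizes, clinical covariates, read-level
noise. Green recovery tests therefore establish that the pipeline recovers
the planted structure under the stated model, not robustness to those
artefacts.

All generators draw from `numpy.random.default_rng([seed, stream])` with a
fixed stream id per product, so identical configs are byte-identical
across runs and across stages.

## Numerical choices

* Fixed-point NB mean fitting: 100 iterations max, relative tolerance
  1e-10; all-zero groups converge to 0 and `xlogy` keeps the likelihood
  finite.
* Dispersion floor 1e-8; fold-change pseudocount 0.5; z-scores use
  population sd; BH ties broken by stable sort.
* K-means: sklearn Lloyd, `n_init = 10`, seeded; clusters inherit the
  centroid class.
* TOM denominator positivity is asserted (guaranteed for a ∈ [0,1]).
* Module labels are ordered by decreasing size; label 0 is reserved for
  unassigned genes, and `module_of` distinguishes "unassigned" (None) from
  an empty set.

## Known limitations

* The NB model has no shrinkage of fold-changes and no outlier handling;
  single extreme counts can inflate a gene's dispersion and cost power.
* Keyword term selection is a proxy for curated IFN/antiviral term lists.
* The static-height module cut is tuned for worlds where background TOM is
  near zero; dense correlated backgrounds would need the dynamic
  algorithm.
* Cohort contrasts are unadjusted for covariates (age/sex not modelled).
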