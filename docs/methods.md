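# Methods

This note documents the statistical models implemented in `mapktome`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Two-colour array model and normalisation

A spot measures two channel intensities R and G; the quantities of
interest are M = log₂(R/G) and A = ½·log₂(RG). The simulator draws A
uniformly on a configurable range (default 6–16; two-colour platforms
vary, and no distributional claim is made) and reconstructs
R = 2^(A+M/2), G = 2^(A−M/2), floored at a small positive constant so
log-intensities are always defined. The measured log-ratio is

```
M = o·(μ_gc + e_gcr) + b(A) + ε
```

with `o = −1` on dye-reversed hybridisations (dye swaps store the
negated biological log-ratio in raw orientation), `μ_gc` the true
effect of gene g in contrast c, `e_gcr ~ N(0, σ²_g)` a biological
deviation shared by the dye pair of replicate r, `b(A)` an arbitrary
intensity-dependent dye bias, and `ε` technical noise (default sd 0.05).
Sharing `e` within a dye pair makes the averaged data carry exactly one
independent value per biological replicate — the premise of the
downstream variance estimation.

Normalisation subtracts a loess fit of M on A per hybridisation
(span 0.3, two robustness iterations, via statsmodels' lowess; local
linear regression with tricube weights). When A is constant the loess is
degenerate and the plain mean of M is subtracted. Averaging then
proceeds duplicate-probes-first, dye-pair-second, with sign alignment
before any mean, and biological replicates kept separate.

## Moderated t-test

Gene variances follow the hierarchical model
σ²_g ~ scaled-inv-χ²(d₀, s₀²); the sample variance then satisfies
s²_g/s₀² ~ F(d_g, d₀). The hyperparameters are fitted by the method of
moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the mean identifies
s₀² and the excess variance beyond the trigamma term identifies d₀
through ψ′(d₀/2), inverted by Newton iteration. If the empirical
variance does not exceed the trigamma term the variances are declared
constant (d₀ = ∞, s₀² = their mean). A unit test cross-checks the fit
against the reference empirical-Bayes implementation in Bioconductor's
limma (`fitFDist`) on shared simulated variances.

The moderated statistic uses the posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), a convex combination of prior and
sample variance. Its null is the **standard normal by default** — the
convention of the study design this package serves — with a
t(d₀ + d_g) null available by flag. The normal null is anticonservative
at small replication (the test suite asserts the direction); the t null
is calibrated. Multiplicity: Bonferroni, Benjamini–Hochberg (the default
for DE calls), or a semi-parametric local fdr (probit-transformed
p-values, Gaussian kernel density for the marginal, null weight π₀
estimated from the p > ½ mass). The local fdr is a documented stand-in
for "optimised FDR" procedures whose internals are not published; it
estimates the same quantity (the posterior null probability).

Kinase dependence of a response uses a fixed effect-size rule rather
than a test: a regulated gene is *affected* in a mutant when its
response differs from the wild-type response by at least 1 log₂ unit
(two-fold), in either direction.

## Constrained Gaussian mixture and controlled assignment

Profiles x_i ∈ ℝ^d (d = 7 contrasts in the reference design) follow
Σ_k π_k N(μ_k, λ_k·C) with det C = 1: component volumes differ,
orientation and shape are shared. The M-step has no closed form under
this constraint; given the weighted scatter matrices W_k it alternates

```
λ_k ← tr(C⁻¹W_k)/(n_k·d);   C ← Σ_k W_k/λ_k, rescaled to det 1
```

to convergence (each step increases the constrained likelihood). EM runs
from 10 k-means++ initialisations by default, stops at a relative
log-likelihood change below 1e-8 or 500 iterations, and asserts
monotonicity. A component that collapses (fewer than d members, or
volume below 1e-8) is reinitialised once; a second collapse aborts that
start. Parameter count m = (K−1) + K·d + K + (d(d+1)/2 − 1); K is chosen
by minimising BIC = −2·loglik + m·log n over K = 2..40 by default.

Assignment: with posteriors p_ik, the candidate thresholds are the
sorted distinct maximum posteriors (plus a value just below the
smallest); for each τ the classified set is {i : max_k p_ik > τ}
(strict inequality) and its estimated **false assignment proportion**
is FAP(τ) = mean over the set of (1 − max_k p_ik), the posterior
expected fraction of wrong assignments. The smallest τ with FAP ≤ α
(default α = 0.05) is chosen, classifying as many profiles as the
control allows. This estimator is the natural Bayesian-FDR analogue for
clustering; Monte-Carlo validation (the acceptance script) shows the
*true* misclassification among classified profiles tracks α to within
estimation error on overlapping three-component mixtures at n = 5,000.
The control is only as good as the posterior calibration: at small n,
parameter-estimation error can push the true error a fraction of a
point above α.

Cluster summaries use linear-interpolation quartiles, whiskers at
Q1 − 1.5·IQR and Q3 + 1.5·IQR, and the per-comparison percentage of
members differentially expressed (Bonferroni p < 0.05); a cluster is
*interpretable* when that percentage exceeds 50% somewhere.

## Preferentially located motifs

Promoters are fixed-length (default 1,000 bp) sequences covering
positions −L..−1 upstream of the TSS; an occurrence of an IUPAC motif is
anchored at the match base closest to the TSS, and reverse-complement
matches are reported at the forward-strand window they occupy (both
strands scanned by default; a window matched on both strands counts
once). Scanning is exact and is property-tested against a brute-force
IUPAC-expansion oracle.

Detection bins anchors at 50 bp, counts genes per bin (a gene counts
once per bin), and tests each bin one-sided against
Binomial(G, 1/n_bins), G the number of genes with any occurrence, with
Bonferroni correction over bins at α = 0.01. The functional window is
the maximal run of contiguous significant bins (ties broken by the
smallest bin p-value). This binned-uniform-null detector is a documented
stand-in for published peak-boundary methods whose internals are not
reproducible from their descriptions; it recovers planted windows and
controls the null declaration rate in simulation. **Limitation:** the
uniform null assumes sparse occurrences; for highly degenerate motifs
with several matches per promoter the bin counts exceed G/n_bins
systematically and windows become too wide. Cluster enrichment is the
exact binomial upper tail P(X ≥ k), X ~ Binomial(n, p₀), with p₀ the
genome-wide proportion of promoters hit inside the window, significant
at p < 0.01; genes count once regardless of match multiplicity.

## Enrichment and kinetic classes

Term enrichment is the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K_term, n) over the annotated part of the
universe, reported for every term with k ≥ 1 together with the
occurrence ratio (k/n)/(K_term/N). Matching the raw-threshold
convention of the analyses this package reproduces, significance is
called on the raw p-value (< 0.05); a Benjamini–Hochberg column is
emitted for users who prefer FDR control.

Kinetic classes summarise linear fold changes at 1 h and 3 h.
*Induced* means fc ≥ 2, *repressed* fc ≤ ½, anything between is basal
(the basal band is a package choice; published class definitions state
the two-fold discrimination rule but no numeric basal cutoff). Induction
branch: F induced→basal, G/H/I induced at both times with the 1 h/3 h
ratio ≥ 2, within two-fold, or ≤ ½ respectively, J basal→induced; A–E
mirror these for repression on reciprocal fold changes. Trajectories
that switch sign (induced at 1 h, repressed at 3 h or vice versa) are
left unclassified rather than forced into a class.

## Interaction networks

PPI (undirected) and TF-target (directed) edge lists are merged into one
neighbour graph restricted to a gene universe (both endpoints must
belong); duplicates within and across sources collapse onto a single
neighbour relation that keeps both type tags, self-loops are dropped,
and isolated genes do not appear. Degree counts distinct partners
regardless of type or direction; hubs are nodes with degree strictly
greater than 19 (degree 19 is not a hub, 20 is). Exports: SIF and
GraphML for external visualisation.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the methods assume:
dye-swap orientation, intensity-dependent bias, the hierarchical
variance prior (verified distributionally by a Kolmogorov–Smirnov test
at 5,000 genes), the constrained mixture law, uniform-background
promoters with window-planted motifs, and edge lists with
guaranteed-degree hubs. They do not emulate spatial array artefacts,
probe cross-hybridisation, sequence composition beyond i.i.d. GC
content, GO term correlation structure, or degree distributions of real
interactomes — so passing tests demonstrate correctness of the
*methods* under their stated assumptions, not robustness to every
real-data pathology. In the end-to-end pipeline the planted true
profiles come from a small set of prototype patterns so that
co-expression clusters, promoter elements, annotation terms and hubs
are mutually consistent; planted hubs connect within the co-expressed
genes, mirroring a network restricted to the clustered universe.

## Problem sizes and numerical choices

Default tests and the acceptance run use desk-scale sizes chosen to make
the statistical claims testable: 5,000 observations per mixture
replicate (20 replicates for the misclassification experiment — at this
size parameter-estimation error contributes only fractions of a point to
the controlled error rate), 10,000 genes for hyperparameter recovery,
2,000 promoters for motif detection. The pipeline default of 2,000 genes
with K scanned over 2..40 completes in minutes on one CPU; examples and
tests scan narrower K ranges on smaller gene sets. Tolerances: det C is
maintained to 1e-6; posterior rows sum to 1 within 1e-10; EM
monotonicity is asserted at 1e-9 relative. Ties at the assignment
threshold are resolved by strict inequality (an observation exactly at τ
is unclassified). Quartiles interpolate linearly between order
statistics. Empty inputs, constant-A hybridisations, all-equal
variances, saturated backgrounds (p₀ = 1) and empty kinetic classes all
have defined, tested behaviour.
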