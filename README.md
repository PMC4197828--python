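# mapktome

Analysis toolkit for genome-wide transcriptome studies of MAMP-triggered
immunity — the kind of experiment that contrasts wild-type plants with
MAP-kinase mutants (*mpk3*, *mpk4*, *mpk6*) before and after elicitation
with the flagellin epitope flg22 on dye-swapped two-colour microarrays.
The package covers the full chain from probe-level intensities to
biological summaries, and ships synthetic-data generators that plant
known signal for every stage, so each method can be validated against
ground truth.

## What it computes

1. **Differential expression.** Per-array loess correction of the
   intensity-dependent dye bias on the (M, A) plane, orientation-aware
   averaging over duplicate probes and dye pairs (one value per gene and
   biological replicate), and the moderated *t*-statistic
   `t_g = m̄_g / (s̃_g √(1/n))` with the empirical-Bayes posterior variance
   `s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g)`, where (d₀, s₀²) are fitted by
   the method of moments on log variances. Adjustment by Bonferroni,
   Benjamini–Hochberg or a semi-parametric local fdr; a gene is
   kinase-dependent when its flg22 response differs from the wild-type
   response by ≥ 1 log₂ unit.
2. **Model-based co-expression clustering.** A Gaussian mixture over the
   seven-contrast profiles with covariances Σ_k = λ_k·C, det C = 1
   (volumes free, orientation and shape shared), fitted by EM with an
   inner alternation for the constrained M-step, K selected by
   BIC = −2·loglik + m·log n. Profiles are assigned to their MAP
   component only above a threshold τ chosen so the estimated proportion
   of misassigned profiles among those classified stays ≤ 5% — a
   clustering analogue of the Bayesian FDR.
3. **Positional cis-elements.** IUPAC scanning of fixed 1,000-bp
   TSS-anchored promoters, detection of preferentially located motifs
   (PLMs) via a binned uniform null, and exact binomial tests of
   per-cluster over-representation inside the functional window.
4. **Enrichment.** One-sided hypergeometric tests for GO terms and for
   kinetic response classes (A–J: repression/induction trajectories at
   1 h and 3 h discriminated by a two-fold rule).
5. **Interaction networks.** Merge of PPI and TF-target edge lists
   restricted to the clustered genes, degree statistics, and regulatory
   hubs (degree > 19).

## A worked example

```sh
python examples/02_mixture_clustering.py
```

draws 3,000 profiles from a known three-component mixture with
overlapping components, selects K by BIC and applies the controlled
assignment rule. It prints:

```
BIC trace (lower is better):
 K   loglik  n_params     bic
 2 -10703.8         9 21479.7
 3 -10602.0        13 21308.0
 4 -10597.1        17 21330.2
 5 -10594.5        21 21357.1

selected K = 3; fitted volumes [0.66 1.07 1.39] (planted 0.7, 1.0, 1.5 up to scale)

threshold tau = 0.824: 1867 of 3000 profiles classified; estimated misassignment 5.0% (about 93 profiles), controlled at 5%
true misclassification among classified: 5.0% — the rule trades coverage for accuracy on overlapping components
```

BIC recovers the planted component number, the constrained EM recovers
the planted volumes, and the threshold rule classifies 62% of profiles
while the *true* error among them matches the 5% it promised to control.
The other scripts in `examples/` demonstrate differential expression,
promoter motif detection, enrichment, network hubs, and the end-to-end
pipeline (`mapktome run-all` on the command line does the same from a
YAML config).

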