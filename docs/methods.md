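# Methods

## Scope and model

`hormsense` quantifies which phytohormones govern a plant's sensitivity to a
dose-structured abiotic stressor, combining two evidence layers per
(tissue, dose-vs-control) contrast:

1. **Concentration layer.** A targeted hormone panel (17 compounds by
   default: ABA, SA, IAA, the ethylene precursor ACC, three jasmonates,
   six cytokinins, three gibberellins, typhasterol) measured in replicate
   in two tissues across a control and three stressor doses. A two-class
   PLS-DA per contrast yields each hormone's VIP; the variation factor
   VF = (mean_treated − mean_control)/mean_control × 100 gives the signed
   percent change; Tukey's HSD across all dose groups gives an adjusted
   p-value per dose-vs-control pair. A hormone is *altered* when VIP > 1,
   |VF| > 25 % and p < 0.05 simultaneously (all strict), and its modified
   VIP is then vip_m = sign(VF)·VIP, otherwise 0.
2. **Transcript layer.** Differentially expressed genes (linear fold change
   strictly outside (0.5, 2.0), p < 0.05) annotated to hormone biosynthetic
   pathways, each gene labelled direct (biosynthetic enzyme / pathway
   regulator, weight 1.0) or indirect (secondary influence, weight 0.5).
   The pathway's Total Weighted Contribution Score is

       TWCS = (1/n) Σ_direct log2 FC_g · 1.0 + (1/m) Σ_indirect log2 FC_g · 0.5

   with an empty class contributing 0 (its term dropped) so that pathways
   lacking one class still score finitely.

The two layers multiply into the Total Hormonal Sensitivity Index,
THSI = vip_m × TWCS(pathway of the hormone). Hormones in one pathway share
the TWCS factor. Within each contrast hormones are ranked by |THSI|
(descending, name-lexicographic tie-break); rank 1 is the contrast's *hub*
hormone. Ranking by absolute value with the sign retained for direction was
chosen because "most sensitive" is a magnitude notion while the sign encodes
up/down response; an all-zero contrast is flagged degenerate rather than
given an arbitrary hub.

## PLS-DA details

* **Scaling.** Predictors are autoscaled (mean-centred, unit variance with
  ddof = 1 per hormone); concentrations span orders of magnitude, and VIPs
  are only comparable across hormones on a common scale. The response is a
  centred 0/1 class code.
* **Extraction.** NIPALS; for a single response column the loop converges in
  one pass but the iteration cap (500) and tolerance (1e-10) are explicit.
  Components are truncated at the predictor rank (with a warning). The sign
  of each weight vector is fixed by forcing its first non-zero entry
  non-negative, so results are byte-reproducible.
* **Zero-variance hormones** are dropped with a warning (autoscaling is
  undefined) and reported with VIP 0.
* **Quality metrics.** R²X and R²Y are cumulative explained-variance
  fractions. Q² = 1 − PRESS/TSS under leave-one-out cross-validation (the
  default: with n = 6 per contrast, k-fold is unstable; k-fold is available
  via the fold-scheme argument). TSS is taken against each training fold's
  response mean, so a model that only predicts the training mean scores
  exactly 0. A fold that would empty a class in training raises an error.
* **Validity gate.** A contrast passes when R²X, R²Y and Q² all strictly
  exceed 0.5. The pipeline warns on — but still scores — failing contrasts,
  flagging them in the model summary, because downstream scores remain
  well-defined and discarding a contrast silently would bias tissue
  summaries.
* **VIP.** VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a) with unit-norm
  weights and SSY_a = q_a² t_aᵀt_a; mean squared VIP is identically 1.

The default component count is A = 2. Note that with n = 6 and a single
separating direction the second component can only model noise; tests that
plant exactly one direction therefore fit one component.

## Significance testing

Dose-vs-control p-values come from one omnibus one-way layout: the pooled
within-group mean square over *all* dose groups feeds the studentized range
statistic q = |mean_d − mean_0| / sqrt(MSE/2 · (1/n_d + 1/n_0)), referred to
the studentized range distribution with k groups and N − k degrees of
freedom. This is exactly Tukey's HSD, evaluated only for the pairs involving
the control (the only pairs the selection uses); the full pairwise scan
computes four times the work for the same numbers. No correction is applied
across hormones. A degenerate panel with zero within-group variance returns
p = 0 for any mean difference and p = 1 otherwise.

## Synthetic data generator

The generator emulates the study design: 2 tissues × doses
{0, 4.80, 20.0, 124.0} mg SCN⁻/L × 3 biological replicates × 17 hormones.

* **Concentrations** are lognormal (they are positive, ng/g FW), with the
  arithmetic group mean and a replicate-level CV (default 0.15, typical for
  targeted phytohormone assays in triplicate). Per-hormone baselines are
  spread lognormally (CV 0.8) around 50 ng/g FW so the panel spans a
  realistic dynamic range; a planted effect sets the treated mean to
  control × (1 + VF/100).
* **DEG tables** are generated from a two-sample t model: each gene's true
  log2 fold change (drawn from the planted pathway (mean, SD), or 0) is
  observed through 3-vs-3 simulated log2 expression replicates with
  within-group SD 0.25, and the reported fold change and p-value both come
  from those replicates — so effect size and significance stay coherent
  instead of being assigned independently. Null genes (default 400) are
  never differential.
* **Template defaults** plant the qualitative response pattern of a
  thiocyanate-stressed rice seedling study: jasmonates and ACC up-regulated,
  strongest in shoots; gibberellins suppressed; distinct hub hormones per
  tissue and dose (JA and GA3 and SA in roots at low/medium/high dose;
  JA-Ile, ACC, JA-Ile in shoots). Every dataset ships with a ground-truth
  record (planted VFs, expected alteration classes and TWCS signs, intended
  hubs) so recovery tests never reverse-engineer the generator.

What the generator does **not** emulate: hormone–hormone correlation
structure, heteroscedastic assay error, probe-level microarray artefacts,
batch effects, or missing values. Passing recovery tests therefore shows
the scoring machinery recovers planted effects under idealized noise, not
that it is robust to real-data pathologies.

## Numerical choices

* Strict inequalities everywhere a threshold is printed (> 1, > 25 %,
  < −25 %, p < 0.05, FC < 0.5 or > 2.0, metrics > 0.5); boundary values are
  excluded by construction and tested.
* VF requires a strictly positive control mean (undefined-baseline error
  otherwise); concentrations are validated non-negative at load, and missing
  cells are rejected rather than imputed — targeted panels are reported
  complete.
* Fold changes are stored linear; log2 is applied only inside TWCS, because
  the DEG thresholds are printed on the linear scale.
* THSI ties break lexicographically by hormone name; determinism end-to-end
  is guaranteed by seeded generators, the NIPALS sign convention, and
  stable sorts, and is asserted byte-wise on the result tables.
* Result tables are written with `%.10g` floats so hashes are stable across
  runs.

## Problem sizes

Simulation-backed checks use 50-problem random suites for the PLS oracle
and VIP normalization, 100 label permutations for the Q² null, 100 seeded
replicates for hub recovery, and 200 seeded datasets for null calibration
of the selection gate — sizes at which the binomial uncertainty on the
reported rates is a few percent, adequate for the ≥95 % and ≤10 % gates
they feed.

## Known limitations

* The VIP_m construction (sign(VF)·VIP under the triple gate) is the
  minimal rule consistent with the published description; other rescalings
  would change THSI magnitudes but not hub identities when gates are shared.
* Two-class PLS-DA only; multi-class and orthogonalized variants are out of
  scope.
* The direct/indirect annotation is a required input: the package does not
  infer mechanistic gene classes.
* Published model-quality values from the original study cannot be
  reproduced exactly because raw data, scaling, and CV scheme are
  unpublished; the validity gate is therefore checked as a rule, not as a
  numeric reproduction.
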