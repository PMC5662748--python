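# Methods

## Model and assumptions

`pbdsn` treats a labeled omics matrix as a family of datasets
D = {S_t | 1 ≤ t ≤ N_s}, one per disease group (static design) or time
point (time-series design), and asks which *pairwise relationships* among
feature ratios are specific to one label. The working assumptions are:

- abundances are strictly positive after imputation, so every ratio
  f_i/f_j and every log fold-change is defined;
- within a label, samples are exchangeable replicates, so a sample Pearson
  correlation over that label's n_t samples estimates the label-specific
  association of two ratios (n_t ≥ 3 is enforced — with n_t = 2 the
  statistic is identically ±1);
- an association is biologically meaningful only above a magnitude
  threshold τ, and only its presence and sign (red/green) matter
  downstream, not its exact value;
- a relationship that is present in the target label but absent or
  sign-flipped in most other labels is discriminative for that label
  (static) or a prospective signal of stage onset when the comparisons are
  restricted to earlier time points (time-series).

The method is deliberately rule-based: there is no null model or p-value
attached to a differential edge, and degree is the only centrality used
for ranking.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ (`tau`) | 0.7 | minimum \|PCC\| (dimensionless, in (0, 1]) for an edge |
| fraction | 2/3 | share of comparison networks an edge must differ in; the requirement is ⌈fraction × n⌉, so with 4 groups an edge must differ in 2 of the 3 others |
| fc threshold | 3 (static), 1 (time-series) | minimum max-pair \|log FC\| to keep a feature; interpreted in `log_base` (default 2) |
| k | 5 | number of top-degree vertices retained as candidates |
| compare_labels | all | restrict the fold-change filter to designated "typical" labels |

The ⌈·⌉ in the "most" rule is computed with a small epsilon guard so that
the floating-point representation of 2/3 times 3 comparisons is exactly 2,
not 3.

## Numerical choices

- **Correlation.** `pearson` implements the (n−1)-denominator definition
  directly and clamps to [−1, 1]; `build_network` computes the full matrix
  with `numpy.corrcoef` (tests assert the two routes agree to 1e−10).
  Thresholding uses ≥, so a correlation exactly equal to τ produces an
  edge. Columns with zero variance within a label (possible after
  minimum-value imputation of an all-missing group) contribute no edges
  rather than raising: the statistic is undefined there and an absent edge
  is the conservative reading.
- **Imputation** falls back to the feature's global minimum positive value
  when an entire group is missing; non-positive values are treated as
  missing because ratios and log fold-changes require positive inputs. The
  operation is idempotent and never touches an already-positive value.
- **Ties and ordering.** All rankings, edge listings and serialized
  outputs sort lexicographically; degree ties break by vertex name. This
  makes two runs with identical inputs byte-identical (the run log uses a
  timestamp-free format, and `run_config.json` omits the bundle's own
  path for the same reason).
- **Logistic AUC.** The model is an unpenalized maximum-likelihood fit
  (scikit-learn, C = ∞, bounded iterations). Under perfect separation the
  MLE diverges but the *ordering* of fitted probabilities is stable, so
  the AUC is still reported, flagged `converged=False`. The ROC is swept
  over the fitted probabilities; with a single covariate the sigmoid is
  monotone, so the AUC coincides with the rank (Mann-Whitney, midpoint
  ties) statistic of the covariate in the fitted direction.
- **Degenerate evaluation inputs.** A constant score yields AUC 0.5 by the
  tie convention; single-sample labels get SE = 0 and a degenerate flag in
  group summaries.

## Synthetic data generator

The generator produces the correlation topology the method is designed to
detect, with known ground truth. Features are lognormal,
f = exp(μ + g), with per-sample log-scale values g mixed from independent
standard-normal latents:

    g_0 = h0·e_0 + c·w              hub numerator
    g_1 = v·u    − c·w              hub denominator
    g_j = v·p + σ·e_j − c·w         partnered tail features
    g_j = σ_big·e_j                 unpartnered tail features

with the coupling latent `w` active only in the target label. The hub
ratio f_0/f_1 and each partner ratio f_0/f_j then share the term 2c·w, so
they correlate strongly (red) in the target label and near zero elsewhere;
the anchor latent `p` gives the partners a mutual correlation in *every*
label, so partner–partner edges are present everywhere with the same sign
and are therefore never differential — only the hub's edges are planted.

Two consequences of this design are worth stating explicitly. First,
partners necessarily correlate with each other: if each partner correlates
at 0.95 with the hub, positive-semidefiniteness forces their mutual
correlation above ~0.89, so "independent partners" is not a constructible
alternative; planting the mutual correlation in all labels is what keeps
the hub's degree distinguished. Second, partners share the hub's numerator
feature, so at most n_features − 2 partners exist (8 for the default 10
features).

Coefficients are solved numerically: the raw-scale Pearson correlation of
two lognormal ratios follows from their log-scale covariance via
corr(e^X, e^Y) = (e^{cov} − 1)/√((e^{varX} − 1)(e^{varY} − 1)), and `c`
(and `h0`, for a nonzero background) are found by root-finding so the
*achieved raw-scale* hub–partner correlation equals `within_target_pcc`
(default 0.95) and the background correlation equals `background_pcc`
(default ≈ 0). Strongly negative raw-scale correlations of lognormals are
bounded away from −1, which is why the planted edges are red. Unpartnered
tails get a large noise variance (σ_big) so their ratios stay clear of the
threshold.

Defaults (4 labels × 20 samples, 10 features, 8 partners, PCC 0.95,
log-noise σ = 0.05) describe a modest multi-group omics study with
moderate technical noise. What the generator does *not* emulate: real
marginal distributions, mean shifts between groups (the planted signal is
purely a correlation change, so fold-change filtering is switched off for
synthetic runs and AUCs on synthetic data hover near chance),
heteroscedastic or correlated measurement error, and batch structure.
Passing the recovery tests therefore shows the *pipeline logic* recovers a
planted differential hub under idealized noise — not that the method
succeeds on any particular real dataset.

## Problem sizes

Tests and the acceptance script run at small scale by choice: toy network
families of ≤ 8 vertices for oracle comparisons, 45-ratio networks
(10 features) for recovery studies over 20 seeds, and single 81-feature
(3240-ratio) matrices only for the dimensionality check. The full suite
completes in a few seconds.

## Known limitations

- The differential rule is deterministic; no significance is attached to
  an edge or a hub, and small n_t makes individual edges noisy (an edge
  near τ flickers between labels).
- With one or two comparison networks the ⌈fraction × n⌉ rule degenerates
  to "all comparisons must differ"; this follows the definition as stated
  and is not further adjusted.
- In time-series mode only earlier time points are compared, so an edge
  persisting into later stages still counts as a signal at its onset.
- Hub ties are resolved lexicographically for determinism; a real tie in
  degree carries no evidence about which vertex matters more.
- The evaluation reports training-set AUCs without cross-validation or
  confidence intervals, matching the method's original usage; they are
  optimistic estimates by construction.
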