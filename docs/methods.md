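# Methods

This document describes the statistical machinery implemented in
`audioprofiles`: the constrained Gaussian-mixture engine, the robust
structure-selection vote, the imputation model, consensus profile
generation, and the reduced-battery classifier. Default parameter values
are given with their rationale.

## 1. Feature battery

Each patient is summarized by 20 features derived from four measurement
groups:

| group | features |
| --- | --- |
| Audiogram (worse ear) | `ac_pta`, `bc_pta`, `abg`, `asymmetry`, `ucl_pta`, `bisgaard_index` |
| Categorical loudness scaling (ACALOS) | `l2_5_1500`, `l15_1500`, `l35_1500`, `l15m35_1500` and the same four at 4 kHz |
| Speech audiometry (GOESA) | `goesa_srt`, `goesa_slope`, `goesa_max` |
| Demographics / questionnaire | `age`, `tinnitus`, `socio_economic_status` |

The *worse ear* is the ear with the higher four-frequency pure-tone
average (0.5/1/2/4 kHz); ties go to the right ear. Interior audiogram
gaps are linearly interpolated on log-frequency before averaging; edge
frequencies are never extrapolated. The Bisgaard index is the ordinal
position (0–18) of the closest standard audiogram by summed absolute
deviation, with standards ordered by ascending PTA.

Three features are affine functions of other features *by definition*:

```
abg          = ac_pta  - bc_pta
l15m35_1500  = l15_1500 - l35_1500
l15m35_4000  = l15_4000 - l35_4000
```

These identities make the 20-column matrix rank-deficient by
construction, which has two consequences handled explicitly below:
full-covariance mixture fits are singular (§3) and imputation must keep
the identities consistent (§4).

All features are min–max scaled to [0, 1] before clustering; constant
columns scale to 0 with a warning. Scaling bounds are retained so
results can be mapped back to clinical units.

## 2. Constrained Gaussian mixtures

Cluster g has covariance Σ_g = λ_g A_g with A_g diagonal (or full),
det(A_g) = 1, giving the eight families:

| family | volume λ | shape A | orientation | covariance parameters |
| --- | --- | --- | --- | --- |
| EII | equal | spherical | — | 1 |
| VII | variable | spherical | — | k |
| EEI | equal | equal | axis-aligned | d |
| VEI | variable | equal | axis-aligned | k + d − 1 |
| EVI | equal | variable | axis-aligned | 1 + k(d − 1) |
| VVI | variable | variable | axis-aligned | kd |
| EEE | equal | equal | equal (full) | d(d+1)/2 |
| VVV | variable | variable | variable (full) | kd(d+1)/2 |

Fitting is by expectation–maximization. M-step updates are closed-form
except VEI and EVI, which alternate the volume and shape sub-updates to
convergence of the expected complete-data log-likelihood; the update
never decreases it (verified against a direct numerical maximizer in
the test suite). Model choice uses the Bayesian information criterion
in the orientation `BIC = 2·loglik − n_params·ln(n)` (larger is
better), with `n_params = (k−1) + kd + covariance parameters`. Both
conventions are cross-checked against the R reference implementation
(`mclust` 6.1.1) in `tests/test_mclust_oracle.py`.

Defaults and safeguards:

- **Initialization.** `n_init` randomized starts (responsibilities from
  a k-means++-style seeding); the best final log-likelihood wins.
  Convergence at relative log-likelihood change < 1e-6, max 500
  iterations.
- **Variance floor 1e-4** (scaled units). Features are min–max scaled,
  so 1e-4 corresponds to a standard deviation of 1% of a feature's
  clinical range — below any plausible within-cluster spread but large
  enough to stop degenerate spikes on near-duplicate rows. A much
  smaller floor lets a component collapse onto a few points and inflate
  the log-likelihood without statistical meaning.
- **Singularity rule.** For the full-covariance families (EEE/VVV) the
  M-step covariance is declared numerically singular when its smallest
  eigenvalue is below 1e-8 times its largest; the fit raises a
  structured failure rather than returning a floor-ridged matrix. This
  matters here because the feature battery is exactly rank-deficient
  (§1): a "successful" full-covariance fit would owe most of its
  log-likelihood to the floor along the three degenerate directions,
  corrupting every BIC comparison. Declaring the fit unavailable
  mirrors the reference implementation, which reports such cells as
  missing in its BIC table; the grid simply proceeds with the families
  that are estimable.
- **Component collapse** (a cluster losing all weight) is reported per
  fit; collapsed fits are excluded from the grid's best-BIC choice.

## 3. Robust structure selection

A single BIC grid on one completed dataset is brittle under
missingness and sampling noise. Selection therefore votes:

1. Draw B subsamples of 95% of the rows *without* replacement
   (bootstrap duplicates can masquerade as micro-clusters).
2. Multiply impute each subsample into m completed datasets (§4).
3. Fit the full (k, family) BIC grid to each completed dataset.
4. Reduce the m best entries to one candidate per subsample by majority
   vote, then take the majority over the B candidates.

Ties break toward smaller k, then toward the family with fewer
covariance parameters. Study-scale defaults are B = 1000, m = 20,
k = 2…30; the `desk_scale()` preset (B = 30, m = 3, k = 2…10, one EM
start, 5 chain iterations) runs in about a minute on 500 × 20 data and
is what the tests and the acceptance script use.

## 4. Imputation

Missing cells are completed by chained equations (MICE) with predictive
mean matching: each incomplete feature is regressed on all others
(ridge-stabilized least squares with Bayesian parameter draws), and
each missing cell receives the *observed* value of one of the 5 nearest
neighbours by predicted mean — so imputed values always lie in the
observed support and respect bounds, discreteness and skew. Chains run
10 iterations by default (5 at desk scale); m independent chains give m
completed datasets. Ordinal features (e.g. the Bisgaard index) are
rounded and clipped to their coded range.

The three derived features of §1 are imputed *passively*: after every
chain sweep they are recomputed from their parents via the exact affine
identity (expressed in scaled units using the scaling bounds) instead
of being regression-imputed. Without this, independently imputed
parents and children break the identities on imputed rows, which both
distorts the joint distribution and re-opens the singularity problem of
§2 through "almost rank-deficient" completed data. Observed cells are
never altered.

## 5. Consensus profile generation

Given the selected (k, family), the full cohort is imputed into m
completed datasets and the mixture is fitted to each with the *same*
initialization stream (and `n_init = 10` restarts), so that differences
between the m solutions reflect imputation variability, not the
vagaries of independent random starts. Pairwise solution similarity is
the fraction of patients on which two solutions agree under the best
one-to-one matching of cluster labels (Hungarian assignment on the
contingency table; verified against brute-force permutation search).
The consensus solution is the one with the highest mean similarity to
the others, and the mean/max similarity are reported as stability
diagnostics. Final profiles are renumbered by ascending median speech
reception threshold, so profile 1 is always the least-impaired group,
and summarized by per-feature medians and quartiles.

## 6. Profile classification

New patients are assigned to profiles from a reduced 12-feature battery
(ACALOS levels and slopes, GOESA SRT and slope, `ac_pta`, `asymmetry`,
Bisgaard index, age) using random forests. Four strategies are
supported: a plain multiclass forest; one-vs-all (k cost-weighted
forests; a patient is claimed at positive vote share > 0.5); one-vs-one
(k(k−1)/2 pairwise forests with voting); and their combination OVAOVO,
where the OVA stage proposes candidates and an OVO vote among the
claimants arbitrates. Class imbalance is handled by upsampling every
profile to the size of the largest with Gaussian jitter of one
within-profile SD per feature. The forests' `max_features` (mtry) is
tuned by cross-validation (LOOCV or repeated stratified K-fold) against
a configurable metric — Cohen's kappa, balanced accuracy, macro F1 or
macro AUPRC. Strategies are compared on out-of-fold macro F1 over
profiles with at least `min_profile_size = 10` training members;
held-out evaluation reports per-profile precision and sensitivity, with
small or never-predicted profiles excluded from the macro means and
flagged.

## 7. Synthetic cohorts

The generator draws cluster centres for the independent feature blocks
(audiogram summaries, ACALOS, GOESA, demographics), samples
within-cluster values with diagonal covariance, derives the dependent
measurement columns (per-frequency thresholds consistent with the
drawn summaries, both ears, asymmetry applied to the worse ear), and
injects missing-completely-at-random cells into measurement columns
only. Key design choices:

- Base SDs are balanced so that `ac_pta`, `bc_pta` and `abg` have
  comparable marginal spread; since the three are linearly dependent,
  some within-cluster correlation among them is unavoidable (≈0.7 at
  equal parent SDs — the attainable minimum).
- Separation is expressed in units of average within-cluster SD, so
  "separation 6" means centroids ~6 SDs apart regardless of scale.
- Limitations: missingness is MCAR only (clinical missingness rarely
  is), clusters are axis-aligned by construction (full-orientation
  families can only be exercised via `sample_mixture`, which draws from
  any of the eight families with known parameters), and measurement
  noise is Gaussian.

## 8. Problem sizes and runtime (single CPU)

| task | size | time |
| --- | --- | --- |
| One EM fit | n = 500, d = 20, k = 5 | < 1 s |
| BIC grid, 9 k-values × 8 families | n = 500, d = 20 | ~10 s |
| Desk-scale robust selection | B = 30, m = 3 | ~1 min |
| Consensus profiles | m = 5, n_init = 10 | ~30 s |
| Classifier train + evaluate | n = 500, k = 5, OVAOVO | ~15 s |
| Acceptance script end to end | n = 500 | ~3 min |

## 9. Reproducibility

Every public entry point takes a single seed; internal stages derive
independent named streams from it via `numpy.random.SeedSequence`
spawning, and all derived seeds stay below 2³¹. Reruns with the same
seed and input are byte-identical — the pipeline writes a manifest with
a SHA-256 hash per artifact and `verify_manifest` re-checks them.
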