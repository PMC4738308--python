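# Methods

This note documents the models, conventions and numerical choices behind
`nnsearch`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Session design

A session has six runs.  Run 1 presents every one of the 200 comparison
stimuli once, in random order; later runs re-present the subsets chosen
by the closed loop, with run sizes 200, 31, 25, 20, 16, 13.  Stimuli
appear for 2 s separated by 2 s blanks.  After every 4th stimulus an
extra 4 s event is inserted, strictly alternating between a blank probe
and the referent (in the imagery condition the referent event is a cue
to imagine), each followed by a 2 s gap.  The alternation phase is not
fully determined by the protocol description; we start each run with a
blank probe (configurable).  Referent events have identical timing in
the two conditions.

Scans per run are `ceil((last event end + washout)/TR)` with an 8 s
washout, TR = 1 s by default.  The 24 s inter-run interval is metadata
only; no scans are simulated in the gap.

## 2. GLM

Stimulus regressors are boxcars convolved with the canonical
double-gamma haemodynamic response (response peak gamma shape 6,
undershoot 16, dispersions 1, peak:undershoot 6:1, 32 s support,
unit-sum kernel).  Convolution runs on a 16× oversampled micro-time grid
and is sampled at scan times.  One regressor per stimulus pools **all**
of its presentations across the runs included so far, so betas are
cumulative; drift, motion and constant columns are per-run
(block-diagonal).  High-pass filtering is implemented by including
orthonormal discrete-cosine drift regressors with period above the 128 s
cut-off — `floor(2·N·TR/cutoff)` columns per run — which is equivalent
to filtering data and model.  Estimation is plain OLS over all voxels at
once; no prewhitening is applied, so serially correlated noise inflates
beta variance, which the downstream permutation tests absorb.  Run-wise
constants (rather than a single intercept) are used.  Stimuli absent
from the included runs are flagged and excluded from similarity; in the
cumulative design every stimulus appeared in run 1, so stale cumulative
estimates remain addressable.

## 3. Closed-loop search

After each run's cumulative fit, every valid stimulus pattern is
compared to the referent's by Spearman correlation across voxels
(average ranks; Pearson on ranks).  The top-k stimuli per the schedule
form the next run; after the final run the neighbourhood is the top ten
of the final similarity vector.  Ties are broken by ascending stimulus
id everywhere, mirrored exactly in the brute-force ground-truth oracle
so that noiseless oracle-equivalence is an exact set-and-order match.
Later-run similarity is computed for all 200 stimuli (cumulative
regressors make stale items' betas available), so unselected items can
in principle re-enter.

## 4. Stimulus features

Eleven sensory features are computed from the images: JPEG byte size
under a pinned encoder configuration (quality 75, 4:2:0 subsampling, no
optimisation — absolute bytes are encoder-specific, so the value is
used only comparatively after z-scoring); mean L\*, a\*, b\*; RMS
contrast (SD of L\*); luridness (mean of SD(a\*) and SD(b\*), the
"mean of two plane SDs" reading rather than a pooled SD); and five
mask-based shape features — area, object-minus-background L\*,
roundness (eigenvalue ratio of the foreground pixel-coordinate
covariance), thickness (area/perimeter²) and horizontal spread
(orientation × (1 − roundness), folded so +π/4 is horizontal and −π/4
vertical).  Six semantic and two emotional features are subjective
ratings ingested as given (5-point scales; animacy and object number on
3 levels).

Conventions: sRGB input with D65 white point and the standard transfer
function (scikit-image); image-level SDs use the population convention
(N) so a two-tone image has RMS contrast exactly 50, while column
z-scoring uses the sample convention (N−1) — a deliberate, documented
asymmetry.  Perimeter counts exposed foreground pixel edges under
4-connectivity; under this convention a rasterised disc's perimeter
tends to the staircase length 8r, so disc thickness tends to π/64 (not
the Euclidean 1/(4π)), while squares and rectangles are exact.  Greys
map to |a\*|, |b\*| below 0.01 (not exactly 0) under the standard
conversion matrices.

## 5. Synthetic data model

A participant's pattern for stimulus *s* is `W f_s + b` with
`W = U · diag(strengths)`: shared random Gaussian directions `U`
(voxels × features) scaled per-feature by the planted tuning strengths,
plus a random baseline `b`.  Both conditions share `U` and `b`, so
condition contrasts isolate strength differences.  The referent's
pattern uses the same map on the referent's feature vector; the
ground-truth neighbourhood is the top-k by noiseless Spearman
similarity, ties by id.  Voxel counts default to a uniform draw from
223–371, the size range of an occipitotemporal ROI.

BOLD runs are the convolved true design times the true patterns plus
optional cosine drift (random weights on sub-cutoff components) and
AR(1) Gaussian noise parameterised by its marginal SD.  Six synthetic
motion covariates (smoothed random walks) are produced and used only as
nuisance regressors — they do not corrupt the signal, because the
analyses only require that nuisance regression not *break* estimation.

Two deliberate modelling choices depart from a literal reading of the
obvious alternatives:

* **Bimodality mixture.**  Under the shared linear model, rank
  similarity orders stimuli by |f_s − f_ref| regardless of the sign of
  the tuning strength, so flipping a participant's strength cannot
  produce opposite-feature neighbourhoods.  Two clusters of imagery
  styles therefore require differing *imagined content*: the mixture
  assigns each participant one of two feature values for the imagined
  referent (e.g. z = +2 or −2), which does produce two separated
  clusters of NN feature means.
* **Neighbourhood-level sampling.**  For large replicate calibration and
  power studies, `sample_neighbourhoods` adds iid Gaussian noise to the
  noiseless similarity vector and takes the top-k, skipping the BOLD and
  GLM layers that the recovery and oracle-equivalence suites already
  exercise.  This keeps 200-replicate studies to seconds without
  weakening what they test: the statistics operate on labels and
  features either way.

What the generator does **not** emulate: spatially structured noise,
voxel-wise HRF variability, motion-correlated artefacts, attentional
drift, and any nonlinearity between features and patterns.  Passing
tests therefore certify the *analysis machinery* (calibration, power,
exactness), not the biological fidelity of the assumed linear code.

## 6. Feature-tuning statistics

The classifier is the diagonal quadratic discriminant: class-conditional
diagonal Gaussians with class-specific variances, variance floored at
1e-6 of the pooled per-feature variance.  **Priors default to uniform.**
With empirical priors at the 10/190 class imbalance, a weakly informative
feature set makes the classifier predict "outside-NN" on every fold, so
every permutation draw yields the identical edge-corrected d′ and the
permutation test degenerates (p = 1 always).  Uniform priors turn the
decision into a pure likelihood comparison, preserve d′'s character as a
bias-free sensitivity, and calibrate correctly; empirical priors remain
available as a configuration switch.

Leave-one-out folds are participant × item; the held-out item's feature
vector is excluded from training **for all participants** (otherwise the
identical vector would leak).  Because excluding an item removes all of
its copies, the per-fold classifier depends only on the held-out item;
the implementation exploits this with O(items) running-sum updates and
is verified against a naive per-fold refit.  Hit and false-alarm rates
pool over all folds; rates of exactly 0 or 1 are edge-corrected to
1/(2N) and 1 − 1/(2N).  Note that retraining after a class swap leaves
d′ invariant (hit′ = 1 − FA); antisymmetry holds only at fixed
predictions.

The permutation null redraws each participant's in-NN set uniformly
(preserving per-participant class counts); p = (1 + #{null ≥ obs}) /
(n_perm + 1), never exactly zero.  Hierarchical testing: stage 1 runs
one multivariate classifier per feature set (sensory/semantic/emotional,
one Holm family of three); stage 2 runs univariate classifiers only
inside significant sets, Holm-corrected within the set.  With m features
in a set, stage 2 needs n_perm ≳ m/α for the smallest achievable p to
clear the Holm threshold — the default 1000 is ample; scaled studies use
300.

Direction of tuning: per-participant mean z-scored feature value over
the NN items, with a one-sample t-test and 95 % t-interval across
participants.  Condition and referent contrasts are paired /
two-sample t-tests on those per-participant means.  Pattern-reliability
QA decodes stimulus identity pairwise (linear SVM, C = 1,
leave-one-run-out) from per-run betas fitted by separate run-wise GLMs —
the cumulative model has one regressor per stimulus and cannot provide
run-specific patterns.

## 7. Geometry

Distances are 1 − Spearman (inheriting the online metric).  Classical
Torgerson scaling double-centres the squared distances; negative
eigenvalues (the metric is non-Euclidean, so they occur routinely) are
reported but not embedded, and variance explained is λ_k/Σ|λ|.
DISTATIS normalises each participant's cross-product matrix by its
first eigenvalue, builds the Rv (normalised inner-product) cross-table
similarity matrix C, weights tables by C's dominant eigenvector
(rescaled to sum 1) and embeds the weighted compromise; λ₁(C)/trace(C)
summarises cross-participant consistency.  The per-table normalisation
means identical inputs reproduce single-table MDS up to one global
scale.  Eigenvector signs are fixed by making the largest-magnitude
coordinate positive.  Procrustes alignment is rigid by default
(rotation + optional reflection + translation, no scaling).  Confidence
ellipses resample participants with replacement and use the covariance
of the bootstrap means, axes scaled by sqrt(χ²₀.₉₅,₂).  The referent's
position is illustrated as the centroid of its neighbourhood's
coordinates, since referent-to-stimulus distances are not on the same
footing as stimulus-to-stimulus distances.

## 8. Individual differences

The consistency test correlates each pair of participants'
referent-similarity vectors (Pearson on the rank-derived similarities;
Spearman available) and permutes each participant's entries
independently for the null.  The dip statistic is computed exactly on
the sorted sample by the iterative greatest-convex-minorant /
least-concave-majorant algorithm and validated against an independent
linear-programming oracle (feasibility of a unimodal CDF within
sup-norm bands, exhaustively on all small three-valued samples).  Its
bootstrap null draws same-size Gaussian samples with the observed mean
and SD (the dip is location-scale invariant, so effectively only n
matters).  The vividness analysis correlates, per participant, the
imagery-minus-perception change in NN mean feature value with VVIQ —
the per-participant tuning measure, since the classifier d′ pools
participants and has no per-participant analogue.  KDE reporting uses a
Gaussian kernel with a fixed absolute bandwidth (default 0.1 on the
z scale).

## 9. Study sizes and calibration targets

The statistical suites run a scaled experiment: 40 stimuli (20
categories × 2), schedule 40/12/10/8/6/5 with 4-item neighbourhoods,
40–60 voxels, 8–21 participants, 100–300 permutations, 200-draw dip
bootstraps.  The full 200-stimulus protocol constants are the
configuration defaults and are exercised once per suite by a noiseless
full-scale session.

Power-study operating points (chosen once from the type-I/power studies,
as the protocol itself leaves SNR unspecified): detection and
tuning-drop studies plant strength 2.0 on one continuous sensory feature
with the referent at z = +2 and similarity noise 0.05; the VVIQ study
uses imagery strength 0.6 − 0.02·(VVIQ − mean) against similarity noise
0.3 (perception 0.05), placing participants on the rising part of the
strength→enrichment curve rather than its plateau; the bimodality study
mixes imagined-referent values z = ±2.  Under these conditions the
measured rates are: type-I ≈ 5 % for the d′ criterion, the mean-NN
t-tests and the dip test; ≥ 90 % detection for the hierarchical
procedure and the paired drop; ≥ 80 % for the VVIQ link; and ~100 % dip
power on mixture cohorts.  For reference, the dip test's power on the
textbook mixture 0.5·N(−2,1) + 0.5·N(2,1) at n = 21 is only ≈ 55 %
(≈ 97 % at ±3) — tight cohort clusters, not the textbook mixture, are
what make the bimodality study well-powered.

## 10. Known limitations

* Plain OLS without prewhitening; AR(1) simulation therefore slightly
  miscalibrates parametric beta-variance formulas (not used for
  inference — permutation tests carry the load).
* The linear feature→pattern code is an analysis assumption, not a claim
  about cortex; nonlinear codes would change what "tuning" means.
* The dip test's Gaussian bootstrap null is conservative against
  heavy-tailed unimodal alternatives.
* Real-data mode ingests NIfTI + events tables but has only synthetic
  round-trip coverage; scanner quirks (partial volumes, dropout) are
  untested.
* JPEG complexity depends on the encoder build; only its z-scored,
  comparative use is meaningful.
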