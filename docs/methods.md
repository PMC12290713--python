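# Methods

`nirsync` implements an end-to-end analysis of multi-participant fNIRS
recordings acquired under naturalistic narrative stimuli (movie watching /
listening), asking two questions: do participants' cortical hemodynamics
synchronize when they follow the same narrative, and is that synchrony
reliable enough to characterize a *single* participant against a group?

## Signal model and preprocessing

A continuous-wave fNIRS channel measures light intensity `I(t)` between a
source-detector pair at two or more wavelengths. The pipeline converts
intensity to optical-density change with the series mean as reference,

    dOD(t, λ) = −ln( I(t, λ) / ⟨I(λ)⟩_t ),

and inverts the modified Beer–Lambert law per channel and time point,

    dOD(λ) / (DPF(λ, age) · ρ) = ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR,

solved exactly for two wavelengths and by least squares for more. ε values
are the HOMER `GetExtinctions` coefficients in cm⁻¹/(mol/L) (760 nm:
645/1669; 785: 787/996.65; 808: 903/804; 830: 1008/778; 850: 1097/781);
ρ is the source-detector distance in cm (~3 cm cortical "long" channels,
0.8 cm scalp-only "short" channels); concentrations are reported in µM.
The differential pathlength factor uses the general age/wavelength
equation

    DPF(λ, A) = 223.3 + 0.05624·A^0.8493 − 5.723e−7·λ³ + 0.001245·λ² − 0.9025·λ,

which for a 23-year-old gives ≈ 6.1 at 760 nm falling to ≈ 5.0 at 850 nm.
The coefficients live in a `DPFModel` dataclass so alternatives can be
plugged in.

Between OD and the Beer–Lambert inversion, a two-stage hybrid motion
correction runs per channel/wavelength:

1. **Spline stage** — artifact detection on the first-differenced series:
   samples whose |Δx| exceeds `threshold` (default 8) times a winsorized
   sd of Δx (values clipped at 10 robust sd before the sd is taken) are
   flagged and dilated by half a detection window (default 1 s); each
   flagged segment has a smoothing-spline trend subtracted and its level
   re-anchored to the preceding clean sample. The winsorized-sd baseline
   ignores the artifacts themselves yet, unlike a plain MAD, is not fooled
   by the slow amplitude modulation of narrowband hemodynamic signals —
   with these defaults artifact-free series pass through untouched.
2. **Wavelet stage** — `db2` decomposition over 4 levels; detail
   coefficients farther than 3 interquartile ranges from their level
   median are zeroed (boundary-padding coefficients are exempt). A
   single-sample spike concentrates in a handful of enormous detail
   coefficients and is suppressed by ≥ 80%, while for clean data the rule
   fires on < 0.01% of coefficients.

Hemoglobin series are band-passed 0.005–0.20 Hz with an order-3 Butterworth
applied forward-backward (zero phase; order configurable). Scalp and
systemic physiology are then removed by **short-channel regression**: all
good-quality short-channel HbO and HbR series are stacked, reduced to
principal components by SVD (avoiding collinearity between adjacent short
channels), and the full component set plus an intercept is regressed out of
every long channel by OLS; one shared component set serves both
chromophores. A short channel is "good" iff its raw intensity shows a
cardiac (~1 Hz) spectral peak at every wavelength — a Welch spectrum local
maximum in 0.5–2 Hz with prominence above 3× the in-band median power. A
recording whose short channels all fail is excluded
(`ParticipantExcluded`), mirroring standard practice. Finally each channel
series is standardized to zero mean and unit variance (idempotent).

Note that band-limited regressors carry few effective degrees of freedom
(a 0.005–0.20 Hz band at ~480 s spans only ~10²), so regressing 2·n_short
principal components removes a visible share of *any* in-band signal, not
just scalp physiology; with 4 short channels the realized ISC of true
signal channels drops by roughly a quarter. This attenuation is a property
of all-components PCA short-channel regression, and the synthetic study
conditions are calibrated on the post-pipeline scale for that reason.

## Inter-subject correlation and group inference

ISC is computed leave-one-out: participant p's series on channel c is
Pearson-correlated with the mean series of all remaining participants;
correlations are Fisher-transformed (clipped at |r| = 1 − 1e−7) and the
HbO and HbR z values averaged, yielding one z per (participant, channel).
Cohorts with unequal series lengths are truncated to the common minimum.

Significance uses **phase-scrambled surrogates**: each series' Fourier
phases are rotated by independent uniform draws (DC and Nyquist fixed),
with the *same* rotation applied to HbO and HbR of a channel so their
anticorrelation survives; amplitude spectra — hence autocorrelation — are
preserved exactly. Per surrogate cohort a one-tailed one-sample t is
computed per channel and the maximum across channels recorded; a channel's
corrected p is the fraction of surrogate maxima at or above its observed
t (max-statistic family-wise correction). Intact > Scrambled contrasts
apply the identical machinery to per-participant ISC differences.
Phase draws are independent across channels and participants.

Computationally, surrogate ISCs are evaluated in the frequency domain:
phase rotation preserves amplitudes, so Pearson sums become weighted
Parseval sums over rFFT bins (`FreqCohort`), and all P drop-one subcohorts
of a leave-one-out analysis share one batched Gram-matrix computation.
Both shortcuts are verified in the test suite to reproduce the explicit
scramble-then-correlate path to 1e−12 given identical random draws. Within
one surrogate iteration of the mask builder, a single full-cohort phase
draw is shared across the P drop-one subcohorts; each subcohort test
remains a valid surrogate test.

## Leave-one-out masks and single-participant consistency

For every participant p, the group analysis (per condition and per
Intact > Scrambled contrast) is recomputed on the cohort *excluding p*;
the significant channels form p's mask. No mask ever saw its
participant's data, which the suite verifies by perturbation.

Consistency of participant p is the **normalized dot product**

    score_p = (1/n) Σ_{i ∈ mask_p} a_i · g_i,

where `a` is p's ISC vector, `g` the leave-one-out group-mean ISC vector,
and n the mask size; the sign is preserved so anti-tracking participants
score negative. The null phase-scrambles the cohort, recomputes `a`, and
rescores against the *original* `g` and mask — i.e., the score a
participant with no stimulus alignment would obtain against the group's
actual ISC topography. (Scrambling `g` as well would shrink the null an
order of magnitude below the score fluctuations of a genuinely
non-tracking participant and label noise "consistent"; the adopted null's
scale, |g|·σ_a/√n, also matches the uncorrected p-values such analyses
report in practice.) The one-sided p counts null ≥ actual;
Benjamini–Hochberg FDR across participants at q < 0.05 sets the
significant flags. As validation, the same score computed from each
participant's *Scrambled* ISCs against the Intact group reference is
compared with the Intact scores by a paired t-test (dof = n − 1).

## Decoding sensitivity

Per left-out participant, 17 classifier families (extra trees, bagging,
AdaBoost, gradient-boosted trees, logistic, ridge, SVM, ν-SVM, Bernoulli
and Gaussian naïve Bayes, Gaussian process, label propagation, label
spreading, linear and quadratic discriminant analysis, k-NN, nearest
centroid; scikit-learn throughout, registry configurable) are trained on
the 2·(n−1) Intact/Scrambled ISC vectors of the remaining participants,
recomputed within that leave-one-out cohort so no training feature
involves the test participant. Features are the union of channels
significant in either single-condition LOO mask (fall-back: all channels,
with a warning). Hyperparameters are tuned by a budgeted random search
(default 25 evaluated configurations; the library defaults always count
as one candidate) maximizing the median balanced accuracy over stratified
3-fold CV; the winning score is the classifier's voting weight. The
ensemble predicts the class with the larger weight sum; exact ties resolve
to Scrambled — the conservative outcome for claims of narrative
processing. Predictions for all left-out participants pool into one
confusion matrix (rows actual, columns predicted, ordered
Scrambled/Intact) from which balanced accuracy, recall and precision
(Intact positive) are computed.

Significance comes from within-participant label permutations: per
iteration each participant's Intact/Scrambled vectors are swapped with
probability ½ and the whole LOO decoding re-run (reduced tuning budget
allowed and logged); p = (1 + #null ≥ observed)/(B + 1). A subtlety worth
knowing: for strongly separable features a *single* shuffled run is
bimodal (an exactly-half swap inverts every training majority, giving
balanced accuracy 0; a full swap is a relabeling, giving 1), but the mean
over random swaps is exactly 0.5 by the swap/complement symmetry — so
chance-level checks evaluate the permutation-null mean, not one draw.
Single-channel decoding repeats the procedure with each channel as the
sole feature and reports the mean LOO balanced accuracy per channel.

## Suspense GLM

Group-averaged Intact hemoglobin series are reduced to the rating grid by
interval averaging (one value per ~2-s rating; decimation available), and
each channel × chromophore series is regressed on [intercept, z-scored
suspense ratings, z-scored same-channel Scrambled group series]. The
nuisance regressor absorbs envelope-driven components that track suspense
by coincidence. Suspense-beta p-values are BH-FDR corrected across all
channel × chromophore tests at q < 0.05; collinear designs (condition
number > 1e6) are recorded per channel rather than raised.

## Synthetic cohorts

`synthetic_data.generate_cohort` draws, per condition, one latent
"narrative" signal shared by all participants — a unit-sd Gaussian
process confined to 0.02–0.15 Hz, the interior of the analysis band,
realized with the same Butterworth design as preprocessing so it passes
the analysis filter with gain ≈ 1. Participant-level ΔHbO on long channel
i is

    w_i·s(t)·[i ∈ signal set] + scalp_p(t) + noise_sd·η_i(t),

with mixing weights w_i ~ U[0.5, 1.5] drawn once per cohort, a
participant-specific scalp process (sd `scalp_sd`) shared between that
participant's long and short channels, and independent channel noise;
ΔHbR is `hbr_ratio` (< 0, default −0.6) times the shared-plus-scalp part
plus independent noise scaled by |hbr_ratio| so both chromophores carry
the same SNR. Short channels carry the scalp process plus 0.2·noise_sd
channel noise and no narrative signal. Scrambled conditions draw an
independent latent restricted to a smaller channel subset (default: empty
to 10% of long channels), mirroring the restricted synchrony such controls
evoke. Intensities follow the forward Beer–Lambert model (I₀ = 1) with
the same extinction table and age-dependent DPF as the inverse — a
noise-free cohort round-trips to 1e−14 — plus a 1.1 Hz cardiac sinusoid
(participant-specific phase, 3× stronger on short channels) and optional
multiplicative measurement noise. Motion artifacts (Poisson-timed spikes
and baseline steps, expressed in channel-OD sd units) can be injected in
OD space; untouched samples stay bit-identical.

Defaults mirror the targeted acquisition: 26 participants, 121 long +
8 short channels, 3.9063 Hz, two stimuli of 478/463 and 312/302 s, ages
drawn from N(23.3, 3.1) clipped to [19, 31]. The default channel noise
(sd 2.0 in latent units) realizes signal-channel ISC ≈ 0.3–0.4 at
hemoglobin level for small (n ≈ 8–10) cohorts — the range
single-participant ISC maps typically span. Because expected leave-one-out
ISC depends on cohort size, r = 1/√((1+V)(1+V/(n−1))) for nuisance
variance V, `noise_sd_for_target_isc` solves this for any target; the
reference studies in `nirsync.studies` use noise sd 2.5 (n = 26) and 2.2
(n = 12) so the *post-pipeline* signal-channel ISC lands at ≈ 0.3.

What the generator does **not** emulate: hemodynamic-response convolution
with event structure, the fixed Scrambled-before-Intact presentation
order, spatially correlated channel noise, realistic optode-coupling
variation, or biophysical photon transport. Passing tests therefore show
the *statistical machinery* behaves as designed under the assumed signal
structure — calibrated nulls, power at a stated effect size, leakage-free
leave-one-out constructions — not that real recordings meet those
assumptions.

Suspense ratings are generated by sampling the latent signal every 2 s,
mixing in an orthogonalized noise component so the realized correlation
equals the requested target exactly, and mapping affinely into the 1–10
rating range.

## Reference studies and problem sizes

`nirsync.studies` fixes the validation conditions (all driven by one seed):

* **Calibration** — 100 null cohorts (8 participants × 20 channels ×
  300 samples, 200 surrogates each): family-wise rejection rate of the
  max-t test, expected ≤ 0.05 + binomial slack.
* **Power/consistency** — one cohort at study scale (26 participants,
  478 s, signal in 5/20 channels, post-pipeline ISC ≈ 0.3, full
  preprocessing including motion correction and short-channel regression;
  200 surrogates): Intact > Scrambled mask recovery of the true channels,
  mask false-positive rate, fraction of participants with significant
  consistency, and the paired Intact-vs-Scrambled validation t.
* **Decoding** — a 12-participant cohort at the same SNR: ensemble
  decoding with 39 label permutations, tuning budget 5 observed / 1 during
  permutations; reports balanced accuracy, permutation p, and the
  permutation-null mean as the shuffled-label reference.
* **Suspense** — beta recovery at noise sd 0.5 and the uncorrected
  false-positive rate when suspense is independent noise.

These sizes keep the full validation run in single-digit minutes on one
CPU while leaving each check comfortably powered.

## Known limitations

* The hybrid motion-correction hyperparameters are reasoned defaults, not
  reproductions of any published implementation; HOMER-exact equivalence
  is a non-goal.
* The max-t null at small n (≤ 10) has heavy tails because leave-one-out
  ISCs share the others-mean across participants; power analyses should
  use realistic cohort sizes.
* Hyperparameter search is a budgeted random search; a Bayesian optimizer
  would explore larger spaces more efficiently but the ensemble's voting
  weights, not any single tuned classifier, carry the result.
* Fisher z values are clipped at |r| = 1 − 1e−7 (z ≈ 8.4); degenerate
  zero-variance series yield ISC 0 with a warning.
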