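# Methods

## The generative model behind the synthetic data

Every simulated trial is a sum of rank-one sensor-space components — a
spatial pattern (an independent unit-norm Gaussian vector, hence
near-orthogonal to the others in expectation) times a non-negative temporal
envelope — plus white sensor noise:

| component | shared by | envelope (defaults) | amplitude |
|---|---|---|---|
| evoked | every trial | onset bump (peak 0.15 s, σ 0.05 s) + plateau (×0.6) while the image is on (0–2 s) | 8 |
| stimulus (image) | one Mooney image across both stages; each grayscale image has its own | Gaussian bump at 0.2 s (σ 0.08 s) + optional second bump at 1.35 s (×0.35, σ 0.12 s) | 6 |
| stimulus (class) | all Mooney images / all grayscale images | same as stimulus | 4 |
| recognition | a post-stage Mooney image and its matching photograph (real sets only) | logistic ramp, midpoint 0.6 s, width 0.1 s | 6 |
| attention | every recognized-condition trial | Gaussian bump at 0.5 s (σ 0.1 s) | 4 |

Noise is i.i.d. standard normal per sensor and sample (scale 1). The
envelope latencies mirror the canonical phenomenology of prior-guided
disambiguation: early stimulus-feature processing, an intermediate
attentional transient around 0.5 s, late recognition-content processing,
and a small late stimulus re-activation. The amplitudes were chosen once so
that, at realistic trial counts (6 + 6 + 3 presentations), the per-image
averaged patterns carry clearly detectable but not noise-free structure;
they are the package's definition of its study conditions and are not
tuned per analysis.

Two modelling points deserve emphasis:

- **The class-level stimulus component is essential.** Without a pattern
  shared by all two-tone images (and a different one shared by all
  photographs), a Mooney image is no more dissimilar to a non-matching
  photograph than to another Mooney image, and the stimulus model — whose
  highest level lives on the Mooney–grayscale off-diagonals — has no early
  correlate in the data.
- **Catch sets carry no recognition or attention component in the post
  stage**: their assigned photograph does not match, so "disambiguation"
  confers nothing. Their grayscale trials are normal photograph trials.

Behavior is a per-image latent recognition state (spontaneous probability
0.34 pre-disambiguation; 0.87 post for real sets; the pre-stage probability
in both stages for catch sets) with the two stages comonotonically coupled
through one uniform draw, plus a per-report lapse (0.1) and a per-stage
verbal lapse (0.05). The lapse makes six-probe recognition counts bimodal
at 0–1 and 5–6, which is what justifies the "not-recognized ≤ 2 /
recognized ≥ 4" classification.

ROI activation patterns reuse the same identity structure in a fresh
feature space per ROI (60 features): stimulus-, recognition-, and
attention-weighted mixtures under per-ROI profiles
(V1 (1, 0.1, 0.05), LOC (0.7, 0.5, 0.2), Frontal (0.15, 1, 0.3),
Parietal (0.1, 0.3, 1)), plus an ROI-wide common activation (0.5) and small
feature noise (0.05) — the patterns stand in for *group-level* activation
estimates, hence the low noise. A strong shared attention component in a
recognition-dominant ROI would make recognized conditions similar to each
other and invert the recognition model's fit, which is why the recognition
ROI keeps a modest attention weight.

### What the generator does not emulate

No forward model, no 1/f or correlated sensor noise, no eye movements or
artifacts, no hemodynamics, no per-subject anatomy, and behavior does not
feed back into the sensor signal (components are gated by condition, not
by simulated reports). Passing tests therefore certify the *analysis
machinery* — its algebra, calibration, and ability to recover planted
structure — not robustness to the full messiness of real recordings.

## Analysis conventions and numerical choices

- **Scheduling.** 39 sets (33 real + 6 catch) divide exactly into 13
  introducing runs of 3; run *r* disambiguates the sets introduced in run
  *r − 1*, so the first and last runs are half runs. Each run repeats its
  block three times, giving 6 Mooney presentations per stage and 3
  grayscale presentations. Set-to-run assignment is exposed (`set_order`).
- **Preprocessing.** 3rd-order Butterworth filters applied
  forward–backward (zero phase; standard for evoked analyses — latency
  *orderings* are still interpretable, but absolute onsets inherit the
  acausal smoothing). Downsampling applies an extra zero-phase anti-alias
  low-pass at 45% of the target rate before decimation, with t = 0 kept on
  a sample. Continuous data are demeaned/detrended per run before
  filtering; the ERF band therefore carries no true DC offset.
  Normalization is a z-score across sensors at each sample with ddof = 1,
  so Pearson r between normalized vectors is their dot product /(S − 1).
- **Decoding.** Odd–even folds split *image sets* by position parity, so
  both stage averages of an image stay in one fold (no image-level
  leakage); folds are deterministic and never re-randomized. The SVM is
  libsvm's C-SVC with a linear kernel and cost 1; prediction ties resolve
  to the negative (pre) class by the solver's deterministic convention.
- **RDMs.** The 99-entry label order is pre 1..33, post 1..33, gray 1..33
  with one image order everywhere, so between-condition block diagonals
  address matching pairs. Correlation RDMs use patterns averaged over the
  first three presentations per Mooney stage (all three for grayscale);
  separability RDMs use all single trials (6/6/3). Distances are raw sums
  over sensors, not normalized by sensor count. Main-diagonal cells are
  stored as NaN and excluded from every summary. Fisher-z transforms clip
  r at ±(1 − 1e−10) so noise-free fixtures stay finite. Cross-validated
  Euclidean folds follow presentation order (6 trials → 3 folds of 2;
  3 trials → 3 folds of 1); within a fold, partition A is the fold and
  partition B its complement, and the three fold products are averaged.
  RDM time courses live on the epochs' native sampling grid, whatever band
  produced them (a fixed 10 ms RSA grid is impossible for a 10 Hz band).
- **Separability.** `r_within` averages the two within-image mean
  Fisher-z correlations; the subtraction happens in z space and is not
  back-transformed, making 0 the exchangeability chance level. (A reading
  of the statistic that *sums* rather than averages the two within-image
  means would shift the chance level to the mean within-correlation,
  contradicting a chance level of 0; the averaged form is used.) With
  m ≠ n the two within-image means are weighted equally, not by pair
  counts.
- **Commonality.** All RDM and model vectors are rank-transformed
  (average ranks on ties) before ordinary least-squares R², so
  single-predictor R² equals squared Spearman rho; a raw-value analysis is
  the same code path minus the ranking. Cells missing in any vector of an
  equation are excluded listwise. Single R² terms are clipped to [0, 1];
  commonalities may be negative (suppression) and are reported as such.
  Rank-deficient predictor sets fall back to a pseudoinverse with a
  warning.
- **Cluster inference.** Per-sample one-tailed one-sample Wilcoxon
  signed-rank tests (exact null distribution up to n = 25 without ties,
  tie-corrected normal approximation otherwise; the vectorized
  implementation is validated against scipy). Clusters are contiguous
  p < 0.05 samples (4-neighbour contiguity in 2-D); the summary is the
  summed W; the null is the per-permutation maximum summary under
  per-subject sign flips of the deviation from chance — the
  exchangeability-preserving analogue of label shuffling for a one-sample
  test. Paired contrasts reuse the same machinery on paired differences.
  Defaults: 500 permutations for decoding, 5000 for RDM condition
  contrasts, 1000 for model RSA and fusion.
- **RDM-order permutation null.** One shuffle of all 3n (condition, image)
  entries applied identically to rows, columns, and every time point.
  Shuffling whole entries is deliberate: conjugating by the *same*
  33-image permutation inside every condition block maps each model level
  class onto itself and leaves the model correlation exactly unchanged —
  a degenerate null. Cluster-forming threshold: per-time 95th percentile
  of the null statistic; cluster significance: maximum-cluster-size
  criterion at the 95th percentile. The fusion significance mask
  additionally requires both the sensor–model and ROI–model correlations
  to clear their own permutation nulls.
- **FDR** is Benjamini–Hochberg (not BY).

## Problem sizes

The test suite and the acceptance script run everything on synthetic data
at sizes the package treats as its reference conditions: the full default
design (33 + 6 sets, 14 runs, 585 trials per subject); 18 subjects at 32
sensors and 10 Hz for decoding calibration; 6 subjects at 48 sensors and
20 Hz for the 33-set recovery battery (model-RSA peaks, separability
transition, fusion onsets, 200-permutation nulls); 200–300 null experiments
of 18 × 35 values for cluster-test calibration; and 100 random small
instances per oracle-equivalence check.

## Known limitations

- The fusion loop recomputes ranked vectors per permutation; at many ROIs
  or a 100 Hz grid it becomes the dominant cost.
- The attention model correlates weakly with early class-structure
  dissimilarity (its Pre–Gray cells are high wherever Mooney and
  photograph classes separate), so small attention commonalities can reach
  significance outside attention-dominant ROIs; conclusions about the
  attentional transient should rest on the time course, not the map alone.
- Envelope latencies are free parameters of the generator; recovered peak
  *orderings* are meaningful, absolute latencies are whatever was planted.
- The exact signed-rank null is computed for tie-free data; heavily
  discretized inputs silently shift the machinery to the normal
  approximation.
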