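# Methods

This note documents the models, defaults and design choices behind
`neurostates`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort generator (`synth`)

The generator produces every input the analysis consumes, with the
statistical structure the downstream stages assume.

**Neural time series.** Each subject's parcel series follows a
Markov-switching multivariate Gaussian: a latent chain with row-stochastic
transition matrix selects, per TR, which state's Gaussian (μ_s, Σ_s) emits
the 17-parcel observation. The initial state is drawn from the chain's
stationary distribution, avoiding burn-in artefacts. Defaults mirror the
target design: 256 subjects, 180 volumes (a 9-minute run at TR = 3 s), 17
parcels, 7 states. Where the design does not pin a value we chose once:

- transition persistence 0.88 (off-diagonal mass uniform), giving mean
  dwell-times of roughly 8 TR ≈ 25 s — in the range reported for
  resting-state HMMs at slow TRs;
- state mean maps from a cosine (DCT-II) pattern with amplitude 0.8 in
  standardised-parcel units: mutually distinct, non-degenerate maps with
  overlap structure, separated enough that multi-restart EM is stable;
- identity state covariances (functional-coupling differences between
  states are not needed by any consumer in this pipeline, which analyses
  mean-activity maps and temporal statistics).

One global seed expands into per-subject substreams keyed by
(stream, subject), so a subject's data are invariant to cohort size and
the generator's products (series, reports, motion, gradients) are mutually
independent.

**Reports.** Latent component scores are linear in the standardised
dwell-times — coefficient `report_effect_size` (default 0.5) on designated
(state, component) pairs, defaults (3→1) and (7→2), zero elsewhere — plus
Gaussian noise (SD 1.0). Items load sparsely (one component each, loading
0.9, item noise SD 0.5) and are discretised to 1–4 by quartile cut-points
of the latent item score, preserving rank information. The well-being
battery uses the identical mechanism for a 168-subject subset with 3
components and pairs (4→1) and (7→2), emitted as integer questionnaire
totals rather than Likert scores. The coupling model is a stand-in: its
effect sizes are free parameters of the generator, not estimates from any
dataset.

**Motion.** Framewise displacement is i.i.d. gamma (shape 4) with a
designated exceedance mechanism: with probability `motion_bad_fraction` a
volume is pushed above the scrub threshold (threshold + Exp(0.1) mm), and
the base gamma mean is solved so the overall expected mean equals
`motion_mean_fd_mm` (default 0.15 mm, bad fraction 0.02). Only the
exclusion rules consume FD, so temporal autocorrelation of real head
motion is deliberately not modelled.

**Gradient basis.** Three zero-mean, unit-norm, mutually orthogonal
columns from a QR decomposition of centred Gaussian noise, with a
deterministic sign convention. It shares the real gradients' algebraic
properties (orthogonality, zero mean) but none of their spatial meaning;
real parcel-resolution gradient maps can be supplied as a parcels × 3 TSV
instead.

**What passing tests do not show.** The generator's emissions are exactly
Gaussian and exactly Markov, its noise is white, and its reports are
exactly linear in dwell-times before discretisation. Passing tests
therefore certify the estimators and their calibration under the model's
own assumptions — not robustness to haemodynamics, physiological
confounds, non-stationarity, or reporting biases in real data.

## Screening and standardisation (`ingest`)

A subject is excluded iff mean FD > 0.3 mm, or more than 15% of volumes
have FD above the per-volume scrub threshold. Both boundaries are
exclusive (exactly 0.3 mm / exactly 15% are retained). "Affected by
motion" is operationalised as FD > 0.5 mm per volume — the same criterion
used for volume-level confound flagging — and is configurable. Retained
subjects are z-scored per subject and parcel (population SD, divisor n)
and concatenated in subject order; a zero-variance parcel within a subject
is an error naming both. Standardise-then-concatenate (rather than
z-scoring the concatenated matrix) is the documented convention
throughout. Inputs are assumed to be already confound-regressed,
band-pass-filtered parcel averages; no image-space processing is done.

## HMM (`hmm`)

Inference is expectation–maximisation (Baum–Welch) with full-covariance
Gaussian emissions rather than variational Bayes: the operative contract
is the multi-restart/best-objective protocol and the downstream metrics,
and EM is exactly checkable against enumeration and an independent
implementation (hmmlearn, used in tests only). Numerical choices:

- restarts: k-means initialisation (4 k-means restarts) plus a seeded
  N(0, 0.1) perturbation of the centres per run; sticky initial transition
  matrix (0.9 diagonal); uniform initial state distribution;
- E-step: scaled forward–backward, batched across subjects with equal
  series length (subjects are grouped by length otherwise);
- covariance regularisation: +1e-6·I after every M-step; the fit is
  flagged when the unregularised covariance was not positive definite at
  the last iteration;
- convergence: relative log-likelihood change < 1e-6 or 500 iterations;
  non-convergence returns the best-so-far fit with a flag;
- Viterbi ties break toward the lowest state index, making decoded paths
  deterministic.

Dwell-time counts truncated runs at the path's start/end as visits. A
state a subject never visits has missing dwell-time; at the
standardisation step missing entries are imputed with the mean (0),
consistent with the 2.5σ outlier rule's substitution-by-mean logic.
`match_states` aligns two solutions by maximising summed Pearson
correlation between mean maps (Hungarian assignment); for constant maps,
where Pearson is undefined, it falls back to cosine similarity of the raw
maps.

## Behavioural decomposition (`behaviour`)

PCA is performed on the item correlation matrix (Likert items share no
natural scale), retention is strictly eigenvalue > 1, and rotation is
varimax with Kaiser row-normalisation (delegated to statsmodels'
orthogonal rotation routines), sign-fixed so each component's
largest-magnitude loading is positive. Scores are least-squares
projections of the standardised items onto the rotated loadings; with
orthogonal rotation they remain mutually uncorrelated and communalities
are invariant. An empty retention set (no eigenvalue above 1) is an error
rather than a silent empty model.

## Association (`association`)

Ordinary least squares multivariate regression; each dwell-time predictor
is tested as a single-df contrast with all other columns retained
(Type III-style partial test), for which the Wilks' Λ F-approximation is
exact: F = ((1−Λ)/Λ)(df2/df1), df1 = p, df2 = n − rank(X) − p + 1, and
partial η² = 1 − Λ. Covariates: mean FD and age z-scored, gender a single
binary column. No correction is applied across the K per-state tests —
the multivariate p-values are reported uncorrected, and each result
records how many tests were run in its family. With the full design
(intercept + 7 dwell-times + 3 covariates) this yields df (8, 238) at
n = 256 with 8 outcome components, and (3, 155) at n = 168 with 3.

## Gradient projection and null (`gradients`)

Coordinates are atanh of the Pearson correlation between a state map and
each gradient, clipped at |r| = 1 − 1e-7 so degenerate toy inputs stay
finite. The weighted distance sum uses the *signed* maximum coordinate,
following the statistic's definition literally — a state with all-negative
coordinates contributes negatively; `use_abs_max=True` switches to the
absolute maximum, exposing rather than hiding this ambiguity. The null
shuffles each state's parcel weights independently per permutation draw
(preserving each map's weight multiset), and the exceedance p uses the
add-one convention (1 + #{null ≥ observed})/(n + 1), never exactly zero.
Similarity is computed at parcel resolution (17 parcels); voxel-level
similarity before parcel reduction is out of scope.

## Pipeline (`pipeline`, CLI)

Stage order: simulate/load → screen → standardise → fit → decode/metrics →
decompose → associate → project/null. Defaults are the study settings
(7 states, 10 restarts, 300 permutations, 2.5σ, 0.3 mm, 15%,
eigenvalue > 1); a YAML/JSON config can override them and overrides are
echoed to the log. Every run writes a manifest with package versions, the
seed, every threshold, per-run objectives and stage timings; the manifest
suffices to re-run bit-identically. Stages are pure functions of recorded
inputs.

## Problem sizes in tests and the acceptance script

Monte-Carlo suites run at sizes chosen to exercise the claims directly:
transition recovery uses 20 replicate cohorts of 50 subjects × 180 volumes
× 17 parcels (K = 3); MANCOVA type-I calibration uses 1000 null
simulations at n = 120; exceedance-p uniformity uses 500 replicate map
sets with 99 permutations each (a 1/100 grid of attainable p-values);
the planted-effect power check uses 100 replicate cohorts at the full
n = 256 design. The acceptance script reuses the same machinery at 5
recovery replicates. These are the package's own choices of problem size;
all full-design quantities (degrees of freedom, permutation counts,
acquisition geometry) are computed at the design's stated scale.

## Known limitations

- The observation model has no temporal embedding or autoregression; very
  fast state dynamics relative to TR are not identifiable.
- EM finds local optima; the multi-restart protocol mitigates but does not
  guarantee the global optimum.
- Model order K is taken as given (default 7, with a 9-state robustness
  path); no free-energy model comparison across K is implemented beyond
  per-run objectives and run-matching stability.
- The synthetic gradient basis is spatially meaningless; conclusions about
  real gradient topography require supplying real parcel-level gradient
  maps.
- The exact split-half reliability instrument used to select K in
  comparable studies is not reproduced; `match_states` provides a
  reasonable run-matching tool but is not claimed to replicate it.
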