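# Methods

This note documents the models, conventions and numerical choices behind
`pmsway`, in the order the pipeline applies them, together with what the
synthetic cohorts do and do not emulate.

## Posture space and preprocessing

A trial is a sequence of lab-frame marker coordinates (meters). The fixed
preprocessing order is: gap filling → trimming → downsampling → mirroring →
symmetric-marker selection → centering + height normalization → segment-mass
weighting → concatenation. Frame counts change only in trimming and
downsampling, and both changes are exactly predictable.

**Gap filling.** Marker occlusions are imputed by iterative truncated-SVD
reconstruction: missing cells are initialized by per-column linear
interpolation in time, then repeatedly replaced by a rank-`n_components`
(default 5) reconstruction of the temporally centered coordinate matrix until
the RMS change of the imputed cells drops below `tol = 1e-8` or 100
iterations. Observed cells are never modified. The scheme is exact on
noise-free low-rank trajectories; preconditions (no fully missing marker,
gap fraction < 50%) are enforced rather than worked around.

**Trimming and downsampling.** The first and last 10 s are dropped
(start-up and end-anticipation transients), and the series is decimated to
120 Hz (every second frame at 240 Hz) to limit noise amplification in the
double differentiation. No anti-alias prefilter is applied before decimation:
postural sway has negligible power near 60 Hz and a 7 Hz low-pass is applied
downstream anyway; decimation keeps the operation exactly reproducible.

**Mirroring.** Trials recorded left-foot-in-front are reflected about the
mediolateral axis and left/right marker labels are swapped, so all trials
describe the same stance. The mediolateral axis is **X** by package
convention (the axis is not dictated by the data; it is configurable).
Mirroring is an involution on coordinates. Asymmetrically placed markers
cannot survive this operation — they are dropped by the symmetric keep-list
(default: the Plug-in-Gait full-body set without hands and without the
wand/offset markers, 28 markers → 84 coordinates).

**Normalization and weighting.** Anthropometric differences are removed by
subtracting each trial's mean posture and dividing by the subject's height;
the result is dimensionless and invariant to rigid lab-origin translation.
Centering is **per trial** (not per subject across trials): "the mean
posture" is ambiguous across repeated stances, and per-trial centering also
removes slow inter-trial stance drift; a per-subject variant would be a
one-line change in `preprocess_cohort`. Each marker's three columns are then
multiplied by its relative segment mass `w` (Winter-style fractions, a
segment's mass split equally over its retained markers, renormalized to 1).
Weights are applied as `w`, matching common mass-weighted-coordinate
practice; note that only `√w` would make the PCA variance literally a
mass-weighted energy — `weight_markers` accepts any weight table, so the
`√w` variant is available by passing square-rooted weights.

## Kinematic PCA

The PCA is an eigendecomposition of the covariance (1/(n−1) convention) of
the concatenated, already-normalized matrix — no per-column
re-standardization, since the height and mass weighting *is* the intended
normalization. Eigenvector sign is fixed by making each component's
largest-magnitude loading positive, so refits are comparable. Scores,
velocities and accelerations use central differences
(`pv_t = (pp_{t+1} − pp_{t−1})·rate/2`, `pa_t = (pp_{t+1} − 2pp_t +
pp_{t−1})·rate²`) with one-sided stencils at the ends; central differences
are exact for quadratics and phase-error free.

Component retention uses the average-column-share rule: a PM is kept iff its
relative eigenvalue strictly exceeds `1/n_columns` (1.2% for 84 columns) —
below that, a component carries less variance than a single raw coordinate.

**Leave-one-out robustness.** The basis is refit with each subject's rows
removed (leaving out a subject, not a trial, since the subject is the unit
of independent variation); components are matched by eigenvalue rank and the
angle `arccos |PC_full · PC_loo|` is aggregated as a per-PM maximum. A PM is
robust when that maximum stays below 15°. Rank matching is correct for
well-separated eigenvalues; a greedy max-|dot| matcher is provided for
near-degenerate spectra, where eigenvector instability is expected and
flagged rather than hidden.

## Control measures

Both score series are conditioned before any measure: a zero-phase
(forward–backward) 6th-order Butterworth low-pass at 7 Hz. Zero-phase
filtering is deliberate — single-pass IIR filtering would shift zero-crossing
times and entropy templates; the price is a squared magnitude response
(single-pass is available via `zero_phase=False`). `PP` is additionally
detrended by subtracting a 501-sample (~4.2 s at 120 Hz) centered moving
average, with the first/last 250 subtracted values held at the nearest
fully-defined average; this removes slow postural drift exactly (degree-0/1
polynomials vanish in the interior) without inventing edge trends.

Processing order per component: `PP → low-pass → detrend → SaEn`;
`PA` (central-differenced from the *unfiltered* `PP`) `→ low-pass → SaEn, N,
σ`. Filtering before detrending keeps the 501-point average from smearing
filter transients. `N`/`σ` are computed on the filtered `PA` by default (the
unfiltered path is exposed via `filter_pa=False`).

**Sample entropy.** Delayed embedding
`u_i = [x(i), x(i+τ), …, x(i+(d−1)τ)]` for `d = m` and `m+1` over the common
index range; `B` and `A` count pairs `i<j` with Chebyshev distance ≤ `r`,
self-matches excluded; `SaEn = −ln(A/B)`. Defaults `m = 2`, `r = 0.2·SD`,
`τ = 12` samples = 100 ms at 120 Hz (a physiologically meaningful
neuromuscular latency). The lag enters the *embedding* — the series is not
subsampled, which would discard 11/12 of the data. `r` uses the SD of the
series as passed in, i.e. after all conditioning: the conditioned series is
what enters the template comparison (population-SD convention, `ddof=0`).
Degenerate cases are explicit: a constant series (r = 0) raises an
undefined-measure error; `A = 0` returns `+inf` with a warning. The table
builder converts both to sentinels without aborting. The O(N²) pair count is
a numba kernel with a chunked numpy fallback; both paths are checked against
an exhaustive pure-Python double loop to 1e-12.

**Zero crossings.** Exact zeros inherit the preceding nonzero sign (leading
zeros the following one), so a zero run contributes at most one crossing.
Crossing times are the time of the first sample after each sign change;
`σ` is the n−1 SD of successive inter-crossing intervals and is undefined
(NaN sentinel) below 3 crossings. For independent timing jitter `J` on the
crossing instants, interval SD converges to `√2·J`.

## Split-plot ANOVA

One between factor (age group) × one within factor (condition), two error
strata. The between effect is tested on subject means against
subjects-within-group; within effects are tested on subject-centered
responses against the condition × subjects-within-group residual. Within and
interaction sums of squares are **Type III** (sum-to-zero coding, model
comparisons), so unequal group sizes are handled as mainstream statistical
software does; with balanced groups the decomposition reduces to the
textbook formulas and effect SS partition the total exactly.

Sphericity: Mauchly's W on the pooled within-group covariance projected
onto orthonormal contrasts, with the first-order chi-square approximation on
`N − g` error dfs; ε_GG from the contrast-covariance eigenvalues; ε_HF as
the small-sample adjustment capped at 1 and floored at ε_GG. The correction
is applied only when Mauchly rejects at α = 0.05 (`always_correct` forces
it): both dfs are scaled by ε_GG when ε_GG < 0.75, else by ε_HF. With too
few subjects the pooled contrast covariance is singular; the test is then
reported as undefined (and no correction applied) rather than fabricated.

Effect size and power: `η_p² = F·df1/(F·df1 + df2)`; observed power is the
noncentral-F tail beyond the α critical value with `λ = F·df1` — the
convention of standard statistics packages — evaluated on the corrected dfs
when a correction was applied. Post-hocs are paired t-tests over all 10
condition pairs with Sidak adjustment `1 − (1 − p)^10` (family size logged
and configurable) and percent changes on condition means. Normality
(Lilliefors-style KS with estimated parameters, plus Shapiro–Wilk) and
Levene (center = mean) checks are advisory: they warn, never gate. Subjects
with any undefined cell in a variable × PM analysis are removed listwise,
with counts logged.

## Synthetic cohorts: what they emulate

`SyntheticCohortSpec` defaults describe the study design the generator
emulates: 23 + 18 subjects in two age groups (heights ~N(1.70, 0.10) and
N(1.60, 0.10) m), five 80 s trials per subject (single task + four dual-task
levels) at 240 Hz with 28 markers, and a dominant low-frequency eigenvalue
profile (51.1, 26.5, 9.7, 3.9, 2.6, 1.9% plus a geometric sub-threshold tail
starting near 0.9%, totalling 100%).

Each component's score series is a sum of three random-phase sinusoids from
a component-specific sub-band of 0.2–2 Hz (disjoint bands keep components
uncorrelated and make lower components slower, as in real sway) mixed with
1/f-filtered Gaussian noise; the noise weight `w ∈ [0,1]` is the
irregularity knob and maps monotonically to sample entropy. Condition
effects multiply `w` through a per-component template ("n" peaked at the
middle condition, "monotone", "flat"; default "n" with amplitude 0.15);
group effects add a constant (default +0.05 for the older group). The
emulated experiment reports only effect directions and percent changes, so
these amplitudes are free simulation parameters chosen once to produce
moderate, detectable effects. Series are rescaled to their exact planted
variance share; trials are mapped to lab coordinates by inverting the
normalization (scores → basis → × height), with optional isotropic marker
noise and occlusion gaps planted as geometric-length runs (mean 0.25 s) —
contiguous runs, not iid frames, because real occlusions are contiguous.

What the generator does **not** emulate: biomechanical segment constraints
(markers move freely in posture space), muscle/joint dynamics, non-planted
cross-component coupling, non-stationarity within a trial, and realistic
marker-noise spectra. Passing tests therefore demonstrate that the
*pipeline* recovers planted structure — eigenvalue spectra, entropy
orderings, condition/group effects — not that the pipeline's outputs on real
recordings would take any particular value.

## Problem sizes and determinism

Test and acceptance runs use scaled-down cohorts chosen to exercise every
code path at comfortable cost: typically 3–6 subjects per group, 30–60 s
trials, full 28-marker posture space, with Monte-Carlo calibrations at
500–1000 replicates on measure-level simulations (type-I error in
[0.03, 0.07]; power within ~3% of the noncentral-F prediction). All
randomness flows through `numpy.random.default_rng` seeds spawned from a
single cohort/config seed; identical seeds give bit-identical trials,
ledgers and measure tables.

## Known limitations

- C3D reading requires the optional `ezc3d` dependency; the native
  interchange format is wide CSV + JSON sidecar.
- Mirroring requires every `L*` marker to have an `R*` partner; genuinely
  asymmetric markers must be excluded from the keep-list (the default list
  already is symmetric).
- The Mauchly chi-square approximation is first-order (mainstream-software
  convention); second-order corrections differ in the third decimal of p.
- Type III between-group SS with more than two groups follows the weighted
  subject-means decomposition; the published design has exactly two groups,
  where weighted and unweighted coincide.
- Observed ("post-hoc") power is reported because the emulated analysis
  reports it; it is a deterministic transform of F and the dfs, not new
  evidence.
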