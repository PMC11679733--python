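# Methods

This note documents the models, numerical choices, and limitations of the
`affectflex` pipeline: what each stage computes, why the defaults are what
they are, and what the synthetic-data generator does and does not emulate.

## The design being analyzed

The pipeline targets a two-group, two-time-point psychophysiological
design. Subjects complete three cognitive-flexibility questionnaires
(CFI, CFS, CCFQ), then undergo an *affective storm* — 13 blocks of
emotionally evocative images whose 12 between-block transitions traverse
every ordered pair of the Russell circumplex quadrants exactly once
(12 images × 10 s per block; 156 images; 1560 s). Heart-rate-variability
(HRV) indices from 2-min baselines before (T0) and after (T1) the storm
quantify the physiological response; the contrast of interest is a
2 (group: Average vs. Extreme cognitive flexibility) × 2 (time) mixed
ANOVA per index.

## Synthetic cohorts (`synthcohort`)

No public recordings exist for this paradigm, so the generator produces
cohorts with the statistical structure the analysis assumes.

**RR model.** Beat-to-beat intervals are directly modulated sinusoids
plus white noise:

    RR_n = mean_rr + lf_amp·sin(2π f_LF t_n) + hf_amp·sin(2π f_HF t_n) + ε_n

with `f_LF = 0.10 Hz`, `f_HF = 0.25 Hz` (band centers of the standard LF
0.04–0.15 Hz and HF 0.15–0.4 Hz bands), `ε_n ~ N(0, noise_sd²)`, and `t_n`
the cumulative beat time. Direct beat-domain modulation was chosen over an
integral-pulse-frequency-modulation model because its band powers are
analytically predictable (a sinusoid of amplitude `a` contributes `a²/2`
ms² in its band; white noise of variance `σ²` spreads `σ²/(rate/2)` per
Hz), which makes the generator its own spectral oracle. The cost is
physiological realism: no respiratory coupling, no baroreflex dynamics,
no 1/f background. Intervals are truncated to the physiologic range
[300, 2000] ms with a logged count; silent resampling is deliberately not
done.

**Pulse waveform.** One raised-cosine bump (default width 300 ms) per
beat at 1024 Hz, optional additive white noise. The clean waveform has a
single local maximum per beat at the beat time, which gives beat
detection an exact ground truth.

**Cell calibration.** `DEFAULT_CELL_PARAMS` maps each (group, phase) cell
to `(lf_amp, hf_amp, noise_sd)` at `mean_rr = 850 ms`, `duration = 120 s`.
The mapping was fitted once: the three moment equations (SDNN², RMSSD²
with the sinusoid difference factors `(2 sin(π f T))²`, and the band-power
ratio with the white-noise band split) are solved for the published cell
means of SDNN, RMSSD and LF/HF, then refined by a short fixed-point
iteration against the package's own index pipeline (400 simulated
recordings per iteration). The shipped constants reproduce the published
cell means of SDNN and RMSSD to well under 1 % and LF/HF to ~3 %.

**Between-subject heterogeneity.** Two unit-mean lognormal factors per
subject, shared across T0 and T1 so phases are correlated within subject:
an overall variability scale (σ = 0.40, driving the between-subject SDNN
spread, coefficient of variation ≈ 0.42 as in the published tables) and
an LF/HF balance factor (σ = 0.60, multiplying `lf_amp` and dividing
`hf_amp` by its square root, driving the spread of the spectral ratio).
Unit means keep the cell means at their calibrated values.

**Questionnaires.** Scale scores are drawn normal-with-truncation
(truncation logged, never silent). Average-group means and SDs follow the
published questionnaire table. The Extreme group is a half/half mixture
of high and low scorers offset by ±δ per scale, with δ = √(SD²_ext −
SD²_avg): the published pattern of near-equal group means with roughly
double the SD in the Extreme group is exactly what such a mixture
produces. The offset sign is consistent across scales within a subject,
so cross-scale rank consistency is recoverable.

## Pulse processing (`pulse`)

* **Notch filter:** zero-phase IIR notch at 50 Hz, Q = 30, for power-line
  interference. Passband (< 10 Hz) gain is unity to well under 1 %.
* **Beat detection:** the classic five-stage energy detector (band-pass →
  derivative → squaring → moving-window integration → adaptive
  dual-threshold peak picking with a 250 ms refractory period),
  re-parameterized for pulse waves: the band-pass is 0.5–8 Hz rather than
  the ECG QRS band, and the fiducial is refined to the local maximum of
  the band-passed signal — the pulse peak — with parabolic sub-sample
  interpolation. All filtering is forward–backward, so beat times carry
  no filter delay. The integration window is 150 ms and centered, keeping
  the energy peak aligned with the (symmetric) pulse.
* **Edge guard:** detections within 0.5 s of the record edges are
  discarded. The 0.5 Hz high-pass edge of the band-pass has a transient
  of a few seconds; together with pulses truncated by the record
  boundary, edge fiducials are biased by over a millisecond while
  interior fiducials are accurate to ~0.1 ms on clean signals. The
  detector therefore reports one beat fewer at each edge rather than two
  wrong ones.
* **Artifact correction:** an interval deviating from its 5-beat running
  median by more than 30 % (relative) is flagged and replaced by a cubic
  spline through unflagged neighbors; flags are preserved for audit.
  Clustered artifacts can capture the running median itself, so a second,
  looser check flags intervals more than 60 % away from the global
  median — genuine slow drift never reaches that. If more than 20 % of
  intervals are flagged the recording is marked unusable instead of
  repaired. This automated rule replaces manual visual inspection; it is
  idempotent on its own output.

## Tachogram and detrending (`tachogram`)

Spectral analysis needs uniform sampling: the RR series (each interval
anchored at its ending beat time) is cubic-spline interpolated onto a
4 Hz grid spanning first to last beat. Slow trends are removed with the
smoothness-priors method: trend = `(I + λ² D₂ᵀD₂)⁻¹ x` with
second-difference operator `D₂` and λ = 500, the conventional value for
short HRV recordings (cutoff ≈ 0.035 Hz at 4 Hz sampling, i.e. just below
the LF band). The solve uses a sparse factorization; it matches a dense
solve to 1e-8 *relative to signal magnitude* — at λ = 500 the system's
condition number (~4·10⁶) makes tighter absolute agreement between
independent solvers unattainable in double precision. Because the
smoother's rows sum to one, the residual has exactly zero mean (enforced
to the last bit by subtracting the numerical round-off mean). The
operation is linear; λ → 0 removes everything, λ → ∞ removes only the
best straight line.

Time-domain and Poincaré indices are computed from the corrected
beat-to-beat series, *not* the detrended tachogram — standard HRV
practice; a config flag (`detrend_before_time_domain`, default off)
switches to the tachogram-based variant for sensitivity analyses.

## Indices (`indices`)

* **Time domain:** RMSSD, SDNN, SD HR (per-interval instantaneous HR =
  60000/RR), HR mean and RR mean. Sample (n−1) variances throughout —
  this convention is what makes the published SE = SD/√n relations come
  out at the printed precision.
* **Spectral:** Burg autoregressive fit (default order 16, the common
  HRV-software default; the order is exposed because short records give
  no principled way to fix it) on the detrended tachogram; the parametric
  PSD is evaluated on a dense grid (2¹⁷+1 points up to Nyquist — near-pure
  oscillations give very sharp AR peaks, and the grid must resolve them
  for band integrals to be trustworthy) and integrated by the trapezoid
  rule over VLF (≤ 0.04 Hz), LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz).
  Normalized units use LF+HF as the denominator; VLF is unreliable on
  2-min records and is excluded. Recordings under 120 s trigger a warning
  rather than an error — the 2-min baselines of this design are
  themselves at the short end for LF estimation.
* **Poincaré:** SD1 and SD2 are the SDs of the rotated lag-1 return-map
  coordinates `(x_{n+1} ∓ x_n)/√2` — the ellipse half-axis definitions.
  SD1² equals Var(ΔRR)/2 exactly; SD2² equals the familiar closed form
  2·Var(RR) − SD1² up to O(1/n) edge terms, and the pair-based definition
  is used precisely so that the ellipse equivalence holds to machine
  precision at any n. A constant series yields SD1 = SD2 = 0 and an
  undefined (NaN) ratio with a degeneracy flag.

## Stimulus design (`storm`)

Quadrant membership uses strict thresholds on 1–9 SAM norms: high arousal
or positive valence requires ratings strictly above 6, low arousal or
negative valence strictly below 4; boundary ratings map to no quadrant.
A 13-block sequence covering all 12 ordered transitions exactly once is
an Eulerian circuit of the complete directed graph on four vertices
(balanced in/out degrees, so a circuit exists and must close on its start,
which therefore hosts 4 of the 13 blocks); it is built with Hierholzer's
algorithm over a seed-shuffled edge order. Images are drawn without
replacement across the whole run — repetition would confound habituation
with transition effects — so a quadrant's eligible pool must cover
(blocks of that quadrant) × 12 images; the synthetic pool generator
samples ratings uniformly inside the open corner regions with a 0.05
margin off the thresholds.

## Grouping (`flexgroup`)

Five scale scores are computed (CFI-Alternatives and CFI-Control as item
means on 1–7; CFS as item mean on 1–6; the two CCFQ subscales as 9-item
sums on 9–63, reverse-keyed items supported). Ranking uses four of the
five (default: CFI-Alt, CFI-Ctrl, CCFQ-CCE, CCFQ-ACF; the source
describes four ranking scores while naming five scales, so the set is
configurable and CFS can be swapped in). Percentiles are
rank/(n+1)·100 with average ranks for ties; per score a subject is High
(> 75th), Low (< 25th) or Average; the final label requires agreement on
at least 3 of the 4 scores, otherwise Unclassified (excluded from group
analysis with a logged count). "Average" is read as the open interval
between the quartile cuts — the only reading under which roughly half a
cohort lands in the middle group. High and Low merge into "Extreme".
Everything is rank-based, hence invariant under strictly monotone
per-scale transforms, and fully deterministic.

## Statistics (`stats`)

* **Mixed ANOVA.** With two within-subject levels the split-plot design
  decomposes exactly: per subject `m = (y₀+y₁)/2` and `d = y₁−y₀`; group
  is a between-subjects ANOVA on `m`, time tests the unweighted grand
  mean of `d` against zero, the interaction tests the group difference of
  `d`; all effects have df (1, N−2) and sphericity is vacuous. Unequal
  group sizes use unweighted marginal means (the Type-III convention of
  mainstream statistics GUIs). The implementation is verified against an
  independent effect-coded design-matrix GLM with error-strata sums of
  squares. Partial eta squared uses the identity
  ηp² = F·df1/(F·df1 + df2).
* **Normality:** Shapiro–Wilk plus Kolmogorov–Smirnov with the
  Lilliefors correction (the normal's parameters are estimated from the
  sample, so the plain KS null distribution would be wrong).
* **JZS Bayes factor:** two-sample t-test Bayes factor with a Cauchy
  prior (default scale √2/2) on the standardized effect size, evaluated
  as a one-dimensional adaptive-quadrature integral over the
  inverse-gamma mixing variable (relative tolerance 1e-8, well inside the
  1e-6 contract). Both BF₁₀ and BF₀₁ are always reported, along with the
  prior scale. Used on the pre-experimental (T0) indices to quantify
  evidence that high- and low-flexibility extremes share a physiological
  profile.
* **A-priori sample size:** noncentral-F power for the within–between
  interaction with λ = N·f²·m/(1−ρ), df = ((g−1)(m−1), (N−g)(m−1)),
  N rounded up to a multiple of g. With f = 0.30, α = 0.05, power 0.95
  and ρ = 0.5 this yields N = 40 (power at N = 38 is 0.9493 — just
  short).

## Orchestration (`cli`)

A thin `click` CLI (`affectflex simulate | design-storm | process | group
| analyze | report`) over the library: YAML config with flag overrides
(flags win), a provenance record (config SHA-256, seed, full parameter
set) written with every run, WARNING-level logs for every automated
correction and exclusion, and exit codes 0 (success), 2 (validation
error), 3 (data-quality abort). Per-subject processing failures are
logged and skipped; more than 20 % failures aborts the run.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to keep the default suite
fast while leaving Monte-Carlo error well inside the asserted tolerances:
SDNN/RMSSD recovery averages 30–50 recordings of 300 s; the calibration
recovery check averages 200 cohorts; the interaction type-I error check
uses 2000 null replicates; the LF/HF interaction detection check uses 40
full cohorts through the complete spectral pipeline (rejection rate
observed ≈ 0.95, so 40 replicates decide "majority" with margin); JZS
null behavior uses 200 replicates.

## Known limitations

* The RR generator's two-tone-plus-noise spectrum is far simpler than
  real HRV (no respiratory frequency wander, no nonstationarity within a
  baseline, no 1/f component); passing recovery tests demonstrate the
  pipeline's correctness on signals with known structure, not
  field-readiness for clinical data.
* The pulse template is a symmetric bump; real photoplethysmograms are
  asymmetric with dicrotic notches, so the detector's sub-millisecond
  accuracy here is an upper bound.
* Artifact correction emulates, but is not, expert visual inspection.
* Between-subject calibration matches published cell means and
  approximate SDs; higher moments and true pre–post correlations are
  unknowable from summary tables.
* 2-min records make LF (and therefore LF/HF and normalized units)
  noisy; the package warns but does not refuse.
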