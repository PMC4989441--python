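# Methods

This note records the scientific and numerical choices behind
`cardiostate`: what each stage assumes, which parameters matter, what
the synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Synthetic cohort

Clinical recordings of this kind are rarely shareable, so the package
ships a generator whose outputs carry full ground truth. Each
subject-state is a set of coupled phase oscillators:

- **Respiration**: instantaneous frequency = mean rate + slow
  Ornstein–Uhlenbeck (OU) wander (τ = 60 s) + band-limited sinusoidal
  modulations; the channel is `sin φ_r` plus white measurement noise.
  OU wander (rather than white noise) keeps instantaneous rates
  physiological and differentiable.
- **Cardiac phase**: dφ_h/dt = 2π(mean HR + RSA·sin φ_r + Σ band
  modulations + common drive + OU jitter). R-peak times are the 2πk
  crossings; the ECG channel places a fixed Gaussian-difference beat
  template at each (only R timing matters downstream). Respiratory
  sinus arrhythmia (RSA) enters as a frequency modulation at the
  breathing rate, producing HRV energy in interval II.
- **Phase locking**: when a ratio m:n (m breaths : n beats) is set,
  locked episodes integrate dφ_h = (n/m)dφ_r with a weak restoring term
  −κ·sin(ψ), ψ = n·φ_resp − m·φ_heart, so ψ stays bounded (exactly
  constant when jitter is zero). The locked fraction of the record is a
  per-state parameter; episodes are ~90 s.
- **Pulse**: `1 − cos φ_h(t − PTT)` — minima (pulse feet) arrive
  exactly one transit time after each R-peak.
- **Conductivity**: baseline level + slow OU drift + band modulations +
  Poisson-timed sweat bursts (fast rise, ~5 s decay).
- **Temperatures** (wrist, ankle): baseline + low-frequency
  oscillations + a small cardiac-frequency ripple that carries the
  pulse–temperature coherence in interval I.
- **Common low-frequency drive**: one ~0.1 Hz oscillator per subject,
  coupled into HRV, conductivity, pulse and temperature. This is what
  gives the awake state its coherent myogenic-band activity; the
  anaesthetised states reduce the couplings by an order of magnitude.

Default state parameters follow the clinical cohort the method was
developed on: mean HR 1.07 Hz (between-subject SD 0.16), respiratory
rate 0.22 Hz awake → 0.37 Hz under sevoflurane (0.23 under propofol),
skin temperature 30 °C rising ~2 °C, conductivity falling ~35%
(log-normal between-subject spread), PTT 0.18 s rising 17%
(sevoflurane) / 11% (propofol), HRV modulation depths reduced across
all bands by sevoflurane but mainly in the slowest bands (V, VI) by
propofol, sweat-burst rate halved, and the phase-locked fraction
roughly doubled (0.05–0.15 → 0.15–0.30 of the record). Awake HRV
modulation amplitudes (0.036–0.09 Hz per band) were chosen once as
typical resting values large enough that locking-transition transients
do not dominate the variability budget.

What the generator does **not** emulate: realistic ECG/pulse morphology,
ectopic beats or movement artefacts, drug pharmacokinetics, non-
stationary drift of state during a recording, and the order-of-magnitude
between-subject conductivity range of real skin. Passing tests therefore
demonstrate that the analysis recovers known dynamics from clean
oscillatory signals — not robustness to clinical artefacts.

## Event detection and variability series

R-peaks: band-pass 5–30 Hz (bypassed at fs ≤ 100 Hz where that band is
most of the spectrum), squared derivative, adaptive threshold at half
the blockwise (10 s) 95th percentile, 0.25 s refractory, apex refinement
on the raw ECG with parabolic sub-sample interpolation. Breath maxima:
low-pass at 1.2 Hz first — respiratory effort lives below 0.6 Hz and
broadband noise otherwise shifts the flat peaks — then prominence-gated
peak picking with a 1 s refractory. Pulse feet are the per-beat minima
of the (integrated) pulse, same machinery inverted.

Variability series assign instantaneous rate 1/interval at interval
midpoints and interpolate linearly onto a uniform 10 Hz grid, held flat
beyond the first/last midpoint (edge samples are excluded from band
averages downstream by the cone-of-influence mask). Rates (Hz), not
intervals (s), are used throughout so that band energies have units
Hz². The midpoint-linear scheme attenuates rate modulations approaching
half the beat rate; band II RFV/HRV estimates near the respiratory
frequency are therefore conservative.

PTT matches each pulse foot to the latest preceding R-peak within
0.6 s; each R-peak is used at most once and unmatched beats are skipped.

## Wavelet analysis

Analytic Morlet with ω₀ = 6 (the standard admissibility/resolution
compromise), 50 voices per decade, computed by circular FFT
convolution. Edge wraparound is confined to the cone of influence
(e-folding time √2·s per scale s), which every time average excludes.
Band energy integrates |W(f,t)|²/f over log-frequency and averages over
the COI interior; the filter gain is calibrated so that a unit-amplitude
sinusoid contributes exactly its variance A²/2 at any frequency,
sampling rate and record length. Interval energies therefore form an
additive variance decomposition and two equal-amplitude oscillations
carry equal energy regardless of band. Rate series are mean-detrended,
raw conductivity/temperature linearly detrended, before transforming.

Interval VI (0.005–0.0095 Hz) extends the five established intervals
contiguously below the endothelial band; it exists because the
conductivity/temperature attribute set references it, and its
definition here is a declared convention.

## Phase coherence and surrogates

Coherence is the modulus of the time-averaged unit phasor of the phase
difference over the joint COI, computed only where at least five
oscillation periods fit inside it (below that the estimator is mostly
bias). Significance uses inter-signal circular time-shift surrogates:
the second signal is rolled by a random offset ≥ 30 s, which preserves
its marginal distribution and spectrum exactly while destroying
cross-alignment — the weakest sufficient null for "these two signals
are aligned". Because the transform itself is a circular convolution,
rolling the coefficient matrix *is* the transform of the rolled signal,
so 99 surrogates cost little more than one.

The threshold is the rank-based order statistic (the 95th of 99
surrogates at α = 0.05): observed coherence is significant where it
exceeds all but ⌈(1−α)(n+1)⌉−1 surrogates, the exact exchangeable-set
criterion. Two caveats are documented deliberately: (i) no multiplicity
correction across frequencies (per-frequency shading is the reporting
convention); (ii) with shifts drawn at random, surrogates can fall
closer to each other than the wavelet decorrelation time, which makes
the empirical threshold slightly anti-conservative on short records —
on 30-minute records the realised type-I error is ≈ 0.06 at nominal
0.05, measured by the acceptance suite. Deterministic, strictly
periodic shared components survive time-shifting (their phase
difference is constant under any lag), so surrogate significance speaks
to aligned *aperiodic* dynamics.

Group contrasts (awake vs anaesthetised curves) use an unpaired
rank-sum test per frequency at α = 0.05; contiguous significant runs
are reported with the physiological intervals they overlap. A paired
variant is available; the group-level contrast is the default because
the published comparison is between group-average curves.

## Synchronisation

Ratio notation: m:n means m breathing cycles per n heartbeats, so the
generalized phase difference is ψ = n·φ_resp − m·φ_heart (bounded under
lock). The index is the circular-mean ("mean phase coherence") form
γ = |⟨exp iψ⟩_window|, which satisfies γ = 1 ⇔ ψ constant — the exact
property behind a "95% of perfect synchronisation" threshold; a
normalised-entropy variant is available behind a flag. Windows are 6T
for 1:n and 8T for 2:n ratios (T = mean respiratory period), sliding at
1 s; candidate ratios are 1:n for n within ±2 of round(HR/RR) and 2:n
for odd n spanning the same range in half-integer steps. Total
synchronisation time is the measure of the union over ratios of
{γ ≥ 0.95} — overlapping ratios are not double-counted. The literal
reading γ ≥ 0.95 is implemented (rather than a null-calibrated 95th
percentile), which is the plainer interpretation of the threshold.

## Cohort statistics

Signed-rank (paired, zero differences discarded, exact null for n ≤ 25
without ties), rank-sum (exact for small tie-free samples) and
two-sample KS (exact small-sample distribution) are delegated to
scipy.stats behind this module's surface; the test suite checks them
against independent full-enumeration oracles for n ≤ 8. All p-values
are two-sided, with no multiple-testing correction — per-variable
reporting is the convention mirrored, and the caveat stands. Attribute
screening keeps a variable if any pairwise group KS test is significant
at α = 0.05 (an awake-vs-pooled-anaesthetised mode is also provided).

## Classification

Feature vectors take the three attribute subsets — mean values (9),
wavelet band powers (15), interactions (12: coherence band means,
synchronisation time and the two window lengths) — plus a reduced
12-attribute "optimal" set (mean respiratory rate; total HRV and RFV
energies; mean temperature; synchronisation time; both window lengths;
pulse–temperature coherence I; HRV energy III and IV; RFV energy V;
conductivity energy VI). Attributes are z-scored using training-fold
statistics only.

The metric A is restricted to a non-negative diagonal: the full
positive-symmetric optimisation is under-determined at cohort sizes of
tens of subjects, while diagonal weights preserve positive
semi-definiteness trivially and stay interpretable. Weights are learned
by coordinate-wise search over a logarithmic grid (2⁻⁴…2⁴ plus exact
zero), objective = internal leave-one-subject-out NN accuracy, ties
broken toward weight 1. A grid rather than golden-section search is
used because the objective is piecewise constant (accuracy), so
bracketing-based line search has no convergence guarantee; starting
from the identity and accepting only improvements guarantees the
learned metric never scores below the identity on its own training
set. Weights are normalised to trace = dimension.

Nearest-neighbour ties break by class order (awake < sevoflurane <
propofol) then subject id, implemented by canonical row ordering so
results are exactly reproducible. Evaluation: repeated stratified
hold-out (default 200 repeats, 50% splits stratified by agent arm) and
leave-one-subject-out CV; both records of a subject always fall on the
same side of a split, preventing identity leakage. Confusion counts are
pooled and reported with row-percentages; a merged mode collapses the
two anaesthetised classes. The attribute cascade runs greedy backward
elimination within each subset by LOSO accuracy (identity metric, for
speed and stability of the selection criterion), merges the survivors
and runs a final pass; it never returns an empty set.

The pipeline enables metric learning only when every class keeps at
least four training subjects per fold (the full default cohort does;
smoke-scale cohorts fall back to the identity metric).

## Pipeline and problem sizes

All slow-band analysis runs on a common 10 Hz grid (rate series
natively; conductivity/temperature/pulse FIR-decimated), since every
analysed frequency is ≤ 2 Hz. The default study conditions are 15 + 12
paired subjects, 600 s per state at 100 Hz — 600 s resolves interval V
with usable COI interior while keeping a full cohort analysis around a
minute on one CPU; the surrogate type-I calibration uses 30-minute
noise records, matching the recording duration the protocol prescribes.
Reports are delimited text plus a JSON manifest (seed, config hash,
versions); a re-run against an existing bundle with the same hash is
skipped.

## Known limitations

- The synthetic cohort is the only validation substrate; absolute
  energy/coherence levels are not calibrated to any clinical dataset,
  and classification accuracies on it should be read as sanity figures,
  not clinical performance.
- Band II variability estimates are attenuated near the respiratory
  frequency by the midpoint-linear rate interpolation.
- Surrogate thresholds are per-frequency and slightly anti-conservative
  on records much shorter than 30 minutes.
- No artefact handling (ectopy, motion, sensor detachment) and no EDF
  reader; recordings exchange as delimited text.
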