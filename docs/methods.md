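# Methods

`emgcancel` simulates the chain from common synaptic input to surface
EMG and isometric force for a pool of motor units, and quantifies how
*amplitude cancellation* — the loss of rectified-EMG amplitude caused
by overlap of positive and negative phases of motor unit action
potentials — distorts the association between the frequency content of
the neural drive and the rectified EMG.  This note documents the model,
its assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Signal model

The neural drive to the muscle is represented by the cumulative spike
train (CST), the binned sum of all motor unit spike trains.  Two EMG
signals are synthesized from the same spikes: the interference EMG
(`emg = Σ_i δ_i * p_i`, with `p_i` the unit's surface action-potential
template) and the no-cancellation EMG (`emg_nc = Σ_i δ_i * |p_i|`), in
which templates are rectified *before* summation so opposite phases of
different units can no longer cancel.  The cancellation signal is
`c(t) = emg_nc(t) − |emg(t)| ≥ 0`, and the cancellation index of a
record is `mean(c)/mean(emg_nc)`.

The `theory` module verifies numerically, on constructed drive/template
pairs, that for a non-negative drive `s`:
`R_{emg_nc,s}(τ) = R_ss(τ) * |p(τ)|` (hence the cross-spectrum is
`G_ss·H_p` and a perfect correspondence with the drive would require a
delta-like rectified template), and that
`R_{|emg|,s}(τ) ≤ R_{emg_nc,s}(τ)` at every lag, with equality exactly
for non-negative templates.  In discrete time both statements hold
algebraically up to boundary terms, so the verifications are exact
pass/fail with estimator tolerances scaling as duration^(−1/2).

## Common input and independent noise (`common_input`)

Every motoneuron receives `offset + G2·Σ_f G1_f sin(2πft + φ_f)`
(f = 1..30 Hz) plus an independent noise current.  `G1_f ~ U(0,1)` and
`φ_f ~ U(0,2π)` are redrawn each repetition.  Drive values are currents
in µA injected into the soma (offset 3.5·10⁻³ µA = 3.5 nA); the study
grid uses offsets {3.5, 3.8, 4.0, 4.3}·10⁻³ and G2 ∈ {5.7·10⁻⁵,
1.5·10⁻⁴, 2.4·10⁻⁴}.  Noise is white Gaussian, low-pass filtered below
100 Hz (zero-phase 4th-order Butterworth — the filter dialect is a
choice; only the cutoff is fixed by the model description) and scaled by
a gain calibrated so that, with the common variability off, the median
inter-spike-interval coefficient of variation of steadily discharging
units (≥ 8 pps) is 0.2, the midpoint of the physiological 10–30 % band.
Restricting the statistic to steady units keeps the bisection
well-conditioned; sputtering near-threshold units have arbitrarily
large CoV and would dominate a pooled median.  Calibration is performed
once per pool size at the centre of the offset range and reused across
conditions.

## Motoneuron pool (`motoneuron`)

Each unit is a two-compartment (soma/dendrite) conductance-based
neuron.  Potentials are relative to rest (0 mV); sodium reverses at
+120 mV and potassium at −10 mV (the printed magnitude is 10 mV; a
potassium reversal above rest could not repolarize, so the sign follows
the source model of this neuron class).  Membrane capacitance is
1 µF/cm², axial resistivity 70 Ω·cm; soma-specific resistance spans
1.15→0.65 kΩ·cm² and dendrite-specific resistance 14.4→6.05 kΩ·cm²
across the pool.  The soma carries Na, fast-K and slow-K conductances
with gating variables (m, h, n, q) driven by a pulse-based scheme: a
rising crossing of the firing threshold switches the opening rates on
for 0.6 ms, after which the variables relax with their closing rates.
Gating and membrane equations are advanced with exponential-Euler
updates (exact for the piecewise-linear gating) at dt = 0.05 ms; spike
times are rising crossings of +60 mV with a 5 ms dead time.  The
integration loop is compiled with numba.

Two population-structure choices matter and were fixed by pilot tuning
(`tools/tune_pool.py`) against the model's printed population
behaviour (recruitment 18 % at 5.9 pps at the lowest offset, ~53 %
recruited at the highest, +22 recruitment points from the lowest to the
highest common-input gain, ISI CoV 10–30 %):

* **Exponential threshold density.**  The population coordinate is
  warped (`recruitment_skew = 2`) so recruitment thresholds have an
  approximately exponential density — many low-threshold, few
  high-threshold units — while every per-unit parameter still spans its
  printed range.  With log-uniform spacing instead, the printed
  recruitment fractions at the two offset extremes cannot both be met.
* **Graded after-hyperpolarization.**  The slow-K decay rate spans
  0.09→0.22 ms⁻¹ (AHP longest in the smallest units), giving low,
  irregular discharge near recruitment and ~18–26 pps for low-threshold
  units at the highest offset, without discharge-rate saturation: once
  recruited, rates increase monotonically with the offset.

Unprinted geometry (soma 77.5–82.5 µm, dendrite diameter 41.5–62.5 µm,
length 5.5–6.8 mm) follows the source model of this neuron class; the
firing threshold (8.05 mV) and maximal conductances are calibration
constants frozen in `parameters.yaml`.

### Known limitation: mean rate over recruited units

A unit is "recruited" when its mean rate over the record is ≥ 1 pps.
Under this definition the recruited set at the highest offset
necessarily includes a tail of near-threshold units discharging
sporadically (the same noise margin that produces 18 % recruitment at
the lowest offset).  That tail caps the mean discharge rate over
recruited units near ~18–20 pps at the highest offset in this
implementation; reported reference behaviour for this quantity
(~28 pps) could not be reproduced jointly with the recruitment
fractions, and the recruitment fractions were prioritized because they
constrain the input generator itself.

## Surface EMG (`emg`)

The full fibre-level multilayer cylindrical volume conductor is out of
scope; templates come from an analytic line-source kernel.  Each unit
innervates 6–69 fibres (exponential profile) scattered in a 2 mm
territory around the unit centre; centres are drawn uniformly in the
printed selection disc (radius 7 mm at depth 5.3 mm below the electrode
for 100 units; 14 mm at 10.5 mm for 400), restricted to the muscle
layer.  A fibre's contribution is a zero-mean biphasic wave
`u·exp(−u²)` propagating at 4 m/s from the innervation zone (scattered
over the printed 10 mm region) and detected bipolarly at the two
electrode sites 10 mm apart, midway between innervation zone and fibre
end.  Tissue filtering is phenomenological: amplitude decays as
`exp(−depth/λ)` with λ = 3.0 mm, and the
temporal width grows with depth as `w = (2.75 + 0.25·depth) ms`.  These
two constants were calibrated so the interference-EMG median frequency
of low-variability conditions falls at ~72 Hz and the cancellation
index spans ~37–71 % across the grid extremes.  All printed geometry
and conductivity values are retained on `VolumeGeometry` even where the
simplified kernel does not consume them.

Each repetition uses one of 15 electrode sites ("libraries").  Sites
differ anatomically: every library redraws the unit positions in the
selection disc, offsets the territory depth by U(−2.5, 2.5) mm and
scales the width law by U(0.80, 1.30).  (A per-site re-pairing of the
innervation profile with the units is available through
`innervation_rank_jitter` but is off by default: it destroys the
drive/EMG association of sparsely active conditions, where one or two
units dominate the electrode.)  The inter-site dispersion bounds the
repetition-to-repetition association between CST and EMG_nc line
powers (r² well below 1) and gives the raw-EMG median frequency its
spread across repetitions; without it the reproduced associations
saturate near 0.85 and the cancellation/association anticorrelation
disappears.

## Force (`force`)

Twitches are critically damped second-order impulse responses
`h_i(t) = P_i (t/T_i) e^{1−t/T_i}` with peak amplitudes spanning a
100-fold range and contraction times 30–90 ms, exponentially
distributed and rank-inverse associated (many small, slow units).  The
per-spike gain follows the standard twitch-summation nonlinearity on
the normalized instantaneous rate `T_i/ISI`: unity at or below 0.4,
sigmoidal fusion above.  MVC is the fused-plateau force with every unit
at its peak rate, 35 pps for the smallest declining to 25 pps for the
largest unit (an onion-skin profile).  Force statistics are computed on
the steady part of the record (after a 2 s settle; shorter for very
short records) so the contraction onset does not inflate the standard
deviation.

## Study orchestration and problem sizes (`experiment`)

A condition is (pool size, G2 level, offset); the full grid crosses
{100, 400} units with 3×4 − 1 = 11 combinations each (the highest-G2 /
highest-offset cell is excluded as it drives contraction above the
model's validity range), 22 conditions at 15 repetitions.  Seeding is
hierarchical (master seed → condition → repetition → ingredient), and
the manifest records every repetition's entropy so any run is
replayable in isolation.

The package's reference profile, used by the tests and the acceptance
script, is the 100-unit half of the grid: 11 conditions × 25
repetitions of 6 s records (the extra repetitions over the full
study's 15 stabilize the squared-correlation estimates at a fraction
of the full study's record length).  Record duration is a free parameter of
the model description; it sets the scale of the two 1/duration noise
floors in the line-power estimates (the CST's shot noise and the
cancellation noise in the rectified EMG) relative to the imposed-line
power, and 6 s places the weakest common-input level in the same
estimator regime as the published association values.  Longer records
(the `duration` argument) strengthen all associations uniformly.  The
analysis extracts line power at the 30 imposed integer frequencies from
single boxcar periodograms (records must span whole seconds so the
lines fall on bins), correlates CST against rectified-EMG and EMG_nc
powers across the repetitions of each condition, and averages r² over
the delta (1–5 Hz), alpha (6–15 Hz) and beta (16–30 Hz) bands.  The
regression is on power, not amplitude (the choice is frozen; amplitude
regression gives slightly higher, not lower, associations here).

## What the generator does and does not emulate

The synthetic study reproduces: graded recruitment with many
low-threshold units, irregular near-threshold discharge, common-drive
coherence across the pool, depth- and site-dependent surface
potentials, amplitude cancellation as an emergent overlap phenomenon,
and twitch low-pass force generation.  It does not emulate: rate
saturation of low-threshold units, persistent inward currents, motor
unit synchronization beyond common drive, electrode noise or movement
artifact, muscle fatigue, or series-elastic dynamics.  Passing tests
therefore speak to the signal-processing claim — how cancellation
degrades the rectified EMG as a drive estimator — not to a complete
physiological account of any particular muscle.

## Numerical choices and degenerate inputs

Exponential-Euler updates are unconditionally stable for the gating
ODEs; a NaN state aborts integration with the offending unit and time.
Spike binning clips to the last bin; empty spike-train sets yield
all-zero CSTs and a flagged (0, 0) recruitment summary.  The
cancellation index raises on silent records.  Periodogram extraction
refuses non-integer-second records rather than tolerate off-bin
leakage.  Zero-variance line powers yield NaN r² and are excluded from
band means.  Noise-gain calibration raises with diagnostics when the
target CoV cannot be bracketed.
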