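# emgcancel

Simulation and analysis of **EMG amplitude cancellation** — the loss of
rectified surface-EMG amplitude caused by overlap of positive and
negative phases of motor unit action potentials — and of how it
distorts the association between the frequency components of the
**neural drive to muscle** and the rectified EMG.

The rectified surface EMG is routinely used as a stand-in for the
neural drive (the ensemble of motor neuron discharge timings, here
represented by the cumulative spike train, CST).  This package is for
motor-control and EMG researchers who want to quantify when that
practice is justified.  It simulates the full chain:

* **common synaptic input**: an offset plus 30 sinusoids (1–30 Hz) with
  repetition-random amplitudes `G1_f ~ U(0,1)` and phases, scaled by a
  variability gain `G2`, plus independent sub-100 Hz Gaussian noise
  calibrated to a 10–30 % inter-spike-interval coefficient of
  variation;
* a **conductance-based motoneuron pool** (two compartments, gating
  variables m, h, n, q; 100 or 400 units with exponentially distributed
  recruitment thresholds — many low-threshold, few high-threshold
  units);
* a **surface EMG model** producing, from the same spike trains, the
  interference EMG `emg = Σ_i δ_i * p_i` and the experimentally
  unmeasurable no-cancellation EMG `emg_nc = Σ_i δ_i * |p_i|`;
* a **force model** (critically damped twitches, 100-fold amplitude
  range, rate-dependent gain, %MVC normalization).

Amplitude cancellation is the signal `c(t) = emg_nc(t) − |emg(t)| ≥ 0`,
summarized per record by the cancellation index
`mean(c)/mean(emg_nc)`.  The analysis extracts periodogram line power
at the 30 imposed frequencies from the CST and both EMG signals,
computes the squared correlation `r²` of line powers across the
repetitions of a condition, and relates band-averaged `r²` (delta
1–5 Hz, alpha 6–15 Hz, beta 16–30 Hz) to contraction level and
cancellation.  A `theory` module verifies the analytical core
numerically: `R_{emg_nc,s}(τ) = R_ss(τ) * |p(τ)|`, its spectral form
`G_{emg_nc,s} = G_ss · H_p`, and the ordering
`R_{|emg|,s}(τ) ≤ R_{emg_nc,s}(τ)` for all lags — the no-cancellation
EMG is never the worse estimator of the drive.

See `docs/methods.md` for model details, assumptions and limitations.

## Worked example

```sh
python examples/emg_cancellation.py
```

```
total spikes: 5862
median frequency of raw EMG: 69.9 Hz
mean |EMG| / mean EMG_nc:    0.34
cancellation index:          65.5 %
```

One 10 s contraction at a middle grid condition (offset 4.0·10⁻³ µA,
low common-input variability): about 40 % of the pool discharges at
~14 pps, the raw interference EMG has a physiological median frequency
(~70 Hz), and the rectified EMG retains only ~34 % of the amplitude of
its no-cancellation counterpart — the remaining ~66 % is cancelled by
overlapping opposite-sign action-potential phases.

Other examples: `common_input_demo.py` (line power of the synthetic
drive vs. the closed form), `pool_recruitment.py` (recruitment and
discharge rates across offsets), `force_steadiness.py` (force
variability vs. common-input strength), `theory_checks.py` (the three
analytical identities), and `run_study.py` (the reduced condition grid
with its summary statistics).

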