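# Methods

## Scope and data model

`isletpulse` analyses per-cell fluorescence time series from calcium
imaging of pancreatic islets. The in-memory containers are deliberately
minimal: a `TraceMatrix` (frames × cells, arbitrary units, sampling rate
`fs` in Hz), an `IsletGeometry` (cell centroids in µm, 2-D or 3-D) and a
`StimulusProtocol` (time-ordered glucose boluses, single-cell illumination
windows with a named target, an optional KCl depolarization, and a
pre-stimulus baseline window). All analysis works in seconds internally;
frames appear only at the I/O edges, converted through `fs`.

## Normalization

Two per-cell normalizations serve different purposes and are never mixed:

- **min-max**, (Fₜ − F_min)/(F_max − F_min): maps each cell onto [0, 1] so
  that onset latencies are comparable across cells and islets with
  different brightness. The reference window for F_min/F_max is the
  per-stimulus epoch when the protocol contains several boluses (each
  injection is analysed separately, and a cell that responds strongly to
  one bolus and weakly to another would otherwise never cross threshold in
  the weak epoch), and the whole session for single-bolus protocols; a
  config switch (`minmax_scope`) forces either.
- **baseline**, (Fₜ − F_min)/F_min: a dF/F-style relative change with no
  imposed ceiling, used for all strength measures (AUC, F_max, peak
  metrics) so that a weak or null response is not inflated by rescaling.

Constant traces and non-positive baselines are rejected
(`DegenerateTraceError`) rather than silently patched.

## Response latency and the first responder

T₂₅ is the time from a glucose stimulus to the first frame whose min-max
value strictly exceeds 0.25, searching only frames inside that stimulus'
epoch (to the next event or the end of the recording); a cell that never
crosses is *censored* (NaN) for that stimulus. The crossing is
frame-quantized by default — matching raster-plot readouts — with linear
sub-frame interpolation available as an option. No smoothing is applied
before T₂₅ detection; smoothing belongs to the connectivity stage only.

The first responder is the cell with the smallest mean T₂₅ over the
stimuli it responded to, with the constraint that cells responding to
*every* stimulus strictly precede partial responders (a fast mean computed
on an incomplete set of boluses should not outrank a complete one). Ties
break on the latency at the first stimulus, then on the lexicographically
smallest cell id, making the ranking total and deterministic.

## Strength of response

AUC is the trapezoidal integral of the baseline-normalized trace over a
fixed post-stimulus window, default 250 frames; a window of *w* frames
spans *w*/fs seconds (*w* trapezoid intervals). Windows clipped by the end
of the recording are truncated and flagged. F_max is the session maximum
of the baseline-normalized trace.

Phase-resolved peak metrics split each glucose epoch into a first phase
(default: the 3 minutes after onset) and a second phase (the remainder).
First phase: amplitude is the within-window maximum; width is the total
time *active*, i.e. above `active_frac` (default 0.25) of the within-phase
maximum. Second phase: peaks are local maxima above the active threshold
with a minimum separation (default 10 s) and a minimum prominence (10% of
the phase maximum), all configurable; the reported amplitude and width are
the mean peak maximum and the mean duration of the active run containing
each peak. Zero detected peaks returns (0, 0) with an `empty` flag rather
than NaNs, so cohort averages remain defined.

## Latency–distance regression

Distances are Euclidean, from the first responder's centroid. The fit is
ordinary least squares of latency on distance; censored cells are excluded
and counted, never imputed. Two modes are reported side by side: `time`
(seconds; slope estimates the reciprocal wave speed) and `rank`
(activation order, average ranks on ties; unit-free and robust to
kinetic outliers). R² is invariant under affine rescaling of distances,
so pixel-calibrated coordinates need no unit conversion for the
coherence readout. Aggregation across islets reports the mean and sample
SD of R² (SD is NaN for a single islet).

## Connectivity

Each trace is smoothed once over the whole recording with a centred
rolling average whose window is 5% of the total frame count (edges use the
shrunken window), then Pearson R is computed for every unordered pair over
the requested phase window. Zero-variance cells yield undefined (NaN)
pairs, excluded from all means rather than set to 0.

Two summary conventions exist in the islet literature for "connected
cell"; the default here counts a cell as connected when its **mean**
pairwise R exceeds the threshold (default 0.2), which is robust to single
spurious pairs; the per-pair alternative (any pair above threshold) is
available as `cell_rule="any_pair"`. `mean_positive_r` averages all pairs
with R > 0. Connectivity line maps draw edges for R ≥ 0.1, colour-binned
blue/green/yellow/red with continuous half-open boundaries at
0.255/0.505/0.755 — the printed two-decimal bin labels (0.1–0.25,
0.26–0.5, …) describe rounding, and these boundaries reproduce that
assignment exactly while leaving no value in two bins.

## Optogenetic co-activation

For an illumination event targeting one cell, every other cell's signal is
expressed as a relative rise over its own pre-event baseline (mean of the
7.5 s before light onset). A cell co-activates when that rise stays at or
above `rise_threshold` (default 0.40, inclusive) for at least
`min_sustain_s` contiguous seconds within the illumination window plus a
22.5 s post-window. "Sustained" is not quantified in the source
convention, so the default of 5 s is an explicit, configurable choice;
co-activation is monotone in the threshold by construction. The
recruitment fraction (co-activated / eligible, eligible = all cells minus
the illuminated one) is binned low (<25%), mid (25–75%, inclusive
boundaries) or high (>75%), and regressed on mean T₂₅ to test whether
faster responders recruit more of the islet.

## Synthetic islet simulator

The simulator is a forward model invented for testability, not a
biophysical islet model. Geometry is uniform random placement in a disc or
sphere with a minimum centroid spacing of 8 µm (cell-diameter scale).
Indicator kinetics are a peak-normalized double-exponential pulse
A·(1 − e^−Δt/τ_rise)·e^−Δt/τ_decay on baseline F₀ with additive white
Gaussian noise; amplitudes are per-cell constants drawn once
(mean 1.5, SD 0.3 in baseline-normalized units — a bright GCaMP6s-scale
response; noise SD 5 on F₀ = 100 ≈ 5% shot noise). Wave scenarios plant a
first responder and set each cell's onset to
t_stim + fr_delay + dᵢ/v + jitterᵢ. A coupling parameter c mixes each
cell's own response with a shared latent drive (c = 1: identical signals
plus private noise; c = 0: independent cells). Presets:

- `wave_zebrafish`: 15 cells, 6 Hz, three boluses 5 min apart, first-phase
  wave at 5 µm/s, fr_delay 2 s, jitter 0.3 s, no secondary oscillations.
- `coordinated_mouse`: 100 cells, 0.5 Hz, 3 min baseline + 33 min high
  glucose + 3 min KCl, full coupling, sustained first phase (τ_decay
  600 s) plus an oscillatory second-phase pulse train (period 40 s).
- `decoupled_mouse`: coupling 0, 20% responders at independent uniform
  onsets — the pharmacologically decoupled phenotype. KCl still
  depolarizes every cell.
- `opto_single_cell`: one illumination event per cell (7.5 s baseline,
  45 s light, 22.5 s post at 6.67 Hz); each cell carries a recruitment
  weight (a 62/24/14% low/mid/high mixture) giving the per-cell
  probability that any other cell co-activates, realized as a sustained
  plateau rise.
- `inhibited_first_responder`: the planted first responder is silenced
  during the final bolus and the islet mounts only a partial (35%
  responders, half amplitude) response at independent onsets.

Everything is drawn from a single `numpy.random.default_rng(seed)` stream,
so outputs are bitwise reproducible, and the ground truth (initiator,
per-cell onsets and response flags, recruitment weights, planted
co-activation sets) is serialized alongside the traces.

What the simulator does **not** emulate: photobleaching and focal drift,
correlated (shared) noise, gap-junction dynamics or travelling second-phase
waves, out-of-plane illumination spill-over, and cell movement. Passing
tests therefore demonstrate the correctness and statistical behaviour of
the analysis code under the stated generative assumptions, not performance
on real microscope data.

## Numerical choices and degenerate inputs

- Threshold crossings use strict inequality on the normalized scale;
  the co-activation rise threshold is inclusive (≥ 40%).
- T₂₅ recovery at zero noise is exact up to the indicator's short rise to
  the 25% level (a deterministic sub-frame lag, identical across cells
  with shared kinetics) plus frame quantization; first-responder
  *identity* is recovered exactly at zero noise.
- Regressions require ≥ 3 points and a non-constant predictor
  (`DegenerateFitError`); R² is defined as 0 when the response is constant.
- Undefined quantities (no positive pairs, zero detected peaks, single-islet
  SD) are NaN-with-flag, never fabricated zeros — except the documented
  (0, 0, empty) convention for a peakless second phase.
- Problem sizes in the test suite and acceptance script (10–100 cells,
  10–12 replicates, recordings of 15–39 min at 0.5–6.7 Hz) were chosen as
  the smallest instances at which the targeted statistics stabilize.

## Known limitations

ROI support covers integer label masks and disc ROIs only (freehand
polygon ROIs from acquisition software are not parsed); no image
registration, bleach correction or automatic segmentation; no
deconvolution to spike trains; no causal (Granger/transfer-entropy)
connectivity and no hub-cell analysis. The "connected cell" and
"sustained rise" conventions each have a documented default plus a config
alternative, since the field's usage varies.
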