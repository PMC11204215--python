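# isletpulse

Quantitative analysis of glucose-stimulated Ca²⁺ dynamics in pancreatic
islet β cells, for labs doing calcium imaging of islets (zebrafish larvae,
cultured mouse islets) with genetically encoded indicators such as GCaMP6
or K-GECO1.

When blood glucose rises, β cells depolarize and admit Ca²⁺, and the
response is not uniform: a *first-responder* cell fires earliest and the
activity spreads to *follower* cells, with onset delay growing with
distance. `isletpulse` implements the trace-level statistics used to
characterize this organisation:

- **T₂₅ response latency** — with each trace min-max normalized,
  F̂ₜ = (Fₜ − F_min)/(F_max − F_min), T₂₅ is the time after a glucose
  stimulus at which F̂ₜ first exceeds 0.25. The **first responder** is the
  cell with the fastest mean T₂₅ over repeated stimulations.
- **Strength of response** — with baseline normalization
  F̃ₜ = (Fₜ − F_min)/F_min (no ceiling, so weak responses are not masked):
  the AUC ∫ F̃ dt over a fixed post-stimulus window (default 250 frames),
  the session maximum F_max, and phase-resolved peak amplitude / peak width
  (time active above 25% of the phase maximum).
- **Latency–distance regression** — OLS of T₂₅ (or activation rank) on
  Euclidean distance to the first responder; slope ≈ 1/v for a radial wave
  of speed v, with R² summarizing wave coherence, aggregated as mean ± SD
  across islets.
- **Functional connectivity** — traces smoothed by a centred rolling
  average (window = 5% of frames), pairwise Pearson R over a response-phase
  window; summaries are the mean positive R and the percentage of
  *connected cells* (mean pairwise R > 0.2), plus colour-binned
  connectivity line maps.
- **Optogenetic co-activation hierarchy** — for single-cell illumination
  experiments, a non-illuminated cell co-activates when it sustains a
  ≥ 40% rise over its pre-event baseline; cells are binned by the fraction
  of the islet they recruit (<25%, 25–75%, >75%).
- **Synthetic islet simulator** — geometry, protocols and traces with
  known ground truth (designated first responder, per-cell onsets,
  recruitment weights) for every regime above, so the whole pipeline is
  testable without microscope data.

## Worked example

```python
import isletpulse as ip

model = ip.IsletModel.from_simulation("wave_zebrafish", seed=1)
results = model.fit()
print(results.summary())
print("true initiator:", model.truth.first_responder)
```

```
Islet calcium-response analysis
==============================================
isletpulse 0.1.0   seed 1

Response metrics (15 cells x 3 stimuli)
----------------------------------------------
  mean T25                  7.637 s   (0 censored)
  mean AUC                 46.710 norm*s
  mean Fmax                 2.105
  first responder      c007

Latency vs distance (time mode, n=15, 0 censored)
----------------------------------------------
  slope                    0.2008
  intercept                 2.073
  R^2                       0.997
...
Connectivity (first phase, threshold 0.2, smoothing 270 frames)
----------------------------------------------
  mean positive R           0.990
  connected cells           100.0 %
true initiator: c007
```

The simulated wave propagates at 5 µm/s, and the fitted slope of the
latency–distance regression recovers its reciprocal (0.2008 ≈ 1/5 s/µm);
the identified first responder `c007` matches the planted initiator, and
the near-unit R² reflects the small onset jitter (0.3 s SD). The same
interface accepts real recordings:

```python
model = ip.IsletModel.from_files("traces.csv", "protocol.json", "geometry.csv")
results = model.fit()
results.save("report/")
```

A `isletpulse` console command exposes the stages individually
(`simulate`, `extract`, `respond`, `spatial`, `connect`, `hierarchy`,
`run-all`); see `isletpulse --help`.

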