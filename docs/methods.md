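# Methods

This note documents the models, parameter choices and numerical decisions
behind `rhizosense`, and what the validation studies do and do not show.

## Circuit model

Each electrode sees a parallel RC load (the soil path to the grounded
neighbouring electrodes) charged through a voltage divider of resistance
`ResVD` from source `Vs`.  Two readings per 5-minute cycle: `V2` after a
charge long enough that capacitive current has died away, and `V1` after a
short charge `TC`.  Resistance follows from the divider identity, and
capacitance from inverting the rising exponential

    V1 = V2 (1 − exp(−TC/τ)),   τ = Cap · Res · ResVD / (Res + ResVD).

Defaults: `Vs = 3.3 V`, `ResVD = 10 kΩ`, `TC = 1 µs` — typical
microcontroller front-end values, configurable in
`circuit.ElectricalConstants`.  The long charge is modelled as exact steady
state in the simulator; any residual transient on real hardware is folded
into measurement noise.  Saturated (`V2 ≥ Vs`), dead (`V ≤ 0`), below-floor
(`V < 0.01 V`) and unresolvable-capacitance readings are *flagged*, not
raised, in the bulk path, so masking can convert them into reduced uptime.
Scalar paths raise typed exceptions for interactive use.

Round-trip exactness (simulate → estimate recovers R and C to ≲1e−11
relative over R ∈ [1 kΩ, 1 MΩ], C ∈ [1 nF, 10 µF]) is a float64 property of
the closed forms.  Whole-trial simulation uses float32 for the bulk
(electrode × time) arrays: all signals of interest are O(10⁻²) to O(1) in
log units, at least five orders of magnitude above float32 resolution, and
the halved memory traffic matters at hundreds of devices.

## Soil and signal simulator

Normalized moisture `m ∈ [0, 1]` maps log-linearly between dry endpoints
(`Res = 50 kΩ`, `Cap = 0.5 nF` at `m = 0`) and wet endpoints (`5 kΩ`,
`2 nF` at `m = 1`), so every moisture change moves the electrode along a
straight line in (log R, log C) — the wetting/drying trajectory, slope
|ΔlogR/ΔlogC| ≈ 1.66 with the defaults.  Moisture relaxes exponentially:
toward the dry equilibrium with a 4-day constant between wettings, toward
the wet equilibrium with a 1-hour constant during an irrigation event that
reaches the electrode's depth.  A diurnal sinusoid (amplitude 0.02 moisture
units at the surface, e-folding depth 12 cm, afternoon-dry phase) is
superimposed.  Measurement noise is multiplicative: i.i.d. Gaussian of
standard deviation `noise_sd = 0.01` on log R and log C per sample — a 1%
reading noise typical of an ADC chain.

Root contacts arrive as an inhomogeneous Poisson process per device
(default 2 roots/day), with per-window rate multipliers for programmed
treatment effects and a depth profile over electrode depth indices
(default: truncated Gaussian centred at index 4, the crown-root zone; a
deep profile centred at index 17 emulates primed deep growth).  A contact
adds a ramped step of `(ΔlogR, ΔlogC) = (−0.10, +0.30)` over 60 minutes to
exactly one electrode and persists (a touched root stays put).  The
contact ratio 1:3 is well inside the root sector — smaller than the
wetting slope — which is the physical signature being detected; magnitude
and duration are not field-measured quantities, so they are declared
configuration, stated here, and varied in tests rather than treated as
truth.  Arrival times are clamped to at least 90 minutes before the end of
the record so the onset ramp completes inside it; an arrival in the final
minutes would be unobservable by any method and would make exact-recall
scoring meaningless.  Two arrivals on one electrode within 2 days are
thinned to one for the same reason (the detector's refractory window makes
them indistinguishable).

Downtime is a daily Bernoulli outage (probability per scenario, length
exponential with 4-hour mean, capped at 24 h) blanking the whole device.
Determinism: every device draws from its own child of
`SeedSequence(config.seed)`, so output is bit-identical across runs and
independent of iteration order.

## Detector

Constants live in `detect.DetectorParams`; they are calibration constants
of this implementation, not values from any field study.

* **Candidate changes**: two-hour lagged differences of log R and log C
  (contact transients are much faster than drying or the diurnal cycle;
  the lagged difference acts as the detrending).  Partial windows against
  the first sample cover the start of a record.
* **Relative normalization**: the cross-electrode median change is
  subtracted (removing drift coherent across the device), and each
  residual magnitude is scored against the median/MAD of contemporaneous
  residual magnitudes over all 264 electrodes.  Robust statistics keep the
  scale insensitive to the event itself.  The MAD is floored at 1e−3 log
  units so noise-free data cannot divide by zero.
* **Thresholds**: a detection needs a normalized magnitude ≥ `k = 5` MADs
  *and* an absolute deflection ≥ 0.08 log units (half the default contact
  magnitude).  With ~2.3 million samples per device-month a purely
  relative threshold admits noise-tail false positives; the absolute floor
  removes them without touching genuine contacts.
* **Root sector**: the change direction must lie more than 20° from the
  wetting line and satisfy |ΔlogR| < slope·|ΔlogC|.  Because any moisture
  change moves *along* the wetting line, wetting and drying — including
  irrigation transients that escape the mask — are rejected by direction
  alone.
* **Masking**: downtime (device silent), low-voltage/invalid estimates,
  and watering windows — flagged when ≥50% of electrodes move by more
  than 0.05 log units within 30 minutes, dilated by ±30 minutes.  Masked
  samples can never fire; they lower `Ut` instead.  Each masked sample
  carries one primary reason, precedence downtime > low-voltage >
  watering.
* **Refractory window**: one detection per electrode per day, matching the
  daily counting of the rate statistics and preventing a persistent touch
  from being recounted.

## Rate statistics

`rt = nt/Ut` with days at `Ut ≤ 0.04` treated as no-data and ignored (the
same cutoff per depth for `rtd = ntd/Utd`).  The time-averaged rate `R`
over `[a, b]` is the mean over the window's *non-missing* days — the
alternative reading (divide by the full window length) is rejected because
it conflates low growth with low uptime; this is the one genuinely
ambiguous definition in the chain and is therefore flagged here.
Cumulative detections sum `rt` over non-missing days, so conservation
(final `ct` = Σ`rt`) is exact by construction and verified on pipeline
output.  Sparse-device exclusion uses true `Ut = 0` days (full-day
outages) for its >50%-missing rule — a different threshold from the 0.04
rate cutoff, and both are kept deliberately: one asks "was the device
alive at all", the other "is the day's rate numerically trustworthy".

Smoothing: first-order Butterworth, normalized cutoff 0.4 (fraction of
Nyquist for the daily-sampled series), applied forward-backward
(`filtfilt`) for zero phase; order 1 preserves event timing in mean-rate
plots and is configurable.  Depth-time matrices are filtered along depth
first, then time.  Missing days are linearly interpolated *only* for
smoothing display, never for window averages.  Series shorter than the
filter warm-up are returned unfiltered with a warning.

Welch t (no equal-variance assumption, one-sided by default) comes from
`scipy.stats`; Cohen's d uses the average variance of the two groups, with
a one-sided 95% lower confidence bound from the asymptotic standard error
`SE(d) = sqrt((nA+nB)/(nA·nB) + d²/(2(nA+nB)))` — a deliberate, documented
choice since the exact noncentral-t interval is not materially different
at the group sizes involved.  The interaction ANOVA is an ordinary
two-way fixed-effects fit (`statsmodels`), model
Rate = Treatment + Genotype + Treatment:Genotype.

## Shovelomics ground truth

Root-crown photographs are segmented by a single global intensity
threshold (bright roots on a dark backdrop by default; polarity is a
flag, and an Otsu helper exists but is off by default).  The electrode
region of interest is a rectangle below the crown anchor spanning the
electrode depth range (1.9–16.1 cm) vertically and the device diameter
(default 10 cm) horizontally, converted through the image's pixel scale;
counts are raw pixel counts `S`, not area-normalized.  Genotype medians of
`S` and of the device detection rate `R` are correlated by simple OLS;
the reported R² equals the squared Pearson correlation for this model.
The synthetic image generator draws root-like polyline strokes from the
anchor with a configurable depth distribution and returns the exact
painted-pixel count inside the ROI, making the segmentation chain testable
to equality.

## Validation studies and their scope

The reference scenarios (`scenarios.py`) fix the study conditions:

* noise-free oracle — 100 devices × 30 days, drying + diurnal + contacts,
  no irrigation/noise/downtime; the detector must be exact
  (precision = recall = 1).
* noisy reference — 100 devices × 30 days with 1% noise, twice-weekly
  3-hour irrigation and 10%/day outages; scored by F1 (≥ 0.9; contacts
  landing inside masked windows are deliberately unrecoverable and show up
  as reduced uptime instead).
* wetting-only — 20 irrigated devices, zero roots, noise-free; any
  detection is a false positive.
* drought recovery — 2 × 300 devices × 20 days, arrival rate ×0.64 over
  days 10–19 in the drought arm; the pipeline-estimated percent reduction
  in mean `R` must recover the programmed 36% within ±10 points with
  Welch p < 0.001.
* depth shift — 2 × 150 devices; the primed arm's arrivals concentrate in
  the deeper half of depth indices (11–21 of 22) over days 10–19; the
  deeper-half `Rd` contrast must be significant at p < 0.01.

Problem sizes were chosen so the full suite runs in minutes on one CPU
while keeping the group contrasts far from their decision boundaries.

What passing these studies shows: the chain is self-consistent — the
programmed physics is inverted exactly, the declared signature is detected
at the declared noise level, and uptime normalization plus group
statistics recover programmed effects without bias visible at n = 300.
What it does not show: performance on real soils, where contact
magnitudes vary with root diameter and soil contact area, noise is
non-Gaussian and temperature-correlated, electrode polarization drifts,
and wetting fronts are not depth-step functions.  The simulator reproduces
the documented phenomenology (drying trajectory, coherent wetting, diurnal
modulation, localized contacts), not soil-water mechanics (no Richards
equation, no root architecture model, no temperature dependence of the
circuit constants).

## Known limitations

* The production detector behind the original hardware is proprietary;
  this module implements the *described* signature (relative magnitude +
  direction + masking) with declared constants, so absolute thresholds are
  not transferable to field data without recalibration.
* One physical root may in principle touch several electrodes; detections
  are per-electrode and no cross-electrode deduplication is attempted.
* Growth-orientation and time-of-day summaries are carried as geometry
  (paddle azimuths) but no statistics are defined for them.
* The depth profile of arrivals is independent of time within a window;
  root systems that deepen continuously would need a time-varying profile.
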