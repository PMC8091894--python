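# Methods

`mnkit` is two things: a generative model of a crowded fibroblast
monolayer's morphological and NF-κB signaling dynamics under periodic
TNF-α stimulation, and the measurement pipeline (segmentation, tracking,
morphometrics, spectral and correlation statistics) that quantifies such
dynamics from track tables or fluorescence movies. The generator's
presets are calibrated so that the pipeline, run end to end on synthetic
data, reproduces the study-level statistics of this system: a ~70 μm
flow correlation length, weakly coordinated triangle-area fluctuation
(ρ ≈ 0.2) in an intrinsic 1/40–1/30 min⁻¹ band, input-locked collective
vibration (ρ ≈ 0.4), nuclear-shape-fluctuation (NSF) entrainment only
near the 20-min input period, NF-κB entrainment at ~1/26 min⁻¹, return
of displaced cells within 20–30 min, and a ~20-percentage-point gain in
low-dose responsiveness of the interconnected monolayer (ICM) over
stand-alone (SA) cells.

## The coupled-oscillator model

Each of N cells (N = round(density × chamber area); 112 at the default
700 cells/mm² in a 400 × 400 μm chamber) carries three observable
channels sampled every `dt` = 2 min for `duration` = 600 min.

**Stimulus.** u(t) is a square pulse train: period T ∈ {20, 60, 90} min,
duty fraction 0.25, amplitude in ng/mL (10 by default, 0.08 for the
low-dose preset), with pulse onset at the start of each cycle and an
optional silent lead-in used for activation baselines.

**Mechanical drive (the entrainment channel).** When the preset is
ICM-like and T lies inside the entrainment window [18, 22] min — the
RAC1 gating rule abstracting the transition from stable to dynamic
cell–cell connections — every cell receives

    m_i(t) = c_nsf · M(t) + (1 − c_nsf) · η_i(t),

where M(t) is a shared mode-hopping oscillation and η_i independent
per-cell copies; both are multiplied by a saturating dose factor
D/(D + 1 ng/mL) and an onset ramp 1 − exp(−t/τ_ramp), τ_ramp = 60 min
(entrainment builds up over cycles of stimulation; an abrupt switch-on
would shock-excite the NF-κB resonance). Outside the window, or for SA
and decoupled drug presets, m_i ≡ 0.

M(t) is built from half-cycles whose durations are drawn from the two
mode periods (20 and 30 min). Three details matter:

* *Equal-impulse half-cycles.* Each half-cycle's amplitude scales as
  1/duration so alternating 10- and 15-min half-waves carry equal area.
  Without this the waveform has a strong low-frequency bias that the
  underdamped NF-κB oscillator (gain ratio ≈ 3000× in power between its
  90-min resonance and the 26-min carrier) amplifies into a spurious
  90-min peak.
* *Phase-budget scheduling (shared mode only).* The fast half-cycle is
  chosen with probability clipped around p₂₀ plus a term proportional to
  the accumulated time deficit, so the long-run carrier stays pinned at
  the schedule mean. The spectral carrier of a hopping wave is the
  time-weighted mean frequency 0.5·n_half/elapsed; pinning it at
  1/26 min⁻¹ requires a fast-half *count* fraction of 0.4 (equivalently
  4/13 ≈ 0.31 of *time* in the fast mode), hence `modehop_p_fast` = 0.4.
  The independent copies η_i hop i.i.d. and phase-diffuse, which is what
  decorrelates them between cells.
* *High-passed forcing.* Before entering the NF-κB oscillator the drive
  is high-passed (zero-phase 3rd-order Butterworth, 50-min cutoff):
  mechano-transduction of nuclear shuttling is rate-sensitive and slow
  mechanical bias should not pump the resonance. The NSF channel uses
  the unfiltered drive.

**Nuclear area (NSF).** A_i(t) = A₀_i (1 − a_NSF·m_i(t)) + noise, with
A₀_i ~ N(180, 20²) μm² and relative modulation a_NSF = 0.06. The NSF
trace normalized by its time mean therefore oscillates in the
1/30–1/20 min⁻¹ band only under ~20-min stimulation; elsewhere it sits
at the 1.5% area-noise floor.

**NF-κB.** A damped driven linear oscillator per cell,

    x″ + 2ζω₀x′ + ω₀²x = γ_i (β_c u(t) + β_m HP[m_i](t)),

with natural period T_N = 90 min (ω₀ = 2π/T_N), damping ratio ζ = 0.1,
chemical gain β_c = 6·10⁻⁵ per ng/mL, mechanical gain β_m = 0.02, and a
per-cell lognormal response gain γ_i (median e^(−σ²/2), σ = 0.9). The
reported trace is baseline 1 + a slow saturating activation envelope
(low-passed u, τ = 30 min, gain 0.12, dose half-saturation 0.1 ng/mL —
NF-κB activation saturates at very low TNF-α) + x + a bounded
quasi-square basal shuttling oscillation (amplitude 0.03, period 40 min,
random phase) + small OU noise (sd 0.004, τ = 10 min), rectified at 0.
ZOH (matrix-exponential) discretization integrates the oscillator
exactly for the piecewise-constant stimulus and to <2% for the sampled
oscillatory drives. The steady-state amplitude gain is the textbook
1/√((1−r²)² + (2ζr)²), r = T_N/T, maximal at the 90-min input — this
closed form is the oracle for the resonance tests.

The basal oscillation is deliberately *bounded* (tanh-saturated sine,
peak/rms ≈ 1.2): the activation statistic (max of the post-stimulus
trace vs baseline mean + 2 sd) would otherwise be decided by the running
maximum of unbounded noise rather than by the activation channel.

**Centroid position.** anchor + directed drift (0.001 μm/min — ICM cells
are near-immobile) + two deformation channels + white position noise
(0.15 μm, centroid localization error):

* *Stimulus kicks (vibration/Δl channel).* At every pulse onset each
  cell is displaced along the gamma-shaped rise-and-relax kernel
  g(t) = (t/θ)e^(1−t/θ), θ = τ_ret/2, τ_ret = 8 min, so excursions decay
  back within ~20–30 min. The kick amplitude mixes a shared component
  (one direction and lognormal magnitude per event — the collective
  contraction of the sheet) with per-cell independent components
  (random directions, intermittent participation π = 0.5), with
  common-mode weight `c_vib`. Per-event random directions are essential:
  Δl = |r − r̄| is a magnitude, and a signed sinusoidal displacement
  would frequency-double under the modulus instead of locking to the
  input. The shared component is translation-like and cancels exactly in
  triangle areas.
* *Sheet breathing (triangle-area channel).* One shared ~35-min
  oscillation E(t) (half-cycle periods uniform in [30, 40] min) drives a
  displacement field composed of a weak uniform dilation about the
  chamber center plus a long-wavelength (250 μm) longitudinal wave,
  weighted 1:1, total amplitude `c_tri`·`tri_amp`; independent per-cell
  jitter at the same timescale carries weight (1 − c_tri). Delaunay
  triangle areas partition the convex hull, so a coherent same-sign area
  fluctuation requires a boundary-moving (dilation) component — that is
  what survives in the population-mean triangle trace — while the wave
  supplies locally coherent divergence at bounded (< 1 μm) displacement,
  which is what the adjacent-pair correlation sees.

**Junction intensities.** Per Delaunay edge: baseline 1 with Gaussian
dips (depth 0.12–0.35, width 6–16 min) at a Poisson rate of 0.2/h,
raised to 1.0/h while the mechano channel is engaged — the dynamic loss
and re-establishment of cell–cell contacts.

**Collective flow.** `sample_flow_field` smooths white-noise vectors
with an isotropic Gaussian kernel of width σ_v on a padded grid and
crops, yielding a stationary sample whose spatial autocorrelation is
exp(−r²/4σ_v²); the 1/e length is exactly 2σ_v, so σ_v = 35 μm encodes
the 70-μm correlation length. Padded-crop synthesis avoids periodic
wrap-around artifacts, and no net-translation mode is generated (a
closed chamber admits no net flow).

## Presets

`icm_default` is the coupled monolayer; `sa_default` shares its geometry
but removes every coupling term (c_* = 0, β_m = 0, no entrainment) and
drifts faster. Drug presets are coupling switches: ROCK inhibition
removes the NSF/mechano channel but leaves collective movement;
cytochalasin, blebbistatin, ML-141 and E-cadherin antibody remove
movement coupling too (and shorten the flow kernel); JASP and E-cadherin
antibody additionally suppress junction-event dynamics; nocodazole (a
microtubule drug) changes nothing. Dose–response curves for the drugs
are out of scope — the switches encode only the qualitative panel.

## Calibration

Free constants were pinned once with `calibrate_preset` (brute-force
grid argmin against a target statistic) *through the full measurement
pipeline*, because the measurement operators — shoelace areas of three
mixed vertices, the modulus in Δl, best-|ρ| lag search — reshape the
ideal linear-mixing closed form ρ = c²/(c² + (1−c)²):

* `c_tri` = 0.6 with `tri_amp` = 1.2 μm → adjacent-triangle best-lag
  correlation ≈ 0.2 at every input period.
* `c_vib` = 0.68 with `vib_amp` = 2.5 μm → neighbor-Δl best-lag
  correlation ≈ 0.4 at the 20-min input.
* `act_gain` = 0.12 and the mechano dose constant 1.0 ng/mL → ≈ half of
  SA cells cross the activation threshold at 0.08 ng/mL and the ICM
  exceeds the SA fraction by ≈ 20 percentage points.

The pure closed form is still verified exactly on directly mixed traces
in the oracle tests. `mnk calibrate` re-runs pipeline calibrations from
the command line.

## Measurement conventions

* **FFT.** Mean removal, Hann window, zero padding to ≥ 4× the record,
  DC and periods longer than half the record excluded, ties to the lower
  frequency. Population dominant frequency is computed on the mean of
  the normalized traces. Parseval holds exactly for the rectangular
  window; the Hann estimate is normalized by the window power.
* **Band amplitude.** √2 × RMS of the mean-normalized trace after a
  zero-phase FFT brick-wall band pass.
* **Cross-correlation.** Pearson on overlapping segments at integer-step
  lags in [−L, L], L defaulting to half the input period (capped at
  10 min for the morphological statistics); the signed coefficient with
  maximal |ρ| is reported, ties resolving to the smallest |lag| then the
  negative lag. At L = T/2 a strictly periodic pair is ±-degenerate
  (anti-phase alignment matches in |ρ|), which depresses the *signed
  mean* for strongly entrained 90-min runs; panel comparisons at 90 min
  are therefore ratios of identical constructions and unaffected.
* **Mode hopping.** 120-min sliding windows, 50% overlap, dominant
  period per window, occupancy of the 18–22 and 27–33 min bands.
* **Segmentation.** Otsu (or fixed) threshold, distance-transform
  watershed split (seed separation 8 μm), components < 40 μm² dropped.
  The reported nuclear area is the subpixel marching-squares contour
  area at half the background-subtracted peak — shape-agnostic (exact
  for Gaussian spots and flat discs) and nearly free of
  pixel-quantization noise; the peak is refined log-quadratically.
  Centroids are intensity-weighted above background.
* **Tracking.** Greedy nearest-pair linking within a 15 μm/frame gate
  (scaled by gap age, gaps ≤ 2 frames bridged and the skipped frames
  linearly interpolated and flagged); tracks below half the movie length
  dropped.
* **PIV.** Windowed cross-correlation peak (image mode) or grid-binned
  per-cell displacements (track mode); featureless windows are flagged
  and filled from valid neighbors.
* **Correlation length.** Azimuthally averaged C(r) = ⟨v·v⟩/⟨|v|²⟩ with
  pair-count weights and the count-weighted mean separation as each
  bin's abscissa (removing the convexity bias of bin centers); the 1/e
  crossing is linearly interpolated, `censored` when never crossed.
  A single 400-μm window holds only ~30 independent patches at a 70-μm
  correlation length, so `flow_correlation_length` averages the
  *curves* over seeds before reading the crossing.
* **Activation.** A cell is active when its post-stimulus maximum
  exceeds its own 60-min pre-stimulus baseline mean + 2 sd.
* **Return time.** Time from pulse onset until the displacement from the
  pre-pulse mean position re-enters 2× its pre-pulse sd for ≥ 3
  consecutive frames (0 for cells that never leave).
* **Phase sweep.** SA cells with an externally imposed sinusoidal
  mechanical drive. The chemical-only and mechanical-only response
  phasors at the drive frequency are measured by demodulation, then the
  imposed drive is amplitude-matched and phase-aligned so Δφ = 0 means
  coincident response phasors — the computational analogue of aligning
  measured NSF minima with TNF-α maxima. The activation envelope is
  disabled to isolate the oscillatory pathway; the resultant amplitude
  then follows the two-phasor form |F_c + F_m e^(−iΔφ)| ∝ |cos(Δφ/2)|.
  Δt↔Δφ conversion is referenced to the mechanical forcing period.

## Problem sizes

Defaults (112 cells, 300 frames) are the study conditions; the test
suite and the acceptance script run the pipeline at these sizes with
5 seeds per condition (10 fields for the flow statistic) and finish in a
few minutes. The segmentation round trip uses a 300 cells/mm²,
30-μm-separation configuration at 1 μm/px: nuclei (FWHM diameter
~15 μm) in a 700 cells/mm² monolayer overlap optically, and blob merging
— not the estimator — then dominates the error, as it would in real
crowded-field imaging.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline measures: per-cell
track tables, neighbor graphs, renderable nuclear images, and the
population statistics listed at the top. It does not model the NF-κB
gene circuit mechanistically (no IκB feedback; entrainment at 1/26 is
imposed through the mode-hopping drive rather than emergent), does not
quantify forces, has no spatial gradient of stimulus arrival, treats
drug action as binary coupling switches, and freezes the neighbor graph
at frame 0 (cells never rearrange). Passing tests therefore certify the
*measurement pipeline* and the *internal consistency* of the model's
emergent statistics with the reported values — not biological prediction
beyond the encoded structure.

## Known limitations

* The Δl and triangle-area statistics share the centroid channel;
  their calibrations interact (documented above) and were fixed jointly.
* The best-lag convention's ±-degeneracy at L = T/2 (see above).
* Marginal-vs-interior contractile asymmetry is exposed only as an
  optional `marginal_boost` on NSF amplitude, default off.
* `duration/dt ≥ 64` is required; spectral operators need ≥ 64 samples.
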