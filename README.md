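# mnkit

Quantification toolkit — with a matched synthetic-data generator — for
collective morphological and NF-κB signaling responses of fibroblast
monolayers under periodic TNF-α stimulation.

Confluent fibroblasts self-organize into an interconnected cell
monolayer (ICM) in which mechanical cues propagate between cells through
the actin layer and cell–cell junctions. Under periodic TNF-α input,
such a monolayer behaves very differently from sparse stand-alone (SA)
cells: collective nuclear shape fluctuation (NSF) and entrained NF-κB
oscillation emerge at a stimulation period (~20 min) far from the NF-κB
natural period (~90 min). `mnkit` is for quantitative biologists who
want to measure these phenomena from single-cell track tables or
fluorescence movies — and to test every stage of that measurement
against a generative model with known ground truth.

## The model in brief

Per cell *i*, three observable channels are simulated on a common clock
(dt = 2 min, 600 min):

* **NF-κB** — a damped driven oscillator
  `x″ + 2ζω₀x′ + ω₀²x = γᵢ(β_c u(t) + β_m mᵢ(t))` with natural period
  T_N = 90 min and ζ = 0.1, so the chemical response alone resonates at
  the 90-min input (gain `1/√((1−r²)² + (2ζr)²)`, r = T_N/T).
* **Mechanical drive** `mᵢ = c·M + (1−c)·ηᵢ` — a mode-hopping
  oscillation alternating 20- and 30-min half-cycles (carrier
  1/26 min⁻¹), mixed from a shared mode M and independent per-cell
  copies, and *gated*: it engages only in ICM-like presets when the
  input period falls inside the 18–22 min entrainment window (the RAC1
  rule). It drives nuclear area (NSF) and forces the NF-κB oscillator.
* **Centroid position** — stimulus-triggered displacement kicks that
  relax back within ~20–30 min (the collective contraction measured by
  the trajectory deviation Δl), plus a shared ~35-min breathing mode of
  the sheet (measured by Delaunay triangle areas), plus drift and noise.

The measurement side computes the corresponding statistics from any
dataset in the track-CSV dialect or from TIFF stacks: Delaunay
triangle-area traces, NSF traces and amplitudes, Δl, junction-event
counts, actin extension, FFT dominant frequencies and band amplitudes,
mode-hop occupancy, best-lag neighbor/input cross-correlation, PIV,
spatial correlation length and active-cell fractions. `docs/methods.md`
has the full model, the calibration procedure and every measurement
convention.

## Worked example

```python
import mnkit as mk
from mnkit import features as ft, spectral as sp, correlation as co

ds = mk.simulate_preset("icm_default", period=20.0, seed=1)
print(f"cells: {ds.n_cells}, frames: {len(ds.times)}, "
      f"neighbor edges: {len(ds.neighbor_edges)}")

nsf = ft.nsf_traces(ds)                      # area / its time mean
amp = ft.nsf_amplitude(nsf).mean()
f_nsf = sp.spectral_summary(nsf, 2.0).population_dominant_frequency
print(f"NSF amplitude (population mean): {amp:.3f}")
print(f"NSF dominant period: {1/f_nsf:.1f} min")

nfkb = ds.nfkb()
norm = nfkb / nfkb.mean(axis=1, keepdims=True)
f_nf = sp.dominant_frequency(norm.mean(axis=0), 2.0)
print(f"NF-kB dominant period: {1/f_nf:.1f} min")

s = co.neighbor_correlation(nsf, ds.neighbor_edges, 2.0, max_lag=10.0)
print(f"NSF neighbor correlation: {s.mean:.2f} +/- {s.sd:.2f}")

dl = ft.vibration_deviation(ds)              # |r(t) - moving average|
s = co.neighbor_correlation(dl, ds.neighbor_edges, 2.0, max_lag=10.0)
print(f"Dl neighbor correlation: {s.mean:.2f} +/- {s.sd:.2f}")
```

prints

```
cells: 112, frames: 300, neighbor edges: 320
NSF amplitude (population mean): 0.064
NSF dominant period: 25.8 min
NF-kB dominant period: 25.8 min
NSF neighbor correlation: 0.65 +/- 0.09
Dl neighbor correlation: 0.38 +/- 0.20
```

Read: under a 20-min TNF-α input the monolayer's nuclei fluctuate at
~6% of their area with a dominant period between 20 and 30 min (the
mode-hopping mechano drive, not the input), the population NF-κB rhythm
is entrained near 1/26 min⁻¹, NSF is strongly coordinated between
neighbors, and trajectory deviations correlate at ~0.4. Re-run with
`period=90.0` and the mechano channel disengages: NSF falls to the
noise floor while NF-κB resonates at its natural 90-min period; with
`"sa_default"` all coordination disappears.

The same analyses run from the shell:

```bash
mnk simulate --preset icm_default --period 20 --seed 7 --out run/
mnk features --tracks run/tracks.csv --feature nsf --out run/nsf.csv
mnk sweep --seed 0 --seed 1 --out results/        # condition sweep
mnk phase-sweep --out results/                    # Δφ synergy experiment
mnk perturb --out results/                        # drug panel
mnk render --preset icm_default --out run/movie.tif
mnk segment --in run/movie.tif --out run/tracks_rec.csv
```

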