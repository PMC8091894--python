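"""Frequency-domain analysis: dominant frequency, oscillation amplitude and
mode-hop occupancy of feature and NF-kB traces.

Conventions: mean removal, Hann window, zero-padding to >= 4x the record
length, and exclusion of DC plus everything slower than 2 cycles per record
(so slow drift cannot masquerade as the dominant oscillation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BandError, MnkitError, NoOscillatoryPowerError
from .features import FeatureTraces

MIN_SAMPLES = 64


@dataclass
class SpectralSummary:
    """Per-entity and population spectral statistics of one feature."""

    entity_ids: list
    dominant_frequency: np.ndarray        # min^-1, per entity
    population_dominant_frequency: float  # of the mean normalized trace
    frequency_grid: np.ndarray            # min^-1
    power: np.ndarray                     # (n_entities, n_freq)
    window_name: str = "hann"


@dataclass
class ModeHopProfile:
    """Sliding-window dominant periods and band occupancies."""

    window_centers: np.ndarray            # min
    dominant_period: np.ndarray           # min, per window
    band_occupancy: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def power_spectrum(trace: np.ndarray, dt: float, window: str | None = "hann",
                   pad_factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of the mean-removed trace.

    Normalized so that the summed power equals the variance of the
    (windowed) trace: with ``window=None`` (rectangular) the identity
    ``power.sum() == trace.var()`` is exact (Parseval); the Hann window
    redistributes power between neighboring bins and is corrected for its
    own power ``mean(w^2)``, so the identity then holds for the
    window-weighted variance.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    x = x - x.mean()
    if window == "hann":
        w = np.hanning(n)
    elif window is None or window == "rect":
        w = np.ones(n)
    else:
        raise MnkitError(f"unknown window {window!r}")
    nfft = int(pad_factor * n)
    spec = np.fft.rfft(x * w, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=dt)
    power = np.abs(spec) ** 2 / (n * nfft * np.mean(w ** 2))
    power[1:] *= 2.0                       # one-sided
    if nfft % 2 == 0:
        power[-1] /= 2.0
    return freqs, power


def _dominant(trace: np.ndarray, dt: float, pad_factor: int = 4) -> float:
    """Frequency (min^-1) of the maximum power bin, excluding DC and
    periods longer than half the record; ties break to lower frequency."""
    x = np.asarray(trace, dtype=float)
    if np.ptp(x) == 0:
        raise NoOscillatoryPowerError("constant trace has no dominant "
                                      "frequency")
    freqs, power = power_spectrum(x, dt, window="hann",
                                  pad_factor=pad_factor)
    duration = len(x) * dt
    sel = freqs >= 2.0 / duration          # >= 2 cycles per record
    if not np.any(sel):
        raise NoOscillatoryPowerError("record too short for any admissible "
                                      "frequency")
    p = np.where(sel, power, -np.inf)
    return float(freqs[int(np.argmax(p))])  # argmax: first max = lower freq


def dominant_frequency(trace: np.ndarray, dt: float,
                       pad_factor: int = 4) -> float:
    """Dominant oscillation frequency (min^-1) of a single trace."""
    if len(trace) < MIN_SAMPLES:
        raise MnkitError(f"trace must have >= {MIN_SAMPLES} samples")
    return _dominant(trace, dt, pad_factor)


def padded_bin_width(n_samples: int, dt: float, pad_factor: int = 4) -> float:
    """Frequency resolution (min^-1) of the zero-padded FFT grid."""
    return 1.0 / (pad_factor * n_samples * dt)


def oscillation_amplitude(trace: np.ndarray, dt: float,
                          band: tuple[float, float]) -> float:
    """sqrt(2) x RMS of the mean-normalized trace band-passed (zero-phase,
    FFT brick-wall) to ``band`` (min^-1)."""
    x = np.asarray(trace, dtype=float)
    lo, hi = band
    nyquist = 0.5 / dt
    if not (0.0 < lo < hi) or lo > nyquist:
        raise BandError(f"band {band} outside (0, {nyquist}]")
    hi = min(hi, nyquist)
    mean = x.mean()
    if abs(mean) > 1e-12:
        x = x / mean
    x = x - x.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=dt)
    keep = (freqs >= lo) & (freqs <= hi)
    if not np.any(keep):
        raise BandError(f"band {band} empty on the frequency grid")
    filtered = np.fft.irfft(np.where(keep, spec, 0.0), n=len(x))
    return float(np.sqrt(2.0) * np.sqrt(np.mean(filtered ** 2)))


def mode_hop_profile(trace: np.ndarray, dt: float, window: float = 120.0,
                     bands: dict | None = None) -> ModeHopProfile:
    """Sliding-window (50% overlap) dominant period and band occupancy.

    Default bands: the 20-min mode (18-22 min) and the 30-min mode
    (27-33 min).
    """
    if bands is None:
        bands = {"fast": (18.0, 22.0), "slow": (27.0, 33.0)}
    longest = max(hi for _, hi in bands.values())
    if window < 2 * longest:
        raise MnkitError("window must span >= 2x the longest band period")
    wlen = int(round(window / dt))
    if len(trace) < wlen:
        raise MnkitError("trace shorter than the analysis window")
    step = max(wlen // 2, 1)
    centers, periods = [], []
    for s in range(0, len(trace) - wlen + 1, step):
        seg = np.asarray(trace[s:s + wlen], dtype=float)
        try:
            f = _dominant(seg, dt, pad_factor=8)
        except NoOscillatoryPowerError:
            continue
        centers.append((s + wlen / 2.0) * dt)
        periods.append(1.0 / f)
    periods_arr = np.asarray(periods)
    occupancy = {}
    for name, (lo, hi) in bands.items():
        if len(periods_arr):
            occupancy[name] = float(np.mean((periods_arr >= lo)
                                            & (periods_arr <= hi)))
        else:
            occupancy[name] = 0.0
    return ModeHopProfile(window_centers=np.asarray(centers),
                          dominant_period=periods_arr,
                          band_occupancy=occupancy)


# ---------------------------------------------------------------------------

def spectral_summary(traces: FeatureTraces, dt: float,
                     pad_factor: int = 4) -> SpectralSummary:
    """Per-entity dominant frequencies plus the population value computed on
    the mean of the (normalized) traces."""
    rows = traces.values[traces.valid]
    ids = [e for e, v in zip(traces.entity_ids, traces.valid) if v]
    freqs = None
    powers, doms = [], []
    for row in rows:
        f, p = power_spectrum(row, dt, pad_factor=pad_factor)
        freqs = f
        powers.append(p)
        try:
            doms.append(_dominant(row, dt, pad_factor))
        except NoOscillatoryPowerError:
            doms.append(np.nan)
    pop = _dominant(rows.mean(axis=0), dt, pad_factor) if len(rows) else \
        np.nan
    return SpectralSummary(entity_ids=ids,
                           dominant_frequency=np.asarray(doms),
                           population_dominant_frequency=float(pop),
                           frequency_grid=freqs if freqs is not None
                           else np.empty(0),
                           power=np.stack(powers) if powers
                           else np.empty((0, 0)))
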