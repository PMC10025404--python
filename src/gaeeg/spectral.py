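"""Weighted-average spectrogram and band-level descriptors.

The time–frequency representation is a short-time Fourier power spectral
density on a 20 s Hann window with 75 % overlap (5 s hop, 0.05 Hz bins).
The four frontal channels are combined as a weighted mean that halves the
contribution of the temporal-leaning electrodes F7 and F8::

    P_av = (0.5 P_F7 + P_Fp1 + P_Fp2 + 0.5 P_F8) / 3

reflecting the frontal origin of the anesthetic α rhythm.  All band
descriptors (absolute/relative band power, peak-frequency tracks and their
smoothing) operate on ``P_av``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .intervals import Interval, mask_from_intervals
from .records import EEGRecord

#: weights for (F7, Fp1, Fp2, F8); temporal electrodes halved
CHANNEL_WEIGHTS = np.array([0.5, 1.0, 1.0, 0.5])
FULL_BAND: Interval = (0.1, 45.0)
DELTA_BAND: Interval = (0.1, 4.0)
ALPHA_BAND: Interval = (8.0, 12.0)
FMAX_BAND: Interval = (8.0, 30.0)


@dataclass
class Spectrogram:
    times: np.ndarray              # s, window centers
    freqs: np.ndarray              # Hz
    power: np.ndarray              # (n_freqs, n_times), µV²/Hz
    window_s: float = 20.0
    overlap_fraction: float = 0.75
    channel_weights: np.ndarray = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class BandPowerSeries:
    times: np.ndarray
    values: np.ndarray             # µV² (absolute) or % (relative)
    band: Interval
    kind: str                      # {"absolute", "relative"}


@dataclass
class PeakFrequencyTrack:
    times: np.ndarray
    values: np.ndarray             # Hz; NaN where undefined
    band: Interval
    smoothed: bool = False

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def spectrogram(record: EEGRecord, window_s: float = 20.0,
                overlap: float = 0.75, f_hi: float = 45.0) -> Spectrogram:
    """Channel-weighted average short-time power spectral density."""
    if record.duration < window_s:
        raise ValueError("record shorter than one spectrogram window")
    nper = int(round(window_s * record.fs))
    nover = int(round(nper * overlap))
    weights = CHANNEL_WEIGHTS[: record.samples.shape[0]]
    pav = None
    for w, sig in zip(weights, record.samples):
        f, t, p = signal.spectrogram(sig, fs=record.fs, window="hann",
                                     nperseg=nper, noverlap=nover,
                                     scaling="density", mode="psd")
        pav = w * p if pav is None else pav + w * p
    pav /= weights.sum()
    keep = f <= f_hi
    return Spectrogram(times=t, freqs=f[keep], power=pav[keep],
                       window_s=window_s, overlap_fraction=overlap,
                       channel_weights=weights)


def _band_rows(spec: Spectrogram, band: Interval) -> np.ndarray:
    lo, hi = band
    if lo < spec.freqs[0] - 1e-9 or hi > spec.freqs[-1] + 1e-9:
        raise ValueError(f"band {band} outside the frequency grid")
    return (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)


def band_power(spec: Spectrogram, band: Interval) -> BandPowerSeries:
    """Absolute band power: trapezoidal area under P_av(f, t) over the band."""
    rows = _band_rows(spec, band)
    values = np.trapezoid(spec.power[rows], spec.freqs[rows], axis=0)
    return BandPowerSeries(times=spec.times, values=values, band=band,
                           kind="absolute")


def relative_band_power(spec: Spectrogram, band: Interval,
                        reference: Interval = FULL_BAND) -> BandPowerSeries:
    """Relative band power in percent of the reference-band energy.

    Times with zero reference energy get NaN and are excluded from means.
    """
    num = band_power(spec, band).values
    den = band_power(spec, reference).values
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, 100.0 * num / den, np.nan)
    return BandPowerSeries(times=spec.times, values=values, band=band,
                           kind="relative")


def mean_band_power(series: BandPowerSeries,
                    window: Interval | None = None) -> float:
    """Discretized mean of a band-power series, optionally over a window."""
    sel = np.ones(series.times.size, dtype=bool)
    if window is not None:
        sel = (series.times >= window[0]) & (series.times <= window[1])
    vals = series.values[sel]
    return float(np.nanmean(vals)) if vals.size else float("nan")


def peak_frequency(spec: Spectrogram, band: Interval,
                   exclusions: list[Interval] | None = None
                   ) -> PeakFrequencyTrack:
    """Frequency of maximal power in the band; NaN inside exclusions.

    Ties take the lowest-frequency bin (argmax of an ascending grid).
    """
    rows = _band_rows(spec, band)
    sub_freqs = spec.freqs[rows]
    values = sub_freqs[np.argmax(spec.power[rows], axis=0)].astype(float)
    if exclusions:
        values[mask_from_intervals(spec.times, exclusions)] = np.nan
    return PeakFrequencyTrack(times=spec.times, values=values, band=band)


def sg_smooth(track: PeakFrequencyTrack, window_s: float = 120.0,
              step_s: float = 5.0) -> PeakFrequencyTrack:
    """Gap-aware Savitzky–Golay smoothing (order-1 local regression).

    For each output time (every ``step_s`` over the track span) an order-1
    polynomial is fitted to the *defined* samples within a centered
    ``window_s`` window; windows with fewer than two defined samples stay
    undefined.  On a gap-free, uniformly sampled track this reduces to the
    classical first-order Savitzky–Golay filter.
    """
    t = track.times
    v = track.values
    good = ~np.isnan(v)
    t_out = np.arange(t[0], t[-1] + 1e-9, step_s)
    out = np.full(t_out.size, np.nan)
    half = window_s / 2.0
    tg, vg = t[good], v[good]
    if tg.size >= 2:
        lo = np.searchsorted(tg, t_out - half, side="left")
        hi = np.searchsorted(tg, t_out + half, side="right")
        for i, (a, b) in enumerate(zip(lo, hi)):
            if b - a < 2:
                continue
            x, y = tg[a:b], vg[a:b]
            xm = x.mean()
            dx = x - xm
            denom = float(dx @ dx)
            if denom == 0:
                out[i] = y.mean()
                continue
            slope = float(dx @ (y - y.mean())) / denom
            out[i] = y.mean() + slope * (t_out[i] - xm)
    # keep the original undefined (exclusion) structure: points whose
    # nearest original sample was undefined remain undefined
    if (~good).any() and t.size > 1:
        nearest = np.clip(np.searchsorted(t, t_out), 0, t.size - 1)
        left = np.clip(nearest - 1, 0, t.size - 1)
        use_left = (np.abs(t[left] - t_out) <= np.abs(t[nearest] - t_out))
        nearest = np.where(use_left, left, nearest)
        out[~good[nearest]] = np.nan
    return PeakFrequencyTrack(times=t_out, values=out, band=track.band,
                              smoothed=True)
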