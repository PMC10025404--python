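"""Iso-electric suppression (IES) and α-suppression (αS) segmentation.

The dual-envelope, dual-threshold rule:

1. ``S(t)`` is the channel-averaged broadband signal; ``Ŝ_α(t)`` is the
   8–16 Hz band-passed channel average normalized to unit RMS.
2. Upper/lower envelopes are linear interpolations through the strict
   local maxima/minima; ``D(t)`` and ``D_α(t)`` are their widths.
3. Thresholds ``T_IES = min(8 µV, median D)`` and
   ``T_α = min(0.25, median D_α)``.
4. Sample-wise sets: IES where ``D < T_IES`` and ``D_α < T_α``; αS where
   ``D ≥ T_IES`` and ``D_α < T_α``.  Thresholding the instantaneous
   envelope width rather than the raw trace avoids firing at every zero
   crossing while preserving the amplitude semantics of the rule.
5. Each set is smoothed with morphological erosion/dilation using a 0.5 s
   structuring element and aggregated into intervals.  The composition
   differs per set: the IES mask is opened then closed (IES epochs sit far
   below threshold, so erosion-first removes sub-element false detections
   without harming genuine epochs), while the αS mask is closed then
   opened (the αS condition sits *between* two thresholds and chatters at
   the sample level, so sub-element dropouts inside genuine epochs must be
   bridged before erosion).  Both compositions remove every feature
   shorter than the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .intervals import (Interval, clip_to_window, intervals_from_mask,
                        max_duration, total_duration)
from .records import EEGRecord


@dataclass
class EnvelopePair:
    times: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    source: str = "broadband"      # or "alpha-normalized"

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class SuppressionSegments:
    ies: list[Interval] = field(default_factory=list)
    alpha_s: list[Interval] = field(default_factory=list)
    t_ies: float = 8.0             # µV
    t_alpha: float = 0.25          # unitless

    @property
    def s_ies_total(self) -> float:
        """Total IES time in minutes."""
        return total_duration(self.ies) / 60.0

    @property
    def l_ies_max(self) -> float:
        """Longest single IES in minutes (0 if none)."""
        return max_duration(self.ies) / 60.0


def alpha_normalize(record: EEGRecord, band: Interval = (8.0, 16.0),
                    order: int = 4) -> np.ndarray:
    """Zero-phase band-pass of the channel average, scaled to unit RMS."""
    if record.fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the α filter band")
    mean_sig = record.samples.mean(axis=0)
    sos = signal.butter(order, band, btype="bandpass", fs=record.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, mean_sig)
    rms = float(np.sqrt(np.mean(filtered**2)))
    if rms == 0:
        raise ValueError("zero-RMS signal cannot be normalized")
    return filtered / rms


def envelopes(track: np.ndarray, fs: float,
              source: str = "broadband") -> EnvelopePair:
    """Upper/lower envelopes through strict local extrema (linear interp).

    A monotone or constant track has no interior extrema; both envelopes
    then degenerate to the track itself (width 0).
    """
    track = np.asarray(track, dtype=float)
    if track.size < 3:
        raise ValueError("track must have at least 3 samples")
    t = np.arange(track.size) / fs
    d = np.diff(track)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
    if maxima.size == 0 or minima.size == 0:
        return EnvelopePair(times=t, upper=track.copy(), lower=track.copy(),
                            source=source)
    upper = np.interp(t, t[maxima], track[maxima])
    lower = np.interp(t, t[minima], track[minima])
    return EnvelopePair(times=t, upper=upper, lower=lower, source=source)


def _smooth_mask(mask: np.ndarray, width: int, close_first: bool) -> np.ndarray:
    """Morphological smoothing with a flat element of ``width`` samples.

    ``close_first=False``: opening then closing — drops True runs shorter
    than the element, then bridges remaining sub-element gaps.
    ``close_first=True``: closing then opening — bridges sub-element gaps
    first, then drops isolated short runs.
    """
    if width <= 1 or not mask.any():
        return mask
    structure = np.ones(width, dtype=bool)
    if close_first:
        out = ndimage.binary_closing(mask, structure=structure)
        return ndimage.binary_opening(out, structure=structure)
    out = ndimage.binary_opening(mask, structure=structure)
    return ndimage.binary_closing(out, structure=structure)


def segment_suppressions(record: EEGRecord, t_ies_cap: float = 8.0,
                         t_alpha_cap: float = 0.25,
                         structuring_s: float = 0.5) -> SuppressionSegments:
    """Segment IES and αS epochs from the envelope widths."""
    fs = record.fs
    broadband = record.samples.mean(axis=0)
    alpha_hat = alpha_normalize(record)

    d = envelopes(broadband, fs, "broadband").width
    d_alpha = envelopes(alpha_hat, fs, "alpha-normalized").width

    t_ies = float(min(t_ies_cap, np.median(d)))
    t_alpha = float(min(t_alpha_cap, np.median(d_alpha)))

    low_alpha = d_alpha < t_alpha
    ies_mask = (d < t_ies) & low_alpha
    alpha_s_mask = (d >= t_ies) & low_alpha

    width = max(int(round(structuring_s * fs)), 1)
    ies_mask = _smooth_mask(ies_mask, width, close_first=False)
    alpha_s_mask = _smooth_mask(alpha_s_mask, width, close_first=True)
    alpha_s_mask &= ~ies_mask      # conditions are mutually exclusive

    times = record.times
    return SuppressionSegments(
        ies=intervals_from_mask(ies_mask, times),
        alpha_s=intervals_from_mask(alpha_s_mask, times),
        t_ies=t_ies, t_alpha=t_alpha,
    )


def suppression_stats(segments: list[Interval],
                      window: Interval) -> tuple[float, float]:
    """(total, longest) suppression time in minutes, clipped to ``window``."""
    clipped = clip_to_window(segments, window)
    return total_duration(clipped) / 60.0, max_duration(clipped) / 60.0
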