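"""Motion-artifact flagging and wavelet quantile normalization (WQN).

Artifacts are flagged per channel with a robust sliding-window rule: the
mean power ``P_i`` of each 10 s window (50 % overlap) is compared to the
median window power; windows whose power *exceeds* it by more than three
median absolute deviations — ``P_i − median(P) > 3·MAD`` with
``MAD = median(|P_i − median(P)|)`` — are marked.  The rule is one-sided:
motion artifacts are high-power events, and flagging low-power windows
would hand genuine iso-electric suppressions to the correction stage.
The final mask is the union over channels.  With a strict inequality a
perfectly constant recording yields no artifacts (MAD = 0 flags nothing).

Flagged intervals are then corrected channel-wise by quantile-normalizing
discrete-wavelet coefficient magnitudes against a clean reference interval
of equal length (nearest preceding unflagged stretch, else the nearest
following one), preserving coefficient signs.  Unflagged samples are left
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .intervals import Interval, clip_to_window, normalize
from .records import EEGRecord

logger = logging.getLogger(__name__)


@dataclass
class ArtifactMask:
    """Flagged artifact intervals plus the per-channel window diagnostics."""

    window_length: float                      # s
    overlap_fraction: float
    window_powers: np.ndarray                 # (n_channels, n_windows), µV²
    window_starts: np.ndarray                 # s
    mad: np.ndarray                           # per channel, µV²
    flagged: list[Interval] = field(default_factory=list)
    flagged_per_channel: list[list[Interval]] = field(default_factory=list)


def detect_artifacts(record: EEGRecord, window_s: float = 10.0,
                     overlap: float = 0.5) -> ArtifactMask:
    """Flag high-power windows per channel by the 3-MAD rule."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nwin = int(round(window_s * record.fs))
    step = max(int(round(nwin * (1 - overlap))), 1)
    if record.n_samples < nwin:
        raise ValueError("record shorter than one analysis window")

    starts = np.arange(0, record.n_samples - nwin + 1, step)
    powers = np.empty((record.samples.shape[0], starts.size))
    for ch, sig in enumerate(record.samples):
        segs = np.lib.stride_tricks.sliding_window_view(sig, nwin)[::step]
        powers[ch] = np.mean(segs[: starts.size] ** 2, axis=1)

    mads = np.empty(powers.shape[0])
    per_channel: list[list[Interval]] = []
    union: list[Interval] = []
    for ch, p in enumerate(powers):
        dev = p - np.median(p)
        mad = float(np.median(np.abs(dev)))
        mads[ch] = mad
        # one-sided and strict: only high-power excursions are artifacts,
        # and a constant recording (MAD 0) flags nothing
        hit = dev > 3.0 * mad
        ivs = normalize([(starts[i] / record.fs,
                          (starts[i] + nwin) / record.fs)
                         for i in np.flatnonzero(hit)])
        per_channel.append(ivs)
        union.extend(ivs)
    return ArtifactMask(window_length=window_s, overlap_fraction=overlap,
                        window_powers=powers, window_starts=starts / record.fs,
                        mad=mads, flagged=normalize(union),
                        flagged_per_channel=per_channel)


def _quantile_map(art: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Remap |art| through the empirical quantile function of |ref|."""
    if art.size == 0 or ref.size == 0:
        return art
    mags = np.abs(art)
    ranks = np.argsort(np.argsort(mags, kind="stable"), kind="stable")
    q = (ranks + 0.5) / mags.size
    ref_sorted = np.sort(np.abs(ref))
    ref_q = (np.arange(ref_sorted.size) + 0.5) / ref_sorted.size
    mapped = np.interp(q, ref_q, ref_sorted)
    return np.sign(art) * mapped


def _find_reference(mask_bool: np.ndarray, a: int, b: int) -> tuple[int, int] | None:
    """Nearest clean stretch of length b−a: preceding preferred, else following."""
    n = b - a
    if n <= 0 or n > mask_bool.size:
        return None
    csum = np.concatenate(([0], np.cumsum(mask_bool.astype(np.int64))))
    # window [s, s+n) is clean iff it contains no flagged samples
    ok = np.flatnonzero(csum[n:] - csum[:-n] == 0)
    if ok.size == 0:
        return None
    before = ok[ok + n <= a]
    if before.size:
        s = int(before[-1])            # nearest preceding
        return s, s + n
    after = ok[ok >= b]
    if after.size:
        s = int(after[0])              # nearest following
        return s, s + n
    return None


def wqn_correct(record: EEGRecord, mask: ArtifactMask,
                wavelet: str = "haar", levels: int = 5) -> EEGRecord:
    """Correct flagged intervals by wavelet quantile normalization.

    Returns a new record; intervals without a clean equal-length reference
    are left uncorrected with a logged warning.
    """
    out = record.copy()
    if not mask.flagged:
        return out
    fs = record.fs
    n_total = record.n_samples
    for ch in range(record.samples.shape[0]):
        ivs = mask.flagged_per_channel[ch] if mask.flagged_per_channel else mask.flagged
        if not ivs:
            continue
        mask_bool = np.zeros(n_total, dtype=bool)
        for t0, t1 in ivs:
            mask_bool[int(round(t0 * fs)):int(round(t1 * fs))] = True
        for t0, t1 in ivs:
            a, b = int(round(t0 * fs)), min(int(round(t1 * fs)), n_total)
            ref = _find_reference(mask_bool, a, b)
            if ref is None:
                logger.warning("no clean reference for artifact [%.1f, %.1f] s "
                               "on channel %s; left uncorrected", t0, t1,
                               record.channel_labels[ch])
                continue
            art_seg = out.samples[ch, a:b]
            ref_seg = record.samples[ch, ref[0]:ref[1]]
            lv = min(levels, pywt.dwt_max_level(b - a, wavelet))
            art_coeffs = pywt.wavedec(art_seg, wavelet, level=lv)
            ref_coeffs = pywt.wavedec(ref_seg, wavelet, level=lv)
            mapped = [_quantile_map(ac, rc)
                      for ac, rc in zip(art_coeffs, ref_coeffs)]
            rec_seg = pywt.waverec(mapped, wavelet)[: b - a]
            out.samples[ch, a:b] = rec_seg
    return out
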