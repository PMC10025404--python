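"""Sigmoid fits of recovery band powers and emergence-trajectory markers.

The δ- and α-band powers over the final window of the recording are each
fitted with a decaying sigmoid

    S(t) = a / (1 + exp(c (t − t0))) + b,      a ≥ 0, c > 0,

by bounded nonlinear least squares with multi-start initialization.  The
emergence markers are the 5 %-amplitude-remaining crossings: ``t_in`` from
the δ fit (the δ plateau has essentially vanished) and ``t_out`` from the
α fit (the α power reaches its lower plateau).  The closed form of the
crossing is ``t = t0 + ln(1/λ − 1)/c``.  The trajectory shifts are
``Δt_ROC = (t_out − t_in)/60`` minutes and ``Δf_ROC = f_max(t_out) −
f_max(t_in)`` Hz, with ``f_max`` looked up at the nearest defined sample
within ±30 s, else linearly interpolated across the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .intervals import Interval
from .spectral import BandPowerSeries, PeakFrequencyTrack


@dataclass
class SigmoidFit:
    a: float            # transition amplitude (band-power units), >= 0
    b: float            # lower plateau
    c: float            # 1/s, > 0 encodes decay
    t0: float           # s, transition center
    rss: float          # residual sum of squares
    band: str = ""      # "delta" or "alpha"
    no_transition: bool = False

    def __call__(self, t):
        z = np.clip(self.c * (np.asarray(t, dtype=float) - self.t0), -700, 700)
        return self.a / (1.0 + np.exp(z)) + self.b


class FitError(RuntimeError):
    """Raised when no sigmoid start converges; carries the best partial fit."""

    def __init__(self, msg: str, best: SigmoidFit | None = None):
        super().__init__(msg)
        self.best = best


def _sigmoid_residuals(params, t, y):
    a, b, c, t0 = params
    z = np.clip(c * (t - t0), -700, 700)
    return a / (1.0 + np.exp(z)) + b - y


def fit_sigmoid(series: BandPowerSeries, window: Interval,
                band: str = "") -> SigmoidFit:
    """Least-squares sigmoid fit of a band-power series over ``window``.

    Multi-start: t0 over five quantiles of the window, slope c in
    {0.005, 0.02, 0.1} 1/s, amplitude/baseline from the series quartiles.
    A fit whose amplitude is negligible against the series spread is
    flagged ``no_transition``.
    """
    sel = (series.times >= window[0]) & (series.times <= window[1])
    t, y = series.times[sel], series.values[sel]
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if t.size < 20:
        raise ValueError("window must contain at least 20 samples")

    q1, q3 = np.percentile(y, [25, 75])
    a0 = max(q3 - q1, 1e-12)
    b0 = q1
    t0_grid = np.quantile(t, [0.1, 0.3, 0.5, 0.7, 0.9])
    best = None
    for t0 in t0_grid:
        for c0 in (0.005, 0.02, 0.1):
            try:
                res = least_squares(
                    _sigmoid_residuals, x0=[a0, b0, c0, t0], args=(t, y),
                    bounds=([0.0, -np.inf, 1e-6, t[0] - 3600.0],
                            [np.inf, np.inf, 10.0, t[-1] + 3600.0]),
                    method="trf", max_nfev=2000)
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        raise FitError("sigmoid fit failed from every start")
    rss, res = best
    a, b, c, t0 = (float(v) for v in res.x)
    spread = max(float(np.ptp(y)), 1e-12)
    fit = SigmoidFit(a=a, b=b, c=c, t0=t0, rss=rss, band=band,
                     no_transition=(a < 0.05 * spread or a < 1e-9))
    if not best[1].success and not fit.no_transition:
        raise FitError("sigmoid fit did not converge", best=fit)
    return fit


def threshold_crossing(fit: SigmoidFit, lam: float = 0.05) -> float:
    """Time where the sigmoid equals ``a·λ + b``: t0 + ln(1/λ − 1)/c."""
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly between 0 and 1")
    if fit.c == 0:
        raise ValueError("degenerate sigmoid slope c = 0")
    return fit.t0 + np.log(1.0 / lam - 1.0) / fit.c


@dataclass
class EmergenceMarkers:
    t_in: float                 # s
    t_out: float                # s
    dt_roc: float               # min
    df_roc: float               # Hz
    fmax_at_in: float           # Hz
    fmax_at_out: float          # Hz
    lambda_in: float = 0.05
    lambda_out: float = 0.05
    flags: list[str] = field(default_factory=list)


def _fmax_lookup(track: PeakFrequencyTrack, t: float,
                 max_gap_s: float = 30.0) -> float:
    """Nearest defined sample within ±max_gap_s, else interpolate the gap."""
    good = track.defined
    if not good.any():
        return float("nan")
    tg, vg = track.times[good], track.values[good]
    i = int(np.argmin(np.abs(tg - t)))
    if abs(tg[i] - t) <= max_gap_s:
        return float(vg[i])
    return float(np.interp(t, tg, vg))


def emergence_markers(delta_fit: SigmoidFit, alpha_fit: SigmoidFit,
                      fmax: PeakFrequencyTrack, lambda_in: float = 0.05,
                      lambda_out: float = 0.05) -> EmergenceMarkers:
    """Recovery markers from the two sigmoid fits and the f_max track."""
    t_in = threshold_crossing(delta_fit, lambda_in)
    t_out = threshold_crossing(alpha_fit, lambda_out)
    flags = []
    if delta_fit.no_transition:
        flags.append("delta_no_transition")
    if alpha_fit.no_transition:
        flags.append("alpha_no_transition")
    if t_out <= t_in:
        flags.append("inconsistent_transition")
    f_in = _fmax_lookup(fmax, t_in)
    f_out = _fmax_lookup(fmax, t_out)
    return EmergenceMarkers(
        t_in=float(t_in), t_out=float(t_out),
        dt_roc=float((t_out - t_in) / 60.0),
        df_roc=float(f_out - f_in),
        fmax_at_in=f_in, fmax_at_out=f_out,
        lambda_in=lambda_in, lambda_out=lambda_out, flags=flags)
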