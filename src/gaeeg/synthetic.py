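"""Synthetic general-anesthesia EEG cohorts with full ground truth.

Each synthetic patient is the sum of

* a narrowband, amplitude-modulated δ oscillation (0.1–4 Hz),
* a narrowband θ oscillation (~6 Hz), the slow cortical rhythm prominent
  under GABAergic anesthetics; it persists through α-suppressions and
  decays together with δ during recovery,
* a narrowband α oscillation whose peak frequency sits in 8–12 Hz during
  maintenance and ramps upward during recovery (the "zip" signature),
* a channel-common broadband beta component (22–28 Hz) carrying the
  residual fast cortical activity of the anesthetized brain,
* independent per-channel 1/f (pink) background noise,
* an independent per-channel fast broadband (25–45 Hz) component standing
  in for high-beta/EMG activity, and
* optional high-amplitude broadband motion-artifact bursts.

During planted iso-electric suppressions (IES) the whole signal is scaled
to a near-zero floor; during α-suppressions only the α component collapses.
During recovery the δ and α band *powers* decay as logistic (sigmoid)
functions of time — δ first — so that the downstream sigmoid fits have an
exact planted truth: ``true_t_in`` is the 5 %-remaining crossing of the δ
power sigmoid.  The α peak frequency ramps linearly upward from ``t_in``;
when the ramp carries the α peak past the 12 Hz band edge the 8–12 Hz
band power collapses before the amplitude transition completes, so
``true_t_out`` is defined as the 5 %-remaining crossing of the planted
*in-band* α power (amplitude sigmoid times band occupancy of the ramping
peak), which coincides with the amplitude crossing whenever the ramp
stays inside the band.  ``true_df_roc`` is the planted peak-frequency
difference between ``true_t_out`` and ``true_t_in``.

Default amplitudes are calibrated analytically so that the relative band
powers of a maintenance epoch sit near the middle of clinically typical
ranges (δ about two thirds of 0.1–45 Hz energy, α about 12 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import Interval, normalize, total_duration, max_duration
from .records import (
    FRONTAL_CHANNELS,
    BandModel,
    EEGRecord,
    InvalidSpecError,
    PhasePlan,
    write_record,
)

LN19 = float(np.log(19.0))  # 5 %-remaining crossing offset: t = t0 + ln(19)/c


@dataclass
class PatientSpec:
    """Per-patient generator parameters (times in the units noted)."""

    fs: float = 250.0
    induction_min: float = 8.0
    maintenance_min: float = 20.0
    recovery_min: float = 20.0

    delta_amp: float = 21.5        # µV, oscillation amplitude
    theta_amp: float = 10.0        # µV, channel-common ~6 Hz rhythm
    alpha_amp: float = 8.3         # µV
    pink_rms: float = 0.8          # µV, per-channel 1/f background
    beta_rms: float = 0.3          # µV, channel-common 22–28 Hz activity
    fast_rms: float = 0.3          # µV, per-channel 25–45 Hz broadband
    delta_freq: float = 1.2        # Hz, δ peak frequency
    theta_freq: float = 6.0        # Hz
    alpha_freq: float = 9.6        # Hz, maintenance α peak frequency
    freq_wander_hz: float = 0.5    # Hz RMS of the slow peak-frequency wander
    am_depth: float = 0.2          # fractional slow amplitude modulation

    dt_roc_min: float = 7.8        # planted nominal t_out − t_in
    df_roc_hz: float = 3.3         # planted α peak-frequency ramp
    t_in_offset_min: float = 5.5   # t_in − recovery_start
    c_delta: float = 0.03          # 1/s, δ power sigmoid slope
    c_alpha: float = 0.03          # 1/s, α power sigmoid slope
    delta_baseline: float = 0.02   # residual δ power fraction after recovery
    alpha_baseline: float = 0.06   # residual α power fraction after recovery

    ies_floor_ratio: float = 0.01  # amplitude scale inside IES
    edge_ramp_s: float = 0.2       # cosine ramp at suppression edges

    bolus_ies: list[Interval] = field(default_factory=list)
    spontaneous_ies: list[Interval] = field(default_factory=list)
    alpha_suppressions: list[Interval] = field(default_factory=list)
    artifact_bursts: list[Interval] = field(default_factory=list)
    artifact_gain: float = 10.0    # burst amplitude relative to background RMS

    extubation_extra_min: float = 1.5  # extubation after t_out

    def validate(self) -> None:
        for name in ("fs", "induction_min", "maintenance_min", "recovery_min",
                     "dt_roc_min", "df_roc_hz"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.fs < 128:
            raise InvalidSpecError("fs must be at least 128 Hz")
        if not 8.0 <= self.alpha_freq <= 12.0:
            raise InvalidSpecError("alpha_freq must lie in [8, 12] Hz")

    @property
    def duration_s(self) -> float:
        return 60.0 * (self.induction_min + self.maintenance_min + self.recovery_min)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort draw."""

    n_patients: int
    group: str = "children"
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    render: bool = True   # False: draw parameters / truth table only

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidSpecError("n_patients must be >= 1")
        if self.group not in GROUP_PRIORS:
            raise InvalidSpecError(f"unknown group {self.group!r}")


# Per-group parameter priors.  Log-normal medians/sigmas for the recovery
# shifts follow published pediatric/adult cohort medians and IQRs
# (children: dt 7.8 [4.2, 10.2] min, df 3.3 [1.8, 5.0] Hz; adults:
# dt 7.3 [5.8, 10.4] min, df 1.9 [1.3, 2.5] Hz); sigma = ln(Q3/Q1)/(2*0.6745).
GROUP_PRIORS: dict[str, dict] = {
    "children": dict(
        dt_roc_lognorm=(np.log(7.8), 0.658), dt_roc_clip=(1.5, 14.0),
        df_roc_lognorm=(np.log(3.3), 0.757), df_roc_clip=(0.5, 8.0),
        alpha_freq=(9.0, 0.2), alpha_freq_clip=(8.6, 9.5),
        bolus_ies_s_lognorm=(np.log(18.0), 0.9),        # L_IES ~ 0.3 min median
        n_spont_ies_poisson=3.0, spont_ies_s_lognorm=(np.log(15.0), 0.6),
        n_alpha_s_poisson=2.0, alpha_s_s_lognorm=(np.log(20.0), 0.5),
        n_artifact_poisson=2.0,
        age=(5.0, 2.0, 15.0), weight=(22.0, 16.0, 45.0),
    ),
    "adults": dict(
        dt_roc_lognorm=(np.log(7.3), 0.433), dt_roc_clip=(1.5, 14.0),
        df_roc_lognorm=(np.log(1.9), 0.485), df_roc_clip=(0.3, 8.0),
        alpha_freq=(9.7, 0.3), alpha_freq_clip=(9.0, 11.0),
        bolus_ies_s_lognorm=None,                        # TCI induction: no bolus
        n_spont_ies_poisson=0.7, spont_ies_s_lognorm=(np.log(10.0), 0.6),
        n_alpha_s_poisson=1.5, alpha_s_s_lognorm=(np.log(20.0), 0.5),
        n_artifact_poisson=2.0,
        age=(37.0, 16.0, 58.0), weight=(80.0, 55.0, 100.0),
    ),
}


def _smooth_noise(rng: np.random.Generator, n: int, smooth_s: float,
                  grid_s: float = 1.0) -> np.ndarray:
    """Unit-RMS Gaussian-smoothed noise on a coarse grid (length n)."""
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(n + 40), smooth_s / grid_s,
                          mode="reflect")[20:-20]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float,
                f_lo: float = 0.05, f_knee: float = 10.0) -> np.ndarray:
    """Background noise with a 1/f power spectrum up to ``f_knee`` and a
    steeper 1/f³ decay above it (anesthesia EEG background falls off much
    faster than 1/f beyond the α range), scaled to the target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    fc = np.maximum(f, f_lo)
    shape = np.where(fc <= f_knee,
                     1.0 / np.sqrt(fc),
                     f_knee / np.sqrt(f_knee) / fc)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / max(x.std(), 1e-12))


def _band_noise(rng: np.random.Generator, n: int, fs: float, rms: float,
                lo: float, hi: float) -> np.ndarray:
    """Flat-spectrum noise restricted to [lo, hi] Hz at the target RMS."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    return x * (rms / max(x.std(), 1e-12))


def _gate(t: np.ndarray, intervals: list[Interval], floor: float,
          ramp_s: float) -> np.ndarray:
    """Multiplicative gate: ``floor`` inside intervals, 1 outside, with a
    cosine ramp of ``ramp_s`` just outside each boundary."""
    gate = np.ones_like(t)
    for a, b in intervals:
        dist = np.maximum(a - t, t - b)          # <0 inside
        w = np.clip(dist / ramp_s, 0.0, 1.0)
        edge = 0.5 - 0.5 * np.cos(np.pi * w)     # 0 at boundary -> 1 outside
        local = floor + (1.0 - floor) * edge
        gate = np.minimum(gate, local)
    return gate


def _power_shape(t: np.ndarray, t0: float, c: float, baseline: float) -> np.ndarray:
    """Unit-plateau logistic power decay with a residual ``baseline``."""
    sig = 1.0 / (1.0 + np.exp(np.clip(c * (t - t0), -60, 60)))
    return baseline + (1.0 - baseline) * sig


def plan_and_band(spec: PatientSpec, seed: int) -> tuple[PhasePlan, BandModel]:
    """Build the ground-truth phase plan and band model without rendering.

    Uses its own seeded stream for the coarse (1 s grid) stochastic tracks,
    so the truth can be produced cheaply for parameter-calibration checks.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    dur = spec.duration_s
    ind_end = spec.induction_min * 60.0
    maint_end = ind_end + spec.maintenance_min * 60.0
    recovery_start = maint_end

    # Recovery timing: planted crossings of the band-power sigmoids.
    t_in = recovery_start + spec.t_in_offset_min * 60.0
    t_out_nominal = t_in + spec.dt_roc_min * 60.0
    if t_out_nominal > dur - 60.0:
        raise InvalidSpecError("recovery too short for the requested dt_roc")
    t0_delta = t_in - LN19 / spec.c_delta
    t0_alpha = t_out_nominal - LN19 / spec.c_alpha

    n_coarse = int(np.ceil(dur)) + 1
    t_coarse = np.arange(n_coarse, dtype=float)
    wander_a = spec.freq_wander_hz * _smooth_noise(rng, n_coarse, 30.0)
    wander_d = 0.4 * _smooth_noise(rng, n_coarse, 30.0)
    ramp_coarse = spec.df_roc_hz * np.clip(
        (t_coarse - t_in) / max(t_out_nominal - t_in, 1.0), 0.0, 1.0)
    f_alpha_coarse = np.clip(spec.alpha_freq + wander_a, 8.05, 11.95) + ramp_coarse
    f_delta_coarse = np.clip(spec.delta_freq + wander_d, 0.3, 3.8)

    # True t_out: 5 %-remaining crossing of the in-band (8-12 Hz) α power.
    # Band occupancy of the ramping spectral peak falls to zero just past
    # the 12 Hz edge (finite spectral width of the windowed tone).  The
    # crossing is computed on the slow component of the planted frequency
    # track (fast wander averages out at the transition scale).
    from scipy.ndimage import gaussian_filter1d

    f_alpha_slow = gaussian_filter1d(f_alpha_coarse, 30.0, mode="nearest")
    p_alpha_coarse = _power_shape(t_coarse, t0_alpha, spec.c_alpha,
                                  spec.alpha_baseline)
    occupancy = np.clip((12.05 - f_alpha_slow) / 0.15, 0.0, 1.0)
    q = p_alpha_coarse * occupancy
    after = t_coarse >= t_in
    q_hi = float(q[after][0])
    q_lo = float(q[after].min())
    level = q_lo + 0.05 * (q_hi - q_lo)
    below = after & (q <= level)
    t_out = float(t_coarse[below][0]) if below.any() else t_out_nominal

    plan = PhasePlan(
        induction_span=(0.0, ind_end),
        maintenance_span=(ind_end, maint_end),
        recovery_start=recovery_start,
        extubation_time=min(t_out + spec.extubation_extra_min * 60.0, dur),
        bolus_ies=normalize(spec.bolus_ies),
        spontaneous_ies=normalize(spec.spontaneous_ies),
        alpha_suppressions=normalize(spec.alpha_suppressions),
        artifact_bursts=normalize(spec.artifact_bursts),
    )
    band = BandModel(
        track_times=t_coarse,
        delta_amp=spec.delta_amp * np.sqrt(
            _power_shape(t_coarse, t0_delta, spec.c_delta, spec.delta_baseline)),
        alpha_amp=spec.alpha_amp * np.sqrt(
            _power_shape(t_coarse, t0_alpha, spec.c_alpha, spec.alpha_baseline)),
        alpha_peak_freq=f_alpha_coarse,
        delta_peak_freq=f_delta_coarse,
        noise_floor=spec.pink_rms,
        true_t_in=t_in,
        true_t_out=t_out,
        true_dt_roc=(t_out - t_in) / 60.0,
        true_df_roc=float(np.interp(t_out, t_coarse, f_alpha_slow) -
                          np.interp(t_in, t_coarse, f_alpha_slow)),
    )
    return plan, band


def synthesize_record(spec: PatientSpec, seed: int,
                      patient_id: str = "patient") -> EEGRecord:
    """Render one synthetic patient record with ground-truth annotations.

    Two calls with the same (spec, seed) are bit-identical.
    """
    plan, band = plan_and_band(spec, seed)
    rng = np.random.default_rng((seed, 1))   # rendering stream
    fs = spec.fs
    dur = spec.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    t_coarse = band.track_times

    t0_delta = band.true_t_in - LN19 / spec.c_delta
    t0_alpha = (band.true_t_in + spec.dt_roc_min * 60.0 -
                LN19 / spec.c_alpha)
    p_delta = _power_shape(t, t0_delta, spec.c_delta, spec.delta_baseline)
    p_alpha = _power_shape(t, t0_alpha, spec.c_alpha, spec.alpha_baseline)

    # Gentle onset over the first 30 s of induction, starting from the
    # awake amplitude scale rather than a flat trace.
    onset = np.clip(0.5 + t / 60.0, 0.0, 1.0)

    # Slow per-band amplitude modulation.
    n_coarse = t_coarse.size
    am_d = 1.0 + spec.am_depth * _smooth_noise(rng, n_coarse, 10.0)
    am_a = 1.0 + spec.am_depth * _smooth_noise(rng, n_coarse, 10.0)
    am_t = 1.0 + 0.15 * _smooth_noise(rng, n_coarse, 10.0)
    am_d = np.interp(t, t_coarse, np.clip(am_d, 0.1, None))
    am_a = np.interp(t, t_coarse, np.clip(am_a, 0.1, None))
    am_t = np.interp(t, t_coarse, np.clip(am_t, 0.5, None))

    delta_env = spec.delta_amp * np.sqrt(p_delta) * am_d * onset
    alpha_env = spec.alpha_amp * np.sqrt(p_alpha) * am_a * onset
    theta_env = spec.theta_amp * np.sqrt(p_delta) * am_t * onset

    f_alpha = np.interp(t, t_coarse, band.alpha_peak_freq)
    f_delta = np.interp(t, t_coarse, band.delta_peak_freq)
    phase_a = 2 * np.pi * np.cumsum(f_alpha) / fs + rng.uniform(0, 2 * np.pi)
    phase_d = 2 * np.pi * np.cumsum(f_delta) / fs + rng.uniform(0, 2 * np.pi)

    ies_gate = _gate(t, plan.all_ies, spec.ies_floor_ratio, spec.edge_ramp_s)
    alpha_gate = _gate(t, plan.alpha_suppressions, spec.ies_floor_ratio,
                       spec.edge_ramp_s)

    beta_common = _band_noise(rng, n, fs, spec.beta_rms, 22.0, 28.0)
    phase_t = 2 * np.pi * spec.theta_freq * t + rng.uniform(0, 2 * np.pi)
    common = (delta_env * np.sin(phase_d) + theta_env * np.sin(phase_t) +
              alpha_env * alpha_gate * np.sin(phase_a) + beta_common)

    background_rms = np.sqrt(spec.pink_rms**2 + spec.fast_rms**2 +
                             spec.beta_rms**2 + spec.delta_amp**2 / 2 +
                             spec.theta_amp**2 / 2 + spec.alpha_amp**2 / 2)

    samples = np.empty((len(FRONTAL_CHANNELS), n))
    for ch in range(len(FRONTAL_CHANNELS)):
        noise = (_pink_noise(rng, n, fs, spec.pink_rms) +
                 _band_noise(rng, n, fs, spec.fast_rms, 25.0, 45.0))
        sig = ies_gate * (common + noise)
        for a, b in plan.artifact_bursts:
            idx = (t >= a) & (t < b)
            m = int(idx.sum())
            if m == 0:
                continue
            gain = spec.artifact_gain * rng.uniform(0.7, 1.3)
            burst = _band_noise(rng, m, fs, gain * background_rms, 0.5, 40.0)
            taper = np.sin(np.pi * np.arange(m) / max(m - 1, 1)) ** 2
            sig[idx] += burst * taper
        samples[ch] = sig

    return EEGRecord(fs=fs, samples=samples, phase_plan=plan, band_model=band,
                     patient_id=patient_id)


# ---------------------------------------------------------------------------
# Cohort drawing


def _draw_lognorm(rng, mu_sigma, clip=None) -> float:
    mu, sigma = mu_sigma
    x = float(np.exp(rng.normal(mu, sigma)))
    if clip is not None:
        x = float(np.clip(x, *clip))
    return x


def _place_intervals(rng, window: Interval, durations: list[float],
                     taken: list[Interval], margin: float = 10.0) -> list[Interval]:
    """Place non-overlapping intervals of given durations inside ``window``."""
    placed: list[Interval] = []
    for d in durations:
        lo, hi = window[0] + margin, window[1] - margin - d
        if hi <= lo:
            continue
        for _ in range(50):
            a = rng.uniform(lo, hi)
            cand = (a, a + d)
            if all(cand[1] + margin < x[0] or cand[0] > x[1] + margin
                   for x in taken + placed):
                placed.append(cand)
                break
    return sorted(placed)


def draw_patient_spec(group: str, rng: np.random.Generator,
                      base: PatientSpec | None = None) -> PatientSpec:
    """Draw one patient's generator parameters from the group priors."""
    pri = GROUP_PRIORS[group]
    spec = base if base is not None else PatientSpec()

    dt = _draw_lognorm(rng, pri["dt_roc_lognorm"], pri["dt_roc_clip"])
    df = _draw_lognorm(rng, pri["df_roc_lognorm"], pri["df_roc_clip"])
    t_in_offset = float(rng.uniform(5.0, 6.5))
    # keep the nominal t_out and a final α plateau inside the recovery window
    max_dt = spec.recovery_min - t_in_offset - 3.0
    dt = min(dt, max_dt)
    spec = replace(
        spec,
        dt_roc_min=dt,
        df_roc_hz=df,
        alpha_freq=float(np.clip(rng.normal(*pri["alpha_freq"]),
                                 *pri["alpha_freq_clip"])),
        delta_freq=float(rng.uniform(0.8, 1.8)),
        alpha_amp=spec.alpha_amp * float(rng.uniform(0.8, 1.25)),
        delta_amp=spec.delta_amp * float(rng.uniform(0.8, 1.25)),
        c_delta=float(rng.uniform(0.025, 0.05)),
        c_alpha=float(rng.uniform(0.025, 0.05)),
        t_in_offset_min=t_in_offset,
        extubation_extra_min=float(rng.uniform(0.5, 2.5)),
    )

    ind_end = spec.induction_min * 60.0
    maint_end = ind_end + spec.maintenance_min * 60.0
    taken: list[Interval] = []
    bolus: list[Interval] = []
    if pri["bolus_ies_s_lognorm"] is not None:
        d = _draw_lognorm(rng, pri["bolus_ies_s_lognorm"], (6.0, 90.0))
        bolus = _place_intervals(rng, (max(ind_end - 150.0, 30.0), ind_end),
                                 [d], taken)
        taken += bolus
    n_sp = int(rng.poisson(pri["n_spont_ies_poisson"]))
    spont = _place_intervals(
        rng, (ind_end, maint_end),
        [_draw_lognorm(rng, pri["spont_ies_s_lognorm"], (5.0, 60.0))
         for _ in range(n_sp)], taken)
    taken += spont
    n_as = int(rng.poisson(pri["n_alpha_s_poisson"]))
    alpha_s = _place_intervals(
        rng, (ind_end, maint_end),
        [_draw_lognorm(rng, pri["alpha_s_s_lognorm"], (5.0, 60.0))
         for _ in range(n_as)], taken)
    taken += alpha_s
    n_art = int(rng.poisson(pri["n_artifact_poisson"]))
    arts = _place_intervals(rng, (30.0, maint_end),
                            [rng.uniform(1.0, 5.0) for _ in range(n_art)], taken)
    return replace(spec, bolus_ies=bolus, spontaneous_ies=spont,
                   alpha_suppressions=alpha_s, artifact_bursts=arts)


def _relative_powers(spec: PatientSpec) -> tuple[float, float]:
    """Analytic maintenance-epoch relative band powers (%, δ then α).

    Accounts for the sinusoidal band powers, the 1/f noise split across
    bands (log split between 0.05 Hz and fs/2), and the flat 20–45 Hz
    component.  Ignores suppressions (short relative to maintenance).
    """
    p_d_osc = spec.delta_amp**2 / 2
    p_t_osc = spec.theta_amp**2 / 2       # 4–8 Hz: outside both bands
    p_a_osc = spec.alpha_amp**2 / 2

    def pink_frac(a, b, f_lo=0.05, f_knee=10.0, f_hi=spec.fs / 2):
        # PSD ∝ 1/f below the knee, ∝ f_knee/f² above it
        def seg(x, y):
            lo1, hi1 = max(x, f_lo), min(y, f_knee)
            part = np.log(hi1 / lo1) if hi1 > lo1 else 0.0
            lo2, hi2 = max(x, f_knee), y
            if hi2 > lo2:
                part += f_knee * (1.0 / lo2 - 1.0 / hi2)
            return part
        return seg(a, b) / seg(f_lo, f_hi)

    pink = spec.pink_rms**2
    fast = spec.fast_rms**2 + spec.beta_rms**2   # all inside [12, 45]
    total = (p_d_osc + p_t_osc + p_a_osc + pink * pink_frac(0.1, 45.0) + fast)
    p_delta = 100.0 * (p_d_osc + pink * pink_frac(0.1, 4.0)) / total
    p_alpha = 100.0 * (p_a_osc + pink * pink_frac(8.0, 12.0)) / total
    return p_delta, p_alpha


def _smoothed_tv_rate(track: np.ndarray, step_s: float = 5.0,
                      window_s: float = 120.0) -> float:
    """Total-variation rate (Hz/min) of a planted track after the same
    2-min local-linear smoothing the pipeline applies."""
    n = track.size
    if n < 3:
        return 0.0
    t = np.arange(n, dtype=float)       # coarse grid is 1 s
    t_out = np.arange(0.0, n - 1, step_s)
    half = window_s / 2
    sm = np.empty(t_out.size)
    for i, tc in enumerate(t_out):
        sel = (t >= tc - half) & (t <= tc + half)
        x, y = t[sel], track[sel]
        slope, icpt = np.polyfit(x, y, 1)
        sm[i] = slope * tc + icpt
    span_min = (t_out[-1] - t_out[0]) / 60.0
    return float(np.abs(np.diff(sm)).sum() / span_min) if span_min > 0 else 0.0


def synthesize_cohort(cohort: CohortSpec,
                      base: PatientSpec | None = None
                      ) -> tuple[list[EEGRecord], pd.DataFrame]:
    """Draw a cohort: records (if ``render``) plus the ground-truth table.

    The table holds the true value of every feature the pipeline later
    estimates, along with drawn demographics.
    """
    pri = GROUP_PRIORS[cohort.group]
    rng = np.random.default_rng(cohort.seed)
    base = base if base is not None else PatientSpec(**cohort.overrides)
    records: list[EEGRecord] = []
    rows = []
    for i in range(cohort.n_patients):
        pid = f"{cohort.group[:2]}{i:03d}"
        spec = draw_patient_spec(cohort.group, rng, base)
        ind_end = spec.induction_min * 60.0
        p_delta, p_alpha = _relative_powers(spec)
        maint_slice = slice(int(ind_end), int(ind_end + spec.maintenance_min * 60))
        pat_seed = int(rng.integers(0, 2**31 - 1))
        if cohort.render:
            rec = synthesize_record(spec, seed=pat_seed, patient_id=pid)
            plan, bm = rec.phase_plan, rec.band_model
            records.append(rec)
        else:
            plan, bm = plan_and_band(spec, pat_seed)
        age_med, age_lo, age_hi = pri["age"]
        w_med, w_lo, w_hi = pri["weight"]
        rows.append(dict(
            patient_id=pid,
            group=cohort.group,
            seed=pat_seed,
            induction_end_s=plan.induction_span[1],
            maintenance_end_s=plan.maintenance_span[1],
            recovery_start_s=plan.recovery_start,
            extubation_time_s=plan.extubation_time,
            s_ies_min=total_duration(plan.all_ies) / 60.0,
            l_ies_min=max_duration(plan.bolus_ies) / 60.0,
            mean_p_alpha=p_alpha,
            mean_p_delta=p_delta,
            v_alpha=_smoothed_tv_rate(bm.alpha_peak_freq[maint_slice]),
            v_delta=_smoothed_tv_rate(bm.delta_peak_freq[maint_slice]),
            t_in_s=bm.true_t_in,
            t_out_s=bm.true_t_out,
            dt_roc_min=bm.true_dt_roc,
            df_roc_hz=bm.true_df_roc,
            extubation_delay_min=(plan.extubation_time - plan.recovery_start) / 60.0,
            age=float(np.clip(rng.normal(age_med, (age_hi - age_lo) / 4),
                              age_lo, age_hi)),
            gender=int(rng.integers(0, 2)),
            weight=float(np.clip(rng.normal(w_med, (w_hi - w_lo) / 4),
                                 w_lo, w_hi)),
        ))
    return records, pd.DataFrame(rows)


def write_cohort(records: list[EEGRecord], truth: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Write one delimited signal file per patient plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_record(rec, out / f"{rec.patient_id}.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)
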