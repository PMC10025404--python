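# gaeeg — spectral EEG analysis of general-anesthesia phases

`gaeeg` quantifies what the frontal EEG does across the three phases of
general anesthesia — induction, maintenance, and recovery — and asks
whether anything measured early in a case predicts how the patient
emerges.  It is written for anesthesia researchers and EEG methodologists
who want a tested, scriptable implementation of this analysis, together
with a synthetic-cohort generator so every stage can be exercised (and
every estimator validated against planted ground truth) without access to
clinical recordings.

## What it computes

From a four-channel frontal montage (F7, Fp1, Fp2, F8) the pipeline
extracts, per patient:

* **Iso-electric suppressions (IES) and α-suppressions (αS).**  The
  channel-averaged signal S(t) and its 8–16 Hz band-passed, RMS-normalized
  version Ŝ_α(t) yield envelope widths D(t) and D_α(t) (linear
  interpolation through local extrema).  With thresholds
  T_IES = min(8 µV, median D) and T_α = min(0.25, median D_α), samples with
  D < T_IES and D_α < T_α are IES; samples with D ≥ T_IES and D_α < T_α are
  αS.  Masks are smoothed morphologically (0.5 s element) and summarized as
  S_IES (total minutes) and L_IES (longest event).
* **Band descriptors.**  A Hann-window spectrogram (20 s window, 75 %
  overlap) averaged over channels with F7/F8 halved:
  P_av = (0.5·P_F7 + P_Fp1 + P_Fp2 + 0.5·P_F8)/3.  Band powers are areas
  under P_av(f, t) over δ = [0.1, 4] Hz and α = [8, 12] Hz, absolute or
  relative to [0.1, 45] Hz; P̄_α and P̄_δ are maintenance means.
* **Emergence markers.**  Over the final 20 min, P_δ and P_α are each fit
  with a decaying sigmoid S(t) = a/(1 + e^{c(t−t0)}) + b.  The markers are
  the 5 %-amplitude-remaining crossings t = t0 + ln(1/λ − 1)/c with
  λ = 0.05: t_in from the δ fit, t_out from the α fit.  The emergence
  trajectory is summarized by Δt_ROC = t_out − t_in (min) and
  Δf_ROC = f_max(t_out) − f_max(t_in) (Hz), where f_max is the
  Savitzky–Golay-smoothed frequency of maximal power in [8, 30] Hz — the
  upward "zip" of the dissolving α rhythm.
* **Band instability.**  The total variation per unit time of the smoothed
  peak-frequency track over suppression-free segments,
  V = Σ|f(t_{i+1}) − f(t_i)| / Σ span (Hz/min), discretized at the track's
  local extrema.
* **Inference.**  Pearson correlations with exact t-transform p-values,
  and null-supporting Bayes factors BF₀₁ under the Zellner–Siow g-prior,

      BF₁₀ = √(n/2)/Γ(½) ∫₀^∞ (1+g)^{(n−p−1)/2} (1+(1−r²)g)^{−(n−1)/2}
                               g^{−3/2} e^{−n/(2g)} dg,

  evaluated by adaptive quadrature on g = u/(1−u); partial correlations
  (residual projection onto age/gender/weight) use the nested-model ratio
  of two such integrals with the models' coefficients of determination.
  Evidence is labeled on the Jeffreys scale (BF₀₁ 1–3 anecdotal, 3–10
  moderate, 10–30 strong, 30–100 very strong, >100 decisive).

The synthetic generator renders cohorts with planted suppressions,
artifacts, band amplitudes, sigmoid recovery decays and peak-frequency
ramps, and returns the true value of every feature the pipeline estimates.

## Worked example

```python
from gaeeg import bf01_correlation, jeffreys_label
from gaeeg.synthetic import CohortSpec, synthesize_cohort
from gaeeg.pipeline import run_patient

records, truth = synthesize_cohort(
    CohortSpec(n_patients=1, group="children", seed=5,
               overrides=dict(induction_min=3.0, maintenance_min=8.0)))
feats = run_patient(records[0])
print(f"S_IES  = {feats.s_ies:.2f} min")
print(f"dt_ROC = {feats.dt_roc:.1f} min   df_ROC = {feats.df_roc:.1f} Hz")
bf = bf01_correlation(-0.44, 27)
print(f"BF01(r=-0.44, n=27) = {bf:.2f}  -> {jeffreys_label(bf)}")
```

prints

```
S_IES  = 1.79 min
dt_ROC = 5.1 min   df_ROC = 0.9 Hz
BF01(r=-0.44, n=27) = 0.49  -> anecdotal evidence for H1
```

The patient spent 1.79 min in iso-electric suppression (the generator
planted 1.82 min); the α band took 5.1 min to dissolve during emergence,
drifting up by 0.9 Hz (planted: 4.6 min, 0.8 Hz).  The Bayes factor for a
correlation of −0.44 at n = 27 is 0.49 — the data mildly favor a real
correlation over the null, but only anecdotally.

Command line:

```bash
gaeeg synth --group children --n 50 --seed 7 --out cohort/
gaeeg run --input cohort/ --out report/
gaeeg bf --r -0.44 --n 27
```

`gaeeg run` writes `features.csv` (one row per patient), `summary.csv`
(per-measure median/Q1/Q3 with r, p, BF₀₁ and Jeffreys labels against both
emergence shifts), `partial_correlations.csv`,
`extubation_correlations.csv`, and a JSON bundle including the
conditional-probability analysis at the 70th percentile.

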