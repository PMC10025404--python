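"""Per-patient feature extraction and cohort-level statistical reports.

``run_patient`` chains preprocessing → spectrogram → suppression
segmentation → band descriptors → sigmoid emergence markers → total
variation, on the phase windows each feature belongs to: S_IES over
induction+maintenance, L_IES over the induction (bolus) window, relative
band-power means and total variations over maintenance, and the emergence
markers over the final 20 minutes.

``run_cohort`` assembles the per-patient feature table and runs the
inference battery: simple and partial (age/gender/weight-controlled)
correlations of each induction/maintenance measure against the recovery
shifts, extubation-delay correlations, and conditional probabilities at
the 70th percentile.  A significance level of 0.05 with no multiplicity
correction is used for the significance marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral
from .emergence import emergence_markers, fit_sigmoid
from .inference import (conditional_probability, correlate, jeffreys_label)
from .intervals import Interval, complement
from .preprocessing import detect_artifacts, wqn_correct
from .records import EEGRecord, PhasePlan
from .spectral import (ALPHA_BAND, DELTA_BAND, FMAX_BAND, mean_band_power,
                       peak_frequency, relative_band_power, sg_smooth,
                       spectrogram)
from .suppression import segment_suppressions, suppression_stats
from .variation import total_variation

logger = logging.getLogger(__name__)

MEASURES = ["s_ies", "l_ies", "mean_p_alpha", "v_alpha", "mean_p_delta",
            "v_delta"]
RECOVERY_MARKERS = ["dt_roc", "df_roc"]
COVARIATES = ["age", "gender", "weight"]


@dataclass
class PatientFeatures:
    patient_id: str
    s_ies: float = np.nan             # min, induction+maintenance
    l_ies: float = np.nan             # min, longest IES in induction
    mean_p_alpha: float = np.nan      # %
    mean_p_delta: float = np.nan      # %
    v_alpha: float = np.nan           # Hz/min
    v_delta: float = np.nan           # Hz/min
    dt_roc: float = np.nan            # min
    df_roc: float = np.nan            # Hz
    t_in_s: float = np.nan
    t_out_s: float = np.nan
    extubation_delay_min: float = np.nan
    age: float = np.nan
    gender: float = np.nan
    weight: float = np.nan
    flags: str = ""


def run_patient(record: EEGRecord, plan: PhasePlan | None = None,
                fit_window_min: float = 20.0,
                correct_artifacts: bool = True) -> PatientFeatures:
    """Extract every feature for one patient; stage errors set flags and
    leave the affected features NaN while the rest are retained."""
    plan = plan or record.phase_plan
    if plan is None:
        raise ValueError("phase boundaries required (events file or "
                         "synthetic annotations)")
    feats = PatientFeatures(patient_id=record.patient_id)
    flags: list[str] = []
    feats.extubation_delay_min = (plan.extubation_time -
                                  plan.recovery_start) / 60.0

    rec = record
    if correct_artifacts:
        try:
            mask = detect_artifacts(rec)
            rec = wqn_correct(rec, mask)
        except Exception as exc:      # pragma: no cover - defensive
            flags.append("preprocessing_failed")
            logger.warning("%s: preprocessing failed: %s", record.patient_id, exc)

    try:
        segs = segment_suppressions(rec)
        ind_maint: Interval = (plan.induction_span[0], plan.maintenance_span[1])
        feats.s_ies, _ = suppression_stats(segs.ies, ind_maint)
        _, feats.l_ies = suppression_stats(segs.ies, plan.induction_span)
        ies_ivs, alpha_s_ivs = segs.ies, segs.alpha_s
    except Exception as exc:
        flags.append("suppression_failed")
        logger.warning("%s: suppression stage failed: %s", record.patient_id, exc)
        ies_ivs, alpha_s_ivs = [], []

    try:
        spec = spectrogram(rec)
        maint = plan.maintenance_span

        rel_a = relative_band_power(spec, ALPHA_BAND)
        rel_d = relative_band_power(spec, DELTA_BAND)
        feats.mean_p_alpha = mean_band_power(rel_a, maint)
        feats.mean_p_delta = mean_band_power(rel_d, maint)

        alpha_track = peak_frequency(spec, ALPHA_BAND,
                                     exclusions=ies_ivs + alpha_s_ivs)
        delta_track = peak_frequency(spec, DELTA_BAND, exclusions=ies_ivs)
        alpha_sg = sg_smooth(alpha_track)
        delta_sg = sg_smooth(delta_track)
        seg_a = complement(ies_ivs + alpha_s_ivs, maint)
        seg_d = complement(ies_ivs, maint)
        feats.v_alpha = total_variation(alpha_sg, seg_a, band="alpha",
                                        min_span_s=120.0).value
        feats.v_delta = total_variation(delta_sg, seg_d, band="delta",
                                        min_span_s=120.0).value
    except Exception as exc:
        flags.append("spectral_failed")
        logger.warning("%s: spectral stage failed: %s", record.patient_id, exc)
        spec = None

    if spec is not None:
        try:
            t_f = record.duration
            window: Interval = (max(t_f - fit_window_min * 60.0, 0.0), t_f)
            if plan.recovery_start >= t_f - 60.0:
                raise ValueError("recording ends before recovery")
            p_delta = spectral.band_power(spec, DELTA_BAND)
            p_alpha = spectral.band_power(spec, ALPHA_BAND)
            fit_d = fit_sigmoid(p_delta, window, band="delta")
            fit_a = fit_sigmoid(p_alpha, window, band="alpha")
            fmax = sg_smooth(peak_frequency(spec, FMAX_BAND))
            markers = emergence_markers(fit_d, fit_a, fmax)
            feats.dt_roc = markers.dt_roc
            feats.df_roc = markers.df_roc
            feats.t_in_s = markers.t_in
            feats.t_out_s = markers.t_out
            flags.extend(markers.flags)
        except Exception as exc:
            flags.append("emergence_failed")
            logger.warning("%s: emergence stage failed: %s",
                           record.patient_id, exc)

    feats.flags = ";".join(flags)
    return feats


def features_table(records: list[EEGRecord],
                   demographics: pd.DataFrame | None = None,
                   **kwargs) -> pd.DataFrame:
    """Run every patient and join demographics on patient_id."""
    rows = [asdict(run_patient(rec, **kwargs)) for rec in records]
    table = pd.DataFrame(rows)
    if demographics is not None:
        cols = ["patient_id"] + [c for c in COVARIATES + ["extubation_delay_min"]
                                 if c in demographics.columns]
        table = table.drop(columns=[c for c in cols[1:] if c in table.columns])
        table = table.merge(demographics[cols], on="patient_id", how="left")
    return table


@dataclass
class CohortReport:
    summary: pd.DataFrame             # per-measure median/Q1/Q3 + r/BF vs shifts
    partial: pd.DataFrame             # covariate-controlled correlations
    extubation: pd.DataFrame          # correlations with extubation delay
    conditional: dict = field(default_factory=dict)
    n_patients: int = 0


def _corr_row(x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
              ) -> dict:
    res = correlate(x, y, z)
    return dict(r=res.r, p=res.pvalue, bf01=res.bf01,
                label=res.evidence_label,
                significant=bool(res.pvalue < 0.05))


def run_cohort(features: pd.DataFrame,
               percentile: float = 70.0,
               t_bol_min: float = 0.5) -> CohortReport:
    """Cohort statistics battery from an assembled feature table."""
    complete = features.dropna(subset=MEASURES + RECOVERY_MARKERS)
    if len(complete) < 4:
        raise ValueError("need at least 4 patients with complete features")

    # the covariate-controlled battery needs spare degrees of freedom
    # (t-transform df = n - 2 - k and the g-prior integral needs n > p' + 2)
    have_cov = len(complete) >= 8 and all(
        c in complete.columns and complete[c].notna().all()
        for c in COVARIATES)

    summary_rows, partial_rows, extub_rows = [], [], []
    for m in MEASURES:
        row = dict(
            measure=m,
            median=float(complete[m].median()),
            q1=float(complete[m].quantile(0.25)),
            q3=float(complete[m].quantile(0.75)),
        )
        prow = dict(measure=m)
        for marker in RECOVERY_MARKERS:
            stats_ = _corr_row(complete[m].values, complete[marker].values)
            for k, v in stats_.items():
                row[f"{k}_vs_{marker}"] = v
            if have_cov:
                pstats = _corr_row(complete[m].values, complete[marker].values,
                                   complete[COVARIATES].values)
                for k, v in pstats.items():
                    prow[f"{k}_vs_{marker}"] = v
        summary_rows.append(row)
        if have_cov:
            partial_rows.append(prow)
        if "extubation_delay_min" in complete.columns and \
                complete["extubation_delay_min"].notna().all():
            erow = dict(measure=m)
            erow.update(_corr_row(complete[m].values,
                                  complete["extubation_delay_min"].values))
            extub_rows.append(erow)

    conditional = {}
    cp = conditional_probability(complete, ("s_ies", percentile),
                                 ("dt_roc", percentile))
    conditional["p_long_roc_given_long_ies"] = asdict(cp)
    cp2 = conditional_probability(complete, ("l_ies", t_bol_min),
                                  ("s_ies", percentile),
                                  condition_is_percentile=False)
    conditional["p_long_ies_given_long_bolus"] = asdict(cp2)

    return CohortReport(summary=pd.DataFrame(summary_rows),
                        partial=pd.DataFrame(partial_rows),
                        extubation=pd.DataFrame(extub_rows),
                        conditional=conditional,
                        n_patients=int(len(complete)))


def write_report(report: CohortReport, out_dir: str | Path) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out / "summary.csv", index=False)
    if len(report.partial):
        report.partial.to_csv(out / "partial_correlations.csv", index=False)
    if len(report.extubation):
        report.extubation.to_csv(out / "extubation_correlations.csv",
                                 index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(dict(
            n_patients=report.n_patients,
            conditional=report.conditional,
            summary=report.summary.to_dict(orient="records"),
            partial=report.partial.to_dict(orient="records"),
            extubation=report.extubation.to_dict(orient="records"),
        ), fh, indent=2, default=float)
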