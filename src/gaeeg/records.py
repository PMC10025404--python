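"""EEG record container and plain-text / EDF I/O.

An :class:`EEGRecord` holds a four-channel frontal montage (F7, Fp1, Fp2,
F8) sampled at a fixed rate, in microvolts, optionally carrying the
ground-truth annotations produced by the synthetic generator.

The native on-disk format is a delimited text file with a small header
(sampling rate and channel labels) followed by one row per sample.  EDF
files are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import Interval

FRONTAL_CHANNELS = ("F7", "Fp1", "Fp2", "F8")


class InvalidSpecError(ValueError):
    """Raised when a generator or record specification is inconsistent."""


@dataclass
class PhasePlan:
    """Ground-truth phase layout of one recording, all times in seconds.

    ``induction_span`` and ``maintenance_span`` tile the pre-recovery part of
    the recording; recovery runs from ``recovery_start`` (hypnotic off) to the
    end of the record, with ``extubation_time`` inside or after it.
    """

    induction_span: Interval
    maintenance_span: Interval
    recovery_start: float
    extubation_time: float
    bolus_ies: list[Interval] = field(default_factory=list)
    spontaneous_ies: list[Interval] = field(default_factory=list)
    alpha_suppressions: list[Interval] = field(default_factory=list)
    artifact_bursts: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.induction_span[1] > self.maintenance_span[0] + 1e-9:
            raise InvalidSpecError("induction must end before maintenance starts")
        if self.maintenance_span[1] > self.recovery_start + 1e-9:
            raise InvalidSpecError("maintenance must end before recovery starts")
        if self.extubation_time <= self.recovery_start:
            raise InvalidSpecError("extubation_time must follow recovery_start")
        for a, b in self.bolus_ies + self.spontaneous_ies:
            if not (self.induction_span[0] <= a and b <= self.maintenance_span[1]):
                raise InvalidSpecError(
                    "planted IES intervals must lie in induction or maintenance"
                )

    @property
    def all_ies(self) -> list[Interval]:
        return sorted(self.bolus_ies + self.spontaneous_ies)


@dataclass
class BandModel:
    """Planted oscillatory-band ground truth on a coarse (1 s) time grid."""

    track_times: np.ndarray        # s
    delta_amp: np.ndarray          # µV
    alpha_amp: np.ndarray          # µV
    alpha_peak_freq: np.ndarray    # Hz
    delta_peak_freq: np.ndarray    # Hz
    noise_floor: float             # µV RMS of the 1/f background
    true_t_in: float               # s
    true_t_out: float              # s
    true_dt_roc: float             # min
    true_df_roc: float             # Hz


@dataclass
class EEGRecord:
    """Labeled multichannel EEG signal (µV) with optional ground truth."""

    fs: float
    samples: np.ndarray            # (n_channels, n_samples)
    channel_labels: tuple[str, ...] = FRONTAL_CHANNELS
    phase_plan: PhasePlan | None = None
    band_model: BandModel | None = None
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs < 128:
            raise InvalidSpecError(f"sampling rate {self.fs} Hz < 128 Hz")
        if self.samples.shape[0] != len(self.channel_labels):
            raise InvalidSpecError("channel count does not match labels")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "EEGRecord":
        return EEGRecord(
            fs=self.fs,
            samples=self.samples.copy(),
            channel_labels=self.channel_labels,
            phase_plan=self.phase_plan,
            band_model=self.band_model,
            patient_id=self.patient_id,
        )


def write_record(record: EEGRecord, path: str | Path) -> None:
    """Write a record as delimited text with a sampling-rate header."""
    path = Path(path)
    header = f"# fs_hz={record.fs}\n# channels={','.join(record.channel_labels)}"
    np.savetxt(path, record.samples.T, fmt="%.4f", delimiter=",", header=header,
               comments="")


def read_record(path: str | Path, patient_id: str | None = None) -> EEGRecord:
    """Read a record from delimited text (native) or EDF (via mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, patient_id)
    fs = None
    labels = FRONTAL_CHANNELS
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").strip().partition("=")
            if key == "fs_hz":
                fs = float(val)
            elif key == "channels":
                labels = tuple(val.split(","))
    if fs is None:
        raise InvalidSpecError(f"{path}: missing 'fs_hz' header")
    data = np.loadtxt(path, delimiter=",", comments="#")
    return EEGRecord(fs=fs, samples=np.atleast_2d(data).T, channel_labels=labels,
                     patient_id=patient_id or path.stem)


def _read_edf(path: Path, patient_id: str | None) -> EEGRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [ch for ch in FRONTAL_CHANNELS if ch in raw.ch_names] or raw.ch_names
    data = raw.get_data(picks=picks) * 1e6  # V -> µV
    return EEGRecord(fs=float(raw.info["sfreq"]), samples=data,
                     channel_labels=tuple(picks), patient_id=patient_id or path.stem)
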