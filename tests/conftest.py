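import numpy as np
import pytest

from gaeeg.records import EEGRecord
from gaeeg.synthetic import PatientSpec, synthesize_record


def tone_record(freq: float = 10.0, amp: float = 20.0, fs: float = 250.0,
                duration: float = 60.0, n_channels: int = 4) -> EEGRecord:
    """Deterministic pure-tone record, identical on all channels."""
    t = np.arange(int(duration * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return EEGRecord(fs=fs, samples=np.tile(sig, (n_channels, 1)))


@pytest.fixture(scope="session")
def short_spec() -> PatientSpec:
    """Compact patient spec used by the signal-level tests."""
    return PatientSpec(fs=250.0, induction_min=3.0, maintenance_min=5.0,
                       recovery_min=20.0)


@pytest.fixture(scope="session")
def clean_record(short_spec) -> "EEGRecord":
    """One rendered patient with no planted suppressions or artifacts."""
    return synthesize_record(short_spec, seed=42)


@pytest.fixture(scope="session")
def suppression_record(short_spec):
    """One rendered patient with planted IES, alphaS and an artifact burst."""
    from dataclasses import replace

    spec = replace(short_spec, bolus_ies=[(120.0, 140.0)],
                   alpha_suppressions=[(300.0, 330.0)],
                   artifact_bursts=[(200.0, 203.0)])
    return spec, synthesize_record(spec, seed=7)
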