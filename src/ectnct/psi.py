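"""Postictal Suppression Index (PSI) from a seizure EEG trace.

The PSI quantifies how strongly the EEG flattens after a tonic-clonic
seizure:

    PSI = 1 - P_termination / P_seizure

where each power is the mean power of three 1.28 s intervals (at the
clinical 200 Hz sampling rate: 256 samples each), taken on either side of
the seizure endpoint. To avoid endpoint artifacts, 3.84 s centered on the
endpoint (1.92 s each side) are disregarded; the seizure windows are the
three contiguous windows ending at the gap's start and the termination
windows the three starting at its end. Window power is the mean squared
demeaned amplitude (DC offset removed); no spectral filtering is applied.

Single-channel computation: a multi-electrode montage reduces to whichever
channel is supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGTrace",
    "PSIResult",
    "read_eeg",
    "write_eeg",
    "segment_windows",
    "mean_power",
    "compute_psi",
    "WINDOW_SECONDS",
    "N_WINDOWS",
    "EXCLUSION_SECONDS",
]

WINDOW_SECONDS = 1.28
N_WINDOWS = 3
EXCLUSION_SECONDS = 3.84


@dataclass(frozen=True)
class EEGTrace:
    """A single-channel seizure EEG recording.

    Attributes
    ----------
    samples
        Amplitude sequence in microvolts.
    sampling_rate
        Sampling rate in Hz (clinically 200 Hz).
    seizure_end_index
        Sample index of the tonic-clonic seizure endpoint.
    """

    samples: np.ndarray = field(repr=False)
    sampling_rate: float = 200.0
    seizure_end_index: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 < self.seizure_end_index < x.shape[0]):
            raise ValueError("seizure_end_index must lie strictly inside the trace")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite EEG samples")
        object.__setattr__(self, "samples", x)


@dataclass(frozen=True)
class PSIResult:
    """PSI with the two phase powers it is computed from."""

    power_seizure: float
    power_termination: float
    psi: float


def segment_windows(
    trace: EEGTrace,
    window_seconds: float = WINDOW_SECONDS,
    n_windows: int = N_WINDOWS,
    exclusion_seconds: float = EXCLUSION_SECONDS,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cut the seizure-phase and termination-phase analysis windows.

    Returns ``(seizure_windows, termination_windows)``, each a list of
    ``n_windows`` arrays of ``round(window_seconds * fs)`` samples. The
    exclusion gap is centered on the seizure endpoint with half on each side.
    """
    fs = trace.sampling_rate
    win = int(round(window_seconds * fs))
    half_gap = int(round(exclusion_seconds * fs / 2.0))
    if win < 1:
        raise ValueError("window too short for the sampling rate")
    need = n_windows * win + half_gap
    end = trace.seizure_end_index
    n = trace.samples.shape[0]
    if end - need < 0 or end + need > n:
        raise ValueError(
            f"trace too short: need {need} samples on each side of the seizure "
            f"endpoint, have {end} before and {n - end} after"
        )
    seiz_block = trace.samples[end - half_gap - n_windows * win : end - half_gap]
    term_block = trace.samples[end + half_gap : end + half_gap + n_windows * win]
    seizure = [seiz_block[k * win : (k + 1) * win] for k in range(n_windows)]
    termination = [term_block[k * win : (k + 1) * win] for k in range(n_windows)]
    return seizure, termination


def mean_power(windows: list[np.ndarray]) -> float:
    """Mean over windows of the mean squared demeaned amplitude."""
    if len(windows) == 0:
        raise ValueError("no windows")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("windows must have equal lengths")
    powers = [float(np.mean((w - np.mean(w)) ** 2)) for w in windows]
    return float(np.mean(powers))


def compute_psi(
    trace: EEGTrace,
    window_seconds: float = WINDOW_SECONDS,
    n_windows: int = N_WINDOWS,
    exclusion_seconds: float = EXCLUSION_SECONDS,
) -> PSIResult:
    """PSI = 1 - (termination-phase power / seizure-phase power)."""
    seizure, termination = segment_windows(
        trace, window_seconds, n_windows, exclusion_seconds
    )
    p_seiz = mean_power(seizure)
    p_term = mean_power(termination)
    if p_seiz <= 0:
        raise ValueError("zero seizure-phase power: PSI undefined")
    return PSIResult(
        power_seizure=p_seiz,
        power_termination=p_term,
        psi=1.0 - p_term / p_seiz,
    )


def write_eeg(trace: EEGTrace, csv_path: str | Path) -> tuple[Path, Path]:
    """Write a trace as a one-column CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, trace.samples, fmt="%.17g")
    meta_path = csv_path.with_suffix(".json")
    meta_path.write_text(
        json.dumps(
            {
                "sampling_rate_hz": trace.sampling_rate,
                "seizure_end_index": int(trace.seizure_end_index),
            },
            indent=2,
        )
        + "\n"
    )
    return csv_path, meta_path


def read_eeg(csv_path: str | Path, meta_path: str | Path | None = None) -> EEGTrace:
    """Read a one-column sample file plus its JSON sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    samples = np.loadtxt(csv_path, dtype=float)
    meta = json.loads(meta_path.read_text())
    return EEGTrace(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        seizure_end_index=int(meta["seizure_end_index"]),
    )
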