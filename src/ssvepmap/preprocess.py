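"""EEG/gaze input, filtering, epoching, and fixation gating.

Filtering follows the acquisition convention of the paradigm: a 50 Hz notch
first, then a 4-35 Hz bandpass, both applied forward-backward (zero phase) so
sinusoidal peaks are not shifted in time.  Trials are kept only if every gaze
sample stays within a 1.5 deg ring around fixation (boundary inclusive:
"beyond the ring" is read as strictly outside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FilterSpec",
    "read_eeg",
    "write_eeg_delimited",
    "apply_filters",
    "extract_epoch",
    "gate_trial",
]

DEFAULT_RING_RADIUS = 1.5  # degrees


@dataclass(frozen=True)
class FilterSpec:
    """Notch + bandpass specification (defaults: 50 Hz notch, 4-35 Hz band).

    ``notch_q`` is the notch quality factor (center / -3 dB bandwidth); the
    acquisition protocol states only the notch frequency, so the bandwidth is
    a package default.  ``order`` is the Butterworth order per pass of the
    forward-backward bandpass.
    """

    notch_freq: float = 50.0
    band: tuple[float, float] = (4.0, 35.0)
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self):
        lo, hi = self.band
        if not lo < hi:
            raise ValueError(f"band low {lo} must be < band high {hi}")
        if self.notch_freq <= 0 or self.order < 1 or self.notch_q <= 0:
            raise ValueError("invalid filter parameters")


def apply_filters(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase notch then bandpass along the last axis.

    Raises
    ------
    ValueError
        If ``fs`` does not support the band (fs <= 2 * band high) or the
        notch frequency is outside the recorded bandwidth.
    """
    if fs <= 2.0 * spec.band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band {spec.band}")
    if spec.notch_freq >= fs / 2:
        raise ValueError(f"notch {spec.notch_freq} Hz at or above Nyquist")
    data = np.asarray(data, dtype=float)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    out = signal.filtfilt(b, a, data, axis=-1)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, out, axis=-1)


def extract_epoch(recording: np.ndarray, onset_sample: int, duration_s: float, fs: float) -> np.ndarray:
    """Slice ``duration_s * fs`` samples starting at ``onset_sample``.

    The window is half-open, 0-based: [onset, onset + duration * fs).
    """
    recording = np.atleast_2d(recording)
    n = int(round(duration_s * fs))
    if onset_sample < 0 or onset_sample + n > recording.shape[-1]:
        raise ValueError(
            f"epoch [{onset_sample}, {onset_sample + n}) outside recording of "
            f"{recording.shape[-1]} samples"
        )
    return recording[..., onset_sample:onset_sample + n]


def gate_trial(gaze: np.ndarray, ring_radius: float = DEFAULT_RING_RADIUS) -> bool:
    """True iff every gaze sample lies within the fixation ring (inclusive).

    ``gaze`` is (n_samples, 2) in degrees relative to fixation.  The decision
    is order-independent and monotone: adding samples can only invalidate.
    """
    gaze = np.asarray(gaze, dtype=float)
    if gaze.size == 0:
        raise ValueError("empty gaze trace")
    ecc = np.hypot(gaze[..., 0], gaze[..., 1])
    return bool(np.all(ecc <= ring_radius))


# -- file I/O -----------------------------------------------------------------


def write_eeg_delimited(path, data: np.ndarray, labels, fs: float) -> None:
    """Write a channels x samples matrix as labeled CSV with an fs header."""
    data = np.atleast_2d(data)
    if len(labels) != data.shape[0]:
        raise ValueError("labels do not match number of rows")
    with open(path, "w") as fh:
        fh.write(f"# fs={fs!r}\n")
        for label, row in zip(labels, data):
            fh.write(label + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_eeg(
    path,
    format: str = "delimited",
    expected_labels=None,
    fs: float | None = None,
):
    """Read a continuous EEG recording.

    Parameters
    ----------
    path
        File path: a labeled delimited matrix (one channel per row, first
        field the channel label, optional ``# fs=...`` header) or an EDF/BDF
        file.
    format
        "delimited" or "edf".
    expected_labels
        If given, every listed channel must be present; a missing channel
        raises an error naming it.
    fs
        Expected sampling rate; a mismatch with the file emits a warning
        (the file's rate wins).

    Returns
    -------
    (data, fs, labels)
        data is channels x samples float64.
    """
    if format == "delimited":
        file_fs = None
        labels, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    if key.strip() == "fs":
                        file_fs = float(val)
                    continue
                first, _, rest = line.partition(",")
                try:
                    float(first)
                except ValueError:
                    labels.append(first)
                    rows.append(np.fromstring(rest, sep=","))
                else:  # unlabeled numeric matrix
                    labels.append(f"ch{len(rows)}")
                    rows.append(np.fromstring(line, sep=","))
        data = np.vstack(rows)
    elif format == "edf":
        import mne  # optional dependency, only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        labels = list(raw.ch_names)
        file_fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unknown EEG format {format!r}")

    if file_fs is None:
        file_fs = fs
    elif fs is not None and abs(file_fs - fs) > 1e-9:
        warnings.warn(
            f"sampling rate in file ({file_fs} Hz) differs from configured "
            f"({fs} Hz); using the file's rate", stacklevel=2,
        )
    if expected_labels is not None:
        missing = [ch for ch in expected_labels if ch not in labels]
        if missing:
            raise ValueError(f"recording is missing channel(s): {', '.join(missing)}")
    return data, file_fs, labels


def read_gaze(path) -> np.ndarray:
    """Read a delimited gaze log with columns (t_s, x_deg, y_deg) -> (n, 2)."""
    df = pd.read_csv(path, comment="#")
    cols = [c for c in ("x_deg", "y_deg") if c in df.columns]
    if len(cols) == 2:
        return df[cols].to_numpy(dtype=float)
    # headerless: assume t, x, y
    arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return arr[:, 1:3]


def write_gaze(path, gaze: np.ndarray, fs: float) -> None:
    gaze = np.asarray(gaze, dtype=float)
    t = np.arange(gaze.shape[0]) / fs
    pd.DataFrame({"t_s": t, "x_deg": gaze[:, 0], "y_deg": gaze[:, 1]}).to_csv(
        path, index=False
    )
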