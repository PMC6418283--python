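"""Synthetic gaze-restricted SSVEP sessions.

The generator produces full sessions — multichannel EEG epochs at 500 Hz,
gaze traces at 60 Hz, and trial metadata — with the statistical structure the
downstream analyses assume:

* a Gaussian falloff of SSVEP amplitude with stimulus eccentricity,
* a multiplicative response boost for stimuli below the horizontal midline,
* occipitally-peaked scalp topography with a contralateral gain for
  lateralized stimuli,
* a 15 Hz fundamental with decaying harmonics over 1/f background noise and
  a 50 Hz line component,
* Gaussian fixation jitter with occasional excursions beyond the 1.5 deg
  fixation ring, and the protocol's repeat-until-success trial bookkeeping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .layout import StimulusLayout
from .montage import Montage
from .preprocess import (
    DEFAULT_RING_RADIUS,
    gate_trial,
    read_eeg,
    read_gaze,
    write_eeg_delimited,
    write_gaze,
)

__all__ = [
    "SimParams",
    "Trial",
    "Session",
    "SimulationError",
    "simulate_amplitude",
    "simulate_topography_weights",
    "simulate_trial_eeg",
    "simulate_gaze",
    "simulate_session",
    "write_session",
    "read_session",
]

EEG_FS = 500.0
GAZE_FS = 60.0
TRIAL_DURATION_S = 4.0


class SimulationError(RuntimeError):
    """Raised when a session cannot be completed (retry cap exhausted)."""


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Attributes
    ----------
    f0 : float
        Flicker fundamental, Hz.
    n_harmonics_sim : int
        Number of harmonics placed in the signal.
    harmonic_decay : tuple
        Per-harmonic amplitude factors; default 1/m.
    A0 : float
        Evoked amplitude at fixation, signal units.
    sigma_r : float
        Width (deg) of the Gaussian eccentricity falloff of evoked amplitude.
    beta_lower : float
        Fractional amplitude boost for stimuli below the horizontal midline.
    gamma_contra : float
        Fractional gain of channels contralateral to a lateralized stimulus.
    noise_alpha : float
        Spectral exponent of the 1/f^alpha background noise.
    snr : float
        A0 divided by the per-channel background-noise RMS.
    line_amp : float
        Amplitude of the 50 Hz line component.
    gaze_sigma : float
        Fixation jitter standard deviation per axis, deg.
    p_excursion : float
        Per-trial probability of a gaze excursion beyond the fixation ring.
    seed : int
        Base seed for session generation.
    phases : tuple
        Harmonic phases (rad); the flicker is driven at phase zero.
    max_attempts : int
        Retry cap per (run, stimulus); the physical paradigm has none, a cap
        guarantees termination here.
    """

    f0: float = 15.0
    n_harmonics_sim: int = 3
    harmonic_decay: tuple[float, ...] | None = None
    A0: float = 1.0
    sigma_r: float = 3.5
    beta_lower: float = 0.3
    gamma_contra: float = 0.5
    noise_alpha: float = 1.0
    snr: float = 2.0
    line_amp: float = 0.5
    gaze_sigma: float = 0.3
    p_excursion: float = 0.1
    seed: int = 0
    phases: tuple[float, ...] | None = None
    max_attempts: int = 20

    def __post_init__(self):
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be positive")
        if not 0.0 <= self.p_excursion <= 1.0:
            raise ValueError("p_excursion must be in [0, 1]")
        for name in ("A0", "snr", "line_amp", "gaze_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_harmonics_sim < 1 or self.max_attempts < 1:
            raise ValueError("n_harmonics_sim and max_attempts must be >= 1")

    def decay(self) -> np.ndarray:
        if self.harmonic_decay is not None:
            d = np.asarray(self.harmonic_decay, dtype=float)
            if d.size != self.n_harmonics_sim:
                raise ValueError("harmonic_decay length mismatch")
            return d
        return 1.0 / np.arange(1, self.n_harmonics_sim + 1)

    def harmonic_phases(self) -> np.ndarray:
        if self.phases is not None:
            p = np.asarray(self.phases, dtype=float)
            if p.size != self.n_harmonics_sim:
                raise ValueError("phases length mismatch")
            return p
        return np.zeros(self.n_harmonics_sim)


@dataclass
class Trial:
    run: int  # 1-based
    stimulus: int  # 1-based stimulus index
    eeg: np.ndarray  # (channels, samples) at EEG_FS
    gaze: np.ndarray  # (samples, 2) at GAZE_FS, deg
    valid: bool
    attempt: int = 1


@dataclass
class Session:
    participant: str
    trials: list[Trial]
    fs_eeg: float = EEG_FS
    fs_gaze: float = GAZE_FS

    @property
    def n_valid(self) -> int:
        return sum(t.valid for t in self.trials)

    @property
    def n_rejected(self) -> int:
        return sum(not t.valid for t in self.trials)

    def valid_trials(self):
        return [t for t in self.trials if t.valid]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(trial=i, run=t.run, stimulus=t.stimulus,
                     valid=t.valid, attempt=t.attempt)
                for i, t in enumerate(self.trials)
            ]
        )


def simulate_amplitude(params: SimParams, position) -> float:
    """Evoked amplitude at a visual-field position.

    A(x, y) = A0 * exp(-e^2 / (2 sigma_r^2)) * (1 + beta_lower * [y < 0]),
    with e the eccentricity of (x, y).  Deterministic.
    """
    x, y = position
    e2 = x * x + y * y
    amp = params.A0 * np.exp(-e2 / (2.0 * params.sigma_r**2))
    if y < 0:
        amp *= 1.0 + params.beta_lower
    return float(amp)


def simulate_topography_weights(
    params: SimParams, montage: Montage, position, normalize: bool = True
) -> np.ndarray:
    """Per-channel forward weights for a stimulus position.

    Weights peak over the occipital pole (Gaussian in schematic scalp
    coordinates) and channels contralateral to a lateralized stimulus are
    scaled by (1 + gamma_contra).  With ``normalize`` the maximum weight is 1.
    """
    occ_center = np.array([0.0, -1.0])  # occipital pole in schematic coords
    occ_width = 0.55
    d2 = np.sum((montage.coords - occ_center) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * occ_width**2))

    x = position[0]
    if x != 0 and params.gamma_contra != 0:
        contra = "left" if x > 0 else "right"
        for i, ch in enumerate(montage.labels):
            if montage.hemisphere(ch) == contra:
                w[i] *= 1.0 + params.gamma_contra
    if normalize:
        w = w / w.max()
    return w


def _one_over_f_noise(rng: np.random.Generator, shape, fs: float, alpha: float) -> np.ndarray:
    """Channels of 1/f^alpha noise with unit RMS, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    noise = np.fft.irfft(spec * gain, n=n, axis=-1)
    rms = np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return noise / rms


def simulate_trial_eeg(
    params: SimParams,
    montage: Montage,
    position,
    duration_s: float = TRIAL_DURATION_S,
    fs: float = EEG_FS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One EEG epoch (channels x samples) for a stimulus position.

    epoch = sum_m w * A * decay_m * sin(2 pi m f0 t + phi_m)
            + (A0 / snr) * 1/f^alpha noise + line_amp * sin(2 pi 50 t + phi).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = int(round(duration_s * fs))
    if abs(duration_s * fs - n) > 1e-9:
        raise ValueError("duration_s * fs must be an integer sample count")
    t = np.arange(1, n + 1) / fs

    amp = simulate_amplitude(params, position)
    w = simulate_topography_weights(params, montage, position)
    decay = params.decay()
    phases = params.harmonic_phases()
    waveform = np.zeros(n)
    for m in range(1, params.n_harmonics_sim + 1):
        waveform += decay[m - 1] * np.sin(2.0 * np.pi * m * params.f0 * t + phases[m - 1])
    epoch = amp * np.outer(w, waveform)

    if params.snr > 0 and params.A0 > 0:
        noise_rms = params.A0 / params.snr
    else:
        noise_rms = 1.0 / params.snr if params.snr > 0 else 0.0
    if noise_rms > 0:
        epoch = epoch + noise_rms * _one_over_f_noise(
            rng, (montage.n_channels, n), fs, params.noise_alpha
        )
    if params.line_amp > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        epoch = epoch + params.line_amp * np.sin(2.0 * np.pi * 50.0 * t + phi)
    return epoch


def simulate_gaze(
    params: SimParams,
    duration_s: float = TRIAL_DURATION_S,
    fs: float = GAZE_FS,
    rng: np.random.Generator | None = None,
    ring_radius: float = DEFAULT_RING_RADIUS,
) -> np.ndarray:
    """Gaze trace (samples x 2, deg): Gaussian jitter plus rare excursions.

    With probability ``p_excursion`` one contiguous ramp excursion crossing
    the fixation ring is injected, guaranteeing the trial fails the gate.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = int(round(duration_s * fs))
    gaze = rng.normal(0.0, params.gaze_sigma, size=(n, 2))
    if rng.random() < params.p_excursion:
        length = int(rng.integers(3, max(4, n // 16)))
        start = int(rng.integers(0, n - length))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        peak = ring_radius + rng.uniform(0.5, 2.0)
        ramp = peak * np.sin(np.linspace(0.0, np.pi, length))  # out and back
        gaze[start:start + length, 0] += ramp * np.cos(theta)
        gaze[start:start + length, 1] += ramp * np.sin(theta)
        # ensure the excursion actually crosses the ring despite jitter
        apex = start + length // 2
        r = np.hypot(*gaze[apex])
        if r <= ring_radius:
            gaze[apex] *= (ring_radius * 1.1) / max(r, 1e-12)
    return gaze


def simulate_session(
    params: SimParams,
    layout: StimulusLayout,
    montage: Montage,
    n_runs: int = 12,
    participant: str = "sim01",
    rng: np.random.Generator | None = None,
    ring_radius: float = DEFAULT_RING_RADIUS,
    dtype=np.float32,
) -> Session:
    """Simulate a complete session.

    Within each run the stimulus order is random; a failed (gaze-excursion)
    trial is retained with ``valid=False`` and repeated until it succeeds, so
    a completed session has exactly one valid trial per (run, stimulus).

    Raises
    ------
    SimulationError
        If a (run, stimulus) pair cannot be completed within
        ``params.max_attempts`` attempts.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    trials: list[Trial] = []
    for run in range(1, n_runs + 1):
        order = rng.permutation(layout.n_stimuli) + 1
        for stim in order:
            stim = int(stim)
            position = layout.position(stim)
            for attempt in range(1, params.max_attempts + 1):
                gaze = simulate_gaze(params, rng=rng, ring_radius=ring_radius)
                eeg = simulate_trial_eeg(params, montage, position, rng=rng)
                valid = gate_trial(gaze, ring_radius)
                trials.append(
                    Trial(run=run, stimulus=stim, eeg=eeg.astype(dtype),
                          gaze=gaze, valid=valid, attempt=attempt)
                )
                if valid:
                    break
            else:
                raise SimulationError(
                    f"run {run}, stimulus {stim}: no valid trial within "
                    f"{params.max_attempts} attempts"
                )
    return Session(participant=participant, trials=trials)


# -- delimited serialization --------------------------------------------------


def write_session(directory, session: Session, montage: Montage) -> None:
    """Write a session as delimited text: metadata.csv + per-trial EEG/gaze."""
    os.makedirs(directory, exist_ok=True)
    os.makedirs(os.path.join(directory, "eeg"), exist_ok=True)
    os.makedirs(os.path.join(directory, "gaze"), exist_ok=True)
    meta = session.metadata()
    meta.insert(0, "participant", session.participant)
    meta.to_csv(os.path.join(directory, "metadata.csv"), index=False)
    for i, t in enumerate(session.trials):
        write_eeg_delimited(
            os.path.join(directory, "eeg", f"trial{i:04d}.csv"),
            np.asarray(t.eeg, dtype=float), montage.labels, session.fs_eeg,
        )
        write_gaze(os.path.join(directory, "gaze", f"trial{i:04d}.csv"),
                   t.gaze, session.fs_gaze)


def read_session(directory, montage: Montage) -> Session:
    """Read a session written by :func:`write_session`."""
    meta = pd.read_csv(os.path.join(directory, "metadata.csv"))
    trials = []
    fs_eeg = EEG_FS
    for _, row in meta.iterrows():
        i = int(row["trial"])
        data, fs, labels = read_eeg(
            os.path.join(directory, "eeg", f"trial{i:04d}.csv"),
            expected_labels=montage.labels,
        )
        fs_eeg = fs or fs_eeg
        order = [labels.index(ch) for ch in montage.labels]
        gaze = read_gaze(os.path.join(directory, "gaze", f"trial{i:04d}.csv"))
        trials.append(
            Trial(run=int(row["run"]), stimulus=int(row["stimulus"]),
                  eeg=data[order], gaze=gaze, valid=bool(row["valid"]),
                  attempt=int(row.get("attempt", 1)))
        )
    participant = str(meta["participant"].iloc[0]) if "participant" in meta else "unknown"
    return Session(participant=participant, trials=trials, fs_eeg=fs_eeg)


def participant_params(params: SimParams, index: int) -> SimParams:
    """Derived per-participant parameter set with a distinct seed."""
    return replace(params, seed=int((params.seed + 7919 * index) % (2**31 - 1)))
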