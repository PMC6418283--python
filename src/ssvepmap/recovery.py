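"""Recovering generative parameters from scored sessions.

Used to validate that simulated sessions carry the intended retinotopic
structure: the Gaussian eccentricity-falloff width and the sign of the
lower-visual-field boost.  The falloff is fitted on layer-averaged
*fundamental projection amplitudes* rather than CCA coefficients, because
the CCA coefficient saturates near 1 and sits on a noise floor, both of
which bias a direct Gaussian fit; the projection amplitude is linear in the
evoked amplitude.  The noise floor enters the fit as a quadrature term:

    a(e) = sqrt( (A * exp(-e^2 / (2 sigma^2)))^2 + c^2 )
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .layout import StimulusLayout

__all__ = [
    "fundamental_amplitude",
    "amplitude_map",
    "fit_eccentricity_falloff",
    "lower_upper_difference",
]


def fundamental_amplitude(epoch: np.ndarray, f0: float, fs: float, channels=None) -> float:
    """RMS (over channels) projection amplitude at the fundamental frequency.

    For each channel the amplitude is 2/N * |sum_t x(t) e^{-i 2 pi f0 t}|,
    i.e. the discrete Fourier amplitude at f0; the channel amplitudes are
    combined by root-mean-square.
    """
    X = np.atleast_2d(np.asarray(epoch, dtype=float))
    if channels is not None:
        X = X[np.asarray(channels, dtype=int)]
    n = X.shape[1]
    t = np.arange(1, n + 1) / fs
    basis = np.exp(-2j * np.pi * f0 * t)
    amps = 2.0 / n * np.abs(X @ basis)
    return float(np.sqrt(np.mean(amps**2)))


def amplitude_map(session, f0: float, layout: StimulusLayout, channels=None) -> pd.Series:
    """Per-stimulus mean fundamental amplitude over valid trials."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for trial in session.valid_trials():
        a = fundamental_amplitude(trial.eeg, f0, session.fs_eeg, channels=channels)
        sums[trial.stimulus] = sums.get(trial.stimulus, 0.0) + a
        counts[trial.stimulus] = counts.get(trial.stimulus, 0) + 1
    means = {s: sums[s] / counts[s] for s in sums}
    return pd.Series(means).reindex(range(1, layout.n_stimuli + 1))


def fit_eccentricity_falloff(layer_values, layer_radii) -> dict:
    """Fit a(e) = sqrt((A exp(-e^2/(2 sigma^2)))^2 + c^2) to layer averages.

    Returns a dict with keys 'A', 'sigma', 'floor'.
    """
    y = np.asarray(layer_values, dtype=float)
    e = np.asarray(layer_radii, dtype=float)
    keep = ~np.isnan(y)
    y, e = y[keep], e[keep]
    if y.size < 3:
        raise ValueError("need at least 3 layer averages to fit the falloff")

    def model(e, A, sigma, c):
        return np.sqrt((A * np.exp(-(e**2) / (2.0 * sigma**2))) ** 2 + c**2)

    span = max(e.max(), 1.0)
    p0 = (max(y.max() - y.min(), 1e-6), span / 3.0, max(y.min(), 1e-6))
    popt, _ = curve_fit(
        model, e, y, p0=p0,
        bounds=([0.0, 1e-3, 0.0], [np.inf, 10.0 * span, np.inf]),
        maxfev=20000,
    )
    return {"A": float(popt[0]), "sigma": float(popt[1]), "floor": float(popt[2])}


def lower_upper_difference(position_map: pd.Series, layout: StimulusLayout) -> float:
    """Mean response below minus above the horizontal midline.

    Positive values indicate the lower-visual-field boost; on-axis stimuli
    (y == 0) are excluded.
    """
    y = layout.positions[:, 1]
    idx = position_map.index.to_numpy() - 1
    vals = position_map.to_numpy(dtype=float)
    lower = vals[y[idx] < 0]
    upper = vals[y[idx] > 0]
    if lower.size == 0 or upper.size == 0:
        raise ValueError("need stimuli on both sides of the horizontal midline")
    return float(np.nanmean(lower) - np.nanmean(upper))
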