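"""Canonical-correlation scoring of EEG epochs against harmonic references.

The SSVEP response of an epoch is the largest canonical correlation R between
the multichannel signal X (channels x samples) and a reference bank Y of
sine/cosine pairs at the stimulus frequency and its harmonics:

    R = max_{Wx, Wy} corr(Wx' X, Wy' Y)

R lies in [0, 1], is invariant to channel permutation, per-channel affine
rescaling and sign flips, and never decreases when channels are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "ReferenceSet",
    "CCAResult",
    "build_reference",
    "cca_coefficient",
    "cca_from_covariances",
    "single_channel_response",
]

#: Relative spectral cutoff for whitening the auto-covariances: eigenvalue
#: directions below ``ridge * largest_eigenvalue`` are truncated
#: (pseudo-inverse style), which leaves well-conditioned problems unbiased
#: and keeps rank-deficient ones (duplicated or constant channels) defined.
DEFAULT_RIDGE = 1e-10


@dataclass(frozen=True)
class ReferenceSet:
    """Harmonic sin/cos reference matrix.

    ``matrix`` has ``2 * n_harmonics`` rows: sin(2*pi*m*f*t), cos(2*pi*m*f*t)
    for m = 1..M, evaluated at t = 1/S, 2/S, ..., N/S (the time base starts at
    one sample period, not zero).
    """

    frequency: float
    n_harmonics: int
    fs: float
    n_samples: int
    matrix: np.ndarray

    @property
    def harmonic_frequencies(self) -> np.ndarray:
        return self.frequency * np.arange(1, self.n_harmonics + 1)


@dataclass
class CCAResult:
    R: float
    w_x: np.ndarray
    w_y: np.ndarray
    channels: tuple | None = None


def build_reference(f: float, M: int, S: float, N: int) -> ReferenceSet:
    """Build the 2M x N harmonic reference matrix.

    Raises
    ------
    ValueError
        If M < 1, N < 2M, or the highest harmonic M*f reaches the Nyquist
        frequency S/2 (aliasing).
    """
    if M < 1:
        raise ValueError("need at least one harmonic (M >= 1)")
    if N < 2 * M:
        raise ValueError(f"N={N} too short for {2 * M} reference rows")
    if M * f >= S / 2:
        raise ValueError(
            f"highest harmonic {M * f:g} Hz reaches Nyquist ({S / 2:g} Hz); "
            "reduce M or f"
        )
    t = np.arange(1, N + 1) / S
    rows = []
    for m in range(1, M + 1):
        phase = 2.0 * np.pi * m * f * t
        rows.append(np.sin(phase))
        rows.append(np.cos(phase))
    return ReferenceSet(frequency=float(f), n_harmonics=int(M), fs=float(S),
                        n_samples=int(N), matrix=np.asarray(rows))


def _inv_sqrt(C: np.ndarray, ridge: float) -> np.ndarray:
    w, V = linalg.eigh(C)
    w_max = float(w[-1])
    if w_max <= 0:
        # degenerate block (no variance at all): whiten to zero
        return np.zeros_like(C)
    inv = np.where(w > ridge * w_max, 1.0 / np.sqrt(np.maximum(w, ridge * w_max)), 0.0)
    return (V * inv) @ V.T


def cca_from_covariances(
    Cxx: np.ndarray, Cyy: np.ndarray, Cxy: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> CCAResult:
    """Largest canonical correlation from (centered) covariance matrices.

    Solves via SVD of the whitened cross-covariance
    Cxx^{-1/2} Cxy Cyy^{-1/2}; whitening truncates eigenvalue directions
    below ``ridge`` (relative to the largest eigenvalue), so rank-deficient
    inputs stay defined and full-rank inputs are solved exactly.
    """
    Wxx = _inv_sqrt(Cxx, ridge)
    Wyy = _inv_sqrt(Cyy, ridge)
    U, s, Vt = linalg.svd(Wxx @ Cxy @ Wyy)
    R = float(np.clip(s[0], 0.0, 1.0))
    w_x = Wxx @ U[:, 0]
    w_y = Wyy @ Vt[0]
    # deterministic sign: first nonzero component of w_x positive
    nz = np.flatnonzero(np.abs(w_x) > 0)
    if nz.size and w_x[nz[0]] < 0:
        w_x, w_y = -w_x, -w_y
    return CCAResult(R=R, w_x=w_x, w_y=w_y)


def cca_coefficient(
    X: np.ndarray,
    Y: ReferenceSet | np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> CCAResult:
    """CCA coefficient between an epoch and a reference set.

    Parameters
    ----------
    X
        Epoch, shape (channels, samples); a 1-D array is treated as one
        channel.  Mean-centered internally.
    Y
        :class:`ReferenceSet` or a raw (components, samples) matrix.

    Notes
    -----
    An all-zero epoch yields R = 0 with a warning; individual zero-variance
    channels are absorbed by the ridge term (with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Ym = Y.matrix if isinstance(Y, ReferenceSet) else np.asarray(Y, dtype=float)
    if X.shape[1] != Ym.shape[1]:
        raise ValueError(
            f"epoch has {X.shape[1]} samples but reference has {Ym.shape[1]}"
        )
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Ym - Ym.mean(axis=1, keepdims=True)

    x_var = np.einsum("ij,ij->i", Xc, Xc)
    if not np.any(x_var > 0):
        warnings.warn("all-zero epoch: CCA coefficient defined as 0", stacklevel=2)
        return CCAResult(R=0.0, w_x=np.zeros(X.shape[0]), w_y=np.zeros(Ym.shape[0]))
    if np.any(x_var == 0):
        warnings.warn("zero-variance channel(s) regularized in CCA", stacklevel=2)

    Cxx = (Xc @ Xc.T) / n
    Cyy = (Yc @ Yc.T) / n
    Cxy = (Xc @ Yc.T) / n
    return cca_from_covariances(Cxx, Cyy, Cxy, ridge=ridge)


def single_channel_response(
    epoch: np.ndarray,
    channel: int,
    Y: ReferenceSet | np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """CCA coefficient of one channel (a row of the epoch) alone."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    return cca_coefficient(epoch[channel:channel + 1], Y, ridge=ridge).R
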