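"""Channel-contribution topographies and the contralateral-effect score.

The contribution of channel i to SSVEP detection is the normalized drop of
the all-channel CCA coefficient when that channel is left out:

    r_i = (R_all - R_without_i) / R_all

The contralateral-effect score of a mirror channel pair p = (p_left,
p_right) for the stimuli on side s within visual angle d is

    E_{s,d,p} = mean_k r[k, p_left] / r[center, p_left]
              - mean_k r[k, p_right] / r[center, p_right]

where r are single-channel responses averaged over valid runs and the
central stimulus serves as the between-hemisphere normalizer.  A positive E
means left-channel dominance (expected for right-hemifield stimuli).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cca import DEFAULT_RIDGE, ReferenceSet, cca_from_covariances
from .layout import StimulusLayout
from .montage import Montage

__all__ = [
    "channel_contribution",
    "channel_contributions",
    "contribution_map",
    "single_channel_table",
    "contralateral_score",
    "contralateral_table",
    "kw_significance",
]

CENTRAL_STIMULUS = 1


def _epoch_covariances(epoch: np.ndarray, Y: ReferenceSet | np.ndarray):
    Ym = Y.matrix if isinstance(Y, ReferenceSet) else np.asarray(Y, dtype=float)
    X = np.asarray(epoch, dtype=float)
    n = X.shape[1]
    if Ym.shape[1] != n:
        raise ValueError("epoch and reference sample counts differ")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Ym - Ym.mean(axis=1, keepdims=True)
    return Xc @ Xc.T / n, Yc @ Yc.T / n, Xc @ Yc.T / n


def channel_contributions(
    epoch: np.ndarray, Y: ReferenceSet | np.ndarray, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Leave-one-out contribution r_i for every channel of one epoch.

    Covariances are computed once and rows/columns dropped per channel, so
    the C leave-one-out CCA solves cost only small eigendecompositions.
    Returns NaNs (with a warning) if the all-channel coefficient is zero.
    """
    Cxx, Cyy, Cxy = _epoch_covariances(epoch, Y)
    C = Cxx.shape[0]
    if C < 2:
        raise ValueError("leave-one-out contributions need at least 2 channels")
    r_all = cca_from_covariances(Cxx, Cyy, Cxy, ridge=ridge).R
    if r_all == 0:
        warnings.warn("all-channel CCA coefficient is 0; contributions undefined",
                      stacklevel=2)
        return np.full(C, np.nan)
    out = np.empty(C)
    for i in range(C):
        keep = np.delete(np.arange(C), i)
        r_wo = cca_from_covariances(
            Cxx[np.ix_(keep, keep)], Cyy, Cxy[keep], ridge=ridge
        ).R
        out[i] = (r_all - r_wo) / r_all
    return out


def channel_contribution(
    epoch: np.ndarray,
    Y: ReferenceSet | np.ndarray,
    channel_index: int,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Leave-one-out contribution of a single channel (see module docstring)."""
    Cxx, Cyy, Cxy = _epoch_covariances(epoch, Y)
    C = Cxx.shape[0]
    if C < 2:
        raise ValueError("leave-one-out contributions need at least 2 channels")
    if not 0 <= channel_index < C:
        raise IndexError(f"channel index {channel_index} out of range 0..{C - 1}")
    r_all = cca_from_covariances(Cxx, Cyy, Cxy, ridge=ridge).R
    if r_all == 0:
        warnings.warn("all-channel CCA coefficient is 0; contribution undefined",
                      stacklevel=2)
        return float("nan")
    keep = np.delete(np.arange(C), channel_index)
    r_wo = cca_from_covariances(Cxx[np.ix_(keep, keep)], Cyy, Cxy[keep], ridge=ridge).R
    return float((r_all - r_wo) / r_all)


def contribution_map(
    session,
    Y: ReferenceSet | np.ndarray,
    montage: Montage,
    preprocess=None,
    ridge: float = DEFAULT_RIDGE,
) -> pd.DataFrame:
    """Per-stimulus mean leave-one-out contributions over valid trials.

    Returns a channels x stimuli DataFrame (rows labeled by montage channel,
    columns by 1-based stimulus index).  ``preprocess`` optionally maps each
    raw epoch to a filtered one before scoring.
    """
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for trial in session.valid_trials():
        epoch = np.asarray(trial.eeg, dtype=float)
        if preprocess is not None:
            epoch = preprocess(epoch)
        contrib = channel_contributions(epoch, Y, ridge=ridge)
        if trial.stimulus not in sums:
            sums[trial.stimulus] = np.zeros(montage.n_channels)
            counts[trial.stimulus] = 0
        sums[trial.stimulus] += contrib
        counts[trial.stimulus] += 1
    data = {s: sums[s] / counts[s] for s in sorted(sums)}
    return pd.DataFrame(data, index=list(montage.labels))


def single_channel_table(
    session,
    Y: ReferenceSet | np.ndarray,
    montage: Montage,
    channels,
    preprocess=None,
) -> pd.DataFrame:
    """Run-averaged single-channel responses, stimuli x channels.

    Each cell is the mean (over valid runs) CCA coefficient of that channel
    alone against the reference set.
    """
    idx = montage.indices(channels)
    acc: dict[int, np.ndarray] = {}
    cnt: dict[int, int] = {}
    for trial in session.valid_trials():
        epoch = np.asarray(trial.eeg, dtype=float)
        if preprocess is not None:
            epoch = preprocess(epoch)
        Cxx, Cyy, Cxy = _epoch_covariances(epoch[idx], Y)
        vals = np.array([
            cca_from_covariances(Cxx[i:i + 1, i:i + 1], Cyy, Cxy[i:i + 1]).R
            for i in range(len(idx))
        ])
        if trial.stimulus not in acc:
            acc[trial.stimulus] = np.zeros(len(idx))
            cnt[trial.stimulus] = 0
        acc[trial.stimulus] += vals
        cnt[trial.stimulus] += 1
    rows = {s: acc[s] / cnt[s] for s in sorted(acc)}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(channels))


def _side_stimuli(layout: StimulusLayout, side: str, d: float) -> np.ndarray:
    return layout.stimuli_within(d, side=side)


def contralateral_score(
    responses: pd.DataFrame,
    layout: StimulusLayout,
    side: str,
    d: float,
    pair: tuple[str, str],
) -> float:
    """Contralateral-effect score E for one (side, angle, channel pair).

    ``responses`` is a stimuli x channels table of run-averaged
    single-channel responses containing both pair members and the central
    stimulus (index 1), which normalizes each hemisphere.

    Returns NaN if no stimulus lies on ``side`` within ``d`` degrees; raises
    if a central reference response is not positive.
    """
    p_left, p_right = pair
    ref_left = float(responses.loc[CENTRAL_STIMULUS, p_left])
    ref_right = float(responses.loc[CENTRAL_STIMULUS, p_right])
    if ref_left <= 0 or ref_right <= 0:
        raise ValueError(f"central reference response must be positive for pair {pair}")
    stimuli = _side_stimuli(layout, side, d)
    stimuli = [s for s in stimuli if s in responses.index]
    if not stimuli:
        return float("nan")
    left = responses.loc[stimuli, p_left].to_numpy(dtype=float)
    right = responses.loc[stimuli, p_right].to_numpy(dtype=float)
    return float(left.mean() / ref_left - right.mean() / ref_right)


def kw_significance(left_values, right_values, alpha: float = 0.05):
    """Kruskal-Wallis rank test between the pair's normalized response groups.

    Returns (H, p, flag) with flag = (p < alpha).  Fully tied data yield
    H = 0, p = 1, flag False.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.size < 2 or right.size < 2:
        raise ValueError("need at least two values per group")
    pooled = np.concatenate([left, right])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, False
    H, p = stats.kruskal(left, right)
    return float(H), float(p), bool(p < alpha)


def contralateral_table(
    responses: pd.DataFrame,
    layout: StimulusLayout,
    pairs: tuple[tuple[str, str], ...] | None = None,
    angles=(2.0, 4.0, 6.0, 8.0, 10.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scores and KW significance flags for every (pair, angle, side).

    One row per combination with columns: pair, angle_deg, side, score,
    kw_H, kw_p, significant.  The KW groups are the two channels' normalized
    per-stimulus responses over the side's stimuli within the angle.
    """
    if pairs is None:
        pairs = (("O1", "O2"), ("PO3", "PO4"), ("P3", "P4"), ("P7", "P8"))
    rows = []
    for pair in pairs:
        p_left, p_right = pair
        ref_left = float(responses.loc[CENTRAL_STIMULUS, p_left])
        ref_right = float(responses.loc[CENTRAL_STIMULUS, p_right])
        for d in angles:
            for side in ("left", "right"):
                score = contralateral_score(responses, layout, side, d, pair)
                stimuli = [s for s in _side_stimuli(layout, side, d)
                           if s in responses.index]
                if len(stimuli) >= 2:
                    left_norm = responses.loc[stimuli, p_left].to_numpy() / ref_left
                    right_norm = responses.loc[stimuli, p_right].to_numpy() / ref_right
                    H, p, flag = kw_significance(left_norm, right_norm, alpha=alpha)
                else:
                    H, p, flag = float("nan"), float("nan"), False
                rows.append(dict(pair=f"{p_left}-{p_right}", angle_deg=d, side=side,
                                 score=score, kw_H=H, kw_p=p, significant=flag))
    return pd.DataFrame(rows)
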