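"""Visual-field response maps and the central-vs-peripheral error statistic.

The "SSVEP response" of a trial is the CCA coefficient computed on the
11-channel occipito-parietal subset.  Per-position means over runs give the
retinotopic map; the competitive-effect *error rate* at visual angle d is the
percentage of runs in which some stimulus of the layer at eccentricity d
out-responds the central stimulus of the same run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.spatial import QhullError

from .layout import StimulusLayout

__all__ = [
    "ResponseTable",
    "position_mean_response",
    "response_map",
    "layer_average",
    "error_rate",
    "error_rate_table",
    "average_error_rates",
    "central_peripheral_ttest",
    "surface_interpolator",
    "surface_grid",
]

ANGLES = (2.0, 4.0, 6.0, 8.0, 10.0)
CENTRAL_STIMULUS = 1


@dataclass
class ResponseTable:
    """Long-format table of per-trial responses (valid trials only).

    ``data`` columns: participant, run, stimulus, response (in [0, 1]).
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"participant", "run", "stimulus", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"ResponseTable missing columns: {sorted(missing)}")

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique())

    def subset(self, participant) -> pd.DataFrame:
        return self.data[self.data["participant"] == participant]

    @classmethod
    def from_records(cls, records) -> "ResponseTable":
        return cls(pd.DataFrame.from_records(
            records, columns=["participant", "run", "stimulus", "response"]))


def _layer_for_angle(layout: StimulusLayout, d: float) -> int:
    radii = layout.layer_radii
    layer = int(np.argmin(np.abs(radii - d))) + 1
    if abs(radii[layer - 1] - d) > 1e-6:
        raise ValueError(f"no layer at visual angle {d} deg (radii {radii})")
    if layer == 1:
        raise ValueError("visual angle 0 denotes the central stimulus, not a layer")
    return layer


def position_mean_response(table: ResponseTable, participant, stimulus: int) -> float:
    """Mean response over valid runs for one stimulus; NaN (+warning) if none."""
    sub = table.subset(participant)
    vals = sub.loc[sub["stimulus"] == stimulus, "response"]
    if vals.empty:
        warnings.warn(
            f"no valid trials for participant {participant!r}, stimulus {stimulus}",
            stacklevel=2,
        )
        return float("nan")
    return float(vals.mean())


def response_map(table: ResponseTable, participant, layout: StimulusLayout) -> pd.Series:
    """Per-stimulus mean responses, indexed by 1-based stimulus index."""
    sub = table.subset(participant)
    means = sub.groupby("stimulus")["response"].mean()
    return means.reindex(range(1, layout.n_stimuli + 1))


def layer_average(maps, layout: StimulusLayout) -> pd.Series:
    """Mean response per layer: over stimuli within layer, then participants.

    ``maps`` is one per-stimulus map (Series) or a dict participant -> map.
    """
    if isinstance(maps, pd.Series):
        maps = {"_single": maps}
    per_participant = []
    for m in maps.values():
        layer_means = {
            layer: float(np.nanmean(m.loc[layout.stimuli_in_layer(layer)]))
            for layer in range(1, layout.n_layers + 1)
        }
        per_participant.append(pd.Series(layer_means))
    return pd.DataFrame(per_participant).mean(axis=0)


def _runwise_frame(sub: pd.DataFrame, layer_stimuli: np.ndarray) -> pd.DataFrame:
    """Per-run central response and layer-stimulus responses (long form)."""
    central = sub[sub["stimulus"] == CENTRAL_STIMULUS].set_index("run")["response"]
    periph = sub[sub["stimulus"].isin(layer_stimuli)]
    return central, periph


def error_rate(
    table: ResponseTable,
    layout: StimulusLayout,
    participant,
    d: float,
    variant: str = "runwise",
) -> tuple[float, int]:
    """Competitive-effect error rate (%) at visual angle ``d``.

    variant "runwise" (default): a run counts as an error iff the maximum
    response over the layer-``d`` stimuli of that run exceeds the central
    response of the same run; the rate is errors / usable runs.  A usable run
    has a valid central trial and at least one valid layer-``d`` trial, so
    rates are multiples of 1/(usable runs).

    variant "pooled": every valid (stimulus, run) comparison at the layer
    counts individually.

    Returns (rate_percent, n_runs_used).
    """
    layer = _layer_for_angle(layout, d)
    layer_stimuli = layout.stimuli_in_layer(layer)
    sub = table.subset(participant)
    central, periph = _runwise_frame(sub, layer_stimuli)
    if central.empty:
        raise ValueError(f"participant {participant!r}: central stimulus has no valid trials")

    if variant == "runwise":
        errors = usable = 0
        for run, c in central.items():
            vals = periph.loc[periph["run"] == run, "response"]
            if vals.empty:
                continue
            usable += 1
            if vals.max() > c:
                errors += 1
        if usable == 0:
            raise ValueError(f"no usable runs at {d} deg for participant {participant!r}")
        return 100.0 * errors / usable, usable
    elif variant == "pooled":
        merged = periph.merge(central.rename("central"), left_on="run", right_index=True)
        if merged.empty:
            raise ValueError(f"no usable comparisons at {d} deg for participant {participant!r}")
        rate = 100.0 * float((merged["response"] > merged["central"]).mean())
        return rate, int(merged["run"].nunique())
    raise ValueError(f"unknown error-rate variant {variant!r}")


def central_peripheral_ttest(
    table: ResponseTable, layout: StimulusLayout, participant, d: float
) -> float:
    """Two-sided Welch t-test p: per-run central vs layer-``d`` responses.

    Degenerate (zero-variance) groups fall back to the convention p = 1 if
    the means are equal, p -> 0 otherwise, with a warning.
    """
    layer = _layer_for_angle(layout, d)
    sub = table.subset(participant)
    central = sub.loc[sub["stimulus"] == CENTRAL_STIMULUS, "response"].to_numpy()
    periph = sub.loc[
        sub["stimulus"].isin(layout.stimuli_in_layer(layer)), "response"
    ].to_numpy()
    if central.size < 2 or periph.size < 2:
        raise ValueError("need at least two values per group for a t-test")
    if np.var(central) == 0 and np.var(periph) == 0:
        warnings.warn("zero variance in both groups; p by degenerate convention",
                      stacklevel=2)
        return 1.0 if np.isclose(central.mean(), periph.mean()) else 0.0
    return float(stats.ttest_ind(central, periph, equal_var=False).pvalue)


def error_rate_table(
    table: ResponseTable,
    layout: StimulusLayout,
    angles=ANGLES,
    variant: str = "runwise",
) -> pd.DataFrame:
    """Participants x angles table of (error_rate, p_value), plus an AVE row.

    Mirrors the published competitive-effect table layout: one row per
    participant with columns ``rate_<d>`` and ``p_<d>``, and a final "AVE"
    row holding the across-participant mean rate per angle.
    """
    rows = {}
    for participant in table.participants:
        row = {}
        for d in angles:
            rate, _ = error_rate(table, layout, participant, d, variant=variant)
            row[f"rate_{d:g}"] = rate
            row[f"p_{d:g}"] = central_peripheral_ttest(table, layout, participant, d)
        rows[participant] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    ave = {f"rate_{d:g}": round(float(df[f"rate_{d:g}"].mean()), 2) for d in angles}
    df.loc["AVE"] = pd.Series(ave)
    return df


def average_error_rates(rates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """AVE row: arithmetic mean of per-participant rates per angle, 2 decimals."""
    arr = np.asarray(rates, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("expected a participants x angles matrix")
    return np.round(arr.mean(axis=0), 2)


def surface_interpolator(position_map: pd.Series, layout: StimulusLayout):
    """Piecewise-linear interpolant of the retinotopic map.

    Triangulates the stimulus positions and linearly interpolates the
    per-position mean responses; queries outside the convex hull return NaN.
    """
    values = position_map.reindex(range(1, layout.n_stimuli + 1)).to_numpy(dtype=float)
    keep = ~np.isnan(values)
    if keep.sum() < 3:
        raise ValueError("need at least 3 positions with responses")
    try:
        return interpolate.LinearNDInterpolator(layout.positions[keep], values[keep])
    except QhullError as exc:
        raise ValueError("stimulus positions are collinear; cannot triangulate") from exc


def surface_grid(
    position_map: pd.Series,
    layout: StimulusLayout,
    grid_resolution: float = 0.25,
):
    """Retinotopic surface sampled on a regular grid over the visual field.

    Grid nodes outside the convex hull of the stimulus positions are NaN.
    Returns (x_axis, y_axis, grid) with grid shape (len(y_axis), len(x_axis)).
    """
    interp = surface_interpolator(position_map, layout)
    half = layout.field_half_angle
    axis = np.arange(-half, half + grid_resolution / 2, grid_resolution)
    gx, gy = np.meshgrid(axis, axis)
    return axis, axis, interp(gx, gy)
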