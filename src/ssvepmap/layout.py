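"""Concentric flicker-stimulus geometry in visual-angle coordinates.

The stimulus array is a central flicker plus concentric rings ("layers") of
flickers, all specified in degrees of visual angle with the fixation point at
the origin (x positive rightward, y positive upward).  Layer 1 is the central
flicker; layer k (k >= 2) sits at eccentricity ``layer_spacing * (k - 1)``.
Stimulus indices are 1-based; index 1 is always the central flicker.

Flickers are presented one at a time, so discs on *different* rings may
overlap spatially; within a ring, the arc spacing must leave room for the
disc diameter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "StimulusLayout",
    "PositionClass",
    "build_layout",
    "classify_position",
]

#: Ring populations used throughout: 3, 6, 9, 12, 15 stimuli on layers 2-6
#: (plus the central flicker: 46 total), giving a uniform ~4.19 deg arc
#: spacing on every ring.
DEFAULT_RING_COUNTS = (3, 6, 9, 12, 15)
DEFAULT_LAYER_SPACING = 2.0
DEFAULT_FLICKER_DIAMETER = 3.0

_AXIS_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a requested stimulus geometry is physically impossible."""


@dataclass(frozen=True)
class PositionClass:
    layer: int
    hemifield: str  # "left" | "right" | "on-axis"
    vertical_field: str  # "lower" | "upper" | "on-axis"


@dataclass(frozen=True)
class StimulusLayout:
    """Immutable description of a concentric flicker array."""

    positions: np.ndarray  # (n, 2) float, degrees visual angle
    layer_index: np.ndarray  # (n,) int, 1-based layer per stimulus
    flicker_diameter: float
    layer_spacing: float
    ring_counts: tuple[int, ...]
    angular_offsets: tuple[float, ...] = field(default=())

    @property
    def n_stimuli(self) -> int:
        return self.positions.shape[0]

    @property
    def n_layers(self) -> int:
        return 1 + len(self.ring_counts)

    @property
    def layer_radii(self) -> np.ndarray:
        """Eccentricity of each layer center, degrees (layer 1 -> 0)."""
        return self.layer_spacing * np.arange(self.n_layers)

    @property
    def field_half_angle(self) -> float:
        """Half-angle of the total covered visual field, degrees."""
        return float(self.layer_radii[-1] + self.flicker_diameter / 2.0)

    def eccentricity(self, stimulus_index: int | None = None) -> np.ndarray | float:
        ecc = np.hypot(self.positions[:, 0], self.positions[:, 1])
        if stimulus_index is None:
            return ecc
        return float(ecc[self._check_index(stimulus_index) - 1])

    def position(self, stimulus_index: int) -> tuple[float, float]:
        i = self._check_index(stimulus_index) - 1
        return float(self.positions[i, 0]), float(self.positions[i, 1])

    def stimuli_in_layer(self, layer: int) -> np.ndarray:
        """1-based stimulus indices belonging to a layer."""
        return np.flatnonzero(self.layer_index == layer) + 1

    def stimuli_within(self, max_eccentricity: float, side: str | None = None) -> np.ndarray:
        """1-based indices of off-center stimuli with eccentricity <= limit.

        ``side`` optionally restricts to one hemifield ("left"/"right").
        """
        ecc = self.eccentricity()
        keep = (ecc <= max_eccentricity + _AXIS_TOL) & (ecc > _AXIS_TOL)
        if side is not None:
            if side == "left":
                keep &= self.positions[:, 0] < -_AXIS_TOL
            elif side == "right":
                keep &= self.positions[:, 0] > _AXIS_TOL
            else:
                raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return np.flatnonzero(keep) + 1

    def _check_index(self, stimulus_index: int) -> int:
        if not 1 <= stimulus_index <= self.n_stimuli:
            raise IndexError(
                f"stimulus index {stimulus_index} out of range 1..{self.n_stimuli}"
            )
        return stimulus_index

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(1, self.n_stimuli + 1):
            c = classify_position(self, i)
            x, y = self.position(i)
            rows.append(
                dict(index=i, x_deg=x, y_deg=y, layer=c.layer,
                     hemifield=c.hemifield, vertical_field=c.vertical_field)
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# layer_spacing={self.layer_spacing!r}\n")
            fh.write(f"# flicker_diameter={self.flicker_diameter!r}\n")
            fh.write(f"# ring_counts={','.join(map(str, self.ring_counts))}\n")
            fh.write(f"# angular_offsets={','.join(map(repr, self.angular_offsets))}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusLayout":
        meta: dict[str, str] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val
                else:
                    body.write(line)
        body.seek(0)
        pd.read_csv(body)  # validates table shape; geometry is rebuilt exactly
        return build_layout(
            layer_spacing=float(meta["layer_spacing"]),
            flicker_diameter=float(meta["flicker_diameter"]),
            ring_counts=tuple(int(v) for v in meta["ring_counts"].split(",") if v),
            angular_offsets=tuple(float(v) for v in meta["angular_offsets"].split(",") if v),
        )


def build_layout(
    layer_spacing: float = DEFAULT_LAYER_SPACING,
    flicker_diameter: float = DEFAULT_FLICKER_DIAMETER,
    ring_counts: tuple[int, ...] = DEFAULT_RING_COUNTS,
    angular_offsets: tuple[float, ...] | None = None,
) -> StimulusLayout:
    """Build a concentric flicker layout.

    Parameters
    ----------
    layer_spacing
        Center-to-center distance between adjacent layers, degrees.
    flicker_diameter
        Disc diameter, degrees.
    ring_counts
        Number of stimuli on each ring (layers 2, 3, ...).
    angular_offsets
        Polar-angle offset of the first stimulus of each ring, degrees
        counter-clockwise from the +x axis.  Defaults to one eighth of the
        ring's arc step: the resulting angles (360/c)(k + 1/8) can never be a
        multiple of 90 deg (8k + 1 is odd), so no stimulus lies exactly on
        the horizontal or vertical midline and hemifield / vertical-field
        labels are always defined, for any ring count.

    Raises
    ------
    GeometryError
        If any ring's within-ring arc spacing is smaller than the flicker
        diameter (adjacent discs on that ring would overlap).
    """
    if layer_spacing <= 0:
        raise GeometryError("layer_spacing must be positive")
    if flicker_diameter <= 0:
        raise GeometryError("flicker_diameter must be positive")
    ring_counts = tuple(int(c) for c in ring_counts)
    if any(c < 1 for c in ring_counts):
        raise GeometryError("every ring must hold at least one stimulus")

    if angular_offsets is None:
        angular_offsets = tuple(45.0 / c for c in ring_counts)
    else:
        angular_offsets = tuple(float(a) for a in angular_offsets)
        if len(angular_offsets) != len(ring_counts):
            raise GeometryError("angular_offsets must match ring_counts length")

    xs, ys, layers = [0.0], [0.0], [1]
    for ring, (count, offset) in enumerate(zip(ring_counts, angular_offsets), start=2):
        radius = layer_spacing * (ring - 1)
        if count > 1:
            chord = 2.0 * radius * np.sin(np.pi / count)
            if chord < flicker_diameter - _AXIS_TOL:
                raise GeometryError(
                    f"ring {ring}: {count} discs of diameter {flicker_diameter} deg "
                    f"overlap at radius {radius} deg (arc chord {chord:.3f} deg)"
                )
        theta = np.deg2rad(offset + 360.0 * np.arange(count) / count)
        xs.extend(radius * np.cos(theta))
        ys.extend(radius * np.sin(theta))
        layers.extend([ring] * count)

    positions = np.column_stack([xs, ys])
    # snap numerically-zero coordinates so axis tests are exact
    positions[np.abs(positions) < _AXIS_TOL] = 0.0
    return StimulusLayout(
        positions=positions,
        layer_index=np.asarray(layers, dtype=int),
        flicker_diameter=float(flicker_diameter),
        layer_spacing=float(layer_spacing),
        ring_counts=ring_counts,
        angular_offsets=angular_offsets,
    )


def classify_position(layout: StimulusLayout, stimulus_index: int) -> PositionClass:
    """Layer / hemifield / vertical-field labels for one stimulus.

    The layer is recovered from eccentricity via the nearest layer radius;
    hemifield and vertical field follow the sign of x and y (zero -> on-axis).
    """
    x, y = layout.position(stimulus_index)
    ecc = float(np.hypot(x, y))
    layer = int(np.argmin(np.abs(layout.layer_radii - ecc))) + 1
    if x < -_AXIS_TOL:
        hemifield = "left"
    elif x > _AXIS_TOL:
        hemifield = "right"
    else:
        hemifield = "on-axis"
    if y < -_AXIS_TOL:
        vertical = "lower"
    elif y > _AXIS_TOL:
        vertical = "upper"
    else:
        vertical = "on-axis"
    return PositionClass(layer=layer, hemifield=hemifield, vertical_field=vertical)
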