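"""31-channel extended 10-20 EEG montage with schematic 2D scalp coordinates.

Coordinates are a standard top-view schematic on the unit head circle
(x positive toward the right ear, y positive toward the nasion); they are
used for topographic output and for the simulator's occipital forward model,
not for source analysis.  Odd-numbered labels are left-hemisphere, even
right, "z" labels midline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "standard_montage", "SYMMETRIC_PAIRS", "ANALYSIS_SUBSET"]

# label -> (x, y) schematic coordinates, unit head radius
_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.65, 0.30), "FC1": (-0.22, 0.27),
    "FC2": (0.22, 0.27), "FC6": (0.65, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.65, -0.30), "CP1": (-0.22, -0.27),
    "CP2": (0.22, -0.27), "CP6": (0.65, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.73), "POz": (0.0, -0.75), "PO4": (0.35, -0.73),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

#: Left-right mirror pairs used for the contralateral-effect analysis.
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("O1", "O2"), ("PO3", "PO4"), ("P3", "P4"), ("P7", "P8"),
)

#: Occipito-parietal channels entering the multichannel SSVEP response.
ANALYSIS_SUBSET: tuple[str, ...] = (
    "P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4", "O1", "Oz", "O2",
)


@dataclass(frozen=True)
class Montage:
    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS
    analysis_subset: tuple[str, ...] = ANALYSIS_SUBSET

    def __post_init__(self):
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        missing = [ch for ch in self.analysis_subset if ch not in self.labels]
        if missing:
            raise ValueError(f"analysis subset channels not in montage: {missing}")
        for left, right in self.pairs:
            if left not in self.labels or right not in self.labels:
                raise ValueError(f"pair ({left}, {right}) not in montage")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.asarray([self.index(ch) for ch in labels], dtype=int)

    def hemisphere(self, label: str) -> str:
        """'left', 'right' or 'midline' from the schematic x coordinate."""
        x = self.coords[self.index(label), 0]
        if x < 0:
            return "left"
        if x > 0:
            return "right"
        return "midline"


def standard_montage() -> Montage:
    """The 31-channel extended 10-20 montage used throughout the package."""
    labels = tuple(_COORDS)
    coords = np.asarray([_COORDS[ch] for ch in labels], dtype=float)
    return Montage(labels=labels, coords=coords)
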