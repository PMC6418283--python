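"""Published reference values from the eight-participant gaze-restricted study.

The competitive-effect error rates (percent) reported for eight participants
at the five peripheral visual angles.  They serve as fixed reference inputs
for consistency checks (e.g. reconstructing the across-participant average
row); they are not produced by this package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REFERENCE_ANGLES", "REFERENCE_ERROR_RATES", "REFERENCE_AVERAGE_ROW"]

#: Visual angles (deg) of the five peripheral layers.
REFERENCE_ANGLES = (2.0, 4.0, 6.0, 8.0, 10.0)

#: Error rates (%) per participant (rows S1..S8) and angle (columns).
REFERENCE_ERROR_RATES = np.array([
    [25.00, 8.33, 8.33, 8.33, 8.33],  # S1
    [8.33, 0.00, 0.00, 0.00, 0.00],   # S2
    [0.00, 0.00, 0.00, 0.00, 0.00],   # S3
    [8.33, 8.33, 0.00, 0.00, 0.00],   # S4
    [9.09, 9.09, 0.00, 0.00, 0.00],   # S5
    [8.33, 8.33, 0.00, 0.00, 0.00],   # S6
    [25.00, 0.00, 0.00, 0.00, 0.00],  # S7
    [8.33, 8.33, 8.33, 8.33, 8.33],   # S8
])

#: Published across-participant average error rates (%) per angle.
REFERENCE_AVERAGE_ROW = np.array([11.55, 5.30, 2.08, 2.08, 2.08])
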