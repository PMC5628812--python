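"""Risk surface: the process-driven sensitivity of a habitat cell.

Risk is the Euclidean distance of a cell from the (SfG=1, Dist=1)
corner of the habitat-template quadrant:

    Risk = sqrt((1 - SfG)^2 + (1 - Dist)^2)

Habitats that are both naturally calm (low Dist) and adverse (low SfG)
carry the highest sensitivity to trawling damage; the maximum value is
sqrt(2). The raw risk is kept for statistics (rank correlations are
unaffected by rescaling but regression coefficients are not); the
rescaled ``risk01`` is provided for map rendering only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import EnvGrid, combine_masks, rescale01

__all__ = ["PDSLayers", "risk_index"]


@dataclass
class PDSLayers:
    """The process-driven sensitivity triple plus raw risk."""

    dist01: EnvGrid
    sfg01: EnvGrid
    risk: EnvGrid            # raw, in [0, sqrt(2)]
    risk01: EnvGrid | None = None


def risk_index(sfg01: EnvGrid, dist01: EnvGrid) -> PDSLayers:
    """Cellwise distance from the benign-disturbed (1, 1) corner."""
    if sfg01.spec != dist01.spec:
        raise ValueError("grids must share one spec")
    mask = combine_masks(sfg01, dist01)
    for g, label in ((sfg01, "sfg01"), (dist01, "dist01")):
        vals = g.values[~mask]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError(f"{label} must be within [0, 1]")
    risk_vals = np.sqrt((1.0 - sfg01.values) ** 2
                        + (1.0 - dist01.values) ** 2)
    risk = EnvGrid(spec=sfg01.spec, values=risk_vals, mask=mask,
                   name="risk", units="1")
    try:
        risk01 = rescale01(risk)
        risk01.name = "risk01"
    except ValueError:
        risk01 = None
    return PDSLayers(dist01=dist01, sfg01=sfg01, risk=risk, risk01=risk01)
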