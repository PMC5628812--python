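"""The process-driven sensitivity stage: from an aligned layer stack to
the Disturbance, Scope-for-Growth and Risk surfaces."""

from __future__ import annotations

import numpy as np

from .grids import EnvGrid, GridStack, rescale01
from .disturbance import (WaveClimate, critical_shear_velocity,
                          disturbance_index, friction_velocity,
                          wave_generated_current)
from .scope_for_growth import (SfGInputs, chla_to_poc, inter_annual_sd,
                               intra_annual_sd, sfg_index)
from .risk import risk_index

__all__ = ["compute_pds"]


def compute_pds(stack: GridStack, sediment, sst_monthly) -> dict:
    """Run the full PDS chain on one stack.

    ``stack`` must carry depth, hs, tp, currents, chla and salinity
    layers; ``sediment`` is the class map with its grain-size lookup;
    ``sst_monthly`` is a year-by-month nest of temperature grids.
    Returns the disturbance result, the SfG result, the combined PDS
    layers and the intermediate temperature/food grids.
    """
    waves = WaveClimate(hs=stack["hs"], tp=stack["tp"])
    wave_curr = wave_generated_current(stack["depth"], waves)
    friction = friction_velocity(wave_curr, stack["currents"])
    critical = critical_shear_velocity(sediment.grain_size_grid())
    dist = disturbance_index(friction, critical, wave_current=wave_curr)

    poc = chla_to_poc(stack["chla"])
    annual_means = [
        EnvGrid(spec=stack.spec,
                values=np.mean([m.values for m in months], axis=0),
                name=f"sst_annual_{i}", units="degC")
        for i, months in enumerate(sst_monthly)
    ]
    sst_mean = EnvGrid(spec=stack.spec,
                       values=np.mean([g.values for g in annual_means],
                                      axis=0),
                       name="sst_mean", units="degC")
    ta = intra_annual_sd(sst_monthly)
    ti = inter_annual_sd(annual_means)
    sfg = sfg_index(SfGInputs(
        fa=_renamed(rescale01(poc), "fa"),
        sst=_renamed(rescale01(sst_mean), "sst"),
        s=_renamed(rescale01(stack["salinity"]), "s"),
        ta=_renamed(rescale01(ta), "ta"),
        ti=_renamed(rescale01(ti), "ti"),
    ))
    pds = risk_index(sfg01=sfg.sfg01, dist01=dist.dist01)
    return {"dist": dist, "sfg": sfg, "pds": pds, "ta": ta, "ti": ti,
            "sst_mean": sst_mean, "poc": poc}


def _renamed(g: EnvGrid, name: str) -> EnvGrid:
    g.name = name
    return g
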