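"""Scope-for-Growth axis: energy available after adaptation costs.

SfG summarises the benign-to-adverse gradient of the benthic
environment as (Fa + SST + S - Ta - Ti) / 5, where every term has first
been min-max rescaled to [0, 1]:

* Fa — food availability: particulate organic carbon derived from a
  chlorophyll-a climatology via log10 POC = 2.27 + 0.35 log10 Chla
  (valid shallower than 300 m), rescaled after the (nonlinear) POC
  transform;
* SST — mean temperature; S — mean salinity;
* Ta — intra-annual temperature variability: SD of monthly means within
  each year, averaged over years;
* Ti — inter-annual temperature variability: SD of annual mean
  temperatures between years.

Sample (n-1) standard deviations are used throughout. High Fa/SST/S and
low variability give a benign habitat; the final index is rescaled to
[0, 1] again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import EnvGrid, combine_masks, rescale01

__all__ = [
    "SfGInputs",
    "SfGResult",
    "chla_to_poc",
    "intra_annual_sd",
    "inter_annual_sd",
    "sfg_index",
]


@dataclass
class SfGInputs:
    """The five SfG terms, each already rescaled to [0, 1]."""

    fa: EnvGrid
    sst: EnvGrid
    s: EnvGrid
    ta: EnvGrid
    ti: EnvGrid

    def layers(self) -> tuple[EnvGrid, ...]:
        return (self.fa, self.sst, self.s, self.ta, self.ti)

    def __post_init__(self) -> None:
        spec = self.fa.spec
        for g in self.layers():
            if g.spec != spec:
                raise ValueError("all five SfG inputs must share one spec")


@dataclass
class SfGResult:
    raw: EnvGrid    # (Fa + SST + S - Ta - Ti)/5, in [-0.4, 0.6]
    sfg01: EnvGrid  # rescaled 0-1


def chla_to_poc(chla: EnvGrid) -> EnvGrid:
    """Particulate organic carbon from chlorophyll-a.

    POC = 10^(2.27 + 0.35 log10 Chla). Non-positive chlorophyll cells
    are masked with a warning rather than raising, since satellite
    climatologies routinely carry a few spurious zeros.
    """
    bad = (~chla.mask) & (chla.values <= 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} non-positive chlorophyll cells masked",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        poc = 10.0 ** (2.27 + 0.35 * np.log10(
            np.where(chla.values > 0, chla.values, np.nan)))
    return chla.with_values(poc, name="poc", units="mg m-3", extra_mask=bad)


def _stack_cube(grids: Sequence[EnvGrid]) -> tuple[np.ndarray, np.ndarray]:
    spec = grids[0].spec
    for g in grids:
        if g.spec != spec:
            raise ValueError("grids must share one spec")
    cube = np.stack([np.where(g.mask, np.nan, g.values) for g in grids])
    return cube, np.all([g.mask for g in grids], axis=0)


def intra_annual_sd(monthly_by_year: Sequence[Sequence[EnvGrid]]) -> EnvGrid:
    """Within-year SD of monthly means, averaged over years.

    ``monthly_by_year`` is a collection of years, each a collection of
    (at least two) monthly-mean grids. Sample (n-1) SD per year and
    cell, then the mean across years.
    """
    if len(monthly_by_year) == 0:
        raise ValueError("need at least one year of monthly means")
    per_year = []
    for months in monthly_by_year:
        if len(months) < 2:
            raise ValueError("need at least two months per year")
        cube, _ = _stack_cube(list(months))
        with np.errstate(all="ignore"):
            per_year.append(np.nanstd(cube, axis=0, ddof=1))
    out = np.nanmean(np.stack(per_year), axis=0)
    g0 = monthly_by_year[0][0]
    mask = ~np.isfinite(out)
    return EnvGrid(spec=g0.spec, values=out, mask=mask,
                   name="ta", units=g0.units)


def inter_annual_sd(annual_means: Sequence[EnvGrid]) -> EnvGrid:
    """Between-year sample SD of annual mean temperatures."""
    if len(annual_means) < 2:
        raise ValueError("need at least two years of annual means")
    cube, _ = _stack_cube(list(annual_means))
    with np.errstate(all="ignore"):
        out = np.nanstd(cube, axis=0, ddof=1)
    mask = ~np.isfinite(out)
    return EnvGrid(spec=annual_means[0].spec, values=out, mask=mask,
                   name="ti", units=annual_means[0].units)


def sfg_index(inputs: SfGInputs) -> SfGResult:
    """(Fa + SST + S - Ta - Ti)/5 on rescaled inputs, then rescaled 0-1."""
    for g in inputs.layers():
        vals = g.unmasked()
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(
                f"SfG input {g.name!r} is outside [0, 1]; rescale it first"
            )
    fa, sst, s, ta, ti = inputs.layers()
    mask = combine_masks(*inputs.layers())
    raw_vals = (fa.values + sst.values + s.values
                - ta.values - ti.values) / 5.0
    raw = EnvGrid(spec=fa.spec, values=raw_vals, mask=mask,
                  name="sfg_raw", units="1")
    sfg01 = rescale01(raw)
    sfg01.name = "sfg01"
    return SfGResult(raw=raw, sfg01=sfg01)
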