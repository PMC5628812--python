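"""Natural disturbance axis: sediment mobility under waves and currents.

Disturbance is the ratio between the characteristic near-bed friction
velocity (wave-generated orbital current plus tidal bottom current,
assumed collinear and therefore summed) and the critical velocity needed
to mobilise the local sediment. The critical velocity comes from a
quartic approximation to the erosion branch of the Hjulström diagram in
log10 grain size. High ratios mark naturally unstable seabed (fine
mobile sediment); low ratios mark stable gravel.

Units: wave and bottom currents are in m/s; the Hjulström quartic yields
a threshold in cm/s, so the friction velocity is converted to cm/s
before the ratio is formed. The quartic's source does not state units —
cm/s is the Hjulström-diagram convention and is recorded in the output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .grids import EnvGrid, combine_masks, rescale01

__all__ = [
    "WaveClimate",
    "SedimentClassMap",
    "DisturbanceResult",
    "wave_number",
    "wave_generated_current",
    "friction_velocity",
    "critical_shear_velocity",
    "disturbance_index",
    "HJULSTROM_COEFFS",
]

GRAVITY = 9.81  # m s^-2

# Quartic in X = log10(grain size in mm); threshold velocity = 10**Y cm/s.
HJULSTROM_COEFFS = (-0.0272, -0.0905, 0.2411, 0.4691, 1.8761)


@dataclass
class WaveClimate:
    """90th-percentile wave climate: significant height (m), period (s)."""

    hs: EnvGrid
    tp: EnvGrid

    def __post_init__(self) -> None:
        if self.hs.spec != self.tp.spec:
            raise ValueError("hs and tp must share one grid spec")
        ok = ~combine_masks(self.hs, self.tp)
        if np.any(self.hs.values[ok] < 0):
            raise ValueError("significant wave height must be >= 0")
        if np.any(self.tp.values[ok] <= 0):
            raise ValueError("wave period must be > 0")


@dataclass
class SedimentClassMap:
    """Integer sediment-class codes plus a class -> mean grain size map (mm)."""

    classes: EnvGrid
    class_mean_grain_mm: Mapping[int, float]

    def __post_init__(self) -> None:
        codes = np.unique(self.classes.unmasked().astype(int))
        for code in codes:
            grain = self.class_mean_grain_mm.get(int(code))
            if grain is None:
                raise ValueError(f"sediment class {code} has no grain size")
            if grain <= 0:
                raise ValueError(f"grain size for class {code} must be > 0")

    def grain_size_grid(self) -> EnvGrid:
        """Map class codes to mean grain size (mm)."""
        out = np.full(self.classes.spec.shape, np.nan)
        codes = self.classes.values
        for code, grain in self.class_mean_grain_mm.items():
            out[(codes == code) & ~self.classes.mask] = grain
        return self.classes.with_values(out, name="grain_size", units="mm")


@dataclass
class DisturbanceResult:
    wave_current: EnvGrid       # m/s
    friction_velocity: EnvGrid  # m/s
    critical_velocity: EnvGrid  # cm/s
    ratio: EnvGrid              # dimensionless
    dist01: EnvGrid             # rescaled 0-1


def wave_number(tp: float, depth: float) -> float:
    """Solve the linear (Airy) dispersion relation for the wavenumber k.

    omega^2 = g k tanh(k h), with omega = 2 pi / Tp. Solved by a
    bracketed root-finder to 1e-10 absolute tolerance. Returns k in
    rad/m.
    """
    omega = 2.0 * np.pi / tp
    target = omega**2

    def f(k: float) -> float:
        return GRAVITY * k * np.tanh(k * depth) - target

    if depth <= 0:
        raise ValueError("depth must be > 0")
    # g k tanh(kh) is increasing in k and bounded above by g k, so the
    # deep-water wavenumber omega^2/g always lies at or below the root.
    lo = 0.5 * target / GRAVITY
    hi = 2.0 * max(target / GRAVITY, np.sqrt(target / (GRAVITY * depth)))
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-10, maxiter=100)


def wave_generated_current(depth: EnvGrid, waves: WaveClimate) -> EnvGrid:
    """Near-bed wave orbital velocity u_b = pi Hs / (Tp sinh(k h)), m/s.

    Linear wave theory; k from the dispersion relation per cell. Zero
    where Hs = 0; decays to zero as depth grows for fixed waves.
    """
    if depth.spec != waves.hs.spec:
        raise ValueError("depth and wave grids must share one spec")
    mask = combine_masks(depth, waves.hs, waves.tp)
    ok = ~mask
    if np.any(depth.values[ok] <= 0):
        raise ValueError("depth must be > 0 where unmasked")
    out = np.full(depth.spec.shape, np.nan)
    h = depth.values
    hs = waves.hs.values
    tp = waves.tp.values
    # k depends only on (tp, h); cache repeated pairs (class-like layers).
    cache: dict[tuple[float, float], float] = {}
    idx = np.argwhere(ok)
    for i, j in idx:
        key = (float(tp[i, j]), float(h[i, j]))
        k = cache.get(key)
        if k is None:
            k = wave_number(*key)
            cache[key] = k
        kh = k * h[i, j]
        # sinh overflows for very deep water; orbital velocity is ~0 there
        if kh > 700.0:
            out[i, j] = 0.0
        else:
            out[i, j] = np.pi * hs[i, j] / (tp[i, j] * np.sinh(kh))
    return EnvGrid(spec=depth.spec, values=out, mask=mask,
                   name="wave_current", units="m/s")


def friction_velocity(wave_current: EnvGrid, bottom_current: EnvGrid) -> EnvGrid:
    """Characteristic friction velocity: cellwise sum of the two currents.

    Tidal bottom currents are assumed collinear with the wave-generated
    current, so the magnitudes add as scalars.
    """
    if wave_current.spec != bottom_current.spec:
        raise ValueError("grids must share one spec")
    u1, u2 = wave_current.units, bottom_current.units
    if u1 and u2 and u1 != u2:
        raise ValueError(f"unit mismatch: {u1!r} vs {u2!r}")
    mask = combine_masks(wave_current, bottom_current)
    out = wave_current.values + bottom_current.values
    return EnvGrid(spec=wave_current.spec, values=out, mask=mask,
                   name="friction_velocity", units=u1 or u2 or "m/s")


def critical_shear_velocity(grain_size_mm):
    """Critical erosion velocity from grain size, Hjulström approximation.

    Y = -0.0272 X^4 - 0.0905 X^3 + 0.2411 X^2 + 0.4691 X + 1.8761 with
    X = log10(grain size in mm); returns 10**Y in cm/s. Accepts a scalar,
    an array, or an :class:`EnvGrid` and returns the same shape.
    """
    if isinstance(grain_size_mm, EnvGrid):
        g = grain_size_mm
        if np.any(g.unmasked() <= 0):
            raise ValueError("grain size must be > 0")
        with np.errstate(invalid="ignore"):
            vals = critical_shear_velocity(
                np.where(g.mask, 1.0, g.values))
        vals = np.where(g.mask, np.nan, vals)
        return g.with_values(vals, name="critical_velocity", units="cm/s")
    arr = np.asarray(grain_size_mm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("grain size must be > 0")
    x = np.log10(arr)
    y = np.polyval(HJULSTROM_COEFFS, x)
    out = 10.0**y
    return float(out) if np.isscalar(grain_size_mm) else out


def disturbance_index(friction: EnvGrid, critical: EnvGrid,
                      wave_current: EnvGrid | None = None) -> DisturbanceResult:
    """Disturbance = friction velocity / critical mobilisation velocity.

    ``friction`` in m/s is converted to cm/s to match the Hjulström
    threshold before dividing; the ratio is then min-max rescaled to
    [0, 1] (``dist01``).
    """
    if friction.spec != critical.spec:
        raise ValueError("grids must share one spec")
    mask = combine_masks(friction, critical)
    crit = critical.values
    if np.any(crit[~mask] <= 0):
        raise ValueError("critical velocity must be > 0")
    fric_cm = friction.values * (100.0 if friction.units in ("m/s", "") else 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_vals = fric_cm / crit
    ratio = EnvGrid(spec=friction.spec, values=ratio_vals, mask=mask,
                    name="disturbance_ratio", units="1")
    dist01 = rescale01(ratio)
    dist01.name = "dist01"
    return DisturbanceResult(
        wave_current=wave_current if wave_current is not None else friction,
        friction_velocity=friction,
        critical_velocity=critical,
        ratio=ratio,
        dist01=dist01,
    )
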