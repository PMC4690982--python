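"""Land-surface temperature retrieval from at-sensor thermal radiance.

Two steps: an atmospheric/emissivity correction that recovers the blackbody
radiance at the surface temperature,

    B = (L_sen - L_up) / (eps * tau) - ((1 - eps) / eps) * L_down,

followed by an inversion of Planck's law for the sensor's thermal band,

    LST = K2 / ln(K1 / B + 1)   [kelvin].

``L_up`` and ``L_down`` are the upwelling and downwelling atmospheric
radiances, ``tau`` the atmospheric transmittance (scene-level scalars from
an atmospheric-correction service), ``eps`` the surface emissivity raster,
and K1, K2 the band calibration constants. Defaults for K1/K2 are the
Landsat 5 TM band 6 handbook values; they are configuration, not physics.

The forward model (temperature -> at-sensor radiance) is provided for
simulation and testing; retrieval inverts it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_geo import RasterGrid

__all__ = [
    "ThermalInputs",
    "K1_LANDSAT5_TM",
    "K2_LANDSAT5_TM",
    "blackbody_radiance",
    "planck_inversion",
    "retrieve_lst",
    "planck_radiance",
    "forward_radiance",
]

# Landsat 5 TM band 6 calibration constants (sensor handbook).
K1_LANDSAT5_TM = 607.76  # W m-2 sr-1 um-1
K2_LANDSAT5_TM = 1260.56  # K


@dataclass
class ThermalInputs:
    """Inputs for one thermal scene.

    L_sen : at-sensor spectral radiance raster (W m-2 sr-1 um-1)
    emissivity : surface emissivity raster, in (0, 1]
    L_up, L_down : scene-level atmospheric radiances (same units as L_sen)
    tau : atmospheric transmittance, in (0, 1]
    K1, K2 : thermal band calibration constants (radiance units / kelvin)
    """

    L_sen: RasterGrid
    emissivity: RasterGrid
    L_up: float
    L_down: float
    tau: float
    K1: float = K1_LANDSAT5_TM
    K2: float = K2_LANDSAT5_TM

    def __post_init__(self) -> None:
        if self.emissivity.values.shape != self.L_sen.values.shape:
            raise ValueError("emissivity and radiance rasters must share a shape")
        eps = self.emissivity.values[~self.emissivity.nodata_mask]
        if eps.size and (np.any(eps <= 0) or np.any(eps > 1)):
            raise ValueError("emissivity must satisfy 0 < eps <= 1 on valid cells")
        if not 0 < self.tau <= 1:
            raise ValueError(f"transmittance tau must be in (0, 1], got {self.tau}")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("calibration constants K1, K2 must be positive")


def blackbody_radiance(inputs: ThermalInputs) -> tuple[RasterGrid, dict]:
    """Correct at-sensor radiance to surface blackbody radiance.

    Cells where the corrected radiance is non-positive (e.g. radiance at or
    below the atmospheric path contribution) are masked rather than raising:
    isolated bad cells should not abort a scene. Returns the radiance grid
    and a diagnostics dict with ``n_nonpositive``.
    """
    eps = inputs.emissivity.values.astype(float)
    mask = inputs.L_sen.nodata_mask | inputs.emissivity.nodata_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        B = (inputs.L_sen.values - inputs.L_up) / (eps * inputs.tau) - (
            (1.0 - eps) / eps
        ) * inputs.L_down
    bad = ~mask & ~(B > 0)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} cell(s) with non-positive corrected radiance masked",
            stacklevel=2,
        )
    out_mask = mask | bad
    B = np.where(out_mask, np.nan, B)
    return inputs.L_sen.like(B, out_mask), {"n_nonpositive": n_bad}


def planck_inversion(B: RasterGrid, K1: float, K2: float) -> RasterGrid:
    """Invert Planck's law: LST = K2 / ln(K1/B + 1), kelvin.

    Requires B > 0 on all non-nodata cells; non-positive radiance reaching
    this point is an upstream defect and raises.
    """
    vals = B.values[~B.nodata_mask]
    if vals.size and not np.all(vals > 0):
        raise ValueError(
            "non-positive blackbody radiance reached planck_inversion; "
            "it must be masked upstream"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lst = K2 / np.log(K1 / B.values + 1.0)
    lst = np.where(B.nodata_mask, np.nan, lst)
    return B.like(lst)


def retrieve_lst(inputs: ThermalInputs) -> tuple[RasterGrid, dict]:
    """At-sensor radiance -> LST in kelvin (correction + Planck inversion)."""
    B, diag = blackbody_radiance(inputs)
    return planck_inversion(B, inputs.K1, inputs.K2), diag


# --- forward model -----------------------------------------------------------

def planck_radiance(T, K1: float, K2: float):
    """Blackbody radiance of the sensor band at temperature T (kelvin)."""
    T = np.asarray(T, dtype=float)
    return K1 / (np.expm1(K2 / T))


def forward_radiance(
    T,
    emissivity,
    L_up: float,
    L_down: float,
    tau: float,
    K1: float = K1_LANDSAT5_TM,
    K2: float = K2_LANDSAT5_TM,
):
    """Surface temperature -> at-sensor radiance (the exact inverse of
    :func:`retrieve_lst` for the same atmosphere)."""
    eps = np.asarray(emissivity, dtype=float)
    B = planck_radiance(T, K1, K2)
    return tau * (eps * B + (1.0 - eps) * L_down) + L_up
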