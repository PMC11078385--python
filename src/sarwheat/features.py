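"""Classification features: mean backscatter, the SAR_add radar index, NDVI.

``SAR_add`` is the sum of the temporal-mean VH and VV backscattering
coefficients (dB).  Summing the two polarizations widens the numeric gaps
between land-cover classes relative to either channel alone, which makes
threshold placement easier: open water drops below roughly -40 dB while
built-up areas stay well above the cropland range.

NDVI is computed from a single optical scene acquired at winter-wheat
maturity, when senescing wheat separates best from still-green vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np

from .preprocess import BackscatterStack, temporal_mean
from .raster import Raster

__all__ = [
    "OpticalScene",
    "FeatureStack",
    "sar_add",
    "ndvi",
    "build_feature_stack",
    "composite_rgb",
]


@dataclass
class OpticalScene:
    """Red (B4) and near-infrared (B8) surface reflectance on one grid."""

    red: Raster
    nir: Raster
    date: Date

    def __post_init__(self) -> None:
        if not self.red.meta.aligned_with(self.nir.meta):
            raise ValueError("red and nir bands are not aligned")
        for name, band in (("red", self.red), ("nir", self.nir)):
            v = band.valid_values()
            if v.size and v.min() < 0:
                raise ValueError(f"negative reflectance in {name} band")


@dataclass
class FeatureStack:
    """The four co-registered feature layers used by the decision tree."""

    sigma_vh_mean: Raster
    sigma_vv_mean: Raster
    sar_add: Raster
    ndvi: Raster

    def __post_init__(self) -> None:
        layers = [self.sigma_vh_mean, self.sigma_vv_mean, self.sar_add, self.ndvi]
        for r in layers[1:]:
            if not layers[0].meta.aligned_with(r.meta):
                raise ValueError("feature layers are not aligned")

    @property
    def meta(self):
        return self.sigma_vh_mean.meta

    def layer(self, name: str) -> Raster:
        return {
            "sigma_vh": self.sigma_vh_mean,
            "sigma_vv": self.sigma_vv_mean,
            "sar_add": self.sar_add,
            "ndvi": self.ndvi,
        }[name]


FEATURE_NAMES = ("sigma_vh", "sigma_vv", "sar_add", "ndvi")


def sar_add(vh_mean: Raster, vv_mean: Raster) -> Raster:
    """Element-wise sum of the mean VH and VV backscatter (dB); nodata where
    either input is nodata."""
    if not vh_mean.meta.aligned_with(vv_mean.meta):
        raise ValueError("VH and VV rasters are not aligned")
    ok = vh_mean.valid_mask & vv_mean.valid_mask
    out = np.where(
        ok, vh_mean.values + vv_mean.values, vh_mean.meta.nodata_value
    )
    return vh_mean.with_values(out, units="dB")


def ndvi(optical: OpticalScene) -> Raster:
    """Normalized difference vegetation index (NIR - red) / (NIR + red).

    Pixels where both bands are zero have no defined index and become
    nodata.  Values lie in [-1, 1] by construction; nothing is clipped.
    """
    red, nir = optical.red, optical.nir
    ok = red.valid_mask & nir.valid_mask
    denom = nir.values + red.values
    ok = ok & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = (nir.values - red.values) / denom
    out = np.where(ok, idx, red.meta.nodata_value)
    return red.with_values(out, units="index")


def build_feature_stack(
    vh_stack: BackscatterStack,
    vv_stack: BackscatterStack,
    optical: OpticalScene,
) -> FeatureStack:
    """Temporal means per polarization, then SAR_add, then NDVI."""
    vh_mean = temporal_mean(vh_stack)
    vv_mean = temporal_mean(vv_stack)
    if not vh_mean.meta.aligned_with(optical.red.meta):
        raise ValueError("SAR and optical grids are not aligned")
    return FeatureStack(
        sigma_vh_mean=vh_mean,
        sigma_vv_mean=vv_mean,
        sar_add=sar_add(vh_mean, vv_mean),
        ndvi=ndvi(optical),
    )


def composite_rgb(
    stack: BackscatterStack, dates: tuple[Date, Date, Date]
) -> np.ndarray:
    """Three-date false-colour composite for visual inspection.

    Each requested date's backscatter raster is stretched from its 2nd-98th
    valid-value percentiles to [0, 255]; a constant band maps to 0.  Returns
    a (rows, cols, 3) uint8 array; nodata pixels are 0 in all channels.
    """
    bands = []
    for d in dates:
        try:
            i = stack.dates.index(d)
        except ValueError:
            raise ValueError(f"date {d} not present in stack") from None
        r = stack.scenes[i]
        v = r.valid_values()
        lo, hi = np.percentile(v, [2, 98]) if v.size else (0.0, 0.0)
        if hi <= lo:
            band = np.zeros(r.values.shape, dtype=np.uint8)
        else:
            scaled = np.clip((r.values - lo) / (hi - lo), 0, 1) * 255
            band = np.where(r.valid_mask, scaled, 0).astype(np.uint8)
        bands.append(band)
    return np.stack(bands, axis=-1)
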