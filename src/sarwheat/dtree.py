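"""Median-rule threshold derivation and the fixed-topology decision tree.

The classifier has a fixed, interpretable structure: NDVI at wheat maturity
first separates other (still green) vegetation from everything else; the
SAR_add radar index then splits the remainder into water (very low
backscatter), winter wheat (intermediate), and building (high).

Each cut point is the midpoint of the statistical means of the two classes
it separates ("median of two values"):

    t_ndvi     = (mean_NDVI(wheat) + mean_NDVI(other vegetation)) / 2
    t_water    = (mean_SAR_add(water) + mean_SAR_add(wheat)) / 2
    t_building = (mean_SAR_add(wheat) + mean_SAR_add(building)) / 2

Boundary handling: the branches are evaluated in order with ``>`` for the
NDVI test and ``<`` for the two SAR_add tests, so a value exactly on a cut
falls through to the later class.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .features import FeatureStack
from .raster import CLASS_LEGEND, CLASS_NODATA, Raster

__all__ = [
    "ThresholdSet",
    "ClassMap",
    "CLASS_CODES",
    "derive_thresholds",
    "classify_pixel",
    "classify_map",
]

CLASS_CODES = {
    "winter_wheat": 1,
    "other_vegetation": 2,
    "building": 3,
    "water": 4,
}


@dataclass(frozen=True)
class ThresholdSet:
    """The three decision-tree cut points.

    t_ndvi: NDVI above which a pixel is other vegetation.
    t_water: SAR_add (dB) below which a pixel is water.
    t_building: SAR_add (dB) above which a pixel is building.
    """

    t_ndvi: float
    t_water: float
    t_building: float

    def __post_init__(self) -> None:
        if not self.t_water < self.t_building:
            raise ValueError("t_water must be below t_building")
        if not -1.0 <= self.t_ndvi <= 1.0:
            raise ValueError("t_ndvi must lie in [-1, 1]")

    def to_yaml(self, path, provenance: dict | None = None) -> None:
        doc = asdict(self)
        if provenance:
            doc["provenance"] = provenance
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            t_ndvi=float(doc["t_ndvi"]),
            t_water=float(doc["t_water"]),
            t_building=float(doc["t_building"]),
        )


@dataclass
class ClassMap:
    """A classified raster (uint8 class codes) plus its legend."""

    raster: Raster
    legend: dict[int, str]

    def __post_init__(self) -> None:
        if self.raster.units != "class-code":
            raise ValueError("ClassMap raster must have class-code units")
        codes = np.unique(self.raster.values)
        for c in codes:
            if int(c) not in self.legend:
                raise ValueError(f"class code {c} missing from legend")

    def pixel_count(self, class_label: str) -> int:
        code = {v: k for k, v in self.legend.items()}[class_label]
        return int(np.sum(self.raster.values == code))


def derive_thresholds(stats) -> ThresholdSet:
    """Derive the three cut points from per-class feature statistics by the
    pairwise-midpoint (median-of-two-means) rule.

    Requires all four classes; raises if the class means are ordered
    incompatibly with the tree (water must lie below wheat and wheat below
    building on SAR_add; wheat below other vegetation on NDVI).
    """
    need = ("winter_wheat", "other_vegetation", "building", "water")
    for c in need:
        if c not in stats.classes:
            raise ValueError(f"missing class in stats: {c}")
    ndvi_wheat = stats.mean("winter_wheat", "ndvi")
    ndvi_other = stats.mean("other_vegetation", "ndvi")
    sa_water = stats.mean("water", "sar_add")
    sa_wheat = stats.mean("winter_wheat", "sar_add")
    sa_building = stats.mean("building", "sar_add")
    if sa_water >= sa_wheat or sa_wheat >= sa_building:
        raise ValueError(
            "class geometry incompatible with the tree: SAR_add means must "
            f"order water < wheat < building, got {sa_water:.2f}, "
            f"{sa_wheat:.2f}, {sa_building:.2f}"
        )
    if ndvi_wheat == ndvi_other:
        warnings.warn("degenerate NDVI threshold: wheat and other-vegetation means equal")
    return ThresholdSet(
        t_ndvi=0.5 * (ndvi_wheat + ndvi_other),
        t_water=0.5 * (sa_water + sa_wheat),
        t_building=0.5 * (sa_wheat + sa_building),
    )


def classify_pixel(ndvi: float, sar_add: float, thresholds: ThresholdSet) -> str:
    """Assign one pixel to a class.  Total and single-valued over the
    (ndvi, sar_add) plane."""
    if ndvi > thresholds.t_ndvi:
        return "other_vegetation"
    if sar_add < thresholds.t_water:
        return "water"
    if sar_add < thresholds.t_building:
        return "winter_wheat"
    return "building"


def classify_map(stack: FeatureStack, thresholds: ThresholdSet) -> ClassMap:
    """Apply the decision tree to every pixel of the feature stack.

    Pixels with nodata in either NDVI or SAR_add become nodata (255).
    """
    ndvi = stack.ndvi
    sar = stack.sar_add
    ok = ndvi.valid_mask & sar.valid_mask
    out = np.full(stack.meta.shape, CLASS_NODATA, dtype=np.uint8)
    other = ndvi.values > thresholds.t_ndvi
    water = ~other & (sar.values < thresholds.t_water)
    wheat = ~other & ~water & (sar.values < thresholds.t_building)
    building = ~other & ~water & ~wheat
    out[ok & other] = CLASS_CODES["other_vegetation"]
    out[ok & water] = CLASS_CODES["water"]
    out[ok & wheat] = CLASS_CODES["winter_wheat"]
    out[ok & building] = CLASS_CODES["building"]
    meta = ndvi.meta
    from dataclasses import replace

    class_meta = replace(meta, nodata_value=CLASS_NODATA)
    return ClassMap(
        Raster(class_meta, out, units="class-code"), dict(CLASS_LEGEND)
    )
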