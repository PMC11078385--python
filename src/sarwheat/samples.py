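"""Labelled sample regions, the stratified train/validation split,
per-class feature statistics, and Jeffries-Matusita separability.

Regions of interest (ROIs) are polygons labelled with one of the four
land-cover classes.  Membership of a pixel in a region is decided by its
centre ("centre-in-polygon").  The train/validation split is stratified by
class at the region level, matching how sample inventories are reported as
ROI counts rather than pixel counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape

from .features import FEATURE_NAMES, FeatureStack
from .raster import GridMeta

__all__ = [
    "CLASS_LABELS",
    "SampleRegion",
    "SampleSet",
    "ClassStats",
    "split_samples",
    "class_stats",
    "jm_distance",
    "jm_from_moments",
    "jm_matrix",
    "read_sample_geojson",
    "write_sample_geojson",
]

CLASS_LABELS = ("winter_wheat", "other_vegetation", "building", "water")


@dataclass
class SampleRegion:
    """One labelled ROI: a set of pixel (row, col) indices plus optional
    polygon geometry for round-tripping through GeoJSON."""

    region_id: str
    class_label: str
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    geometry: object | None = None  # shapely geometry in map coordinates

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError(f"region {self.region_id} has no pixels")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass
class SampleSet:
    regions: list[SampleRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids are not unique")

    def __len__(self) -> int:
        return len(self.regions)

    def by_class(self) -> dict[str, list[SampleRegion]]:
        out: dict[str, list[SampleRegion]] = {}
        for r in self.regions:
            out.setdefault(r.class_label, []).append(r)
        return out

    def class_counts(self) -> dict[str, int]:
        return {c: len(rs) for c, rs in self.by_class().items()}

    def pixels_by_class(self) -> dict[str, np.ndarray]:
        out: dict[str, list[np.ndarray]] = {}
        for r in self.regions:
            out.setdefault(r.class_label, []).append(r.pixels)
        return {c: np.concatenate(p) for c, p in out.items()}


def split_samples(
    samples: SampleSet, train_fraction: float, seed: int
) -> tuple[SampleSet, SampleSet]:
    """Stratified region-level split into training and validation sets.

    Per class, ``round(train_fraction * n_class)`` regions (round half up)
    go to training; the rest to validation.  Deterministic given the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[SampleRegion] = []
    valid: list[SampleRegion] = []
    for label in CLASS_LABELS:
        regs = [r for r in samples.regions if r.class_label == label]
        if not regs:
            continue
        if len(regs) < 2:
            raise ValueError(f"class {label} has fewer than 2 regions")
        regs = sorted(regs, key=lambda r: r.region_id)
        n_train = int(np.floor(train_fraction * len(regs) + 0.5))
        if n_train == 0 or n_train == len(regs):
            raise ValueError(
                f"degenerate split for class {label}: "
                f"{n_train}/{len(regs)} regions in training"
            )
        order = rng.permutation(len(regs))
        train.extend(regs[i] for i in sorted(order[:n_train]))
        valid.extend(regs[i] for i in sorted(order[n_train:]))
    return SampleSet(train), SampleSet(valid)


@dataclass
class ClassStats:
    """Mean, population standard deviation and pixel count per class and
    per feature, stored as a tidy DataFrame."""

    table: pd.DataFrame  # index (class, feature); columns mean, std, n

    def mean(self, class_label: str, feature: str) -> float:
        return float(self.table.loc[(class_label, feature), "mean"])

    def std(self, class_label: str, feature: str) -> float:
        return float(self.table.loc[(class_label, feature), "std"])

    def count(self, class_label: str, feature: str) -> int:
        return int(self.table.loc[(class_label, feature), "n"])

    @property
    def classes(self) -> list[str]:
        return list(self.table.index.get_level_values(0).unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def class_stats(stack: FeatureStack, samples: SampleSet) -> ClassStats:
    """Per-class mean/std/count of every feature over all valid sample
    pixels.  Nodata pixels are excluded; a class whose pixels are all
    nodata in some feature raises."""
    rows = []
    n_rows, n_cols = stack.meta.shape
    for label, pix in samples.pixels_by_class().items():
        if (pix[:, 0].min() < 0 or pix[:, 1].min() < 0
                or pix[:, 0].max() >= n_rows or pix[:, 1].max() >= n_cols):
            raise ValueError(f"sample pixels of class {label} fall outside the grid")
        for feat in FEATURE_NAMES:
            layer = stack.layer(feat)
            vals = layer.values[pix[:, 0], pix[:, 1]]
            ok = vals != layer.meta.nodata_value
            if not ok.any():
                raise ValueError(
                    f"class {label} has zero valid pixels in feature {feat}"
                )
            v = vals[ok].astype(float)
            rows.append(
                {
                    "class": label,
                    "feature": feat,
                    "mean": float(v.mean()),
                    "std": float(v.std(ddof=0)),
                    "n": int(v.size),
                }
            )
    table = pd.DataFrame(rows).set_index(["class", "feature"])
    return ClassStats(table)


def jm_from_moments(
    mu1: np.ndarray, cov1: np.ndarray, mu2: np.ndarray, cov2: np.ndarray
) -> float:
    """Gaussian Jeffries-Matusita distance from class moments.

    JM = 2 (1 - exp(-B)) with the Bhattacharyya distance

        B = (1/8) d' [(S1+S2)/2]^-1 d
          + (1/2) ln( |(S1+S2)/2| / sqrt(|S1| |S2|) ),   d = mu1 - mu2.

    JM lies in [0, 2]; 2 means fully separable classes.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    cov2 = np.atleast_2d(np.asarray(cov2, dtype=float))
    pooled = 0.5 * (cov1 + cov2)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    s1, logdet1 = np.linalg.slogdet(cov1)
    s2, logdet2 = np.linalg.slogdet(cov2)
    if sign <= 0 or s1 <= 0 or s2 <= 0:
        raise ValueError(
            "singular covariance; reduce the feature subset for this pair"
        )
    diff = mu1 - mu2
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; reduce the feature subset"
        ) from exc
    b = 0.125 * float(diff @ sol) + 0.5 * (
        logdet_pooled - 0.5 * (logdet1 + logdet2)
    )
    return float(2.0 * (1.0 - np.exp(-b)))


def jm_distance(x1: np.ndarray, x2: np.ndarray) -> float:
    """Jeffries-Matusita distance between two classes given their sample
    feature matrices of shape (n_pixels, n_features)."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    cov1 = np.cov(x1, rowvar=False, ddof=0).reshape(x1.shape[1], x1.shape[1])
    cov2 = np.cov(x2, rowvar=False, ddof=0).reshape(x2.shape[1], x2.shape[1])
    return jm_from_moments(mu1, cov1, mu2, cov2)


def _class_feature_matrix(
    stack: FeatureStack, samples: SampleSet, label: str, features: list[str]
) -> np.ndarray:
    pix = samples.pixels_by_class()[label]
    cols = []
    ok = np.ones(len(pix), dtype=bool)
    for feat in features:
        layer = stack.layer(feat)
        vals = layer.values[pix[:, 0], pix[:, 1]]
        ok &= vals != layer.meta.nodata_value
        cols.append(vals)
    return np.stack(cols, axis=1)[ok].astype(float)


def jm_matrix(
    stack: FeatureStack,
    samples: SampleSet,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise J-M distances between all sampled classes over the chosen
    feature subset (default: all four features).  Diagonal is 0."""
    features = list(features) if features else list(FEATURE_NAMES)
    labels = [c for c in CLASS_LABELS if c in samples.class_counts()]
    mats = {c: _class_feature_matrix(stack, samples, c, features) for c in labels}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = jm_distance(mats[a], mats[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out


def rasterize_regions(
    geoms: list[tuple[str, str, object]], meta: GridMeta
) -> SampleSet:
    """Convert (region_id, class_label, shapely geometry) triples to pixel
    sets by centre-in-polygon membership."""
    rows = np.arange(meta.n_rows)
    cols = np.arange(meta.n_cols)
    x0, y0 = meta.origin
    cx = x0 + (cols + 0.5) * meta.pixel_size
    cy = y0 - (rows + 0.5) * meta.pixel_size
    xx, yy = np.meshgrid(cx, cy)
    regions = []
    for rid, label, geom in geoms:
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
        rr, cc = np.nonzero(inside)
        if rr.size == 0:
            raise ValueError(f"region {rid} covers no pixel centre")
        regions.append(SampleRegion(rid, label, np.stack([rr, cc], axis=1), geom))
    return SampleSet(regions)


def read_sample_geojson(path, meta: GridMeta) -> SampleSet:
    """Load ROIs from a GeoJSON FeatureCollection with properties
    ``region_id`` and ``class`` and rasterize them onto ``meta``."""
    with open(path) as fh:
        fc = json.load(fh)
    geoms = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        rid = str(props.get("region_id", i))
        label = props["class"]
        geoms.append((rid, label, shape(feat["geometry"])))
    return rasterize_regions(geoms, meta)


def write_sample_geojson(samples: SampleSet, meta: GridMeta, path) -> None:
    """Write ROIs as GeoJSON polygons.  Regions without stored geometry get
    the union of their pixel footprints."""
    feats = []
    ps = meta.pixel_size
    x0, y0 = meta.origin
    for r in samples.regions:
        geom = r.geometry
        if geom is None:
            squares = [
                box(x0 + c * ps, y0 - (row + 1) * ps, x0 + (c + 1) * ps, y0 - row * ps)
                for row, c in r.pixels
            ]
            geom = shapely.union_all(squares)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"region_id": r.region_id, "class": r.class_label},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
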