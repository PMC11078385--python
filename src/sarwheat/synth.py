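"""Synthetic four-class agricultural scenes for end-to-end testing.

The generator emulates the statistical structure the extraction pipeline
assumes, with no satellite download:

* a rectangular-field landscape of winter wheat, other vegetation,
  building and water patches, produced by recursive random splitting;
* a nine-date, dual-polarization (VH/VV) SAR time series with
  class- and date-dependent mean backscatter, fully developed
  multiplicative gamma speckle (intensity ~ mean * Gamma(ENL, 1/ENL)),
  and DN encoding that is the exact inverse of the ``DN^2/A^2``
  calibration;
* one red/near-infrared optical scene at wheat maturity whose
  class-conditional reflectances give the canonical NDVI ordering
  (other vegetation >> wheat > building > 0 > water);
* stratified single-class sample ROIs drawn from the truth map.

All default radiometry/optics numbers are generator configuration, chosen
to be realistic for C-band cropland scenes; they live in editable config,
not in code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date

import numpy as np
from scipy import ndimage

from .dtree import CLASS_CODES, ClassMap
from .features import OpticalScene
from .preprocess import SARScene, apply_shift
from .raster import CLASS_LEGEND, CLASS_NODATA, GridMeta, Raster
from .samples import CLASS_LABELS, SampleRegion, SampleSet

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "default_radiometry",
    "default_optics",
    "generate_landscape",
    "render_sar",
    "render_optical",
    "draw_samples",
    "generate_scene",
]

#: the nine acquisition dates (12-day repeat, regreening to maturity) and
#: their growth-stage labels
SAR_DATES: list[Date] = [
    Date(2022, 3, 7),
    Date(2022, 3, 19),
    Date(2022, 3, 31),
    Date(2022, 4, 12),
    Date(2022, 4, 24),
    Date(2022, 5, 6),
    Date(2022, 5, 18),
    Date(2022, 5, 30),
    Date(2022, 6, 11),
]
PHENOLOGY_LABELS = tuple("ABCDEFGHI")
OPTICAL_DATE = Date(2022, 6, 8)


def default_radiometry(n_dates: int = 9) -> dict[str, dict[str, np.ndarray]]:
    """Per class x polarization x date mean backscatter (dB).

    Winter wheat follows a rising-then-dipping VH trajectory across the
    growing season (canopy growth, then senescence); the other classes are
    temporally flat.  The temporal means put the class SAR_add values at
    roughly water -48, wheat -35, other vegetation -30, building -22 dB,
    i.e. >= 5 dB gaps between the classes the SAR branch must separate.
    """
    wheat_traj = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 2.0, 1.0, 0.0, -3.0])
    if n_dates != 9:
        wheat_traj = np.interp(
            np.linspace(0, 8, n_dates), np.arange(9), wheat_traj
        )
        wheat_traj -= wheat_traj.mean()

    def flat(v: float) -> np.ndarray:
        return np.full(n_dates, v)

    return {
        "winter_wheat": {"VH": -21.0 + wheat_traj, "VV": -14.0 + 0.5 * wheat_traj},
        "other_vegetation": {"VH": flat(-17.0), "VV": flat(-13.0)},
        "building": {"VH": flat(-12.0), "VV": flat(-10.0)},
        "water": {"VH": flat(-30.0), "VV": flat(-18.0)},
    }


def default_optics() -> dict[str, dict[str, float]]:
    """Class-conditional red/NIR reflectance (mean, std), tuned so the
    class NDVI means are approximately wheat 0.25, other vegetation 0.65,
    building 0.10, water -0.30."""
    return {
        "winter_wheat": {
            "red_mean": 0.12, "red_std": 0.010, "nir_mean": 0.20, "nir_std": 0.015,
        },
        "other_vegetation": {
            "red_mean": 0.05, "red_std": 0.008, "nir_mean": 0.2357, "nir_std": 0.015,
        },
        "building": {
            "red_mean": 0.18, "red_std": 0.015, "nir_mean": 0.22, "nir_std": 0.015,
        },
        "water": {
            "red_mean": 0.065, "red_std": 0.006, "nir_mean": 0.035, "nir_std": 0.005,
        },
    }


@dataclass
class SceneConfig:
    """Everything needed to generate one synthetic scene."""

    grid: GridMeta = field(
        default_factory=lambda: GridMeta(
            n_rows=128,
            n_cols=128,
            pixel_size=10.0,
            origin=(500_000.0, 4_080_000.0),
            crs_id="EPSG:32650",
        )
    )
    seed: int = 0
    n_dates: int = 9
    enl: float = 4.0
    calib_A: float = 1000.0
    speckle: bool = True  # False = ENL -> infinity limit (noise off)
    # landscape geometry
    min_patch: int = 6
    max_patch: int = 24
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "winter_wheat": 0.5,
            "other_vegetation": 0.2,
            "building": 0.2,
            "water": 0.1,
        }
    )
    radiometry: dict[str, dict[str, np.ndarray]] | None = None
    optics: dict[str, dict[str, float]] | None = None
    # optional integer mis-registration (drow, dcol) applied per date index
    shifts: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.enl <= 0:
            raise ValueError("enl must be positive")
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("mixture proportions must sum to 1")
        if self.radiometry is None:
            self.radiometry = default_radiometry(self.n_dates)
        if self.optics is None:
            self.optics = default_optics()
        for cls, bands in self.optics.items():
            if bands["red_mean"] < 0 or bands["nir_mean"] < 0:
                raise ValueError(f"negative configured reflectance mean for {cls}")

    @property
    def dates(self) -> list[Date]:
        from datetime import timedelta

        if self.n_dates <= 9:
            return SAR_DATES[: self.n_dates]
        # extend the 12-day repeat cycle beyond the nine standard dates
        extra = [
            SAR_DATES[-1] + timedelta(days=12 * (i + 1))
            for i in range(self.n_dates - 9)
        ]
        return SAR_DATES + extra


@dataclass
class SyntheticScene:
    truth: ClassMap
    sar_scenes: list[SARScene]
    optical: OpticalScene
    samples: SampleSet
    config: SceneConfig


def generate_landscape(config: SceneConfig) -> ClassMap:
    """Rectangular-field mosaic by recursive random splits.

    Each axis-aligned block is split along its longer side until no side
    exceeds ``max_patch``; splits keep both halves at least ``min_patch``
    wide.  Leaves are assigned classes by the mixture proportions.
    Deterministic given ``config.seed``.
    """
    grid = config.grid
    if config.min_patch > min(grid.n_rows, grid.n_cols):
        raise ValueError("min_patch larger than the grid")
    rng = np.random.default_rng(config.seed)
    labels = list(config.proportions)
    probs = np.array([config.proportions[c] for c in labels])
    codes = np.array([CLASS_CODES[c] for c in labels], dtype=np.uint8)
    out = np.zeros(grid.shape, dtype=np.uint8)

    stack = [(0, grid.n_rows, 0, grid.n_cols)]
    while stack:
        r0, r1, c0, c1 = stack.pop()
        h, w = r1 - r0, c1 - c0
        if max(h, w) <= config.max_patch or max(h, w) < 2 * config.min_patch:
            out[r0:r1, c0:c1] = codes[rng.choice(len(codes), p=probs)]
            continue
        if h >= w:
            cut = int(rng.integers(r0 + config.min_patch, r1 - config.min_patch + 1))
            stack.append((r0, cut, c0, c1))
            stack.append((cut, r1, c0, c1))
        else:
            cut = int(rng.integers(c0 + config.min_patch, c1 - config.min_patch + 1))
            stack.append((r0, r1, c0, cut))
            stack.append((r0, r1, cut, c1))

    meta = replace(grid, nodata_value=CLASS_NODATA)
    return ClassMap(Raster(meta, out, units="class-code"), dict(CLASS_LEGEND))


def render_sar(truth: ClassMap, config: SceneConfig) -> list[SARScene]:
    """Render the dual-polarization DN time series from the truth map.

    Per pixel, linear backscatter sigma = 10^(mu/10) for the pixel's class
    mean mu (dB); intensity I = sigma * G with G ~ Gamma(shape=ENL,
    mean=1) when speckle is on, I = sigma otherwise; DN = A * sqrt(I).
    Configured mis-registration shifts are applied after rendering.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = truth.raster.meta
    codes = truth.raster.values
    scenes: list[SARScene] = []
    dates = config.dates
    for d in range(config.n_dates):
        for pol in ("VH", "VV"):
            mu = np.zeros(grid.shape)
            for cls in CLASS_LABELS:
                if cls not in config.radiometry:
                    raise ValueError(f"missing radiometry for class {cls}")
                if pol not in config.radiometry[cls]:
                    raise ValueError(f"missing radiometry for {cls}/{pol}")
                mu[codes == CLASS_CODES[cls]] = config.radiometry[cls][pol][d]
            sigma_lin = 10.0 ** (mu / 10.0)
            if config.speckle:
                g = rng.gamma(shape=config.enl, scale=1.0 / config.enl, size=grid.shape)
                intensity = sigma_lin * g
            else:
                intensity = sigma_lin
            dn = config.calib_A * np.sqrt(intensity)
            meta = replace(grid, nodata_value=-9999.0)
            raster = Raster(meta, dn, units="DN")
            if d in config.shifts:
                raster = apply_shift(raster, config.shifts[d])
            scenes.append(
                SARScene(
                    raster=raster,
                    polarization=pol,
                    date=dates[d],
                    phenology_label=PHENOLOGY_LABELS[d % 9],
                    calib_A=config.calib_A,
                )
            )
    return scenes


def render_optical(truth: ClassMap, config: SceneConfig) -> OpticalScene:
    """Render the maturity-date red/NIR bands: per-pixel Gaussian
    reflectance around the class mean, truncated at zero."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = truth.raster.meta
    codes = truth.raster.values
    red = np.zeros(grid.shape)
    nir = np.zeros(grid.shape)
    for cls in CLASS_LABELS:
        o = config.optics[cls]
        m = codes == CLASS_CODES[cls]
        n = int(m.sum())
        if n == 0:
            continue
        red[m] = np.maximum(0.0, rng.normal(o["red_mean"], o["red_std"], n))
        nir[m] = np.maximum(0.0, rng.normal(o["nir_mean"], o["nir_std"], n))
    meta = replace(grid, nodata_value=-9999.0)
    return OpticalScene(
        red=Raster(meta, red, units="reflectance"),
        nir=Raster(meta, nir, units="reflectance"),
        date=OPTICAL_DATE,
    )


def draw_samples(
    truth: ClassMap,
    per_class_counts: dict[str, int] | None = None,
    roi_size: int = 3,
    seed: int = 0,
) -> SampleSet:
    """Place square single-class ROIs on the truth map, stratified by class.

    Default counts (wheat 60, other vegetation 30, building 60, water 30)
    are sized so a 70/30 stratified split yields 126 training and 54
    validation ROIs.  ROIs never overlap and are entirely inside one class.
    """
    if per_class_counts is None:
        per_class_counts = {
            "winter_wheat": 60,
            "other_vegetation": 30,
            "building": 60,
            "water": 30,
        }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    codes = truth.raster.values
    occupied = np.zeros(codes.shape, dtype=bool)
    regions: list[SampleRegion] = []
    for cls in CLASS_LABELS:
        want = per_class_counts.get(cls, 0)
        if want == 0:
            continue
        pure = ndimage.minimum_filter(
            (codes == CLASS_CODES[cls]).astype(np.uint8),
            size=roi_size,
            mode="constant",
            cval=0,
        ).astype(bool)
        # minimum_filter window is centred; valid centres need the full
        # square inside the grid
        half = roi_size // 2
        candidates = np.argwhere(pure)
        candidates = candidates[
            (candidates[:, 0] >= half)
            & (candidates[:, 1] >= half)
            & (candidates[:, 0] < codes.shape[0] - half)
            & (candidates[:, 1] < codes.shape[1] - half)
        ]
        rng.shuffle(candidates)
        placed = 0
        for cr, cc in candidates:
            sl = (
                slice(cr - half, cr - half + roi_size),
                slice(cc - half, cc - half + roi_size),
            )
            if occupied[sl].any():
                continue
            occupied[sl] = True
            rr, ccols = np.mgrid[sl]
            regions.append(
                SampleRegion(
                    region_id=f"{cls}_{placed:03d}",
                    class_label=cls,
                    pixels=np.stack([rr.ravel(), ccols.ravel()], axis=1),
                )
            )
            placed += 1
            if placed == want:
                break
        if placed < want:
            raise ValueError(
                f"insufficient pure area for class {cls}: "
                f"placed {placed}/{want} ROIs"
            )
    return SampleSet(regions)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate the full labelled scene: truth, SAR time series, optical
    bands and stratified sample ROIs."""
    truth = generate_landscape(config)
    return SyntheticScene(
        truth=truth,
        sar_scenes=render_sar(truth, config),
        optical=render_optical(truth, config),
        samples=draw_samples(truth, seed=config.seed),
        config=config,
    )
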