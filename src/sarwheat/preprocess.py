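"""SAR preprocessing: coregistration, speckle filtering, calibration, and
temporal mean compositing.

The chain mirrors standard GRD handling of a dual-polarization C-band time
series: scenes are first registered to a common grid by integer-pixel
normalized cross-correlation, speckle is suppressed with a refined Lee
filter operating on linear intensity, digital numbers are calibrated to
backscattering coefficient in dB via ``sigma0 = DN^2 / A^2``, and the
per-polarization time series is averaged in the dB domain to obtain the
mean backscatter feature images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Sequence

import numpy as np
from scipy import ndimage

from .raster import GridMeta, Raster

__all__ = [
    "SARScene",
    "BackscatterStack",
    "coregister_shift",
    "apply_shift",
    "refined_lee",
    "calibrate",
    "temporal_mean",
]


@dataclass
class SARScene:
    """One acquisition date x one polarization of uncalibrated DN values.

    ``calib_A`` is the scalar radiometric calibration parameter relating
    digital numbers to the linear backscatter power ratio DN^2 / A^2.
    ``phenology_label`` tags the crop growth stage (A-I for the nine dates
    from regreening to maturity).
    """

    raster: Raster
    polarization: str
    date: Date
    phenology_label: str = ""
    calib_A: float = 1000.0

    def __post_init__(self) -> None:
        if self.polarization not in ("VH", "VV"):
            raise ValueError(f"polarization must be VH or VV, got {self.polarization}")
        if self.calib_A <= 0:
            raise ValueError("calibration parameter A must be positive")
        vals = self.raster.values[self.raster.valid_mask]
        if vals.size and vals.min() < 0:
            raise ValueError("DN values must be non-negative")


@dataclass
class BackscatterStack:
    """Date-ordered calibrated (dB) rasters for one polarization."""

    polarization: str
    dates: list[Date]
    scenes: list[Raster] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.scenes):
            raise ValueError("dates and scenes length mismatch")
        for a, b in zip(self.dates, self.dates[1:]):
            if not a < b:
                raise ValueError("dates must be strictly increasing")
        for r in self.scenes[1:]:
            if not self.scenes[0].meta.aligned_with(r.meta):
                raise ValueError("stack rasters are not aligned")


def coregister_shift(
    reference: Raster, moving: Raster, max_shift: int
) -> tuple[int, int]:
    """Integer-pixel registration by exhaustive normalized cross-correlation.

    Returns the ``(drow, dcol)`` within ``+-max_shift`` that, applied to the
    moving image with :func:`apply_shift`, maximizes the normalized
    cross-correlation with the reference over the overlapping valid pixels.
    Ties are broken by smallest Euclidean shift magnitude, then
    lexicographically.
    """
    if reference.values.shape != moving.values.shape:
        raise ValueError("reference and moving rasters must share one shape")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    ref = np.where(reference.valid_mask, reference.values, np.nan).astype(float)
    mov = np.where(moving.valid_mask, moving.values, np.nan).astype(float)
    for name, arr in (("reference", ref), ("moving", mov)):
        v = arr[np.isfinite(arr)]
        if v.size < 2 or np.nanstd(v) == 0:
            raise ValueError(f"degenerate correlation: {name} image has zero variance")

    n_rows, n_cols = ref.shape
    best: tuple[float, float, tuple[int, int]] | None = None
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            # overlap of reference with moving translated by (dr, dc)
            r0, r1 = max(0, dr), min(n_rows, n_rows + dr)
            c0, c1 = max(0, dc), min(n_cols, n_cols + dc)
            if r0 >= r1 or c0 >= c1:
                continue
            a = ref[r0:r1, c0:c1]
            b = mov[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2:
                continue
            av, bv = a[ok], b[ok]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue
            ncc = float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
            key = (-ncc, float(dr * dr + dc * dc), (dr, dc))
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("degenerate correlation: no valid overlap")
    return best[2]


def apply_shift(raster: Raster, shift: tuple[int, int]) -> Raster:
    """Translate values by integer ``(drow, dcol)``; exposed margins become
    nodata.  Positive drow moves content southwards, positive dcol eastwards."""
    dr, dc = int(shift[0]), int(shift[1])
    n_rows, n_cols = raster.values.shape
    if abs(dr) > n_rows or abs(dc) > n_cols:
        raise ValueError("shift exceeds raster dimensions")
    out = np.full_like(raster.values, raster.meta.nodata_value)
    r0, r1 = max(0, dr), min(n_rows, n_rows + dr)
    c0, c1 = max(0, dc), min(n_cols, n_cols + dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = raster.values[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return raster.with_values(out)


def _masked_window_stats(
    values: np.ndarray, valid: np.ndarray, kernel: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed mean/variance over valid pixels only, for one boolean kernel."""
    k = kernel.astype(float)
    v0 = np.where(valid, values, 0.0)
    cnt = ndimage.correlate(valid.astype(float), k, mode="constant", cval=0.0)
    s1 = ndimage.correlate(v0, k, mode="constant", cval=0.0)
    s2 = ndimage.correlate(v0 * v0, k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean * mean, 0.0)
    return mean, var, cnt


def _directional_kernels(window: int) -> np.ndarray:
    """The 8 edge-aligned half-window kernels (E, W, S, N, SE, NW, SW, NE);
    each includes the centre pixel."""
    c = window // 2
    r, j = np.mgrid[0:window, 0:window]
    return np.stack(
        [
            j >= c,          # 0: east half
            j <= c,          # 1: west half
            r >= c,          # 2: south half
            r <= c,          # 3: north half
            r + j >= 2 * c,  # 4: south-east half (below the anti-diagonal)
            r + j <= 2 * c,  # 5: north-west half
            r - j >= 0,      # 6: south-west half (below the main diagonal)
            r - j <= 0,      # 7: north-east half
        ]
    )


def refined_lee(
    intensity: Raster, window: int = 7, enl: float = 4.0, edge_k: float = 2.5
) -> Raster:
    """Refined Lee speckle filter on a linear-intensity raster.

    Per pixel, the minimum-mean-square-error estimate

        x_hat = y_bar + b * (y - y_bar),   b = clip(var_x / var_y, 0, 1)

    is computed inside an edge-aligned directional half-window wherever the
    3x3 grid of local sub-window means indicates an edge, and inside the
    full window otherwise.  The direction (one of eight) is selected from
    the sub-mean gradients so that statistics are taken on the same side of
    an edge as the centre pixel; this is what preserves structure relative
    to a plain boxcar.  A pixel counts as lying on an edge when the largest
    sub-mean gradient exceeds ``edge_k`` times the gradient level expected
    from speckle alone (std of the difference of two sub-means,
    ``|m| * sqrt(2 / (enl * n_sub))``).  ``var_x`` uses the multiplicative
    speckle model with coefficient of variation ``sigma_v^2 = 1/enl``.

    Nodata pixels are excluded from all local statistics and preserved.
    """
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    if enl <= 0:
        raise ValueError("enl must be positive")
    values = intensity.values.astype(float)
    valid = intensity.valid_mask

    # 3x3 grid of sub-window means at offsets +-o around each pixel
    sub = max(3, (window // 3) | 1)
    off = (window - sub) // 2 if window > sub else 1
    k_sub = np.ones((sub, sub), dtype=bool)
    m_sub, _, _ = _masked_window_stats(values, valid, k_sub)
    m_sub = np.where(np.isfinite(m_sub), m_sub, 0.0)

    def shifted(di: int, dj: int) -> np.ndarray:
        # sub-window mean at offset (di*off, dj*off), edge-replicated
        p = np.pad(m_sub, off, mode="edge")
        r0 = off + di * off
        c0 = off + dj * off
        return p[r0 : r0 + m_sub.shape[0], c0 : c0 + m_sub.shape[1]]

    m = {(a, b): shifted(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)}
    g_h = np.abs(m[(0, -1)] - m[(0, 1)])    # west-east gradient
    g_v = np.abs(m[(-1, 0)] - m[(1, 0)])    # north-south
    g_d1 = np.abs(m[(-1, -1)] - m[(1, 1)])  # NW-SE
    g_d2 = np.abs(m[(-1, 1)] - m[(1, -1)])  # NE-SW
    grads = np.stack([g_h, g_v, g_d1, g_d2])
    axis = np.argmax(grads, axis=0)

    center = m[(0, 0)]
    # edge present only where the max gradient exceeds the speckle level
    speckle_level = np.abs(center) * np.sqrt(2.0 / (enl * sub * sub))
    on_edge = grads.max(axis=0) > edge_k * speckle_level
    # per axis, pick the side whose sub-mean is closer to the centre mean
    side_pairs = {
        0: ((0, 1), (0, -1)),    # axis h: east kernel 0 vs west kernel 1
        1: ((1, 0), (-1, 0)),    # axis v: south kernel 2 vs north kernel 3
        2: ((1, 1), (-1, -1)),   # axis d1: SE kernel 4 vs NW kernel 5
        3: ((1, -1), (-1, 1)),   # axis d2: SW kernel 6 vs NE kernel 7
    }
    direction = np.zeros(values.shape, dtype=np.int8)
    for ax, (p_first, p_second) in side_pairs.items():
        pick_second = np.abs(m[p_second] - center) < np.abs(m[p_first] - center)
        direction = np.where(axis == ax, 2 * ax + pick_second, direction)
    direction = np.where(on_edge, direction, 8)  # 8 = full window

    kernels = list(_directional_kernels(window))
    kernels.append(np.ones((window, window), dtype=bool))
    means = np.empty((9,) + values.shape)
    varis = np.empty((9,) + values.shape)
    counts = np.empty((9,) + values.shape)
    for d in range(9):
        means[d], varis[d], counts[d] = _masked_window_stats(values, valid, kernels[d])
    idx = direction[None, ...]
    y_bar = np.take_along_axis(means, idx, axis=0)[0]
    var_y = np.take_along_axis(varis, idx, axis=0)[0]
    cnt = np.take_along_axis(counts, idx, axis=0)[0]

    sigma_v2 = 1.0 / enl
    with np.errstate(invalid="ignore", divide="ignore"):
        var_x = (var_y - y_bar * y_bar * sigma_v2) / (1.0 + sigma_v2)
        b = np.clip(var_x / var_y, 0.0, 1.0)
    b = np.where(var_y > 0, b, 0.0)
    x_hat = y_bar + b * (values - y_bar)

    out = np.where(valid & (cnt > 0), x_hat, intensity.meta.nodata_value)
    return intensity.with_values(out)


def calibrate(scene: SARScene) -> Raster:
    """Radiometric calibration of DN to backscattering coefficient in dB.

    The linear power ratio is ``sigma0 = DN^2 / A^2``; the returned raster is
    ``10 * log10(sigma0) = 20 * log10(DN / A)``.  DN = 0 has no defined dB
    value and becomes nodata.
    """
    raster = scene.raster
    valid = raster.valid_mask
    dn = raster.values.astype(float)
    if dn[valid].size and dn[valid].min() < 0:
        raise ValueError("negative DN cannot be calibrated")
    ok = valid & (dn > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 20.0 * np.log10(dn / scene.calib_A)
    out = np.where(ok, db, raster.meta.nodata_value)
    return raster.with_values(out, units="dB")


def temporal_mean(stack: BackscatterStack) -> Raster:
    """Per-pixel arithmetic mean of the dB rasters across dates.

    A pixel is nodata only where it is nodata at every date; otherwise the
    mean is taken over the valid dates.
    """
    if not stack.scenes:
        raise ValueError("empty stack")
    first = stack.scenes[0]
    arr = np.stack(
        [np.where(r.valid_mask, r.values, np.nan) for r in stack.scenes]
    )
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-dates-nodata pixels produce an empty nanmean slice on purpose
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    out = np.where(np.isfinite(mean), mean, first.meta.nodata_value)
    return first.with_values(out, units="dB")
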