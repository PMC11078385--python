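"""Confusion-matrix accuracy assessment and area estimation.

Accuracy is computed per validation pixel: every pixel of every validation
ROI is tallied into a (reference class x predicted class) confusion matrix,
from which overall accuracy, Cohen's kappa, and per-class producer's and
user's accuracies are derived:

    OA    = trace / n
    kappa = (p0 - pe) / (1 - pe),  p0 = trace/n,  pe = sum_i a_i b_i / n^2
    PA_c  = diagonal_c / row-sum_c      (recall: omission errors)
    UA_c  = diagonal_c / column-sum_c   (precision: commission errors)

with a_i, b_i the row and column sums.  The mapped area of a class is its
pixel count times the pixel area, reported in km^2 with the relative error
against an external reference area (e.g. a statistical-yearbook figure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtree import ClassMap
from .samples import CLASS_LABELS, SampleSet

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion",
    "overall_accuracy",
    "kappa",
    "producer_user_accuracy",
    "area_and_error",
    "build_report",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are reference classes, columns predictions."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS
    n_unclassified: int = 0  # validation pixels falling on nodata predictions

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion(class_map: ClassMap, validation: SampleSet) -> ConfusionMatrix:
    """Tally every validation pixel into (reference, predicted).

    Pixels whose prediction is nodata are counted separately in
    ``n_unclassified`` rather than entering the matrix.
    """
    if len(validation) == 0:
        raise ValueError("empty validation set")
    label_to_idx = {c: i for i, c in enumerate(CLASS_LABELS)}
    code_to_label = {k: v for k, v in class_map.legend.items()}
    values = class_map.raster.values
    nodata = class_map.raster.meta.nodata_value
    n_rows, n_cols = values.shape
    counts = np.zeros((len(CLASS_LABELS), len(CLASS_LABELS)), dtype=np.int64)
    n_unclassified = 0
    for region in validation.regions:
        pix = region.pixels
        if (pix[:, 0].min() < 0 or pix[:, 1].min() < 0
                or pix[:, 0].max() >= n_rows or pix[:, 1].max() >= n_cols):
            raise ValueError(
                f"validation region {region.region_id} lies outside the map"
            )
        pred = values[pix[:, 0], pix[:, 1]]
        ref_i = label_to_idx[region.class_label]
        for code, cnt in zip(*np.unique(pred, return_counts=True)):
            if code == nodata:
                n_unclassified += int(cnt)
                continue
            counts[ref_i, label_to_idx[code_to_label[int(code)]]] += int(cnt)
    return ConfusionMatrix(counts, CLASS_LABELS, n_unclassified)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified validation pixels (trace / n)."""
    return float(np.trace(cm.counts) / cm.n)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement."""
    n = cm.n
    p0 = np.trace(cm.counts) / n
    a = cm.counts.sum(axis=1)
    b = cm.counts.sum(axis=0)
    pe = float((a * b).sum()) / (n * n)
    if pe >= 1.0:
        raise ValueError("degenerate single-class table: chance agreement is 1")
    return float((p0 - pe) / (1.0 - pe))


def producer_user_accuracy(
    cm: ConfusionMatrix, class_label: str
) -> tuple[float, float]:
    """(PA, UA) for one class; an undefined component (class absent from the
    reference / the predictions) is returned as NaN."""
    i = cm.labels.index(class_label)
    row = cm.counts[i].sum()
    col = cm.counts[:, i].sum()
    diag = cm.counts[i, i]
    pa = diag / row if row > 0 else math.nan
    ua = diag / col if col > 0 else math.nan
    return float(pa), float(ua)


def area_and_error(
    class_map: ClassMap, class_label: str, reference_area_km2: float
) -> tuple[float, float]:
    """Mapped area of a class in km^2 and its relative error (%) against a
    reference area."""
    if reference_area_km2 <= 0:
        raise ValueError("reference area must be positive")
    if class_label not in class_map.legend.values():
        raise ValueError(f"unknown class: {class_label}")
    px = class_map.pixel_count(class_label)
    ps = class_map.raster.meta.pixel_size  # metres
    area_km2 = px * ps * ps / 1e6
    rel_err = abs(area_km2 - reference_area_km2) / reference_area_km2 * 100.0
    return float(area_km2), float(rel_err)


@dataclass
class AccuracyReport:
    """Full assessment: confusion matrix, OA, kappa, per-class PA/UA, and
    (optionally) mapped areas with relative error against a reference."""

    cm: ConfusionMatrix
    oa: float
    kappa: float
    pa: dict[str, float]
    ua: dict[str, float]
    area_km2: dict[str, float] = field(default_factory=dict)
    relative_error_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {
            c: {"PA": self.pa[c], "UA": self.ua[c]} for c in self.cm.labels
        }
        df = pd.DataFrame(rows).T
        df.loc["__overall__", "PA"] = self.oa
        df.loc["__overall__", "UA"] = self.kappa
        return df

    def render_text(self) -> str:
        lines = ["Confusion matrix (rows = reference, cols = predicted):"]
        lines.append(self.cm.to_frame().to_string())
        lines.append("")
        for c in self.cm.labels:
            lines.append(
                f"{c:>18s}  PA {100 * self.pa[c]:6.2f}%   UA {100 * self.ua[c]:6.2f}%"
            )
        lines.append(f"{'OA':>18s}  {100 * self.oa:6.2f}%")
        lines.append(f"{'Kappa':>18s}  {self.kappa:6.2f}")
        if "winter_wheat" in self.area_km2:
            lines.append(
                f"{'wheat area':>18s}  {self.area_km2['winter_wheat']:8.2f} km^2"
            )
        if self.relative_error_pct is not None:
            lines.append(f"{'relative error':>18s}  {self.relative_error_pct:6.2f}%")
        return "\n".join(lines)


def build_report(
    class_map: ClassMap,
    validation: SampleSet,
    reference_area_km2: float | None = None,
) -> AccuracyReport:
    """Assemble the standard accuracy report for a classified map."""
    cm = confusion(class_map, validation)
    pa, ua = {}, {}
    for c in cm.labels:
        pa[c], ua[c] = producer_user_accuracy(cm, c)
    areas: dict[str, float] = {}
    rel_err = None
    for c in cm.labels:
        px = class_map.pixel_count(c)
        ps = class_map.raster.meta.pixel_size
        areas[c] = px * ps * ps / 1e6
    if reference_area_km2 is not None:
        _, rel_err = area_and_error(class_map, "winter_wheat", reference_area_km2)
    return AccuracyReport(
        cm=cm,
        oa=overall_accuracy(cm),
        kappa=kappa(cm),
        pa=pa,
        ua=ua,
        area_km2=areas,
        relative_error_pct=rel_err,
    )
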