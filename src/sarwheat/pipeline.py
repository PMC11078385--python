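"""End-to-end orchestration of the wheat-extraction workflow.

The full chain is: preprocess the SAR time series (register, filter,
calibrate, temporal mean) -> assemble the feature stack (mean VH, mean VV,
SAR_add, NDVI) -> stratified 70/30 sample split -> per-class statistics on
the training ROIs -> median-rule thresholds -> decision-tree map ->
accuracy assessment on the validation ROIs.

A run is a pure function of (inputs, configuration); artefacts are written
with a provenance JSON carrying the configuration hash and seed so a map
can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import AccuracyReport, build_report
from .dtree import ClassMap, ThresholdSet, classify_map, derive_thresholds
from .features import FeatureStack, OpticalScene, build_feature_stack
from .preprocess import (
    BackscatterStack,
    SARScene,
    apply_shift,
    calibrate,
    coregister_shift,
    refined_lee,
    temporal_mean,
)
from .raster import write_raster
from .samples import CLASS_LABELS, SampleSet, class_stats, split_samples

log = logging.getLogger("sarwheat")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "preprocess_scenes",
    "run_pipeline",
    "compare_reports",
]


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run.

    Exactly one of ``scene_dir`` (a manifest-addressed scene on disk) or
    ``synthetic`` (a generator configuration) must be provided.
    """

    scene_dir: str | None = None
    synthetic: object | None = None  # a synth.SceneConfig
    out_dir: str | None = None
    window: int = 7
    enl: float = 4.0
    max_shift: int = 0  # 0 disables coregistration
    train_fraction: float = 0.7
    seed: int = 0
    reference_area_km2: float | None = None

    def validate(self) -> None:
        if (self.scene_dir is None) == (self.synthetic is None):
            raise ValueError(
                "config must set exactly one of scene_dir or synthetic"
            )
        if self.window % 2 == 0 or self.window < 5:
            raise ValueError("window must be odd and >= 5")
        if self.enl <= 0:
            raise ValueError("enl must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.reference_area_km2 is not None and self.reference_area_km2 <= 0:
            raise ValueError("reference_area_km2 must be positive")

    def digest(self) -> str:
        # fingerprint of the scientific configuration only: where the
        # artefacts land must not change what they contain
        doc = asdict(self)
        doc.pop("out_dir", None)
        if self.synthetic is not None:
            sdoc = asdict(self.synthetic)
            sdoc["grid"] = asdict(self.synthetic.grid)
            doc["synthetic"] = sdoc
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    report: AccuracyReport
    class_map: ClassMap
    thresholds: ThresholdSet
    stack: FeatureStack
    train: SampleSet
    validation: SampleSet
    stats: object
    provenance: dict = field(default_factory=dict)


def preprocess_scenes(
    scenes: Sequence[SARScene],
    window: int = 7,
    enl: float = 4.0,
    max_shift: int = 0,
) -> tuple[BackscatterStack, BackscatterStack]:
    """Run the SAR preprocessing chain and return (VH, VV) dB stacks.

    Order: optional integer-pixel registration of every scene to the first
    VH acquisition, refined Lee filtering on linear intensity (DN^2),
    radiometric calibration to dB.  Filtering before calibration and
    dividing by A^2 afterwards commutes, since A is a per-scene scalar.
    """
    by_pol: dict[str, list[SARScene]] = {"VH": [], "VV": []}
    for s in scenes:
        by_pol[s.polarization].append(s)
    for pol in by_pol:
        by_pol[pol].sort(key=lambda s: s.date)
    if not by_pol["VH"] or not by_pol["VV"]:
        raise ValueError("need scenes in both VH and VV polarizations")
    reference = by_pol["VH"][0].raster

    stacks = {}
    for pol, pol_scenes in by_pol.items():
        rasters = []
        for s in pol_scenes:
            raster = s.raster
            if max_shift > 0 and raster is not reference:
                shift = coregister_shift(reference, raster, max_shift)
                if shift != (0, 0):
                    log.info("registering %s %s: shift %s", pol, s.date, shift)
                raster = apply_shift(raster, shift)
            # speckle filtering on linear intensity DN^2
            valid = raster.valid_mask
            intensity = raster.with_values(
                np.where(valid, raster.values.astype(float) ** 2,
                         raster.meta.nodata_value)
            )
            filtered = refined_lee(intensity, window=window, enl=enl)
            fvalid = filtered.valid_mask
            dn_f = raster.with_values(
                np.where(fvalid, np.sqrt(np.maximum(filtered.values, 0.0)),
                         raster.meta.nodata_value),
                units="DN",
            )
            db = calibrate(
                SARScene(dn_f, s.polarization, s.date, s.phenology_label, s.calib_A)
            )
            rasters.append(db)
        stacks[pol] = BackscatterStack(
            polarization=pol,
            dates=[s.date for s in pol_scenes],
            scenes=rasters,
        )
    return stacks["VH"], stacks["VV"]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full extraction workflow and (optionally) persist every
    artefact under ``config.out_dir``."""
    config.validate()
    if config.synthetic is not None:
        from .synth import generate_scene

        scene = generate_scene(config.synthetic)
        sar_scenes, optical = scene.sar_scenes, scene.optical
        samples = scene.samples
    else:
        from .scene_io import load_scene

        sar_scenes, optical, _truth, samples = load_scene(config.scene_dir)
        if samples is None:
            raise ValueError(f"scene {config.scene_dir} has no sample regions")

    log.info("preprocessing %d SAR scenes", len(sar_scenes))
    vh, vv = preprocess_scenes(
        sar_scenes, window=config.window, enl=config.enl, max_shift=config.max_shift
    )
    stack = build_feature_stack(vh, vv, optical)

    train, validation = split_samples(samples, config.train_fraction, config.seed)
    log.info(
        "split %d regions into %d training / %d validation",
        len(samples), len(train), len(validation),
    )
    stats = class_stats(stack, train)
    thresholds = derive_thresholds(stats)
    log.info(
        "thresholds: t_ndvi=%.4f t_water=%.2f t_building=%.2f",
        thresholds.t_ndvi, thresholds.t_water, thresholds.t_building,
    )
    cmap = classify_map(stack, thresholds)
    report = build_report(cmap, validation, config.reference_area_km2)

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_train_regions": len(train),
        "n_validation_regions": len(validation),
        "thresholds": asdict(thresholds),
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        thresholds.to_yaml(
            os.path.join(config.out_dir, "thresholds.yaml"),
            provenance={"config_hash": provenance["config_hash"],
                        "seed": config.seed},
        )
        write_raster(cmap.raster, os.path.join(config.out_dir, "map.tif"))
        stats.to_csv(os.path.join(config.out_dir, "class_stats.csv"))
        report.cm.to_frame().to_csv(
            os.path.join(config.out_dir, "confusion_matrix.csv")
        )
        report.to_frame().to_csv(os.path.join(config.out_dir, "accuracy.csv"))
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(report.render_text() + "\n")
        with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
    return PipelineResult(
        report=report,
        class_map=cmap,
        thresholds=thresholds,
        stack=stack,
        train=train,
        validation=validation,
        stats=stats,
        provenance=provenance,
    )


def _as_metrics(report) -> dict:
    """Coerce an AccuracyReport or a plain mapping into a metrics dict with
    keys oa, kappa, pa, ua (oa/pa/ua on the proportion scale)."""
    if isinstance(report, AccuracyReport):
        return {
            "oa": report.oa,
            "kappa": report.kappa,
            "pa": dict(report.pa),
            "ua": dict(report.ua),
        }
    if isinstance(report, Mapping):
        return {
            "oa": report.get("oa"),
            "kappa": report.get("kappa"),
            "pa": dict(report.get("pa", {})),
            "ua": dict(report.get("ua", {})),
        }
    raise TypeError("reports must be AccuracyReport objects or mappings")


def compare_reports(reports: Sequence) -> pd.DataFrame:
    """Differences of the first report against each of the others.

    Accuracy-type metrics (OA, PA, UA) are differenced in percentage
    points; kappa as a plain difference.  All reports must describe the
    same class set.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    metrics = [_as_metrics(r) for r in reports]
    base = metrics[0]
    base_classes = set(base["pa"]) | set(base["ua"])
    rows = []
    for i, other in enumerate(metrics[1:], start=1):
        classes = set(other["pa"]) | set(other["ua"])
        if base_classes and classes and base_classes != classes:
            raise ValueError("mismatched class sets between reports")
        row: dict[str, float] = {"vs": i}
        if base["oa"] is not None and other["oa"] is not None:
            row["delta_oa_pct_points"] = 100.0 * (base["oa"] - other["oa"])
        if base["kappa"] is not None and other["kappa"] is not None:
            row["delta_kappa"] = base["kappa"] - other["kappa"]
        for c in sorted(base["pa"]):
            if c in other["pa"]:
                row[f"delta_pa_{c}_pct_points"] = 100.0 * (
                    base["pa"][c] - other["pa"][c]
                )
        for c in sorted(base["ua"]):
            if c in other["ua"]:
                row[f"delta_ua_{c}_pct_points"] = 100.0 * (
                    base["ua"][c] - other["ua"][c]
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("vs")
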