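"""Manifest-addressed persistence of a full scene on disk.

A scene directory contains the SAR DN GeoTIFFs, the optical red/NIR bands,
an optional truth class map, a samples GeoJSON, and a ``manifest.yaml``
tying them together (path, polarization, date, growth-stage label and
calibration constant per SAR scene).
"""

from __future__ import annotations

import os
from datetime import date as Date

import yaml

from .dtree import ClassMap
from .features import OpticalScene
from .preprocess import SARScene
from .raster import CLASS_LEGEND, Raster, read_raster, write_raster
from .samples import SampleSet, read_sample_geojson, write_sample_geojson

__all__ = [
    "write_scene",
    "load_scene",
    "load_manifest",
    "write_feature_stack",
    "read_feature_stack",
]


_STACK_FILES = {
    "sigma_vh_mean": "sigma_vh_mean.tif",
    "sigma_vv_mean": "sigma_vv_mean.tif",
    "sar_add": "sar_add.tif",
    "ndvi": "ndvi.tif",
}


def write_feature_stack(stack, out_dir: str) -> None:
    """Persist the four feature layers as single-band GeoTIFFs plus a JSON
    manifest."""
    import json

    os.makedirs(out_dir, exist_ok=True)
    for attr, fname in _STACK_FILES.items():
        write_raster(getattr(stack, attr), os.path.join(out_dir, fname))
    with open(os.path.join(out_dir, "stack.json"), "w") as fh:
        json.dump(_STACK_FILES, fh, indent=1)


def read_feature_stack(stack_dir: str):
    from .features import FeatureStack

    layers = {
        attr: read_raster(os.path.join(stack_dir, fname))
        for attr, fname in _STACK_FILES.items()
    }
    return FeatureStack(**layers)


def write_scene(scene, out_dir: str) -> str:
    """Write a synthetic (or assembled) scene to ``out_dir``; returns the
    manifest path."""
    os.makedirs(os.path.join(out_dir, "sar"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "optical"), exist_ok=True)
    entries = []
    for s in scene.sar_scenes:
        rel = f"sar/{s.date.isoformat()}_{s.polarization}.tif"
        write_raster(s.raster, os.path.join(out_dir, rel))
        entries.append(
            {
                "path": rel,
                "polarization": s.polarization,
                "date": s.date.isoformat(),
                "phenology_label": s.phenology_label,
                "calib_A": float(s.calib_A),
            }
        )
    write_raster(scene.optical.red, os.path.join(out_dir, "optical/red.tif"))
    write_raster(scene.optical.nir, os.path.join(out_dir, "optical/nir.tif"))
    manifest = {
        "sar_scenes": entries,
        "optical": {
            "red": "optical/red.tif",
            "nir": "optical/nir.tif",
            "date": scene.optical.date.isoformat(),
        },
    }
    if scene.truth is not None:
        write_raster(scene.truth.raster, os.path.join(out_dir, "truth.tif"))
        manifest["truth"] = "truth.tif"
    if scene.samples is not None and len(scene.samples):
        write_sample_geojson(
            scene.samples,
            scene.optical.red.meta,
            os.path.join(out_dir, "samples.geojson"),
        )
        manifest["samples"] = "samples.geojson"
    path = os.path.join(out_dir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_manifest(scene_dir: str) -> dict:
    with open(os.path.join(scene_dir, "manifest.yaml")) as fh:
        return yaml.safe_load(fh)


def load_scene(scene_dir: str):
    """Load a scene directory back into in-memory objects.

    Returns ``(sar_scenes, optical, truth_or_None, samples_or_None)``.
    """
    man = load_manifest(scene_dir)
    sar_scenes = []
    for e in man["sar_scenes"]:
        raster = read_raster(os.path.join(scene_dir, e["path"]))
        sar_scenes.append(
            SARScene(
                raster=raster,
                polarization=e["polarization"],
                date=Date.fromisoformat(e["date"]),
                phenology_label=e.get("phenology_label", ""),
                calib_A=float(e["calib_A"]),
            )
        )
    red = read_raster(os.path.join(scene_dir, man["optical"]["red"]))
    nir = read_raster(os.path.join(scene_dir, man["optical"]["nir"]))
    optical = OpticalScene(red, nir, Date.fromisoformat(man["optical"]["date"]))
    truth = None
    if "truth" in man:
        r = read_raster(os.path.join(scene_dir, man["truth"]))
        truth = ClassMap(r, dict(CLASS_LEGEND))
    samples = None
    if "samples" in man:
        samples = read_sample_geojson(
            os.path.join(scene_dir, man["samples"]), red.meta
        )
    return sar_scenes, optical, truth, samples
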