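"""Readers and writers: LabelMe JSON, COCO JSON, heatmap bundles, run config.

Formats
-------
- **LabelMe JSON** (read/write): one record per image; an instance is either
  four point shapes labeled ``top``/``left``/``bottom``/``right`` sharing a
  ``group_id``, or a single polygon shape from which the extreme points are
  derived.
- **COCO instances / results JSON** (read/write): standard ``bbox`` mode
  ``[x, y, w, h]``; conversion to corner boxes is ``x_max = x + w``.
- **Heatmap bundle** (read/write): a NumPy ``.npz`` holding one named array
  per map plus a JSON sidecar recording H, W, s, σ, seed and class names, so
  the decoder never guesses geometry.  Round-trips bit-exactly.
- **Run config** (read/write): a single YAML file; unknown keys are
  rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .decoding import Detection, GroupingConfig
from .errors import ValidationError
from .evaluation import DetBox, GtBox
from .keypoints import ExtremeSet
from .synthetic.render import HeatmapBundle
from .synthetic.scenes import Scene
from .synthetic.shapes import extreme_points

logger = logging.getLogger(__name__)

DIRECTION_LABELS = ("top", "left", "bottom", "right")


# ---------------------------------------------------------------- LabelMe

@dataclass(frozen=True)
class AnnotatedInstance:
    label: str
    extremes: ExtremeSet
    polygon: np.ndarray | None = None


def write_labelme(scene: Scene, image_path: str, out_path) -> None:
    """Write a scene as LabelMe-style JSON: per instance one polygon shape
    plus four direction-labeled points sharing a group id."""
    shapes = []
    for gid, inst in enumerate(scene.instances):
        shapes.append(
            {
                "label": inst.label,
                "group_id": gid,
                "shape_type": "polygon",
                "points": np.asarray(inst.polygon, dtype=float).tolist(),
            }
        )
        for direction in DIRECTION_LABELS:
            x, y = getattr(inst.extremes, direction)
            shapes.append(
                {
                    "label": direction,
                    "group_id": gid,
                    "shape_type": "point",
                    "points": [[float(x), float(y)]],
                }
            )
    record = {
        "version": "5.0.1",
        "imagePath": image_path,
        "imageHeight": scene.height,
        "imageWidth": scene.width,
        "shapes": shapes,
    }
    _atomic_write_json(out_path, record)


def read_labelme(path) -> list[AnnotatedInstance]:
    """Read one LabelMe JSON file into annotated instances.

    Point shapes labeled by direction are grouped by ``group_id``; groups
    with a polygon but missing direction points fall back to deriving
    extremes from the polygon; groups with neither are skipped with a
    warning.  A class label is taken from the group's non-direction label
    (default ``"cell"``).
    """
    with open(path) as fh:
        record = json.load(fh)

    groups: dict = {}
    for shape in record.get("shapes", []):
        gid = shape.get("group_id")
        groups.setdefault(gid, []).append(shape)

    out: list[AnnotatedInstance] = []
    for gid, shapes in groups.items():
        points = {
            s["label"]: tuple(map(float, s["points"][0]))
            for s in shapes
            if s["label"] in DIRECTION_LABELS and s.get("shape_type") == "point"
        }
        polygons = [s for s in shapes if s.get("shape_type") == "polygon"]
        label = next(
            (s["label"] for s in shapes if s["label"] not in DIRECTION_LABELS), "cell"
        )
        polygon = np.asarray(polygons[0]["points"], dtype=float) if polygons else None
        if len(points) == 4:
            es = ExtremeSet(
                top=points["top"],
                left=points["left"],
                bottom=points["bottom"],
                right=points["right"],
            )
        elif polygon is not None:
            es = extreme_points(polygon)
        else:
            logger.warning("group %r lacks direction points and polygon; skipped", gid)
            continue
        out.append(AnnotatedInstance(label=label, extremes=es, polygon=polygon))
    return out


# ------------------------------------------------------------------- COCO

def write_coco_gt(scenes: list[Scene], out_path) -> None:
    """Write ground truth for a list of scenes as COCO instances JSON.

    Image ids are the scene indices; category ids are assigned in sorted
    label order starting at 1.
    """
    labels = sorted({inst.label for sc in scenes for inst in sc.instances})
    cat_id = {lab: i + 1 for i, lab in enumerate(labels)}
    images, annotations = [], []
    ann_id = 1
    for img_id, sc in enumerate(scenes):
        images.append({"id": img_id, "width": sc.width, "height": sc.height,
                       "file_name": f"scene_{img_id:04d}.png"})
        for inst in sc.instances:
            x0, y0, x1, y1 = inst.extremes.box()
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[inst.label],
                    "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                    "area": float((x1 - x0) * (y1 - y0)),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": cid, "name": lab} for lab, cid in cat_id.items()],
    }
    _atomic_write_json(out_path, doc)


def read_coco_gt(path) -> list[GtBox]:
    with open(path) as fh:
        doc = json.load(fh)
    names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    out = []
    for ann in doc.get("annotations", []):
        x, y, w, h = _check_bbox(ann["bbox"], where=f"annotation {ann.get('id')}")
        out.append(
            GtBox(
                image_id=int(ann["image_id"]),
                label=names.get(ann["category_id"], str(ann["category_id"])),
                box=(x, y, x + w, y + h),
            )
        )
    return out


def write_coco_detections(dets: list[Detection], image_id: int, cat_id: dict, out_path) -> None:
    """Write decoder detections for one image as COCO results JSON."""
    results = detections_to_coco(dets, image_id, cat_id)
    _atomic_write_json(out_path, results)


def detections_to_coco(dets: list[Detection], image_id: int, cat_id: dict) -> list[dict]:
    results = []
    for d in dets:
        x0, y0, x1, y1 = d.box
        results.append(
            {
                "image_id": int(image_id),
                "category_id": int(cat_id[d.label]),
                "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                "score": float(d.score),
            }
        )
    return results


def read_coco_detections(path, categories: dict | None = None) -> list[DetBox]:
    """Read a COCO results JSON; ``categories`` maps category_id → name."""
    with open(path) as fh:
        results = json.load(fh)
    out = []
    for i, r in enumerate(results):
        x, y, w, h = _check_bbox(r["bbox"], where=f"result {i}")
        name = (categories or {}).get(r["category_id"], str(r["category_id"]))
        out.append(
            DetBox(
                image_id=int(r["image_id"]),
                label=name,
                box=(x, y, x + w, y + h),
                score=float(r["score"]),
            )
        )
    return out


def _check_bbox(bbox, where: str) -> tuple[float, float, float, float]:
    if len(bbox) != 4:
        raise ValidationError(f"{where}: bbox must have 4 entries", fields=["bbox"])
    x, y, w, h = map(float, bbox)
    if w < 0 or h < 0:
        raise ValidationError(f"{where}: bbox has negative extent {bbox}", fields=["bbox"])
    return x, y, w, h


# ---------------------------------------------------------- array bundles

def save_bundle(bundle: HeatmapBundle, prefix) -> None:
    """Save a heatmap bundle as ``<prefix>.npz`` + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    arrays = {}
    for lab, maps in bundle.heatmaps.items():
        for kind, arr in maps.items():
            arrays[f"hm/{lab}/{kind}"] = arr
    for lab, maps in bundle.gt_heatmaps.items():
        for kind, arr in maps.items():
            arrays[f"gt/{lab}/{kind}"] = arr
    for kind, arr in bundle.offsets.items():
        arrays[f"off/{kind}"] = arr
    np.savez(prefix.with_suffix(".npz"), **arrays)
    sidecar = {
        "width": bundle.width,
        "height": bundle.height,
        "s": bundle.s,
        "sigma": bundle.sigma,
        "seed": bundle.seed,
        "classes": sorted(bundle.heatmaps),
    }
    _atomic_write_json(prefix.with_suffix(".json"), sidecar)


def load_bundle(prefix) -> HeatmapBundle:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    with np.load(prefix.with_suffix(".npz")) as npz:
        heatmaps: dict = {}
        gt: dict = {}
        offsets: dict = {}
        for key in npz.files:
            parts = key.split("/")
            if parts[0] == "hm":
                heatmaps.setdefault(parts[1], {})[parts[2]] = npz[key]
            elif parts[0] == "gt":
                gt.setdefault(parts[1], {})[parts[2]] = npz[key]
            elif parts[0] == "off":
                offsets[parts[1]] = npz[key]
    return HeatmapBundle(
        heatmaps=heatmaps,
        gt_heatmaps=gt,
        offsets=offsets,
        width=int(sidecar["width"]),
        height=int(sidecar["height"]),
        s=int(sidecar["s"]),
        sigma=float(sidecar["sigma"]),
        seed=int(sidecar["seed"]),
    )


def export_heatmap_png(heatmap: np.ndarray, out_path) -> None:
    """Write one heatmap as an 8-bit grayscale PNG (inspection only)."""
    from PIL import Image

    arr = (np.clip(np.asarray(heatmap, dtype=float), 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(out_path)


# ------------------------------------------------------------- run config

@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline in one serializable record."""

    peak_threshold: float = 0.1
    center_threshold: float = 0.1
    score_threshold: float = 0.1
    suppression_iou: float = 0.5
    max_peaks: int = 40
    verify_spectrum: bool = False
    strict_center: bool = True
    sigma: float = 2.5
    s: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    verbosity: str = "INFO"

    def grouping(self) -> GroupingConfig:
        return GroupingConfig(
            peak_threshold=self.peak_threshold,
            center_threshold=self.center_threshold,
            score_threshold=self.score_threshold,
            suppression_iou=self.suppression_iou,
            max_peaks=self.max_peaks,
            verify_spectrum=self.verify_spectrum,
            strict_center=self.strict_center,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}", fields=unknown)
        return cls(**data)


def _atomic_write_json(path, obj) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1)
    tmp.replace(path)
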