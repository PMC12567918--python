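"""Dual-mask dataset I/O.

Scenes are serialized as a COCO-style JSON where each annotation carries
both a ``segmentation`` (visible mask) and an ``amodal_segmentation``
(complete mask), each as uncompressed column-major RLE — the convention
used by amodal-segmentation datasets. Individual masks round-trip through
0/255 single-channel PNGs. All encodings are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .compositing import PodInstance, SceneAnnotation

__all__ = [
    "DualMaskRecord",
    "rle_encode",
    "rle_decode",
    "mask_bbox",
    "write_dataset",
    "read_dataset",
    "read_mask_png",
    "write_mask_png",
    "export_occlusion_csv",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major runs, first run counts zeros."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.ravel(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # counts must start with a (possibly zero-length) run of 0s
        runs = [0] + runs
    return {"size": [h, w], "counts": [int(r) for r in runs]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    total = sum(counts)
    if total != h * w:
        raise ValueError(f"RLE runs sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def mask_bbox(mask: np.ndarray) -> list[float]:
    """Tight [x, y, w, h] bounding box (0-based, half-open) of a mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    return [float(xs.min()), float(ys.min()), float(xs.max() - xs.min() + 1), float(ys.max() - ys.min() + 1)]


@dataclass
class DualMaskRecord:
    """One image's worth of decoded dual-mask annotations."""

    image_id: int
    image_size: tuple[int, int]  # (H, W)
    instances: list[dict]  # instance_id, category, visible/amodal masks, bboxes, occlusion_ratio

    def to_scene(self, alpha: float = 1.0) -> SceneAnnotation:
        scene = SceneAnnotation(canvas_size=self.image_size, alpha=alpha)
        for i, inst in enumerate(self.instances):
            scene.instances.append(
                PodInstance(
                    instance_id=inst["instance_id"],
                    full_mask=inst["amodal_mask"],
                    visible_mask=inst["visible_mask"],
                    z_index=inst.get("z_index", i),
                    occlusion_ratio=inst["occlusion_ratio"],
                )
            )
        return scene


def write_dataset(scenes: list[SceneAnnotation], out_dir: str | Path) -> Path:
    """Serialize scenes to ``annotations.json`` + ``manifest.json``.

    Returns the manifest path. Raises on an empty scene list.
    """
    if not scenes:
        raise ValueError("no scenes to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    for img_id, scene in enumerate(scenes, start=1):
        H, W = scene.canvas_size
        images.append({"id": img_id, "height": H, "width": W, "rng_seed": scene.rng_seed})
        for inst in scene.instances:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "instance_id": inst.instance_id,
                    "z_index": inst.z_index,
                    "segmentation": rle_encode(inst.visible_mask),
                    "amodal_segmentation": rle_encode(inst.full_mask),
                    "bbox": mask_bbox(inst.visible_mask),
                    "bbox_amodal": mask_bbox(inst.full_mask),
                    "area": int(inst.visible_mask.sum()),
                    "area_amodal": int(inst.full_mask.sum()),
                    "occlusion_ratio": float(inst.occlusion_ratio),
                }
            )
            ann_id += 1
    coco = {
        "info": {
            "description": "soypod dual-mask synthetic dataset",
            "alphas": sorted({float(s.alpha) for s in scenes}),
        },
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "pod"}],
    }
    ann_path = out / "annotations.json"
    try:
        ann_path.write_text(json.dumps(coco))
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed to write {ann_path}: {exc}") from exc
    manifest = {
        "annotations": ann_path.name,
        "n_images": len(images),
        "n_instances": len(annotations),
        "alphas": coco["info"]["alphas"],
        "seeds": [s.rng_seed for s in scenes],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_dataset(manifest_path: str | Path) -> list[DualMaskRecord]:
    """Load and validate a dual-mask dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    ann_path = manifest_path.parent / manifest["annotations"]
    if not ann_path.exists():
        raise FileNotFoundError(f"annotation file not found: {ann_path}")
    try:
        coco = json.loads(ann_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {ann_path}: {exc}") from exc

    by_image: dict[int, DualMaskRecord] = {}
    for img in coco["images"]:
        by_image[img["id"]] = DualMaskRecord(
            image_id=img["id"], image_size=(img["height"], img["width"]), instances=[]
        )
    for ann in coco["annotations"]:
        rec = by_image.get(ann["image_id"])
        if rec is None:
            raise ValueError(f"annotation {ann['id']} references unknown image {ann['image_id']}")
        visible = rle_decode(ann["segmentation"])
        amodal = rle_decode(ann["amodal_segmentation"])
        if visible.shape != rec.image_size or amodal.shape != rec.image_size:
            raise ValueError(
                f"annotation {ann['id']} (instance {ann.get('instance_id')}): "
                "mask size inconsistent with image size"
            )
        if np.any(visible & ~amodal):
            raise ValueError(
                f"annotation {ann['id']} (instance {ann.get('instance_id')}): "
                "visible mask not contained in amodal mask"
            )
        rec.instances.append(
            {
                "instance_id": ann.get("instance_id", ann["id"]),
                "category": "pod",
                "visible_mask": visible,
                "amodal_mask": amodal,
                "bbox_visible": ann["bbox"],
                "bbox_amodal": ann["bbox_amodal"],
                "occlusion_ratio": float(ann["occlusion_ratio"]),
                "z_index": ann.get("z_index", 0),
            }
        )
    return [by_image[k] for k in sorted(by_image)]


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG (0 / 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    img = Image.fromarray((mask.astype(bool) * 255).astype(np.uint8), mode="L")
    img.save(Path(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG as a boolean mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = Image.open(path)
    if img.mode != "L":
        raise ValueError(f"{path}: expected single-channel (L) PNG, got mode {img.mode!r}")
    arr = np.asarray(img)
    values = np.unique(arr)
    if not np.all(np.isin(values, [0, 255])):
        raise ValueError(f"{path}: mask PNG must contain only 0 and 255")
    return arr == 255


def export_occlusion_csv(scenes: list[SceneAnnotation], path: str | Path) -> None:
    """Per-instance occlusion ratio table (image, instance, ratio)."""
    rows = [
        {
            "image_index": i,
            "instance_id": inst.instance_id,
            "z_index": inst.z_index,
            "occlusion_ratio": inst.occlusion_ratio,
        }
        for i, scene in enumerate(scenes)
        for inst in scene.instances
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
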