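"""File I/O: images, models, detections, run summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .color import ColorTreeModel
from .pipeline import RunResult, TrainedModels
from .shape import ShapeTreeModel

__all__ = [
    "read_image",
    "write_image",
    "write_label_image",
    "save_models",
    "load_models",
    "detections_to_frame",
    "write_run_result",
]


def read_image(path) -> np.ndarray:
    """8-bit RGB image from PNG/TIFF."""
    arr = np.asarray(Image.open(path).convert("RGB"))
    return arr


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_label_image(path, label: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(label, dtype=np.uint16))


def save_models(directory, models: TrainedModels) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    models.color.save(directory / "color_tree.json")
    models.shape_pos.save(directory / "shape_tree_pos.json")
    models.shape_neg.save(directory / "shape_tree_neg.json")


def load_models(directory) -> TrainedModels:
    directory = Path(directory)
    return TrainedModels(
        color=ColorTreeModel.load(directory / "color_tree.json"),
        shape_pos=ShapeTreeModel.load(directory / "shape_tree_pos.json"),
        shape_neg=ShapeTreeModel.load(directory / "shape_tree_neg.json"),
    )


def detections_to_frame(result: RunResult) -> pd.DataFrame:
    rows = []
    for region_id, dets in result.detections.items():
        for i, d in enumerate(dets):
            rows.append(
                {
                    "id": i,
                    "row": d.centroid[0],
                    "col": d.centroid[1],
                    "area_px": d.area,
                    "polarity": d.polarity,
                    "stage": d.stage,
                    "tumor_region_id": region_id,
                }
            )
    return pd.DataFrame(
        rows, columns=["id", "row", "col", "area_px", "polarity", "stage", "tumor_region_id"]
    )


def write_run_result(directory, result: RunResult, *, config=None, seed=None) -> None:
    """CSV of detections plus a JSON summary per tumor region."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    detections_to_frame(result).to_csv(directory / "detections.csv", index=False)
    summary = {
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "regions": {
            str(rid): dataclasses.asdict(est) for rid, est in result.estimates.items()
        },
    }
    with open(directory / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
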