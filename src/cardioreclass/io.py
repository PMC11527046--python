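"""Readers and writers for the package's plain-text interchange formats.

Cohort tables travel as TSV with the documented header, generator parameters
as YAML, and detection fixtures either as JSON records
(``{"image_id", "boxes": [{"x_min", ...}]}``) or as YOLO-format text files
(one ``class x_center y_center width height [confidence]`` line per box,
coordinates normalised to the canvas).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .synth_cohort import CANVAS_H, CANVAS_W, COHORT_COLUMNS, CohortParams


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort TSV missing required columns: {missing}")
    return df


def write_params_yaml(params: CohortParams, path) -> None:
    d = dataclasses.asdict(params)
    d["age_range"] = list(d["age_range"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_params_yaml(path) -> CohortParams:
    d = yaml.safe_load(Path(path).read_text())
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    if "count_levels" in d:
        d["count_levels"] = {int(k): float(v) for k, v in d["count_levels"].items()}
    return CohortParams(**d)


# ---------------------------------------------------------------------------
# detection fixtures: JSON and YOLO text
# ---------------------------------------------------------------------------

def write_boxes_json(records: list, path) -> None:
    Path(path).write_text(json.dumps(records, indent=1))


def read_boxes_json(path) -> list:
    return json.loads(Path(path).read_text())


def boxes_to_yolo(record: dict, width: int = CANVAS_W, height: int = CANVAS_H) -> str:
    """One image record -> YOLO text (class 0; confidence appended if present)."""
    lines = []
    for b in record["boxes"]:
        xc = (b["x_min"] + b["x_max"]) / 2 / width
        yc = (b["y_min"] + b["y_max"]) / 2 / height
        w = (b["x_max"] - b["x_min"]) / width
        h = (b["y_max"] - b["y_min"]) / height
        parts = [f"0 {xc:.8f} {yc:.8f} {w:.8f} {h:.8f}"]
        if "confidence" in b:
            parts.append(f"{b['confidence']:.8f}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def yolo_to_boxes(text: str, image_id: str, width: int = CANVAS_W, height: int = CANVAS_H) -> dict:
    """YOLO text -> image record; inverse of :func:`boxes_to_yolo`."""
    boxes = []
    for line in text.splitlines():
        fields = line.split()
        if not fields:
            continue
        if len(fields) not in (5, 6):
            raise ValueError(f"malformed YOLO line: {line!r}")
        _, xc, yc, w, h = (float(v) for v in fields[:5])
        box = {
            "x_min": (xc - w / 2) * width,
            "y_min": (yc - h / 2) * height,
            "x_max": (xc + w / 2) * width,
            "y_max": (yc + h / 2) * height,
        }
        if len(fields) == 6:
            box["confidence"] = float(fields[5])
        boxes.append(box)
    return {"image_id": image_id, "boxes": boxes}


def write_yolo_dir(records: list, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        (directory / f"{rec['image_id']}.txt").write_text(boxes_to_yolo(rec))


def read_yolo_dir(directory) -> list:
    directory = Path(directory)
    return [
        yolo_to_boxes(p.read_text(), p.stem)
        for p in sorted(directory.glob("*.txt"))
    ]
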