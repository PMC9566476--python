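"""Readers and writers for the on-disk recording layout.

A recording is a directory holding one depth CSV per frame (rectangular
grid of decimal meters, six decimal places), a ``manifest.csv`` index
(frame_index, filename, timestamp), per-frame labels in ``labels.csv``,
ground-truth boxes in ``boxes.csv``, and — after colorization — one
lossless 8-bit RGB PNG per frame next to a ``range.json`` sidecar that
records the depth bounds used for encoding, so recovery always uses the
same range.  Models serialize to JSON; run configuration loads from YAML.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml
from PIL import Image

from .actions import ActionLabel, NO_PERSON
from .colorization import ColorFrame, ColorizationRange, DepthFrame
from .detection import BoundingBox
from .hmm import HmmModel


# ---------------------------------------------------------------------------
# depth CSV
# ---------------------------------------------------------------------------

def read_depth_csv(path: str | Path) -> DepthFrame:
    """Read one depth frame from CSV; errors name the offending row/cell."""
    path = Path(path)
    rows: List[List[float]] = []
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            try:
                rows.append([float(c) for c in row])
            except ValueError as exc:
                raise ValueError(f"{path}, row {i + 1}: non-numeric cell ({exc})") from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}, row {i + 1}: ragged row ({len(rows[-1])} cells, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty depth CSV")
    return DepthFrame(values=np.asarray(rows))


def write_depth_csv(frame: DepthFrame, path: str | Path) -> None:
    """Write a depth frame as CSV with six-decimal meters."""
    np.savetxt(path, frame.values, fmt="%.6f", delimiter=",")


# ---------------------------------------------------------------------------
# PNG
# ---------------------------------------------------------------------------

def write_png(frame: ColorFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError(f"{path}: colorized frames must be stored as lossless PNG")
    Image.fromarray(frame.pixels, mode="RGB").save(path, format="PNG")


def read_png(path: str | Path) -> ColorFrame:
    """Read a colorized frame; rejects lossy formats (they break decoding)."""
    path = Path(path)
    with Image.open(path) as img:
        if img.format != "PNG":
            raise ValueError(
                f"{path}: stored as {img.format}; only lossless PNG decodes back to depth"
            )
        return ColorFrame(pixels=np.asarray(img.convert("RGB"), dtype=np.uint8))


# ---------------------------------------------------------------------------
# sidecars: range, manifest, labels, boxes
# ---------------------------------------------------------------------------

def write_range(crange: ColorizationRange, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"d_min": crange.d_min, "d_max": crange.d_max}, indent=2))


def read_range(path: str | Path) -> ColorizationRange:
    d = json.loads(Path(path).read_text())
    return ColorizationRange(d_min=d["d_min"], d_max=d["d_max"])


def write_manifest(
    filenames: Sequence[str], path: str | Path, fps: float = 1.0, start_time: float = 0.0
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "filename", "timestamp"])
        for i, name in enumerate(filenames):
            w.writerow([i, name, f"{start_time + i / fps:.3f}"])


def read_manifest(path: str | Path) -> List[str]:
    """Filenames in frame order."""
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        rows = sorted(reader, key=lambda r: int(r["frame_index"]))
    return [r["filename"] for r in rows]


def write_labels_csv(labels: Sequence[int], path: str | Path) -> None:
    """Per-frame labels as (frame_index, label-name) rows."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "label"])
        for i, lab in enumerate(labels):
            name = "NoPerson" if lab == NO_PERSON else ActionLabel(int(lab)).display_name
            w.writerow([i, name])


def read_labels_csv(path: str | Path) -> np.ndarray:
    out: Dict[int, int] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["label"]
            out[int(row["frame_index"])] = (
                NO_PERSON if name.lower() == "noperson" else int(ActionLabel.from_name(name))
            )
    return np.asarray([out[i] for i in sorted(out)], dtype=np.int64)


def write_boxes_csv(boxes: Sequence[Optional[BoundingBox]], path: str | Path) -> None:
    """Per-frame boxes; frames without a person are simply absent."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "x0", "y0", "x1", "y1", "confidence"])
        for i, b in enumerate(boxes):
            if b is not None:
                w.writerow([i, b.x0, b.y0, b.x1, b.y1, f"{b.confidence:.4f}"])


def read_boxes_csv(path: str | Path, n_frames: int) -> List[Optional[BoundingBox]]:
    boxes: List[Optional[BoundingBox]] = [None] * n_frames
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            boxes[int(row["frame_index"])] = BoundingBox(
                x0=int(row["x0"]),
                y0=int(row["y0"]),
                x1=int(row["x1"]),
                y1=int(row["y1"]),
                confidence=float(row["confidence"]),
            )
    return boxes


# ---------------------------------------------------------------------------
# descriptors, model, config
# ---------------------------------------------------------------------------

def write_descriptors_csv(X: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """Flat descriptor rows: label index first, then the vector entries."""
    data = np.column_stack([np.asarray(y, dtype=np.float64), X])
    np.savetxt(path, data, fmt="%.9g", delimiter=",")


def read_descriptors_csv(path: str | Path):
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    from .hmm import LabeledDescriptors

    return LabeledDescriptors(X=data[:, 1:], y=data[:, 0].astype(np.int64))


def write_model_json(model: HmmModel, path: str | Path, metadata: dict | None = None) -> None:
    doc = model.to_dict()
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path: str | Path) -> HmmModel:
    return HmmModel.from_dict(json.loads(Path(path).read_text()))


#: Recognized run-configuration keys and their defaults.
CONFIG_DEFAULTS: Dict[str, object] = {
    "d_min": 0.5,
    "d_max": 5.0,
    "crop_size": 128,
    "motion_epsilon": 0.05,
    "alpha_transitions": 1e-3,
    "alpha_emissions": 1e-3,
    "assigner": "svm",
    "knn_k": 5,
    "bw_max_iter": 100,
    "bw_tol": 1e-4,
    "chunk_minutes": 1.0,
    "fps": 1.0,
    "seed": 0,
}


def load_config(path: str | Path | None) -> Dict[str, object]:
    """Merge a YAML config over the defaults; unknown keys are rejected."""
    cfg = dict(CONFIG_DEFAULTS)
    if path is None:
        return cfg
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(loaded) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg.update(loaded)
    return cfg
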