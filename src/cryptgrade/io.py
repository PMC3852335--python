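"""Reading and writing images, contour sidecars and feature tables."""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import Boundary, ContourSet
from .grades import Grade
from .pipeline import FEATURE_NAMES, QCRecord
from .synthetic import LabeledImage

# ITU-R BT.709 luminance weights for RGB -> grayscale
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path, grade: Optional[Grade] = None) -> LabeledImage:
    """Read a PNG/TIFF image; RGB(A) is converted by luminance."""
    arr = iio.imread(path)
    color = None
    if arr.ndim == 3:
        color = arr[..., :3]
        gray = color.astype(float) @ _LUMA
    else:
        gray = arr.astype(float)
    return LabeledImage(gray, grade=grade, source_id=Path(path).stem, color=color)


def write_image(path: str | Path, image: LabeledImage) -> None:
    px = np.clip(np.asarray(image.pixels, dtype=float), 0, 255).round().astype(np.uint8)
    iio.imwrite(path, px)


def contours_to_json(contours: ContourSet) -> dict:
    return {
        "crypts": [b.vertices.tolist() for b in contours.crypts],
        "muscularis": (contours.muscularis.vertices.tolist()
                       if contours.muscularis is not None else None),
    }


def contours_from_json(doc: dict) -> ContourSet:
    return ContourSet(
        crypts=[Boundary(np.array(v), closed=True) for v in doc["crypts"]],
        muscularis=(Boundary(np.array(doc["muscularis"]), closed=False)
                    if doc.get("muscularis") else None),
    )


def write_contours(path: str | Path, contours: ContourSet) -> None:
    with open(path, "w") as fh:
        json.dump(contours_to_json(contours), fh)


def read_contours(path: str | Path) -> ContourSet:
    with open(path) as fh:
        return contours_from_json(json.load(fh))


def write_feature_table(path: str | Path, rows: List[Tuple[str, np.ndarray, QCRecord]],
                        grades: Optional[List[Grade]] = None) -> None:
    """Feature CSV: source_id, the 11 features, QC counts, optional grade."""
    records = []
    for i, (source_id, vec, qc) in enumerate(rows):
        rec = {"source_id": source_id}
        rec.update({name: float(val) for name, val in zip(FEATURE_NAMES, vec)})
        rec["n_crypts"] = qc.n_crypts
        rec["n_degenerate"] = qc.n_degenerate
        if grades is not None:
            rec["grade"] = grades[i].name
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_feature_table(path: str | Path, labels_col: str = "grade"):
    """Load a feature CSV; returns (source_ids, features, grades-or-None)."""
    df = pd.read_csv(path)
    feats = df[FEATURE_NAMES].to_numpy(dtype=float)
    ids = df["source_id"].astype(str).tolist() if "source_id" in df else [str(i) for i in range(len(df))]
    grades = None
    if labels_col in df.columns:
        grades = [Grade.from_name(str(g)) for g in df[labels_col]]
    return ids, feats, grades
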