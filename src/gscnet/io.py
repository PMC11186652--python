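"""Manifest I/O: the CSV schema tying images, scores and labels together.

The label column is definitional, not data: on read the CGI label is
re-derived from the AIS/CIS scores and any mismatch is an error.  Manifests
without score columns (real, biopsy-free data) are accepted in image-only
mode, where the stored labels are taken as ground truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cgi_rule import SectionScores, diagnose_cgi
from .synthetic import (
    Cohort,
    GRADE_FIELDS,
    MANIFEST_COLUMNS,
    PatientTriplet,
    SECTIONS,
)

__all__ = ["read_manifest", "write_manifest"]

_REQUIRED = ["patient_id", "antrum_path", "body_path", "cardia_path", "cgi"]


def _load_image(root: Path, rel: str) -> np.ndarray:
    path = root / rel
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0


def read_manifest(path: str | Path, load_images: bool = True) -> Cohort:
    """Read a cohort manifest; labels are re-derived and verified from scores.

    ``load_images=False`` returns a cohort whose patients carry empty image
    arrays (scores and labels only), useful for label-level analyses.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    has_scores = all(c in frame.columns for c in GRADE_FIELDS)
    root = path.parent
    patients = []
    for _, row in frame.iterrows():
        scores = None
        label = int(row["cgi"])
        if has_scores:
            scores = SectionScores(**{f: int(row[f]) for f in GRADE_FIELDS})
            derived = diagnose_cgi(scores.profile())
            if derived != label:
                raise ValueError(
                    f"{path}: patient {row['patient_id']} has cgi={label} but the "
                    f"decision rule derives {derived} from its scores"
                )
        if load_images:
            images = {s: _load_image(root, row[f"{s}_path"]) for s in SECTIONS}
        else:
            empty = np.zeros((0, 0, 3), dtype=np.float32)
            images = {s: empty for s in SECTIONS}
        patients.append(
            PatientTriplet(
                str(row["patient_id"]),
                images["antrum"],
                images["body"],
                images["cardia"],
                scores=scores,
                label=label,
            )
        )
    return Cohort(patients, frame)


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort's manifest CSV (schema-ordered columns first)."""
    frame = cohort.manifest
    ordered = [c for c in MANIFEST_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    frame[ordered + extra].to_csv(path, index=False)
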