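"""CSV manifest handling for on-disk frame datasets."""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import EyeLabel
from .synth import MANIFEST_COLUMNS

__all__ = ["ManifestError", "read_manifest", "write_manifest", "load_frames"]

_VALID_LABELS = {l.value for l in EyeLabel}


class ManifestError(ValueError):
    """Malformed manifest file (message carries the offending line)."""


def read_manifest(path: Path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a dataset manifest.

    The manifest is a CSV with header ``path,label,cx,cy,visible_fraction,
    seed``; image paths are relative to the manifest's directory.  Unknown
    labels, non-numeric fields, and (optionally) missing image files are
    rejected with the 1-based line number of the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"path": str, "label": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["label"] not in _VALID_LABELS:
            raise ManifestError(f"{path}:{line}: unknown label {row['label']!r}")
        for col in ("cx", "cy", "visible_fraction"):
            if not np.isfinite(row[col]):
                raise ManifestError(f"{path}:{line}: non-finite {col}")
        if check_paths and not (path.parent / row["path"]).exists():
            raise ManifestError(f"{path}:{line}: image {row['path']!r} not found")
    return df


def write_manifest(manifest: pd.DataFrame, path: Path) -> None:
    """Write a manifest CSV (lossless round-trip with read_manifest)."""
    manifest[MANIFEST_COLUMNS].to_csv(Path(path), index=False)


def load_frames(manifest: pd.DataFrame, root: Path) -> List[np.ndarray]:
    """Load every manifest image as an 8-bit grayscale array."""
    frames = []
    for rel in manifest["path"]:
        img = Image.open(Path(root) / rel).convert("L")
        frames.append(np.asarray(img, dtype=np.uint8))
    return frames
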