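"""File I/O: TIFF fields and label masks, CSV tables, field manifests.

Images travel as multi-channel TIFF (channel order: dsDNA, nucleus
stain, cytoplasm stain) or as three single-channel TIFFs listed in a
manifest CSV with columns ``field_id, dsdna, nucleus, cytoplasm,
dose_gy, quality`` (single-file fields put the same path in all three
channel columns).  Label masks are written as 16-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth import FieldOfView, GroundTruth

__all__ = [
    "write_field",
    "read_field",
    "read_manifest",
    "write_label_mask",
    "write_truth",
]

CHANNEL_ORDER = ("dsdna", "nucleus", "cytoplasm")


def write_field(fov: FieldOfView, path: str | Path) -> Path:
    """Write one field as a 3-channel float32 TIFF (dsDNA, nucleus, cytoplasm)."""
    path = Path(path)
    stack = np.stack(
        [fov.dsdna, fov.nucleus_stain, fov.cytoplasm_stain]
    ).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     planarconfig="separate", metadata={"axes": "CYX"})
    return path


def read_field(
    path: str | Path,
    field_id: str | None = None,
    dose_gy: float = 0.0,
    quality: str = "xray",
) -> FieldOfView:
    """Read a 3-channel TIFF back into a :class:`FieldOfView`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-channel stack, got shape {stack.shape}")
    return FieldOfView(
        dsdna=np.asarray(stack[0], dtype=float),
        nucleus_stain=np.asarray(stack[1], dtype=float),
        cytoplasm_stain=np.asarray(stack[2], dtype=float),
        field_id=field_id or path.stem,
        dose_gy=float(dose_gy),
        quality=quality,
    )


def read_manifest(path: str | Path) -> list[FieldOfView]:
    """Load every field listed in a manifest CSV.

    Columns: ``field_id, dsdna, nucleus, cytoplasm, dose_gy, quality``.
    Paths are resolved relative to the manifest's directory.  When the
    three channel paths are identical the file is read as one
    multi-channel TIFF; otherwise each channel comes from its own
    single-channel file.
    """
    path = Path(path)
    man = pd.read_csv(path)
    required = {"field_id", "dsdna", "nucleus", "cytoplasm", "dose_gy", "quality"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    fovs = []
    for _, row in man.iterrows():
        paths = [path.parent / row[c] for c in CHANNEL_ORDER]
        if paths[0] == paths[1] == paths[2]:
            fov = read_field(
                paths[0], field_id=str(row["field_id"]),
                dose_gy=float(row["dose_gy"]), quality=str(row["quality"]),
            )
        else:
            chans = [np.asarray(tifffile.imread(p), dtype=float) for p in paths]
            fov = FieldOfView(
                dsdna=chans[0], nucleus_stain=chans[1], cytoplasm_stain=chans[2],
                field_id=str(row["field_id"]), dose_gy=float(row["dose_gy"]),
                quality=str(row["quality"]),
            )
        fovs.append(fov)
    return fovs


def write_label_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write a labelled integer mask as a 16-bit TIFF."""
    path = Path(path)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit mask")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def write_truth(truth: GroundTruth, directory: str | Path, stem: str) -> None:
    """Persist ground truth as JSON (focus records) + label-mask TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_label_mask(truth.nucleus_labels, directory / f"{stem}_nuclei.tif")
    write_label_mask(truth.cell_labels, directory / f"{stem}_cells.tif")
    records = truth.foci.to_dict(orient="records")
    with open(directory / f"{stem}_foci.json", "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
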