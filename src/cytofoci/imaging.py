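"""Compartment-restricted counting of cytoplasmic dsDNA foci.

The counting rule: a connected component of above-threshold dsDNA
signal is a cytoplasmic focus if its area is at least ``min_area``
pixels (default 5), no pixel of it lies on a nucleus, and it sits
inside a cell's cytoplasmic territory.  Nuclear dsDNA is typically
overexposed when the camera is tuned for the dim cytosolic signal, so
the nucleus-exclusion rule is strict: a single shared pixel with a
nucleus label disqualifies the component.

Conventions used throughout (stated once, used everywhere):

* 8-connectivity for dsDNA components and nuclei;
* 0-based (row, col) coordinates, integer pixel areas;
* label 0 is background in every labelled mask;
* deterministic labelling in raster-scan order of first pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

from .synth import FieldOfView, GroundTruth

__all__ = [
    "SegmentationResult",
    "SpotComponent",
    "Focus",
    "segment_nuclei",
    "segment_cytoplasm",
    "segment_field",
    "detect_dsdna_signals",
    "filter_cytoplasmic_foci",
    "count_foci_per_cell",
    "group_summary",
    "background_correct",
    "process_field",
    "process_fields",
    "evaluate_detection",
]

_CONNECTIVITY = 2  # 8-connectivity, as skimage "connectivity" for 2-D


@dataclass
class SegmentationResult:
    """Labelled nucleus and cytoplasm masks plus per-cell records.

    ``cytoplasm_labels`` holds the cell territories with nucleus pixels
    removed; each territory label matches its nucleus label.  ``cells``
    has columns ``cell_id, nucleus_area, cytoplasm_area,
    touches_border``.
    """

    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    cells: pd.DataFrame

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def analysis_cells(self, exclude_border: bool = True) -> np.ndarray:
        """Cell ids entering per-cell statistics (border-touching
        territories excluded by default)."""
        c = self.cells
        if exclude_border:
            c = c[~c["touches_border"]]
        return c["cell_id"].to_numpy()


@dataclass
class SpotComponent:
    """One connected component of above-threshold dsDNA signal."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    area: int
    centroid: tuple[float, float]


@dataclass
class Focus:
    """A spot component after the compartment/size adjudication."""

    pixels: np.ndarray
    area: int
    centroid: tuple[float, float]
    cell_id: int = 0
    accepted: bool = False
    reason: str | None = None  # too_small | in_nucleus | outside_cytoplasm | unassigned


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in order of each component's first pixel in
    raster scan, so labelling is reproducible across library versions."""
    out = np.zeros_like(labels)
    next_id = 1
    flat = labels.ravel()
    seen: dict[int, int] = {}
    order = np.flatnonzero(flat)
    for pos in order:
        lab = flat[pos]
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
    for old, new in seen.items():
        out[labels == old] = new
    return out


def segment_nuclei(
    nucleus_stain: np.ndarray,
    min_nucleus_area: int = 50,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei in the DNA counterstain channel.

    Global Otsu threshold (overridable), 8-connected components,
    components below ``min_nucleus_area`` dropped.  Touching nuclei are
    *not* split: they come back as one label (no-splitting policy; the
    planted-cell generator keeps nuclei apart, and real clumps would
    need a dedicated declumping step that is out of scope here).
    A blank or constant image yields an empty mask.
    """
    img = np.asarray(nucleus_stain, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=np.int32)
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    labels = sk_label(mask, connectivity=_CONNECTIVITY)
    if min_nucleus_area > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_nucleus_area)
        labels[np.isin(labels, small[small > 0])] = 0
    return _relabel_raster_order(labels).astype(np.int32)


def segment_cytoplasm(
    cytoplasm_stain: np.ndarray,
    nucleus_labels: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Partition the stained cell area into one territory per nucleus.

    The stain is thresholded (Otsu unless overridden), merged with the
    nucleus pixels so each cell body is contiguous, and flooded from
    the nuclei by a nearest-seed watershed on the distance-from-nucleus
    map.  Stained regions not connected to any nucleus stay unlabelled;
    nucleus pixels are excluded from the returned cytoplasm mask.
    """
    img = np.asarray(cytoplasm_stain, dtype=float)
    if img.shape != nucleus_labels.shape:
        raise ValueError(
            f"shape mismatch: stain {img.shape} vs nucleus mask {nucleus_labels.shape}"
        )
    if nucleus_labels.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)
    if threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=np.int32)
        threshold = float(threshold_otsu(img))
    foreground = (img > threshold) | (nucleus_labels > 0)
    dist = ndimage.distance_transform_edt(nucleus_labels == 0)
    territories = watershed(dist, markers=nucleus_labels, mask=foreground)
    cytoplasm = np.where(nucleus_labels > 0, 0, territories)
    return cytoplasm.astype(np.int32)


def segment_field(
    fov: FieldOfView,
    min_nucleus_area: int = 50,
    nucleus_threshold: float | None = None,
    cytoplasm_threshold: float | None = None,
) -> SegmentationResult:
    """Nucleus + cytoplasm segmentation of one field with per-cell records."""
    nucleus_labels = segment_nuclei(
        fov.nucleus_stain, min_nucleus_area=min_nucleus_area, threshold=nucleus_threshold
    )
    cytoplasm_labels = segment_cytoplasm(
        fov.cytoplasm_stain, nucleus_labels, threshold=cytoplasm_threshold
    )
    rows = []
    border = np.zeros(nucleus_labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    ids = np.unique(nucleus_labels)
    for cid in ids[ids > 0]:
        nuc = nucleus_labels == cid
        cyt = cytoplasm_labels == cid
        rows.append(
            dict(
                cell_id=int(cid),
                nucleus_area=int(nuc.sum()),
                cytoplasm_area=int(cyt.sum()),
                touches_border=bool((border & (nuc | cyt)).any()),
            )
        )
    cells = pd.DataFrame(
        rows, columns=["cell_id", "nucleus_area", "cytoplasm_area", "touches_border"]
    )
    return SegmentationResult(nucleus_labels, cytoplasm_labels, cells)


def detect_dsdna_signals(
    dsdna: np.ndarray,
    threshold: float | None = None,
    mad_k: float = 5.0,
) -> list[SpotComponent]:
    """Connected components of above-threshold dsDNA signal.

    The default threshold is median + ``mad_k`` * scaled MAD of the
    whole channel.  A robust location/scale pair is used instead of
    Otsu because the saturated nuclei put a huge spike at the top of
    the histogram while foci occupy a tiny pixel fraction; the median
    and MAD see essentially only background.  Saturated nuclear blobs
    are returned like any other component -- the compartment filter
    removes them later.
    """
    img = np.asarray(dsdna, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med))) * 1.4826
        threshold = med + mad_k * mad
    mask = img > threshold
    labels = sk_label(mask, connectivity=_CONNECTIVITY)
    labels = _relabel_raster_order(labels)
    comps = []
    for cid in range(1, labels.max() + 1):
        pix = np.argwhere(labels == cid)
        comps.append(
            SpotComponent(
                pixels=pix,
                area=int(len(pix)),
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
            )
        )
    return comps


def filter_cytoplasmic_foci(
    components: list[SpotComponent],
    segmentation: SegmentationResult,
    min_area: int = 5,
    min_cytoplasm_fraction: float = 0.5,
) -> list[Focus]:
    """Adjudicate spot components against the compartment and size rules.

    Accepted iff area >= ``min_area`` AND no pixel overlaps any nucleus
    label AND the centroid plus at least ``min_cytoplasm_fraction`` of
    the pixels lie inside one cytoplasm territory.  Rejection reasons
    are assigned with precedence in_nucleus > too_small >
    outside_cytoplasm: nucleus contact dominates because overexposed
    nuclear dsDNA must never leak into cytoplasmic counts.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    nuc = segmentation.nucleus_labels
    cyt = segmentation.cytoplasm_labels
    out: list[Focus] = []
    for comp in components:
        pr, pc = comp.pixels[:, 0], comp.pixels[:, 1]
        focus = Focus(pixels=comp.pixels, area=comp.area, centroid=comp.centroid)
        if (nuc[pr, pc] > 0).any():
            focus.reason = "in_nucleus"
        elif comp.area < min_area:
            focus.reason = "too_small"
        else:
            cr = int(round(comp.centroid[0]))
            cc = int(round(comp.centroid[1]))
            cr = min(max(cr, 0), cyt.shape[0] - 1)
            cc = min(max(cc, 0), cyt.shape[1] - 1)
            centroid_label = int(cyt[cr, cc])
            labels_under = cyt[pr, pc]
            if centroid_label > 0:
                frac = float(np.mean(labels_under == centroid_label))
                if frac >= min_cytoplasm_fraction:
                    focus.accepted = True
                    focus.cell_id = centroid_label
                else:
                    focus.reason = "outside_cytoplasm"
            else:
                # centroid off-territory; if the pixel-majority rule would
                # still pass for some territory the assignment is ambiguous
                inside = labels_under[labels_under > 0]
                if inside.size and np.max(np.bincount(inside)) / comp.area >= min_cytoplasm_fraction:
                    focus.reason = "unassigned"
                else:
                    focus.reason = "outside_cytoplasm"
        out.append(focus)
    return out


def count_foci_per_cell(
    foci: list[Focus],
    segmentation: SegmentationResult,
    field_id: str = "field_0",
    dose_gy: float = 0.0,
    quality: str = "xray",
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Per-cell accepted focus counts.

    One row per analysed cell, zero-count cells included.  Cells whose
    territory touches the image border are excluded by default (their
    cytoplasm is truncated, biasing the count low).  A focus assigned
    to a cell id absent from the segmentation is an error.
    """
    known = set(int(c) for c in segmentation.cell_ids)
    for f in foci:
        if f.accepted and int(f.cell_id) not in known:
            raise ValueError(f"focus assigned to unknown cell id {f.cell_id}")
    cells = segmentation.analysis_cells(exclude_border=exclude_border)
    counts = {int(c): 0 for c in cells}
    for f in foci:
        if f.accepted and int(f.cell_id) in counts:
            counts[int(f.cell_id)] += 1
    return pd.DataFrame(
        [
            dict(field_id=field_id, cell_id=c, dose_gy=float(dose_gy),
                 quality=quality, n_foci=n)
            for c, n in sorted(counts.items())
        ],
        columns=["field_id", "cell_id", "dose_gy", "quality", "n_foci"],
    )


def group_summary(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Mean foci/cell per (quality, dose) group with SD, SE and n."""
    if cell_table.empty:
        return pd.DataFrame(
            columns=["quality", "dose_gy", "n_cells", "mean_foci", "sd_foci", "se_foci"]
        )
    g = cell_table.groupby(["quality", "dose_gy"])["n_foci"]
    out = g.agg(n_cells="size", mean_foci="mean", sd_foci="std").reset_index()
    out["sd_foci"] = out["sd_foci"].fillna(0.0)
    out["se_foci"] = out["sd_foci"] / np.sqrt(out["n_cells"])
    return out


def background_correct(summary: pd.DataFrame) -> pd.DataFrame:
    """Subtract each quality's 0 Gy mean from its dose-group means.

    Adds a ``corrected_mean`` column: raw mean minus the unirradiated
    (background) mean of the same radiation quality.  The 0 Gy group
    itself corrects to exactly 0.  Corrected means may come out
    negative by sampling noise; they are reported as computed.  A
    missing 0 Gy group for any quality present is an error.
    """
    out = summary.copy()
    corrected = np.empty(len(out))
    for quality, idx in out.groupby("quality").groups.items():
        sub = out.loc[idx]
        zero = sub[sub["dose_gy"] == 0.0]
        if zero.empty:
            raise ValueError(f"no 0 Gy (background) group for quality {quality!r}")
        bg = float(zero["mean_foci"].iloc[0])
        corrected[out.index.get_indexer(idx)] = sub["mean_foci"].to_numpy() - bg
    out["corrected_mean"] = corrected
    return out


def process_field(
    fov: FieldOfView,
    min_area: int = 5,
    mad_k: float = 5.0,
    min_nucleus_area: int = 50,
    min_cytoplasm_fraction: float = 0.5,
    exclude_border: bool = True,
) -> tuple[SegmentationResult, list[Focus], pd.DataFrame]:
    """Segment one field, detect dsDNA components, apply the focus rules
    and return the per-cell count table."""
    seg = segment_field(fov, min_nucleus_area=min_nucleus_area)
    comps = detect_dsdna_signals(fov.dsdna, mad_k=mad_k)
    foci = filter_cytoplasmic_foci(
        comps, seg, min_area=min_area, min_cytoplasm_fraction=min_cytoplasm_fraction
    )
    table = count_foci_per_cell(
        foci, seg, field_id=fov.field_id, dose_gy=fov.dose_gy,
        quality=fov.quality, exclude_border=exclude_border,
    )
    return seg, foci, table


def process_fields(fovs: list[FieldOfView], **kwargs) -> pd.DataFrame:
    """Per-cell count table concatenated over several fields."""
    tables = [process_field(f, **kwargs)[2] for f in fovs]
    if not tables:
        return pd.DataFrame(columns=["field_id", "cell_id", "dose_gy", "quality", "n_foci"])
    return pd.concat(tables, ignore_index=True)


def evaluate_detection(
    foci: list[Focus],
    truth: GroundTruth,
    min_area: int = 5,
    match_radius: float = 3.0,
) -> dict:
    """Precision/recall of accepted foci against planted cytoplasmic truth.

    Truth positives are planted cytoplasmic foci of area >= ``min_area``.
    Accepted detections are matched one-to-one to the nearest unmatched
    truth centroid within ``match_radius`` pixels (greedy, closest pair
    first).
    """
    accepted = [f for f in foci if f.accepted]
    t = truth.foci
    pos = t[(t["compartment"] == "cytoplasmic") & (t["area_px"] >= min_area)]
    t_xy = pos[["row", "col"]].to_numpy(dtype=float)
    d_xy = np.array([f.centroid for f in accepted], dtype=float).reshape(-1, 2)
    pairs = []
    for i in range(len(d_xy)):
        for j in range(len(t_xy)):
            dist = float(np.hypot(*(d_xy[i] - t_xy[j])))
            if dist <= match_radius:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
    tp = len(used_t)
    precision = tp / len(d_xy) if len(d_xy) else 1.0
    recall = tp / len(t_xy) if len(t_xy) else 1.0
    return dict(
        n_truth=int(len(t_xy)),
        n_detected=int(len(d_xy)),
        n_matched=tp,
        precision=float(precision),
        recall=float(recall),
    )
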