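"""QC overlays and survival-curve plots (thin matplotlib wrappers)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .imaging import Focus, SegmentationResult
from .survival import LQFit
from .synth import FieldOfView

__all__ = ["save_overlay", "save_survival_curves"]


def save_overlay(
    fov: FieldOfView,
    seg: SegmentationResult,
    foci: list[Focus],
    path: str | Path,
) -> Path:
    """Write a QC PNG: dsDNA channel with compartment outlines, accepted
    foci circled in green, rejected ones in red."""
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6), dpi=120)
    img = np.log1p(fov.dsdna)  # log scale tames the saturated nuclei
    ax.imshow(img, cmap="gray")
    for labels, color in ((seg.nucleus_labels, "deepskyblue"),
                          (seg.cytoplasm_labels, "orange")):
        edges = find_boundaries(labels, mode="outer")
        ys, xs = np.nonzero(edges)
        ax.scatter(xs, ys, s=0.05, c=color, marker=".")
    for f in foci:
        color = "lime" if f.accepted else "red"
        ax.scatter([f.centroid[1]], [f.centroid[0]], s=60,
                   facecolors="none", edgecolors=color, linewidths=1.0)
    ax.set_title(f"{fov.field_id}  ({fov.dose_gy:g} Gy {fov.quality})")
    ax.axis("off")
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def save_survival_curves(fits: dict[str, LQFit], path: str | Path,
                         dose_max: float = 10.0) -> Path:
    """Semilog surviving-fraction curves for each fitted quality."""
    fig, ax = plt.subplots(figsize=(5, 4), dpi=120)
    d = np.linspace(0, dose_max, 200)
    for quality, fit in sorted(fits.items()):
        ax.semilogy(d, fit.survival(d),
                    label=f"{quality} (a={fit.alpha:.2f}, b={fit.beta:.3f})")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("surviving fraction")
    ax.legend()
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
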