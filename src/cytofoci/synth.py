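"""Ground-truthed synthetic data generators.

Every downstream stage of the pipeline (imaging, dose-response, survival,
expression) is exercised against data produced here, so each generator
returns both the observable data and the exact truth used to build it:

* :func:`generate_field` -- three-channel fluorescence fields (dsDNA,
  nucleus stain, cytoplasm stain) with planted cytoplasmic dsDNA foci.
  Foci per cell are Poisson with mean ``b + s_q * dose`` (a linear
  dose response whose slope depends on radiation quality) and the
  nuclear dsDNA signal is rendered saturated, as happens when exposure
  is optimised for the much dimmer cytosolic signal.
* :func:`generate_survival_data` -- clonogenic colony counts under the
  linear-quadratic survival law ``S(D) = exp(-alpha*D - beta*D**2)``.
* :func:`generate_cq_table` -- qPCR quantification-cycle tables with
  Gaussian replicate noise.
* :func:`generate_expression_matrix` -- log-normal FPKM matrices with a
  planted differentially-expressed gene fraction.

All generators are bit-reproducible given their parameters: randomness
flows through :func:`numpy.random.default_rng` seeded with the integer
seed in the parameter object (mixed with a stream index where a family
of outputs is produced, e.g. one substream per microscope field).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "ImagingTruthParams",
    "SurvivalTruthParams",
    "ExpressionTruthParams",
    "QPCRDesign",
    "FieldOfView",
    "GroundTruth",
    "PlacementError",
    "generate_field",
    "generate_survival_data",
    "generate_cq_table",
    "generate_expression_matrix",
    "lq_survival",
]


class PlacementError(RuntimeError):
    """Raised when cells or foci cannot be placed under the geometric
    constraints within the bounded retry budget."""


def _substream(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic child generator: the stream indices are mixed into
    the seed material, so (seed, stream) pairs never collide."""
    return np.random.default_rng([int(seed), *[int(s) for s in stream]])


# ---------------------------------------------------------------------------
# imaging truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingTruthParams:
    """Parameters of the synthetic microscope field generator.

    Geometry is deliberately simple -- elliptical nuclei inside larger
    elliptical cell territories -- because the generator's job is to
    provide an exact oracle for compartment-restricted focus counting,
    not to imitate real cell morphology.

    Attributes
    ----------
    n_cells
        Cells per field.
    nucleus_radii
        Major/minor nucleus semi-axes in pixels.
    cytoplasm_margin
        Width in pixels of the cytoplasmic territory beyond the nucleus.
    focus_rate_intercept
        ``b``: mean planted cytoplasmic foci per cell at 0 Gy.  The
        unirradiated background rate is a free parameter of the model;
        there is no canonical literature value.
    focus_rate_slope
        ``s_q``: mean foci per cell per Gy for the simulated radiation
        quality.
    focus_area
        Inclusive (min, max) pixel-area range of planted foci; areas are
        drawn uniformly so a detection size cutoff can be exercised on
        both sides.
    focus_amplitude
        Intensity of focus pixels above background, before blur.
    psf_sigma
        Gaussian blur applied to the dsDNA channel (0 = no blur).
    noise_sd
        Additive Gaussian read noise on all channels.
    nuclear_dsdna_level
        Intensity at which the nuclear area is rendered in the dsDNA
        channel.  The default sits near the sensor maximum to emulate
        overexposure of nuclear dsDNA when the camera exposure is tuned
        for the dim cytosolic foci.
    nuclear_saturation_level
        Sensor maximum; the dsDNA channel is clipped here.
    n_nuclear_foci_per_cell
        Extra foci planted straddling the nucleus boundary (compartment
        label ``"nuclear"``); used to stress-test the compartment rule.
    focus_nucleus_margin, focus_edge_margin
        Minimum pixel distance of planted cytoplasmic foci from the
        nucleus and from the outer cell boundary; keeps blurred foci
        from bleeding across compartment boundaries.
    focus_min_gap
        Minimum Chebyshev gap in pixels between planted focus pixel
        sets, so clean foci never merge into one connected component.
    """

    n_cells: int = 10
    nucleus_radii: tuple[float, float] = (9.0, 6.0)
    cytoplasm_margin: float = 14.0
    focus_rate_intercept: float = 1.0
    focus_rate_slope: float = 0.3
    focus_area: tuple[int, int] = (5, 9)
    focus_amplitude: float = 150.0
    psf_sigma: float = 0.7
    noise_sd: float = 8.0
    nuclear_dsdna_level: float = 3000.0
    nuclear_saturation_level: float = 4095.0
    background: float = 10.0
    nucleus_stain_level: float = 150.0
    cytoplasm_stain_level: float = 80.0
    image_shape: tuple[int, int] = (256, 256)
    n_nuclear_foci_per_cell: float = 0.0
    focus_nucleus_margin: float = 4.0
    focus_edge_margin: float = 2.0
    focus_min_gap: int = 2
    cell_gap: int = 2
    max_placement_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.focus_rate_intercept < 0 or self.focus_rate_slope < 0:
            raise ValueError("focus rate parameters must be >= 0")
        if self.focus_area[0] < 1 or self.focus_area[1] < self.focus_area[0]:
            raise ValueError("focus_area must be an increasing range with min >= 1")


@dataclass
class FieldOfView:
    """Three registered single-channel intensity images for one field."""

    dsdna: np.ndarray
    nucleus_stain: np.ndarray
    cytoplasm_stain: np.ndarray
    field_id: str = "field_0"
    dose_gy: float = 0.0
    quality: str = "xray"

    def __post_init__(self) -> None:
        if not (self.dsdna.shape == self.nucleus_stain.shape == self.cytoplasm_stain.shape):
            raise ValueError("all three channels must share one shape")


@dataclass
class GroundTruth:
    """Exact truth behind one synthetic field.

    ``foci`` has one row per planted focus with columns
    ``focus_id, cell_id, row, col, area_px, compartment``; the matching
    pixel sets live in ``foci_pixels`` (list of ``(area, 2)`` arrays,
    aligned with the frame's integer index).
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    foci: pd.DataFrame
    foci_pixels: list[np.ndarray]

    def cytoplasmic_counts(self, min_area: int = 1) -> pd.Series:
        """Planted cytoplasmic foci of area >= ``min_area`` per cell,
        including zero counts for focus-free cells."""
        cells = np.unique(self.cell_labels)
        cells = cells[cells > 0]
        sel = self.foci[
            (self.foci["compartment"] == "cytoplasmic")
            & (self.foci["area_px"] >= min_area)
        ]
        counts = sel.groupby("cell_id").size()
        return counts.reindex(cells, fill_value=0).rename("n_foci")


def digital_disk(area: int) -> np.ndarray:
    """Offsets (row, col) of the ``area`` pixels of a digital disk.

    Pixels are taken in order of squared distance from the centre with a
    lexicographic tie-break, so the shape is deterministic for every
    area and exactly ``area`` pixels large.
    """
    if area < 1:
        raise ValueError("area must be >= 1")
    r = int(np.ceil(np.sqrt(area / np.pi))) + 2
    offs = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)]
    offs.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o[0], o[1]))
    return np.asarray(offs[:area], dtype=int)


def _place_cells(params: ImagingTruthParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping elliptical cells.

    Returns (nucleus_labels, cell_labels).  Cell footprints keep a
    ``cell_gap`` pixel clearance from each other and never touch the
    image border region closer than the footprint radius, so every cell
    is fully inside the frame.
    """
    shape = params.image_shape
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)

    a = params.nucleus_radii[0] + params.cytoplasm_margin
    b = params.nucleus_radii[1] + params.cytoplasm_margin
    rmax = int(np.ceil(max(a, b))) + 1
    if shape[0] <= 2 * rmax + 2 or shape[1] <= 2 * rmax + 2:
        raise PlacementError(
            f"image_shape {shape} too small for cell footprint radius {rmax}"
        )

    gap_struct = np.ones((2 * params.cell_gap + 1,) * 2, dtype=bool)
    for cid in range(1, params.n_cells + 1):
        for _ in range(params.max_placement_tries):
            cr = rng.integers(rmax + 1, shape[0] - rmax - 1)
            cc = rng.integers(rmax + 1, shape[1] - rmax - 1)
            theta = rng.uniform(0.0, np.pi)
            rr, cc2 = draw_ellipse(cr, cc, a, b, shape=shape, rotation=theta)
            if blocked[rr, cc2].any():
                continue
            cell_labels[rr, cc2] = cid
            nr, nc = draw_ellipse(
                cr, cc, params.nucleus_radii[0], params.nucleus_radii[1],
                shape=shape, rotation=theta,
            )
            nucleus_labels[nr, nc] = cid
            foot = np.zeros(shape, dtype=bool)
            foot[rr, cc2] = True
            blocked |= ndimage.binary_dilation(foot, structure=gap_struct)
            break
        else:
            raise PlacementError(
                f"could not place cell {cid}/{params.n_cells} without overlap "
                f"after {params.max_placement_tries} tries "
                f"(footprint radius {rmax} px in image {shape})"
            )
    # renumber cells in raster-scan order of the first nucleus pixel so
    # truth ids line up with deterministic segmentation labels downstream
    flat = nucleus_labels.ravel()
    order: dict[int, int] = {}
    for lab in flat[flat > 0]:
        if lab not in order:
            order[int(lab)] = len(order) + 1
    lut = np.zeros(params.n_cells + 1, dtype=np.int32)
    for old, new in order.items():
        lut[old] = new
    return lut[nucleus_labels], lut[cell_labels]


def _plant_foci(
    params: ImagingTruthParams,
    dose: float,
    nucleus_labels: np.ndarray,
    cell_labels: np.ndarray,
    rng: np.random.Generator,
):
    """Plant Poisson-distributed cytoplasmic foci (plus optional
    nucleus-straddling foci) respecting compartment and spacing rules."""
    shape = params.image_shape
    records: list[dict] = []
    pixel_sets: list[np.ndarray] = []
    forbidden = np.zeros(shape, dtype=bool)
    gap = params.focus_min_gap

    def _forbid(pix: np.ndarray) -> None:
        # mark the Chebyshev-gap neighbourhood of a placed pixel set
        for dr in range(-gap, gap + 1):
            rr = np.clip(pix[:, 0] + dr, 0, shape[0] - 1)
            for dc in range(-gap, gap + 1):
                cc = np.clip(pix[:, 1] + dc, 0, shape[1] - 1)
                forbidden[rr, cc] = True

    dist_to_nucleus = ndimage.distance_transform_edt(nucleus_labels == 0)
    inside_cell = cell_labels > 0
    depth_in_cell = ndimage.distance_transform_edt(inside_cell)
    # pixels where a planted cytoplasmic focus pixel may legally sit
    core = (
        inside_cell
        & (dist_to_nucleus >= params.focus_nucleus_margin)
        & (depth_in_cell >= params.focus_edge_margin)
    )

    mean_rate = params.focus_rate_intercept + params.focus_rate_slope * dose
    any_nucleus = nucleus_labels > 0
    nucleus_rim = any_nucleus & ~ndimage.binary_erosion(
        any_nucleus, structure=np.ones((3, 3), dtype=bool)
    )
    fid = 0
    cell_ids = np.unique(cell_labels)
    cell_ids = cell_ids[cell_ids > 0]
    for cid in cell_ids:
        allowed = core & (cell_labels == cid)
        coords = np.argwhere(allowed)
        n_foci = int(rng.poisson(mean_rate))
        n_nuc = int(rng.poisson(params.n_nuclear_foci_per_cell)) \
            if params.n_nuclear_foci_per_cell > 0 else 0

        for compartment, n in (("cytoplasmic", n_foci), ("nuclear", n_nuc)):
            if compartment == "nuclear":
                # centre on the nucleus rim so the pixel set overlaps it
                coords_c = np.argwhere(nucleus_rim & (nucleus_labels == cid))
            else:
                coords_c = coords
            for _ in range(n):
                area = int(rng.integers(params.focus_area[0], params.focus_area[1] + 1))
                offsets = digital_disk(area)
                placed = False
                for _try in range(params.max_placement_tries):
                    if len(coords_c) == 0:
                        break
                    ctr = coords_c[rng.integers(len(coords_c))]
                    pix = ctr[None, :] + offsets
                    if (pix < 0).any() or (pix[:, 0] >= shape[0]).any() \
                            or (pix[:, 1] >= shape[1]).any():
                        continue
                    pr, pc = pix[:, 0], pix[:, 1]
                    if forbidden[pr, pc].any():
                        continue
                    if compartment == "cytoplasmic":
                        if not core[pr, pc].all() or not (cell_labels[pr, pc] == cid).all():
                            continue
                    else:
                        # must overlap the nucleus and stay inside the cell
                        if not (cell_labels[pr, pc] == cid).all():
                            continue
                        if not (nucleus_labels[pr, pc] == cid).any():
                            continue
                    records.append(
                        dict(
                            focus_id=fid,
                            cell_id=int(cid),
                            row=float(pix[:, 0].mean()),
                            col=float(pix[:, 1].mean()),
                            area_px=area,
                            compartment=compartment,
                        )
                    )
                    pixel_sets.append(pix)
                    _forbid(pix)
                    fid += 1
                    placed = True
                    break
                if not placed:
                    raise PlacementError(
                        f"could not place a {compartment} focus of area {area} px "
                        f"in cell {cid} after {params.max_placement_tries} tries "
                        "(compartment margins or spacing too tight)"
                    )
    foci = pd.DataFrame(
        records,
        columns=["focus_id", "cell_id", "row", "col", "area_px", "compartment"],
    )
    return foci, pixel_sets


def generate_field(
    params: ImagingTruthParams,
    dose_gy: float,
    quality: str = "xray",
    field_index: int = 0,
) -> tuple[FieldOfView, GroundTruth]:
    """Render one three-channel field with exact ground truth.

    Foci per cell are Poisson with mean
    ``focus_rate_intercept + focus_rate_slope * dose_gy``; the nuclear
    area of the dsDNA channel is rendered at ``nuclear_dsdna_level`` and
    the whole channel clipped at ``nuclear_saturation_level``.  The same
    ``(params, dose, field_index)`` always yields bit-identical output.
    """
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    rng = _substream(params.seed, field_index)
    shape = params.image_shape

    if params.n_cells == 0:
        nucleus_labels = np.zeros(shape, dtype=np.int32)
        cell_labels = np.zeros(shape, dtype=np.int32)
        foci = pd.DataFrame(
            columns=["focus_id", "cell_id", "row", "col", "area_px", "compartment"]
        )
        pixel_sets: list[np.ndarray] = []
    else:
        nucleus_labels, cell_labels = _place_cells(params, rng)
        foci, pixel_sets = _plant_foci(params, dose_gy, nucleus_labels, cell_labels, rng)

    dsdna = np.full(shape, params.background, dtype=np.float64)
    for pix in pixel_sets:
        dsdna[pix[:, 0], pix[:, 1]] += params.focus_amplitude
    if params.nuclear_dsdna_level > 0:
        dsdna[nucleus_labels > 0] = params.nuclear_dsdna_level

    nucleus_stain = np.full(shape, params.background / 2.0, dtype=np.float64)
    nucleus_stain[nucleus_labels > 0] = params.nucleus_stain_level
    cytoplasm_stain = np.full(shape, params.background / 2.0, dtype=np.float64)
    cytoplasm_stain[cell_labels > 0] = params.cytoplasm_stain_level

    if params.psf_sigma > 0:
        dsdna = ndimage.gaussian_filter(dsdna, params.psf_sigma)
        nucleus_stain = ndimage.gaussian_filter(nucleus_stain, params.psf_sigma)
        cytoplasm_stain = ndimage.gaussian_filter(cytoplasm_stain, params.psf_sigma)
    if params.noise_sd > 0:
        dsdna = dsdna + rng.normal(0.0, params.noise_sd, shape)
        nucleus_stain = nucleus_stain + rng.normal(0.0, params.noise_sd, shape)
        cytoplasm_stain = cytoplasm_stain + rng.normal(0.0, params.noise_sd, shape)

    dsdna = np.clip(dsdna, 0.0, params.nuclear_saturation_level)
    nucleus_stain = np.clip(nucleus_stain, 0.0, None)
    cytoplasm_stain = np.clip(cytoplasm_stain, 0.0, None)

    fov = FieldOfView(
        dsdna=dsdna,
        nucleus_stain=nucleus_stain,
        cytoplasm_stain=cytoplasm_stain,
        field_id=f"{quality}_{dose_gy:g}Gy_f{field_index}",
        dose_gy=float(dose_gy),
        quality=quality,
    )
    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        foci=foci,
        foci_pixels=pixel_sets,
    )
    return fov, truth


# ---------------------------------------------------------------------------
# clonogenic survival
# ---------------------------------------------------------------------------


def lq_survival(dose: np.ndarray | float, alpha: float, beta: float) -> np.ndarray | float:
    """Linear-quadratic survival ``S(D) = exp(-alpha*D - beta*D**2)``."""
    d = np.asarray(dose, dtype=float)
    s = np.exp(-(alpha * d + beta * d * d))
    return s if s.ndim else float(s)


@dataclass(frozen=True)
class SurvivalTruthParams:
    """True linear-quadratic parameters of a simulated colony assay.

    ``n_seeded`` may be one integer, or a mapping dose -> cells seeded
    (in a real assay more cells are seeded at higher doses to aim for a
    statistically useful ~100 colonies per flask).
    """

    alpha: float = 0.3
    beta: float = 0.03
    plating_efficiency: float = 0.5
    n_seeded: int | Mapping[float, int] = 500
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    replicates: int = 3
    quality: str = "xray"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0 < self.plating_efficiency <= 1):
            raise ValueError("plating_efficiency must be in (0, 1]")


def generate_survival_data(params: SurvivalTruthParams) -> pd.DataFrame:
    """Simulate a colony-forming assay.

    Per flask, colonies ~ Binomial(n_seeded, PE * S(D)) with the LQ law
    above.  Columns: ``dose_gy, quality, replicate, cells_seeded,
    colonies``.  A 0 Gy dose is required (it defines plating
    efficiency downstream).
    """
    if 0.0 not in [float(d) for d in params.doses]:
        raise ValueError("doses must include 0 Gy (plating-efficiency control)")
    rng = _substream(params.seed, 1)
    rows = []
    for dose in params.doses:
        if isinstance(params.n_seeded, Mapping):
            seeded = int(params.n_seeded[dose])
        else:
            seeded = int(params.n_seeded)
        p = params.plating_efficiency * lq_survival(dose, params.alpha, params.beta)
        for rep in range(1, params.replicates + 1):
            colonies = int(rng.binomial(seeded, p))
            rows.append(
                dict(
                    dose_gy=float(dose),
                    quality=params.quality,
                    replicate=rep,
                    cells_seeded=seeded,
                    colonies=colonies,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression (qPCR + RNA-seq style FPKM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRDesign:
    """Sample layout of a qPCR run: biological samples per condition and
    technical replicate wells per (sample, gene)."""

    conditions: tuple[str, ...] = ("0Gy", "8Gy")
    control_condition: str = "0Gy"
    n_samples: int = 3
    n_tech_replicates: int = 2

    def __post_init__(self) -> None:
        if self.control_condition not in self.conditions:
            raise ValueError("control_condition must appear in conditions")


@dataclass(frozen=True)
class ExpressionTruthParams:
    """Truth for expression simulators (Cq tables and FPKM matrices).

    ``true_fold_changes`` maps target gene -> {condition: fold change
    relative to the control condition}; reference genes are stable by
    construction unless ``reference_shifts`` perturbs them.
    """

    # qPCR side
    reference_genes: tuple[str, ...] = ("Gapdh", "Rpl13a")
    true_fold_changes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"Ifnb1": {"8Gy": 4.0}, "Trex1": {"8Gy": 2.0}}
    )
    baseline_cq: Mapping[str, float] = field(default_factory=dict)
    cq_noise_sd: float = 0.15
    reference_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # RNA-seq side
    n_genes: int = 500
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"ctrl": 3, "irr": 3}
    )
    de_fraction: float = 0.1
    log2_effect_size: float = 2.0
    fpkm_log2_mean: float = 3.0
    fpkm_log2_sd: float = 1.5
    fpkm_within_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.reference_genes) < 2:
            raise ValueError("at least 2 reference genes are required")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.fpkm_log2_sd <= 0:
            raise ValueError("fpkm_log2_sd must be positive")
        for n in self.group_sizes.values():
            if n < 2:
                raise ValueError("every group needs >= 2 replicates")


_DEFAULT_BASELINES = {"Gapdh": 18.0, "Rpl13a": 20.0, "Ifnb1": 30.0, "Trex1": 25.0}


def generate_cq_table(params: ExpressionTruthParams, design: QPCRDesign) -> pd.DataFrame:
    """Simulate a qPCR Cq table.

    Cq = baseline(gene) - log2(true relative expression in the sample's
    condition) + N(0, cq_noise_sd).  Reference genes have relative
    expression 1 in every condition (optionally shifted by
    ``reference_shifts`` for stability stress tests), so with zero noise
    the downstream ddCt computation recovers ``true_fold_changes``
    exactly.  Columns: ``sample, condition, gene, replicate, cq``.
    """
    rng = _substream(params.seed, 2)
    genes = list(params.reference_genes) + list(params.true_fold_changes)
    rows = []
    for cond in design.conditions:
        for s in range(1, design.n_samples + 1):
            sample = f"{cond}_s{s}"
            for gene in genes:
                base = params.baseline_cq.get(
                    gene, _DEFAULT_BASELINES.get(gene, 24.0)
                )
                if gene in params.reference_genes:
                    rel = 1.0
                    shift = params.reference_shifts.get(gene, {}).get(cond, 0.0)
                else:
                    rel = 1.0 if cond == design.control_condition else \
                        float(params.true_fold_changes[gene].get(cond, 1.0))
                    shift = 0.0
                cq0 = base - np.log2(rel) + shift
                for rep in range(1, design.n_tech_replicates + 1):
                    noise = rng.normal(0.0, params.cq_noise_sd) if params.cq_noise_sd > 0 else 0.0
                    rows.append(
                        dict(sample=sample, condition=cond, gene=gene,
                             replicate=rep, cq=cq0 + noise)
                    )
    return pd.DataFrame(rows)


def generate_expression_matrix(
    params: ExpressionTruthParams,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a gene x sample FPKM matrix with planted DE genes.

    A random ``de_fraction`` of genes receive a log2 shift of
    ``log2_effect_size`` (random sign) in every non-first group.  Sample
    values are log-normal: log2 FPKM = gene baseline + effect +
    N(0, fpkm_within_sd).

    Returns
    -------
    (matrix, groups, truth)
        ``matrix``: genes x samples FPKM DataFrame; ``groups``: sample ->
        group label; ``truth``: per gene ``is_de`` flag and
        ``true_log2fc``.
    """
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if len(params.group_sizes) < 2:
        raise ValueError("need at least 2 groups")
    rng = _substream(params.seed, 3)
    genes = [f"G{i:05d}" for i in range(1, params.n_genes + 1)]
    group_names = list(params.group_sizes)
    samples, labels = [], []
    for g in group_names:
        for r in range(1, params.group_sizes[g] + 1):
            samples.append(f"{g}_{r}")
            labels.append(g)
    groups = pd.Series(labels, index=samples, name="group")

    base = rng.normal(params.fpkm_log2_mean, params.fpkm_log2_sd, params.n_genes)
    n_de = int(round(params.de_fraction * params.n_genes))
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(params.n_genes)
    log2fc[de_idx] = sign * params.log2_effect_size

    data = np.empty((params.n_genes, len(samples)))
    for j, g in enumerate(groups):
        effect = log2fc if g != group_names[0] else 0.0
        noise = rng.normal(0.0, params.fpkm_within_sd, params.n_genes) \
            if params.fpkm_within_sd > 0 else 0.0
        data[:, j] = 2.0 ** (base + effect + noise)
    matrix = pd.DataFrame(data, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"is_de": log2fc != 0.0, "true_log2fc": log2fc}, index=genes
    )
    return matrix, groups, truth
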