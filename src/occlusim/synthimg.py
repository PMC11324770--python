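"""Seeded generator of synthetic three-channel epithelial monolayer fields.

Emulates a confluent "cobblestone" alveolar epithelial monolayer imaged in
three fluorescence channels — nuclei (Hoechst-like), whole-cell
(CellMask-like) and tight-junction (anti-occludin-like) — together with the
ground truth (cell labels, membrane skeleton, true junction mask) needed to
validate the quantification pipeline.

Geometry is a Voronoi tessellation of rejection-sampled nucleus centers with
a minimum separation of twice the nucleus radius.  Membranes are rendered as
intensity *dips* in the whole-cell channel (the segmentation pipeline inverts
that channel to turn them into watershed ridges).  Junction dropout under
compound treatment is segment-wise: whole shared cell-cell edges lose signal,
producing the contiguous gaps seen in degraded epithelium rather than
salt-and-pepper loss.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import disk

__all__ = [
    "MonolayerSpec",
    "FieldGroundTruth",
    "FieldImages",
    "PackingError",
    "generate_field",
    "iter_plate_fields",
    "simulate_plate",
    "default_layout",
    "default_concentration_series",
    "write_field",
    "read_field",
    "hill_integrity",
    "hill_cell_loss",
]

MAX_UINT16 = 65535


class PackingError(ValueError):
    """Raised when the requested cell count cannot be packed at the minimum
    center separation within the field."""


@dataclasses.dataclass(frozen=True)
class MonolayerSpec:
    """Parameters of one synthetic monolayer field.

    ``junction_integrity`` is the fraction of total membrane-skeleton length
    carrying junction signal (1 = healthy, 0 = fully disrupted) and
    ``cell_loss_fraction`` the fraction of cells lost to cytotoxicity.
    Intensity levels are in arbitrary camera units on a 16-bit scale.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    n_cells: int = 64
    pixel_size_um: float = 0.325
    junction_integrity: float = 1.0
    cell_loss_fraction: float = 0.0
    noise_sd: float = 20.0
    background_level: float = 100.0
    cytoplasm_level: float = 1000.0
    membrane_dip: float = 600.0
    junction_level: float = 2000.0
    nucleus_level: float = 3000.0
    nucleus_radius_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.junction_integrity <= 1.0:
            raise ValueError("junction_integrity must be in [0, 1]")
        if not 0.0 <= self.cell_loss_fraction < 1.0:
            raise ValueError("cell_loss_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("background_level", "cytoplasm_level", "membrane_dip",
                     "junction_level", "nucleus_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.effective_n_cells < 1:
            raise ValueError("effective cell count must be >= 1")

    @property
    def effective_n_cells(self) -> int:
        """Cell count after cytotoxic loss: round(n_cells * (1 - loss))."""
        return int(round(self.n_cells * (1.0 - self.cell_loss_fraction)))


@dataclasses.dataclass
class FieldGroundTruth:
    """Ground truth for one field: label grid (0 = none), nucleus centers,
    1-px membrane skeleton and the true junction mask (skeleton subset
    dilated by 1 px)."""

    cell_label_grid: np.ndarray
    nucleus_centers: np.ndarray  # (n, 2) float, (row, col)
    membrane_skeleton: np.ndarray
    true_junction_mask: np.ndarray


@dataclasses.dataclass
class FieldImages:
    """One microscopy field: three co-registered non-negative intensity
    grids plus the physical pixel scale in micrometres per pixel."""

    nuclei_channel: np.ndarray
    cellmask_channel: np.ndarray
    junction_channel: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {self.nuclei_channel.shape, self.cellmask_channel.shape,
                  self.junction_channel.shape}
        if len(shapes) != 1:
            raise ValueError("all three channels must share one shape")
        for ch in (self.nuclei_channel, self.cellmask_channel,
                   self.junction_channel):
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError("intensities must be finite and >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def _sample_centers(rng: np.random.Generator, n: int, height: int, width: int,
                    min_sep: float) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    centers: list[tuple[float, float]] = []
    max_attempts = 2000 * n + 1000
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} cells with minimum separation "
                f"{min_sep:.1f} px in a {height}x{width} field")
        attempts += 1
        # keep rounded centers strictly inside the grid
        r = rng.uniform(0.5, height - 0.5)
        c = rng.uniform(0.5, width - 0.5)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep ** 2
               for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float)


def _membrane_skeleton(labels: np.ndarray) -> np.ndarray:
    """1-px inter-cell boundary: a pixel whose right or lower 4-neighbour
    carries a different label.  Image-border pixels are not boundaries."""
    skel = np.zeros(labels.shape, dtype=bool)
    skel[:-1, :] |= labels[:-1, :] != labels[1:, :]
    skel[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return skel


def _edge_segments(labels: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Group skeleton pixels by the (unordered) pair of cell labels whose
    shared edge they mark."""
    segments: dict[tuple[int, int], list[tuple[int, int]]] = {}
    h, w = labels.shape
    down_diff = labels[:-1, :] != labels[1:, :]
    right_diff = labels[:, :-1] != labels[:, 1:]
    for i, j in zip(*np.nonzero(down_diff)):
        pair = (min(labels[i, j], labels[i + 1, j]),
                max(labels[i, j], labels[i + 1, j]))
        segments.setdefault(pair, []).append((int(i), int(j)))
    for i, j in zip(*np.nonzero(right_diff)):
        pair = (min(labels[i, j], labels[i, j + 1]),
                max(labels[i, j], labels[i, j + 1]))
        px = (int(i), int(j))
        bucket = segments.setdefault(pair, [])
        if px not in bucket:
            bucket.append(px)
    return segments


def _select_junction_pixels(rng: np.random.Generator,
                            segments: dict[tuple[int, int], list[tuple[int, int]]],
                            total_px: int, integrity: float) -> np.ndarray | None:
    """Choose whole edges (and a partial final edge) until the selected
    skeleton length reaches integrity * total length."""
    if integrity >= 1.0:
        return None  # sentinel: take the full skeleton
    target = integrity * total_px
    if target <= 0:
        return np.empty((0, 2), dtype=int)
    keys = sorted(segments.keys())
    order = rng.permutation(len(keys))
    chosen: list[tuple[int, int]] = []
    acc = 0
    for k in order:
        pixels = segments[keys[k]]
        if acc + len(pixels) <= target:
            chosen.extend(pixels)
            acc += len(pixels)
        else:
            need = int(round(target - acc))
            if need > 0:
                idx = rng.choice(len(pixels), size=need, replace=False)
                chosen.extend(pixels[i] for i in idx)
            break
    return np.asarray(chosen, dtype=int).reshape(-1, 2)


def _render_nuclei(shape: tuple[int, int], centers: np.ndarray,
                   level: float, radius: float) -> np.ndarray:
    """Gaussian blobs (sigma = radius / 2.5) at each nucleus center; the
    sigma is chosen so blobs stay disjoint at the enforced 2 x radius
    center separation once thresholded."""
    img = np.zeros(shape, dtype=float)
    sigma = radius / 2.5
    half = int(np.ceil(3 * sigma))
    h, w = shape
    for r, c in centers:
        r0, c0 = int(round(r)), int(round(c))
        rs = slice(max(0, r0 - half), min(h, r0 + half + 1))
        cs = slice(max(0, c0 - half), min(w, c0 + half + 1))
        rr, cc = np.mgrid[rs, cs]
        img[rs, cs] += level * np.exp(-((rr - r) ** 2 + (cc - c) ** 2)
                                      / (2 * sigma ** 2))
    return img


def generate_field(spec: MonolayerSpec) -> tuple[FieldImages, FieldGroundTruth]:
    """Generate one synthetic field and its ground truth.

    Deterministic: the same spec (including ``seed``) yields bit-identical
    output.  Raises :class:`PackingError` when ``n_cells`` cannot be placed
    at the minimum center separation (2 x nucleus radius).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    n_eff = spec.effective_n_cells
    min_sep = 2.0 * spec.nucleus_radius_px
    centers = _sample_centers(rng, n_eff, h, w, min_sep)

    # Voronoi tessellation by nearest-center assignment (labels 1..n_eff).
    tree = cKDTree(centers)
    rr, cc = np.mgrid[0:h, 0:w]
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    labels = (nearest + 1).astype(np.int32).reshape(h, w)

    skeleton = _membrane_skeleton(labels)
    segments = _edge_segments(labels)
    total_px = int(skeleton.sum())

    selected = _select_junction_pixels(rng, segments, total_px,
                                       spec.junction_integrity)
    junction_skel = np.zeros((h, w), dtype=bool)
    if selected is None:
        junction_skel = skeleton.copy()
    elif len(selected):
        junction_skel[selected[:, 0], selected[:, 1]] = True
    true_junction = ndi.binary_dilation(junction_skel, structure=disk(1))

    nuclei = spec.background_level + _render_nuclei(
        (h, w), centers, spec.nucleus_level, spec.nucleus_radius_px)
    cellmask = np.full((h, w), spec.cytoplasm_level, dtype=float)
    cellmask[skeleton] -= spec.membrane_dip
    cellmask = np.maximum(cellmask, 0.0) + spec.background_level
    junction = np.full((h, w), spec.background_level, dtype=float)
    junction[true_junction] += spec.junction_level

    if spec.noise_sd > 0:
        nuclei = nuclei + rng.normal(0.0, spec.noise_sd, (h, w))
        cellmask = cellmask + rng.normal(0.0, spec.noise_sd, (h, w))
        junction = junction + rng.normal(0.0, spec.noise_sd, (h, w))
    nuclei = np.clip(nuclei, 0.0, None)
    cellmask = np.clip(cellmask, 0.0, None)
    junction = np.clip(junction, 0.0, None)

    images = FieldImages(nuclei, cellmask, junction, spec.pixel_size_um)
    truth = FieldGroundTruth(labels, centers, skeleton, true_junction)
    return images, truth


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------

def default_concentration_series() -> np.ndarray:
    """9-point 1:3 serial dilution from 100 uM (lowest point 15.2 nM)."""
    return 100.0 / 3.0 ** np.arange(9)


def default_layout(compound_id: str = "CMPD",
                   n_replicate_wells: int = 2,
                   n_vehicle_wells: int = 2) -> pd.DataFrame:
    """Default single-compound plate layout: a 9-point series in duplicate
    plus vehicle (1% DMSO) wells.

    Returns a table with columns ``well_id, compound_id, concentration_um,
    role`` (role is ``vehicle`` or ``treated``).
    """
    rows = []
    series = default_concentration_series()
    well = 0
    for conc in series:
        for rep in range(n_replicate_wells):
            rows.append({"well_id": f"W{well:02d}", "compound_id": compound_id,
                         "concentration_um": float(conc), "role": "treated",
                         "replicate": rep + 1})
            well += 1
    for rep in range(n_vehicle_wells):
        rows.append({"well_id": f"W{well:02d}", "compound_id": compound_id,
                     "concentration_um": 0.0, "role": "vehicle",
                     "replicate": rep + 1})
        well += 1
    return pd.DataFrame(rows)


def hill_integrity(conc_um: float, ic50_um: float, hill: float) -> float:
    """Junction integrity under treatment: 1 / (1 + (c / IC50)^h)."""
    if conc_um <= 0:
        return 1.0
    return 1.0 / (1.0 + (conc_um / ic50_um) ** hill)


def hill_cell_loss(conc_um: float, ec50_um: float, hill: float) -> float:
    """Cytotoxic cell-loss fraction: 1 - 1 / (1 + (c / EC50)^h)."""
    if conc_um <= 0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + (conc_um / ec50_um) ** hill)


def _field_seed(master_seed: int, plate: str, well_id: str, field: int) -> int:
    """Counter-based seed splitting: master seed + (plate, well, field)
    entropy through a SeedSequence; any single field is regenerable alone."""
    key = [int(master_seed)]
    for token in (plate, well_id):
        key.extend(token.encode())
    key.append(int(field))
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def iter_plate_fields(layout: pd.DataFrame,
                      pharmacology: dict,
                      base_spec: MonolayerSpec,
                      fields_per_well: int = 16,
                      seed: int = 0,
                      plate_id: str = "P1"):
    """Lazily generate every field of a screening plate.

    ``pharmacology`` carries ``junction_ic50_um, junction_hill`` and
    optionally ``viability_ec50_um, viability_hill`` (omit for no cytotoxic
    confound).  For a well at concentration c the generated field has
    integrity 1/(1+(c/IC50)^h) and cell loss 1 - 1/(1+(c/EC50)^h); vehicle
    wells use integrity 1 and loss 0.  Per-field seeds are derived
    deterministically from the master seed and the (plate, well, field)
    coordinates, so any single field is regenerable in isolation.

    Yields ``(manifest_row_dict, FieldImages, FieldGroundTruth)``.
    """
    required = {"well_id", "concentration_um", "role"}
    if not required.issubset(layout.columns):
        raise ValueError(f"layout must have columns {sorted(required)}")
    if not (layout["role"] == "vehicle").any():
        raise ValueError("layout must contain at least one vehicle well")
    treated = layout[layout["role"] == "treated"]
    if (treated["concentration_um"] <= 0).any():
        raise ValueError("treated concentrations must be strictly positive")

    ic50 = float(pharmacology["junction_ic50_um"])
    jhill = float(pharmacology.get("junction_hill", 1.0))
    via_ec50 = pharmacology.get("viability_ec50_um")
    via_hill = float(pharmacology.get("viability_hill", 1.0))

    for _, row in layout.iterrows():
        conc = float(row["concentration_um"])
        if row["role"] == "vehicle":
            integrity, loss = 1.0, 0.0
        else:
            integrity = hill_integrity(conc, ic50, jhill)
            loss = (hill_cell_loss(conc, float(via_ec50), via_hill)
                    if via_ec50 is not None else 0.0)
        for f in range(fields_per_well):
            fseed = _field_seed(seed, plate_id, str(row["well_id"]), f)
            spec = dataclasses.replace(base_spec,
                                       junction_integrity=integrity,
                                       cell_loss_fraction=loss,
                                       seed=fseed)
            images, truth = generate_field(spec)
            rec = {"plate": plate_id, "well": row["well_id"], "field": f,
                   "compound": row.get("compound_id", "CMPD"),
                   "concentration_um": conc, "role": row["role"],
                   "path_nuc": "", "path_mask": "", "path_junc": ""}
            yield rec, images, truth


def simulate_plate(layout: pd.DataFrame,
                   pharmacology: dict,
                   base_spec: MonolayerSpec,
                   fields_per_well: int = 16,
                   seed: int = 0,
                   out_dir: str | Path | None = None,
                   plate_id: str = "P1") -> tuple[list, pd.DataFrame]:
    """Simulate a full screening plate (see :func:`iter_plate_fields`).

    If ``out_dir`` is given the TIFF triplets and ground truth are written
    to disk and the manifest carries their paths; otherwise fields stay in
    memory only.  Returns ``(fields, manifest)`` where fields is a list of
    ``(FieldImages, FieldGroundTruth)`` in manifest row order.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    fields = []
    manifest_rows = []
    for rec, images, truth in iter_plate_fields(
            layout, pharmacology, base_spec, fields_per_well, seed,
            plate_id):
        fields.append((images, truth))
        if out is not None:
            base = f"{plate_id}_{rec['well']}_f{rec['field']:02d}"
            paths = write_field(images, truth, out, base)
            rec.update(path_nuc=str(paths["nuc"]),
                       path_mask=str(paths["mask"]),
                       path_junc=str(paths["junc"]))
        manifest_rows.append(rec)
    manifest = pd.DataFrame(manifest_rows)
    if out is not None:
        manifest.to_csv(out / f"{plate_id}_manifest.csv", index=False)
    return fields, manifest


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_field(images: FieldImages, truth: FieldGroundTruth | None,
                directory: str | Path, basename: str) -> dict[str, Path]:
    """Write a field as three 16-bit grayscale TIFFs plus ground truth
    (label-grid TIFF and centers CSV).

    Intensities are quantized by rounding to the nearest integer; values
    above 65535 raise rather than clip silently.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    channels = {"nuc": images.nuclei_channel, "mask": images.cellmask_channel,
                "junc": images.junction_channel}
    for tag, grid in channels.items():
        q = np.round(grid)
        if q.max() > MAX_UINT16:
            raise ValueError(
                f"channel '{tag}' exceeds the 16-bit range (max {q.max():.0f})")
        path = directory / f"{basename}_{tag}.tif"
        tifffile.imwrite(path, q.astype(np.uint16))
        paths[tag] = path
    if truth is not None:
        lpath = directory / f"{basename}_labels.tif"
        if truth.cell_label_grid.max() > MAX_UINT16:
            raise ValueError("too many cell labels for uint16 storage")
        tifffile.imwrite(lpath, truth.cell_label_grid.astype(np.uint16))
        paths["labels"] = lpath
        cpath = directory / f"{basename}_centers.csv"
        pd.DataFrame(truth.nucleus_centers,
                     columns=["row", "col"]).to_csv(cpath, index=False)
        paths["centers"] = cpath
    return paths


def read_field(path_nuc: str | Path, path_mask: str | Path,
               path_junc: str | Path, pixel_size_um: float) -> FieldImages:
    """Read a TIFF triplet back into a :class:`FieldImages`."""
    return FieldImages(
        tifffile.imread(path_nuc).astype(float),
        tifffile.imread(path_mask).astype(float),
        tifffile.imread(path_junc).astype(float),
        pixel_size_um,
    )
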