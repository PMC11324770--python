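"""Quantification of junctional (occludin) staining at the cell membrane.

The pipeline mirrors a high-content-screening membrane/junction readout:

1. nuclei are segmented and enumerated from the nuclear channel;
2. the whole-cell channel is inverted (membranes stain as dim ridges) and
   flooded by a marker-controlled watershed seeded at the nuclei, giving a
   1-pixel outline of all cell membranes;
3. the outline is grown by 10 px on either side (Euclidean disk dilation) to
   a membrane band;
4. the junction channel is thresholded, skeletonized and grown the same way;
5. per-field areas are the thresholded staining area inside the band, in
   um^2, totalled over the whole image; per-well metrics are field means
   normalized to the mean nuclei count.

Coordinates are (row, col), 0-based.  Boundary tests use 4-connectivity,
connected components 8-connectivity.  Thresholds are Otsu per channel per
field, so all masks are invariant to a global intensity rescaling.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, skeletonize
from skimage.segmentation import watershed

from .synthimg import FieldImages

__all__ = [
    "NucleiParams",
    "JunctionParams",
    "QuantifyParams",
    "NucleiResult",
    "MembraneSegmentation",
    "FieldMetrics",
    "WellMetrics",
    "count_nuclei",
    "segment_membranes",
    "junction_band",
    "field_metrics",
    "aggregate_well",
    "analyze_manifest",
]


@dataclasses.dataclass(frozen=True)
class NucleiParams:
    smooth_sigma_px: float = 2.0
    threshold_method: str = "otsu"
    min_area_px: int = 20
    max_area_px: int = 2000
    min_separation_px: int = 7


@dataclasses.dataclass(frozen=True)
class JunctionParams:
    threshold_method: str = "otsu"
    min_area_px: int = 10
    #: "skeletonize" thresholds then reduces the stain to 1-px curves before
    #: growing; "dilate" grows the raw threshold mask directly.
    mode: str = "skeletonize"


@dataclasses.dataclass(frozen=True)
class QuantifyParams:
    nuclei: NucleiParams = NucleiParams()
    junction: JunctionParams = JunctionParams()
    grow_halfwidth_px: int = 10
    #: include boundaries against the image border in the outline mask
    include_image_border: bool = False
    #: per-well normalization: "ratio_of_means" (default) or "mean_of_ratios"
    normalization: str = "ratio_of_means"


@dataclasses.dataclass
class NucleiResult:
    count: int
    label_grid: np.ndarray
    centers: np.ndarray  # (n, 2) float (row, col)


@dataclasses.dataclass
class MembraneSegmentation:
    cell_label_grid: np.ndarray
    outline_mask: np.ndarray
    band_mask: np.ndarray
    #: set when no nuclei were available to seed the watershed
    empty: bool = False


@dataclasses.dataclass
class FieldMetrics:
    nuclei_count: int
    membrane_area_um2: float
    junction_at_membrane_area_um2: float


@dataclasses.dataclass
class WellMetrics:
    mean_nuclei_count: float
    membrane_area_per_cell_um2: float
    junction_area_per_cell_um2: float
    n_fields: int
    #: set when the mean nuclei count is zero and per-cell values undefined
    undefined_per_cell: bool = False


def _remove_small(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than min_area_px pixels."""
    if min_area_px <= 1 or not mask.any():
        return mask
    comps = cc_label(mask, connectivity=2)
    sizes = np.bincount(comps.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[comps]


def _otsu(grid: np.ndarray) -> float | None:
    """Otsu threshold; None for a constant image (nothing to separate)."""
    if np.ptp(grid) == 0:
        return None
    return threshold_otsu(grid)


def count_nuclei(nuclei_channel: np.ndarray,
                 params: NucleiParams = NucleiParams()) -> NucleiResult:
    """Segment and enumerate nuclei.

    Gaussian smooth -> Otsu threshold -> size filter -> split touching blobs
    by a distance-transform local-maxima watershed with a minimum peak
    separation.  An all-constant image yields count 0.
    """
    grid = np.asarray(nuclei_channel, dtype=float)
    if grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("nuclei channel must be non-empty and finite")
    smoothed = gaussian(grid, sigma=params.smooth_sigma_px,
                        preserve_range=True)
    thr = _otsu(smoothed)
    if thr is None:
        return NucleiResult(0, np.zeros(grid.shape, dtype=np.int32),
                            np.empty((0, 2)))
    mask = smoothed > thr
    mask = _remove_small(mask, params.min_area_px)
    comps = cc_label(mask, connectivity=2)
    # drop oversized components
    sizes = np.bincount(comps.ravel())
    too_big = np.nonzero(sizes > params.max_area_px)[0]
    for lbl in too_big:
        if lbl != 0:
            mask[comps == lbl] = False
    if not mask.any():
        return NucleiResult(0, np.zeros(grid.shape, dtype=np.int32),
                            np.empty((0, 2)))
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=params.min_separation_px,
                           exclude_border=False)
    markers = np.zeros(grid.shape, dtype=np.int32)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    # relabel consecutively and compute centroids (vectorized)
    ids, inv = np.unique(labels, return_inverse=True)
    inv = inv.reshape(labels.shape)
    offset = 1 if ids[0] == 0 else 0
    out = (inv + (1 - offset)).astype(np.int32)
    out[labels == 0] = 0
    n = len(ids) - offset
    rr, cc = np.nonzero(out)
    vals = out[rr, cc]
    counts = np.bincount(vals, minlength=n + 1)[1:]
    rows = np.bincount(vals, weights=rr, minlength=n + 1)[1:] / counts
    cols = np.bincount(vals, weights=cc, minlength=n + 1)[1:] / counts
    return NucleiResult(n, out, np.column_stack([rows, cols]))


def _outline_from_labels(labels: np.ndarray,
                         include_border: bool) -> np.ndarray:
    """1-px outline: pixels whose right or lower 4-neighbour carries a
    different nonzero label (optionally also the image border)."""
    outline = np.zeros(labels.shape, dtype=bool)
    down = (labels[:-1, :] != labels[1:, :]) & (labels[:-1, :] > 0) \
        & (labels[1:, :] > 0)
    right = (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) \
        & (labels[:, 1:] > 0)
    outline[:-1, :] |= down
    outline[:, :-1] |= right
    if include_border:
        outline[0, :] = outline[-1, :] = True
        outline[:, 0] = outline[:, -1] = True
    return outline


def segment_membranes(cellmask_channel: np.ndarray,
                      nuclei: NucleiResult,
                      grow_halfwidth_px: int = 10,
                      include_image_border: bool = False) -> MembraneSegmentation:
    """Invert the whole-cell channel and run a marker-controlled watershed
    seeded at the nuclei; derive the 1-px membrane outline and the grown
    band (Euclidean disk dilation of radius ``grow_halfwidth_px``)."""
    grid = np.asarray(cellmask_channel, dtype=float)
    if nuclei.count == 0:
        warnings.warn("no nuclei to seed the watershed; empty segmentation",
                      stacklevel=2)
        z = np.zeros(grid.shape, dtype=bool)
        return MembraneSegmentation(np.zeros(grid.shape, dtype=np.int32),
                                    z, z.copy(), empty=True)
    inverted = grid.max() - grid
    # seed from nucleus centroids: a full nucleus blob near a cell edge
    # could spill over the 1-px membrane ridge and bias the watershed line
    markers = np.zeros(grid.shape, dtype=np.int32)
    for k, (r, c) in enumerate(nuclei.centers, start=1):
        markers[int(round(r)), int(round(c))] = k
    cells = watershed(inverted, markers)
    outline = _outline_from_labels(cells, include_image_border)
    band = ndi.binary_dilation(outline, structure=disk(grow_halfwidth_px)) \
        if outline.any() else outline.copy()
    return MembraneSegmentation(cells.astype(np.int32), outline, band)


def _junction_stain_mask(junction_channel: np.ndarray,
                         params: JunctionParams) -> np.ndarray:
    """Thresholded, despeckled junction staining (no inversion needed given
    the specific staining pattern)."""
    grid = np.asarray(junction_channel, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("junction channel must be finite")
    thr = _otsu(grid)
    if thr is None:
        return np.zeros(grid.shape, dtype=bool)
    return _remove_small(grid > thr, params.min_area_px)


def junction_band(junction_channel: np.ndarray,
                  params: JunctionParams = JunctionParams(),
                  grow_halfwidth_px: int = 10) -> np.ndarray:
    """Thickened junction mask: threshold the raw junction channel,
    despeckle, skeletonize to 1-px curves and grow by the same disk radius
    as the membrane band."""
    mask = _junction_stain_mask(junction_channel, params)
    if not mask.any():
        return mask
    if params.mode == "skeletonize":
        core = skeletonize(mask)
    elif params.mode == "dilate":
        core = mask
    else:
        raise ValueError(f"unknown junction mode {params.mode!r}")
    return ndi.binary_dilation(core, structure=disk(grow_halfwidth_px))


def field_metrics(images: FieldImages,
                  params: QuantifyParams = QuantifyParams()) -> FieldMetrics:
    """Quantify one field.

    membrane area = (thresholded cell-mask staining AND membrane band)
    pixels x um^2/px; junction-at-membrane area = thresholded junction
    *staining* within the overlay of the thickened junction mask and the
    membrane band, again x um^2/px.  Both are totalled over the entire
    image.
    """
    nuc = count_nuclei(images.nuclei_channel, params.nuclei)
    seg = segment_membranes(images.cellmask_channel, nuc,
                            params.grow_halfwidth_px,
                            params.include_image_border)
    stain = _junction_stain_mask(images.junction_channel, params.junction)
    jband = junction_band(images.junction_channel, params.junction,
                          params.grow_halfwidth_px)
    px_area = images.pixel_size_um ** 2
    thr = _otsu(images.cellmask_channel)
    cm_mask = images.cellmask_channel > thr if thr is not None \
        else np.zeros(images.cellmask_channel.shape, dtype=bool)
    membrane_area = float(np.count_nonzero(cm_mask & seg.band_mask)) * px_area
    junction_area = float(
        np.count_nonzero(stain & jband & seg.band_mask)) * px_area
    return FieldMetrics(nuc.count, membrane_area, junction_area)


def aggregate_well(fields: list[FieldMetrics],
                   normalization: str = "ratio_of_means") -> WellMetrics:
    """Aggregate per-field metrics to a well.

    Default convention is ratio of means: (mean area over fields) / (mean
    nuclei count over fields), which is robust when individual fields hold
    few cells.  ``mean_of_ratios`` averages per-field per-cell values
    instead.  A zero mean nuclei count flags the per-cell values undefined
    rather than silently emitting NaN.
    """
    if not fields:
        raise ValueError("need at least one field")
    counts = np.array([f.nuclei_count for f in fields], dtype=float)
    mem = np.array([f.membrane_area_um2 for f in fields])
    jun = np.array([f.junction_at_membrane_area_um2 for f in fields])
    mean_count = counts.mean()
    if mean_count == 0:
        return WellMetrics(0.0, 0.0, 0.0, len(fields),
                           undefined_per_cell=True)
    if normalization == "ratio_of_means":
        mem_pc = mem.mean() / mean_count
        jun_pc = jun.mean() / mean_count
    elif normalization == "mean_of_ratios":
        ok = counts > 0
        if not ok.any():
            return WellMetrics(mean_count, 0.0, 0.0, len(fields),
                               undefined_per_cell=True)
        mem_pc = float((mem[ok] / counts[ok]).mean())
        jun_pc = float((jun[ok] / counts[ok]).mean())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return WellMetrics(float(mean_count), float(mem_pc), float(jun_pc),
                       len(fields))


def analyze_manifest(manifest: pd.DataFrame,
                     params: QuantifyParams = QuantifyParams(),
                     pixel_size_um: float = 0.325,
                     fields: list | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every field of a plate manifest and aggregate per well.

    ``fields`` may pass in-memory ``(FieldImages, truth)`` pairs in manifest
    row order to skip re-reading TIFFs.  Returns ``(field_table,
    well_table)`` with the documented CSV schemas.
    """
    from .synthimg import read_field

    frows = []
    for idx, row in manifest.reset_index(drop=True).iterrows():
        if fields is not None:
            images = fields[idx][0]
        else:
            images = read_field(row["path_nuc"], row["path_mask"],
                                row["path_junc"], pixel_size_um)
        fm = field_metrics(images, params)
        frows.append({
            "plate": row["plate"], "well": row["well"], "field": row["field"],
            "compound": row["compound"],
            "concentration_um": row["concentration_um"], "role": row["role"],
            "nuclei_count": fm.nuclei_count,
            "membrane_area_um2": fm.membrane_area_um2,
            "junction_at_membrane_area_um2": fm.junction_at_membrane_area_um2,
        })
    field_table = pd.DataFrame(frows)

    wrows = []
    for (plate, well), grp in field_table.groupby(["plate", "well"], sort=False):
        fms = [FieldMetrics(int(r.nuclei_count), r.membrane_area_um2,
                            r.junction_at_membrane_area_um2)
               for r in grp.itertuples()]
        wm = aggregate_well(fms, params.normalization)
        wrows.append({
            "plate": plate, "well": well,
            "compound": grp["compound"].iloc[0],
            "concentration_um": grp["concentration_um"].iloc[0],
            "role": grp["role"].iloc[0],
            "n_fields": wm.n_fields,
            "mean_nuclei_count": wm.mean_nuclei_count,
            "membrane_area_per_cell_um2": wm.membrane_area_per_cell_um2,
            "junction_area_per_cell_um2": wm.junction_area_per_cell_um2,
            "undefined_per_cell": wm.undefined_per_cell,
        })
    return field_table, pd.DataFrame(wrows)
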