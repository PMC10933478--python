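"""Field segmentation and per-cell measurement for the fixed-cell screen.

Nuclei are segmented from Hoechst by rescale → downsample → median filter →
adaptive (tiled) Otsu → upsample → fill holes → area filter, with touching
nuclei split by distance-transform watershed. Cells come from a seeded
watershed on the thresholded RFP channel, one region per nucleus; cytoplasm
is cell minus nucleus. Intensities are measured on eroded compartment masks
to suppress boundary/over-segmentation error, after scalar background
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed
from skimage.transform import resize

__all__ = [
    "SegmentationParams",
    "LabeledField",
    "subtract_background",
    "segment_nuclei",
    "segment_cells",
    "measure_cells",
    "segment_and_measure",
]


@dataclass
class SegmentationParams:
    """Knobs of the segmentation stage.

    The adaptive Otsu window defaults to roughly 4x the expected nucleus
    diameter; erosion_radius shrinks the intensity-measurement masks.
    """

    rescale_percentiles: tuple[float, float] = (0.5, 99.5)
    downsample: int = 2
    median_radius: int = 2
    adaptive_window: int = 128  # px, at full resolution
    min_area_px: int = 100
    erosion_radius: int = 3
    subtract_bg: bool = True
    expected_nucleus_diameter_px: int = 30

    def __post_init__(self):
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        if self.erosion_radius < 0:
            raise ValueError("erosion radius must be >= 0")


@dataclass
class LabeledField:
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    unsegmentable: list[int]  # nucleus labels without an RFP-positive cell body


def subtract_background(image: np.ndarray, object_mask: np.ndarray) -> np.ndarray:
    """Subtract a scalar background estimated outside all objects.

    The estimate is the median intensity outside the dilated union of object
    masks; the result is clipped at zero.
    """
    image = np.asarray(image, float)
    mask = np.asarray(object_mask, bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image")
    outside = ~ndi.binary_dilation(mask, structure=disk(5))
    if not outside.any():
        raise ValueError("mask covers the entire image; no background sample")
    return (image - np.median(image[outside])).clip(0.0)


def _rescale(image: np.ndarray, percentiles) -> np.ndarray:
    lo, hi = np.percentile(image, percentiles)
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return ((image - lo) / (hi - lo)).clip(0.0, 1.0)


def _adaptive_otsu(image: np.ndarray, window: int) -> np.ndarray:
    """Tiled Otsu: per-block thresholds interpolated to a smooth surface."""
    h, w = image.shape
    ny = max(1, h // window)
    nx = max(1, w // window)
    thr = np.zeros((ny, nx))
    global_thr = threshold_otsu(image) if np.ptp(image) > 0 else np.inf
    for i in range(ny):
        for j in range(nx):
            block = image[i * h // ny:(i + 1) * h // ny,
                          j * w // nx:(j + 1) * w // nx]
            if np.ptp(block) > 1e-6:
                t = threshold_otsu(block)
                # a block without foreground yields a spurious low threshold;
                # clamp to a band around the global value
                thr[i, j] = np.clip(t, 0.7 * global_thr, 1.5 * global_thr)
            else:
                thr[i, j] = np.inf
    if not np.isfinite(thr).any():
        return np.zeros_like(image, bool)
    fin = np.isfinite(thr)
    thr[~fin] = thr[fin].max()
    surface = resize(thr, image.shape, order=1, mode="edge")
    return image > surface


def _declump(mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Split touching objects by watershed on the distance transform."""
    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(dist, min_distance=min_distance, labels=mask,
                            exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
        return labels
    return watershed(-dist, markers, mask=mask)


def segment_nuclei(hoechst: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Label image of nuclei from the Hoechst channel."""
    if hoechst.ndim != 2:
        raise ValueError("expected a 2D image")
    img = _rescale(np.asarray(hoechst, float), params.rescale_percentiles)
    ds = params.downsample
    small = img[::ds, ::ds] if ds > 1 else img
    small = ndi.median_filter(small, footprint=disk(params.median_radius))
    mask_small = _adaptive_otsu(small, max(params.adaptive_window // ds, 16))
    if ds > 1:
        mask = resize(mask_small, img.shape, order=0,
                      preserve_range=True).astype(bool)
    else:
        mask = mask_small
    mask = ndi.binary_fill_holes(mask)
    labels = _declump(mask, min_distance=params.expected_nucleus_diameter_px // 2)
    # drop objects below the minimum area
    sizes = np.bincount(labels.ravel())
    small_ids = np.flatnonzero(sizes < params.min_area_px)
    labels[np.isin(labels, small_ids)] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def segment_cells(rfp: np.ndarray, nucleus_labels: np.ndarray,
                  params: SegmentationParams) -> tuple[np.ndarray, list[int]]:
    """One cell region per nucleus via seeded watershed on thresholded RFP.

    Returns the cell label image (labels match nucleus labels) and the list
    of nucleus labels that fell outside any RFP-positive area (flagged
    unsegmentable; their cells are dropped).
    """
    rfp = _rescale(np.asarray(rfp, float), params.rescale_percentiles)
    smooth = ndi.median_filter(rfp, footprint=disk(params.median_radius))
    mask = _adaptive_otsu(smooth, params.adaptive_window)
    mask |= nucleus_labels > 0  # the nucleus area always belongs to its cell
    cells = watershed(-smooth, markers=nucleus_labels, mask=mask)
    unsegmentable = []
    for prop in regionprops(nucleus_labels):
        lab = prop.label
        nuc = nucleus_labels == lab
        body = (cells == lab) & ~nuc
        if body.sum() < nuc.sum() * 0.05:  # essentially no cytoplasm ring
            unsegmentable.append(lab)
            cells[cells == lab] = 0
    return cells, unsegmentable


def measure_cells(channels: dict[str, np.ndarray], labeled: LabeledField,
                  params: SegmentationParams, pixel_size: float = 1.0,
                  meta: dict | None = None) -> pd.DataFrame:
    """Per-cell compartment intensities, morphology, and reporter ratios.

    Intensities are means over the eroded nucleus / cytoplasm masks; nucleus
    area (µm²) and solidity come from the un-eroded nucleus mask. Cells whose
    compartments vanish under erosion are flagged ``measurable=False`` and
    carry NaN ratios.
    """
    nuc, cyto = labeled.nucleus_labels, labeled.cytoplasm_labels
    selem = disk(params.erosion_radius) if params.erosion_radius > 0 else None
    if selem is not None:
        nuc_er = np.where(ndi.binary_erosion(nuc > 0, structure=selem), nuc, 0)
        cyto_er = np.where(ndi.binary_erosion(cyto > 0, structure=selem), cyto, 0)
    else:
        nuc_er, cyto_er = nuc, cyto

    rows = []
    meta = meta or {}
    for prop in regionprops(nuc):
        lab = prop.label
        row = dict(meta)
        row.update({
            "label": lab,
            "nucleus_area_um2": prop.area * pixel_size ** 2,
            "nucleus_solidity": prop.solidity,
        })
        ok = (nuc_er == lab).any() and (cyto_er == lab).any()
        row["measurable"] = bool(ok)
        for name, img in channels.items():
            img = np.asarray(img, float)
            nm = img[nuc_er == lab].mean() if (nuc_er == lab).any() else np.nan
            cm = img[cyto_er == lab].mean() if (cyto_er == lab).any() else np.nan
            row[f"{name}_nuc_mean"] = nm
            row[f"{name}_cyto_mean"] = cm
        rfp_n, rfp_c = row.get("rfp_nuc_mean"), row.get("rfp_cyto_mean")
        gfp_n, gfp_c = row.get("gfp_nuc_mean"), row.get("gfp_cyto_mean")
        row["rfp_nuc_cyto"] = rfp_n / rfp_c if ok and rfp_c and rfp_c > 0 else np.nan
        row["gfp_cyto_nuc"] = gfp_c / gfp_n if ok and gfp_n and gfp_n > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def segment_and_measure(channels: dict[str, np.ndarray],
                        params: SegmentationParams | None = None,
                        pixel_size: float = 1.0,
                        meta: dict | None = None
                        ) -> tuple[LabeledField, pd.DataFrame]:
    """Full stage: segment nuclei and cells, then measure one field."""
    params = params or SegmentationParams()
    hoechst = np.asarray(channels["hoechst"], float)
    rfp = np.asarray(channels["rfp"], float)
    nuc = segment_nuclei(hoechst, params)
    cells, unseg = segment_cells(rfp, nuc, params)
    nuc = np.where(np.isin(nuc, unseg), 0, nuc)
    cyto = np.where(cells > 0, cells, 0) * (nuc == 0)
    labeled = LabeledField(nucleus_labels=nuc, cell_labels=cells,
                           cytoplasm_labels=cyto, unsegmentable=unseg)
    if params.subtract_bg:
        union = cells > 0
        channels = {k: subtract_background(v, union) for k, v in channels.items()}
    records = measure_cells(channels, labeled, params, pixel_size, meta)
    return labeled, records
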