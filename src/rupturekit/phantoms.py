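"""Synthetic phantoms with known ground truth.

Two generators:

* :func:`make_screen_plate` — 2D multi-channel fields emulating a fixed-cell
  rupture screen: nuclei (Hoechst), cytoplasm (RFP-Cyto), nuclear reporter
  (GFP-Nuc). Ruptured cells gain nuclear RFP; rupturing cells additionally show
  cytoplasmic GFP. Mitotic / dead / out-of-focus contaminants carry their
  characteristic signatures. :func:`simulate_cell_records` produces the same
  per-cell truth at the measurement level without rendering pixels, for
  statistics-scale simulations.
* :func:`make_lamina_phantom` — anisotropic 3D two-channel stacks (DAPI fill,
  lamin shell) where the shell is perforated by spherical-cap gaps of known
  direction and angular radius, with the analytic cap area stored as truth.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

CELL_STATES = ("intact", "ruptured", "rupturing", "mitotic", "dead", "out_of_focus")

# Measurement-level intensity model (arbitrary fluorescence units).  Ratios are
# log-normal per cell to mimic expression variability; the separation between
# the intact and ruptured RFP nuc:cyto populations is the assay's effect size.
INTENSITY_MODEL = {
    "hoechst_mean": 500.0,
    "hoechst_log_sd": 0.20,
    "mitotic_hoechst_factor": 2.5,
    "oof_intensity_factor": 0.45,
    "rfp_ratio_intact": 0.35,
    "rfp_ratio_ruptured": 1.10,
    "rfp_ratio_log_sd": 0.25,
    "gfp_ratio_intact": 0.30,
    "gfp_ratio_rupturing": 1.20,
    "gfp_ratio_log_sd": 0.25,
    "nucleus_area_mean": 180.0,  # µm²
    "nucleus_area_sd": 25.0,
    "dead_area_factor": 0.30,
    "solidity_mean": 0.97,
    "solidity_sd": 0.012,
    "dead_solidity": 0.75,
    "mitotic_solidity": 0.995,
}


@dataclass
class WellSpec:
    """Design of a single well: identity, cell count, and rupture biology."""

    well_id: str
    condition: str
    replicate: int
    n_cells: int = 200
    rupture_prob: float = 0.1
    gfp_mislocalized_frac_of_ruptured: float = 0.2
    rfp_expression_mean: float = 200.0
    rfp_expression_sd: float = 0.35  # log-sd of the per-cell expression level
    contaminant_fracs: dict = field(
        default_factory=lambda: {"mitotic": 0.0, "dead": 0.0, "out_of_focus": 0.0}
    )

    def validate(self) -> None:
        probs = [self.rupture_prob, self.gfp_mislocalized_frac_of_ruptured,
                 *self.contaminant_fracs.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"well {self.well_id}: probabilities must be in [0,1]")
        if self.n_cells < 0:
            raise ValueError(f"well {self.well_id}: n_cells must be >= 0")
        if sum(self.contaminant_fracs.values()) > 1.0:
            raise ValueError(f"well {self.well_id}: contaminant fractions exceed 1")


@dataclass
class PlateSpec:
    """Design of a synthetic screen plate."""

    wells: list[WellSpec]
    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65  # µm
    noise_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        for w in self.wells:
            w.validate()
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class PlateTruth:
    """Ground truth for a generated plate.

    ``records`` holds one row per cell (state label plus the noiseless
    measurement-level quantities); ``masks`` maps well_id -> dict of label
    images (nucleus / cell), present only when pixels were rendered.
    """

    records: pd.DataFrame
    masks: dict = field(default_factory=dict)


def _draw_states(well: WellSpec, rng: np.random.Generator) -> np.ndarray:
    """One state label per cell; contaminants first, then rupture biology."""
    n = well.n_cells
    states = np.full(n, "intact", dtype=object)
    u = rng.random(n)
    edges = np.cumsum([well.contaminant_fracs.get(k, 0.0)
                       for k in ("mitotic", "dead", "out_of_focus")])
    states[u < edges[0]] = "mitotic"
    states[(u >= edges[0]) & (u < edges[1])] = "dead"
    states[(u >= edges[1]) & (u < edges[2])] = "out_of_focus"
    clean = states == "intact"
    ruptured = clean & (rng.random(n) < well.rupture_prob)
    states[ruptured] = "ruptured"
    rupturing = ruptured & (rng.random(n) < well.gfp_mislocalized_frac_of_ruptured)
    states[rupturing] = "rupturing"
    return states


def simulate_cell_records(spec: PlateSpec, rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Draw per-cell states and measurement-level quantities for a plate.

    Returns a tidy frame with one row per cell carrying the true state, the
    compartment mean intensities, the RFP nuc:cyto and GFP cyto:nuc ratios,
    and nucleus morphology — the same schema the imaging pipeline measures,
    so the QC / calling / statistics stages run on it directly.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = INTENSITY_MODEL
    rows = []
    for well in spec.wells:
        n = well.n_cells
        states = _draw_states(well, rng)
        hoechst = np.exp(rng.normal(math.log(M["hoechst_mean"]), M["hoechst_log_sd"], n))
        rfp_cyto = np.exp(rng.normal(math.log(well.rfp_expression_mean),
                                     well.rfp_expression_sd, n))
        area = rng.normal(M["nucleus_area_mean"], M["nucleus_area_sd"], n).clip(20.0)
        solidity = rng.normal(M["solidity_mean"], M["solidity_sd"], n).clip(0.5, 1.0)

        rfp_ratio = np.exp(rng.normal(math.log(M["rfp_ratio_intact"]),
                                      M["rfp_ratio_log_sd"], n))
        gfp_ratio = np.exp(rng.normal(math.log(M["gfp_ratio_intact"]),
                                      M["gfp_ratio_log_sd"], n))
        hi_rfp = np.isin(states, ("ruptured", "rupturing"))
        rfp_ratio[hi_rfp] = np.exp(rng.normal(math.log(M["rfp_ratio_ruptured"]),
                                              M["rfp_ratio_log_sd"], hi_rfp.sum()))
        hi_gfp = states == "rupturing"
        gfp_ratio[hi_gfp] = np.exp(rng.normal(math.log(M["gfp_ratio_rupturing"]),
                                              M["gfp_ratio_log_sd"], hi_gfp.sum()))

        hoechst[states == "mitotic"] *= M["mitotic_hoechst_factor"]
        solidity[states == "mitotic"] = M["mitotic_solidity"]
        area[states == "dead"] *= M["dead_area_factor"]
        solidity[states == "dead"] = M["dead_solidity"]
        oof = states == "out_of_focus"
        hoechst[oof] *= M["oof_intensity_factor"]
        rfp_cyto[oof] *= M["oof_intensity_factor"]

        gfp_nuc = np.exp(rng.normal(math.log(300.0), 0.25, n))
        rows.append(pd.DataFrame({
            "well": well.well_id,
            "condition": well.condition,
            "replicate": well.replicate,
            "field": 0,
            "label": np.arange(1, n + 1),
            "true_state": states,
            "hoechst_nuc_mean": hoechst,
            "rfp_cyto_mean": rfp_cyto,
            "rfp_nuc_mean": rfp_ratio * rfp_cyto,
            "gfp_nuc_mean": gfp_nuc,
            "gfp_cyto_mean": gfp_ratio * gfp_nuc,
            "rfp_nuc_cyto": rfp_ratio,
            "gfp_cyto_nuc": gfp_ratio,
            "nucleus_area_um2": area,
            "nucleus_solidity": solidity,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# 2D field rendering


def _place_centers(n: int, shape: tuple[int, int], min_dist: float,
                   rng: np.random.Generator, well_id: str,
                   max_retries: int = 1000) -> np.ndarray:
    """Rejection-sample cell centers with a minimum pairwise distance."""
    margin = min_dist * 0.6
    centers: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_retries):
            c = rng.uniform([margin, margin],
                            [shape[0] - margin, shape[1] - margin])
            if all(np.hypot(*(c - p)) >= min_dist for p in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells in well {well_id}")
    return np.asarray(centers).reshape(n, 2)


def _ellipse_mask(shape, center, radii, angle):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def render_field(records: pd.DataFrame, spec: PlateSpec, well: WellSpec,
                 rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Render one field for a well from its record rows.

    Returns ``(channels, masks)`` where channels is a (3, H, W) float array in
    order Hoechst / RFP / GFP and masks holds nucleus and cell label images
    matching the record labels.
    """
    shape = spec.field_shape
    px = spec.pixel_size
    n = len(records)
    nuc_r_px = np.sqrt(records["nucleus_area_um2"].to_numpy() / math.pi) / px
    min_dist = 2.0 * float(np.max(nuc_r_px, initial=8.0)) * 2.2
    centers = _place_centers(n, shape, min_dist, rng, well.well_id)

    hoechst = np.zeros(shape)
    rfp = np.zeros(shape)
    gfp = np.zeros(shape)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)

    for i, (_, rec) in enumerate(records.iterrows()):
        lab = int(rec["label"])
        r = nuc_r_px[i]
        ecc = rng.uniform(0.85, 1.0)
        angle = rng.uniform(0, math.pi)
        nmask = _ellipse_mask(shape, centers[i], (r / ecc, r * ecc), angle)
        cmask = _ellipse_mask(shape, centers[i], (r * 1.9 / ecc, r * 1.9 * ecc), angle)
        if rec["true_state"] == "dead":
            # fragmented look: keep a small blobby core
            nmask = _ellipse_mask(shape, centers[i], (r * 0.8, r * 0.6), angle)
        nuc_labels[nmask] = lab
        cell_labels[cmask] = lab
        cyto = cmask & ~nmask
        hoechst[nmask] += rec["hoechst_nuc_mean"]
        rfp[cyto] += rec["rfp_cyto_mean"]
        rfp[nmask] += rec["rfp_nuc_mean"]
        gfp[nmask] += rec["gfp_nuc_mean"]
        gfp[cyto] += rec["gfp_cyto_mean"]
        if rec["true_state"] == "out_of_focus":
            for img in (hoechst, rfp, gfp):
                sub = img * cmask
                img[cmask] = ndi.gaussian_filter(sub, 3.0)[cmask]

    background = 10.0
    channels = np.stack([hoechst, rfp, gfp]) + background
    channels = ndi.gaussian_filter(channels, (0, 1.0, 1.0))
    channels += rng.normal(0.0, spec.noise_sd, channels.shape)
    channels = channels.clip(0.0)
    return channels, {"nucleus": nuc_labels, "cell": cell_labels}


def make_screen_plate(spec: PlateSpec, render: bool = True
                      ) -> tuple[dict, PlateTruth, pd.DataFrame]:
    """Generate a synthetic screen plate.

    Returns ``(images, truth, plate_map)``: images maps well_id to a
    (3, H, W) channel stack (empty dict when ``render=False``), truth carries
    the per-cell records and truth masks, and plate_map is the well table
    (well_id, condition, replicate, field_index).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = simulate_cell_records(spec, rng)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, dict] = {}
    if render:
        for well in spec.wells:
            sub = records[records["well"] == well.well_id]
            images[well.well_id], masks[well.well_id] = render_field(
                sub, spec, well, rng)
    plate_map = pd.DataFrame(
        [(w.well_id, w.condition, w.replicate, 0) for w in spec.wells],
        columns=["well_id", "condition", "replicate", "field_index"])
    return images, PlateTruth(records=records, masks=masks), plate_map


# ---------------------------------------------------------------------------
# 3D lamina phantom


@dataclass
class PhantomSpec3D:
    """Design of a 3D nucleus phantom: a lamin shell around a DAPI-filled core.

    ``gaps`` lists (direction, angular_radius_deg) spherical caps removed from
    the shell. ``semi_axes`` are in µm; a sphere uses three equal axes.
    """

    semi_axes: tuple[float, float, float] = (6.0, 6.0, 6.0)
    voxel_spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)  # (dz, dy, dx) µm
    lamina_thickness: float = 0.4  # µm
    gaps: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    dapi_level: float = 100.0
    lamin_level: float = 100.0
    noise_sd: float = 10.0
    margin_voxels: int = 6
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        for direction, theta in self.gaps:
            if theta <= 0:
                raise ValueError("gap angular radius must be positive")
            if theta > 90.0:
                raise ValueError("gap larger than a hemisphere")
        # distinct gaps must not overlap
        dirs = [np.asarray(d, float) / np.linalg.norm(d) for d, _ in self.gaps]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                sep = math.degrees(math.acos(np.clip(dirs[i] @ dirs[j], -1, 1)))
                if sep < self.gaps[i][1] + self.gaps[j][1]:
                    raise ValueError(f"gaps {i} and {j} overlap")


@dataclass
class GapTruth:
    direction: np.ndarray
    angular_radius_deg: float
    cap_area_um2: float
    footprint: np.ndarray  # boolean voxel footprint on the shell


@dataclass
class PhantomTruth3D:
    nucleus_mask: np.ndarray
    lamina_mask: np.ndarray
    gaps: list[GapTruth]
    center_um: np.ndarray
    radius_um: float


def spherical_cap_area(radius_um: float, theta_deg: float) -> float:
    """Area of a spherical cap of angular radius theta on a sphere: 2πR²(1−cosθ)."""
    return 2.0 * math.pi * radius_um ** 2 * (1.0 - math.cos(math.radians(theta_deg)))


def make_lamina_phantom(spec: PhantomSpec3D
                        ) -> tuple[np.ndarray, np.ndarray, PhantomTruth3D]:
    """Generate a two-channel 3D phantom: (dapi, lamin, truth).

    The lamin channel is a shell of the stated thickness centered on the
    nuclear surface, perforated at each gap's spherical cap; DAPI fills the
    nucleus up to the mid-shell surface. Noise is additive Gaussian.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.voxel_spacing, float)
    ax = np.asarray(spec.semi_axes, float)
    half_t = spec.lamina_thickness / 2.0
    shape = tuple((np.ceil(2 * (ax + half_t) / sp)).astype(int) + 2 * spec.margin_voxels)
    center = (np.asarray(shape) - 1) / 2.0 * sp

    zz, yy, xx = np.meshgrid(*[np.arange(s) * d for s, d in zip(shape, sp)],
                             indexing="ij")
    delta = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    # signed radial coordinate: for a sphere this is exact Euclidean distance
    # from the surface; for an ellipsoid it is the scaled level-set value.
    rho = np.sqrt(((delta / ax[:, None, None, None]) ** 2).sum(axis=0))
    r_eff = float(np.mean(ax))
    radial = (rho - 1.0) * r_eff

    nucleus = radial <= 0.0
    shell = np.abs(radial) <= half_t

    unit = delta / np.maximum(np.sqrt((delta ** 2).sum(axis=0)), 1e-12)
    gap_truths = []
    shell_open = shell.copy()
    for direction, theta in spec.gaps:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        cosang = (unit * d[:, None, None, None]).sum(axis=0)
        cap = shell & (cosang >= math.cos(math.radians(theta)))
        shell_open &= ~cap
        gap_truths.append(GapTruth(
            direction=d, angular_radius_deg=theta,
            cap_area_um2=spherical_cap_area(r_eff, theta),
            footprint=cap))

    dapi = np.where(nucleus, spec.dapi_level, 0.0)
    lamin = np.where(shell_open, spec.lamin_level, 0.0)
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0, spec.noise_sd, shape)
        lamin = lamin + rng.normal(0, spec.noise_sd, shape)
    truth = PhantomTruth3D(nucleus_mask=nucleus, lamina_mask=shell_open,
                           gaps=gap_truths, center_um=center, radius_um=r_eff)
    return dapi.clip(0.0), lamin.clip(0.0), truth


def make_ellipsoid_mask(semi_axes_um, spacing, margin_voxels=4) -> np.ndarray:
    """Boolean voxelization of an ellipsoid, for surface/morphometry tests."""
    sp = np.asarray(spacing, float)
    ax = np.asarray(semi_axes_um, float)
    shape = tuple((np.ceil(2 * ax / sp)).astype(int) + 2 * margin_voxels)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    grids = np.meshgrid(*[np.arange(s) * d for s, d in zip(shape, sp)], indexing="ij")
    rho = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, ax))
    return rho <= 1.0
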