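"""3D nuclear-lamina gap detection and nuclear morphometry.

The detector localizes discontinuities in the lamin shell by comparing two
distance maps from a seed inside the nucleus: the unconstrained Euclidean
distance and the geodesic distance constrained to avoid the binarized lamin
signal. Where the two agree, a straight path escapes the nucleus without
crossing lamin — like light leaving a punctured sphere with an internal
source. Projecting the agreement region onto the (slightly dilated) nuclear
perimeter yields the gap footprints, which are then filtered by size, local
lamin intensity, and surface curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes, mesh_surface_area

from .geodesic import cartesian_distance, equality_map, geodesic_distance

__all__ = [
    "GapParams",
    "NuclearVolume",
    "GapRecord",
    "SurfaceCloud",
    "NucleusMorphometry",
    "binarize_3d",
    "derive_masks",
    "detect_gaps",
    "filter_gaps",
    "build_surface_cloud",
    "gap_curvature",
    "morphometry",
    "bin_gap_count",
    "analyze_nucleus",
]

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class GapParams:
    """Tunable knobs of the gap pipeline (all lengths in µm or voxels as noted).

    dilation/erosion are in xy voxels, scaled down along z by the anisotropy
    so the structuring element is roughly isotropic in physical units.
    """

    dilation_voxels: int = 2
    erosion_voxels: int = 3
    equality_ratio_tol: float = 1.04
    size_min_voxels: int = 2
    intensity_max: float | None = None  # default: Otsu threshold of lamin channel
    merge_cut_um3: float = 5.0
    cloud_density: float = 10.0  # points / µm²
    curvature_k: int = 9
    curvature_radius_um: float = 1.0
    volume_bounds_um3: tuple[float, float] | None = None


@dataclass
class NuclearVolume:
    """One nucleus: channels, spacing, and the derived masks."""

    dapi: np.ndarray
    lamin: np.ndarray
    spacing: tuple[float, float, float]
    nucleus: np.ndarray | None = None
    lamina: np.ndarray | None = None
    seed: np.ndarray | None = None
    dilated: np.ndarray | None = None
    perimeter: np.ndarray | None = None


@dataclass
class GapRecord:
    gap_id: int
    voxels: np.ndarray  # (n, 3) voxel indices on the perimeter shell
    size_um3: float
    area_um2: float
    mean_lamin_intensity: float
    mean_curvature: float | None = None
    status: str = "putative"  # kept / removed-<reason>


@dataclass
class SurfaceCloud:
    points: np.ndarray  # (n, 3) physical zyx coordinates, µm
    normals: np.ndarray
    curvature: np.ndarray  # mean curvature, µm⁻¹, convex-outward positive
    density: float
    surface_area_um2: float


@dataclass
class NucleusMorphometry:
    height_um: float
    volume_um3: float
    surface_area_um2: float
    mean_intensities: dict = field(default_factory=dict)


def _aniso_ball(radius_xy: int, spacing) -> np.ndarray:
    """Ellipsoidal structuring element: radius_xy voxels in xy, scaled in z."""
    dz, dy, dx = spacing
    r_um = radius_xy * min(dy, dx)
    rz = max(1, int(round(r_um / dz)))
    z, y, x = np.mgrid[-rz:rz + 1, -radius_xy:radius_xy + 1, -radius_xy:radius_xy + 1]
    return (z / rz) ** 2 + (y / radius_xy) ** 2 + (x / radius_xy) ** 2 <= 1.0


def binarize_3d(volume: np.ndarray, channel: str, spacing=None) -> np.ndarray:
    """Global-Otsu binarization of a 3D channel with standard cleanup.

    DAPI keeps only the largest connected component and closes/fills it;
    lamin keeps all shell voxels after closing (thin structures must survive).
    """
    volume = np.asarray(volume, float)
    thr = threshold_otsu(volume)
    mask = volume > thr
    if not mask.any():
        raise ValueError(f"empty foreground after Otsu threshold ({channel})")
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3, 3), bool))
    if channel.lower() in ("dapi", "nucleus", "hoechst"):
        labels, n = ndi.label(mask, structure=_STRUCT26)
        if n > 1:
            sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndi.binary_fill_holes(mask)
    return mask


def derive_masks(vol: NuclearVolume, params: GapParams) -> NuclearVolume:
    """Populate nucleus / lamina / seed / dilated / perimeter masks in place."""
    if vol.nucleus is None:
        vol.nucleus = binarize_3d(vol.dapi, "dapi", vol.spacing)
    if vol.lamina is None:
        vol.lamina = binarize_3d(vol.lamin, "lamin", vol.spacing)
    vol.seed = ndi.binary_erosion(
        vol.nucleus, structure=_aniso_ball(params.erosion_voxels, vol.spacing))
    if not vol.seed.any():
        raise ValueError("seed erosion emptied the nucleus mask")
    vol.dilated = ndi.binary_dilation(
        vol.nucleus, structure=_aniso_ball(params.dilation_voxels, vol.spacing))
    vol.perimeter = vol.dilated & ~ndi.binary_erosion(vol.dilated, _STRUCT26)
    return vol


def detect_gaps(equality: np.ndarray, perimeter: np.ndarray, spacing,
                lamin: np.ndarray | None = None,
                surface_mesh: tuple[np.ndarray, np.ndarray] | None = None
                ) -> list[GapRecord]:
    """Putative gaps: 26-connected components of equality ∩ perimeter.

    Gap size is voxel count × voxel volume. Footprint area is estimated from
    the surface mesh of the dilated object when given (sum of face areas whose
    centroid lies on the footprint) — this avoids the orientation bias of
    voxel counting — otherwise from voxel count × median voxel face area.
    """
    if not perimeter.any():
        raise ValueError("perimeter shell is empty")
    voxel_vol = float(np.prod(spacing))
    footprint = equality & perimeter
    labels, n = ndi.label(footprint, structure=_STRUCT26)
    gaps = []
    for i in range(1, n + 1):
        vox = np.argwhere(labels == i)
        mean_int = float(np.mean(lamin[tuple(vox.T)])) if lamin is not None else np.nan
        gaps.append(GapRecord(
            gap_id=i, voxels=vox,
            size_um3=len(vox) * voxel_vol,
            area_um2=len(vox) * float(np.median(spacing)) ** 2,
            mean_lamin_intensity=mean_int))
    if surface_mesh is not None and gaps:
        _mesh_footprint_areas(gaps, surface_mesh, spacing)
    return gaps


def _mesh_footprint_areas(gaps: list[GapRecord],
                          surface_mesh: tuple[np.ndarray, np.ndarray],
                          spacing) -> None:
    """Assign footprint areas by collecting mesh faces over each gap patch."""
    from scipy.spatial import cKDTree

    verts, faces = surface_mesh
    centroids = verts[faces].mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]]), axis=1)
    # just above the half voxel diagonal: every face over a footprint voxel is
    # caught while the spurious rim band stays one face wide
    cutoff = 0.6 * float(np.linalg.norm(spacing))
    sp = np.asarray(spacing, float)
    for gap in gaps:
        tree = cKDTree(gap.voxels * sp)
        d, _ = tree.query(centroids, distance_upper_bound=cutoff)
        gap.area_um2 = float(areas[np.isfinite(d)].sum())


def filter_gaps(gaps: list[GapRecord], params: GapParams,
                lamin_volume: np.ndarray | None = None,
                cloud: SurfaceCloud | None = None,
                spacing=None) -> list[GapRecord]:
    """Apply the gap filter cascade; removal reasons are recorded in place.

    Order: minimum size (noise specks), lamin intensity (false gaps over dim
    but present lamina), merged gaps above the size cut (nearby gaps fused
    into one oversized component), and negative mean curvature
    (mis-segmentation). Returns the kept gaps.
    """
    intensity_max = params.intensity_max
    if intensity_max is None and lamin_volume is not None:
        intensity_max = float(threshold_otsu(np.asarray(lamin_volume, float)))
    kept = []
    for gap in gaps:
        if len(gap.voxels) < params.size_min_voxels:
            gap.status = "removed-size"
            continue
        if intensity_max is not None and np.isfinite(gap.mean_lamin_intensity) \
                and gap.mean_lamin_intensity > intensity_max:
            gap.status = "removed-intensity"
            continue
        if gap.size_um3 > params.merge_cut_um3:
            gap.status = f"removed-merged>{params.merge_cut_um3:g}µm³"
            continue
        if cloud is not None and spacing is not None:
            gap.mean_curvature = gap_curvature(gap, cloud, params.curvature_radius_um,
                                               spacing)
            if gap.mean_curvature is not None and gap.mean_curvature < 0:
                gap.status = "removed-negative-curvature"
                continue
        gap.status = "kept"
        kept.append(gap)
    return kept


def _mesh_of(mask: np.ndarray, spacing, smooth_sigma: float = 1.0):
    """Marching-cubes mesh of a mask, in physical zyx coordinates."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if len(zs) < 2:
        raise ValueError("degenerate (single-slice) mask")
    vol = ndi.gaussian_filter(mask.astype(float), smooth_sigma)
    pad = np.pad(vol, 2)
    verts, faces, _, _ = marching_cubes(pad, level=0.5, spacing=spacing)
    verts -= 2 * np.asarray(spacing)
    return verts, faces


def build_surface_cloud(mask: np.ndarray, spacing,
                        density: float = 10.0, k: int = 9,
                        rng: np.random.Generator | int | None = 0) -> SurfaceCloud:
    """Sample the bounding surface of a mask and estimate per-point curvature.

    A marching-cubes surface envelops the mask; points are sampled uniformly
    at the configured density (points/µm²). Normals come from the supporting
    faces, oriented outward. Mean curvature per point is a local quadric fit
    over the k nearest neighbors, convex-outward positive (sphere 1/r > 0,
    plane 0).
    """
    import trimesh

    verts, faces = _mesh_of(mask, spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    area = float(mesh.area)
    count = max(int(round(density * area)), 100)
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else rng
    points, face_idx = trimesh.sample.sample_surface(mesh, count, seed=seed)
    normals = mesh.face_normals[face_idx]
    # orient outward: normal should point away from the mask centroid
    centroid = verts.mean(axis=0)
    flip = ((points - centroid) * normals).sum(axis=1) < 0
    normals = np.where(flip[:, None], -normals, normals)
    curvature = _quadric_mean_curvature(points, normals, k)
    return SurfaceCloud(points=points, normals=normals, curvature=curvature,
                        density=density, surface_area_um2=area)


def _quadric_mean_curvature(points: np.ndarray, normals: np.ndarray,
                            k: int) -> np.ndarray:
    """Per-point mean curvature from a local quadric height-field fit."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k + 1)
    curv = np.empty(len(points))
    for i in range(len(points)):
        n = normals[i]
        # tangent basis
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        q = points[nbr[i]] - points[i]
        h = q @ n
        x = q @ u
        y = q @ v
        A = np.column_stack([x ** 2, x * y, y ** 2, x, y, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        # h ≈ (1/2)(κ1 x² + κ2 y²) in the principal frame along the outward
        # normal: a convex surface bends away from the normal, so H = -(a+c).
        curv[i] = -(coef[0] + coef[2])
    return curv


def gap_curvature(gap: GapRecord, cloud: SurfaceCloud, radius_um: float,
                  spacing) -> float | None:
    """Mean curvature over cloud points within radius of the gap footprint.

    Returns None when no cloud point covers the gap (curvature undefined).
    """
    from scipy.spatial import cKDTree

    gap_um = gap.voxels * np.asarray(spacing)
    tree = cKDTree(cloud.points)
    idx = tree.query_ball_point(gap_um, r=radius_um)
    covering = sorted({i for lst in idx for i in lst})
    if not covering:
        return None
    return float(np.mean(cloud.curvature[covering]))


def morphometry(mask: np.ndarray, spacing,
                intensities: dict[str, np.ndarray] | None = None
                ) -> NucleusMorphometry:
    """Height, volume, surface area, and mean label intensities of a nucleus."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    dz = spacing[0]
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    height = (zs[-1] - zs[0] + 1) * dz
    volume = float(mask.sum()) * float(np.prod(spacing))
    verts, faces = _mesh_of(mask, spacing)
    area = float(mesh_surface_area(verts, faces))
    means = {name: float(np.mean(np.asarray(img)[mask]))
             for name, img in (intensities or {}).items()}
    return NucleusMorphometry(height_um=height, volume_um3=volume,
                              surface_area_um2=area, mean_intensities=means)


def bin_gap_count(n_gaps: int) -> str:
    """Bin a per-nucleus gap count: 0 none, 1-3 low, >=4 high."""
    if n_gaps < 0:
        raise ValueError("gap count must be >= 0")
    if n_gaps == 0:
        return "none"
    return "low" if n_gaps <= 3 else "high"


def analyze_nucleus(dapi: np.ndarray, lamin: np.ndarray, spacing,
                    params: GapParams | None = None,
                    compute_curvature: bool = True) -> dict:
    """Run the full gap pipeline on one two-channel stack.

    Returns a dict with the derived volume, distance maps, putative and kept
    gaps, the surface cloud (if curvature was computed), and morphometry.
    Nuclei outside ``params.volume_bounds_um3`` are flagged mis-segmented and
    skipped.
    """
    params = params or GapParams()
    vol = NuclearVolume(dapi=np.asarray(dapi, float),
                        lamin=np.asarray(lamin, float), spacing=tuple(spacing))
    derive_masks(vol, params)

    result = {"volume": vol, "excluded": False}
    morph = morphometry(vol.nucleus, spacing, {"dapi": vol.dapi, "lamin": vol.lamin})
    result["morphometry"] = morph
    if params.volume_bounds_um3 is not None:
        lo, hi = params.volume_bounds_um3
        if not lo <= morph.volume_um3 <= hi:
            result["excluded"] = True
            result["gaps"] = []
            result["putative_gaps"] = []
            return result

    traversable = ~vol.lamina
    seed = vol.seed & traversable
    if not seed.any():
        raise ValueError("seed lies entirely within the lamin mask")
    cart = cartesian_distance(seed, spacing)
    # only distances up to the perimeter matter; beyond the equality band the
    # geodesic value is irrelevant, so the search stops there.  Paths never
    # profit from crossing the seed interior (every seed voxel is a source),
    # so only the seed boundary is kept as source and the interior is blocked.
    dmax = float(cart[vol.perimeter].max()) * params.equality_ratio_tol \
        + float(np.max(spacing)) * 2.0
    seed_src = seed & ~ndi.binary_erosion(seed)
    trav_band = traversable & ~(seed & ~seed_src)
    geo = geodesic_distance(seed_src, trav_band, spacing, max_dist=dmax)
    geo[seed] = 0.0
    eq = equality_map(cart, geo, spacing, ratio_tol=params.equality_ratio_tol)
    result["cartesian"] = cart
    result["geodesic"] = geo
    result["equality"] = eq

    dil_mesh = _mesh_of(vol.dilated, spacing)
    putative = detect_gaps(eq, vol.perimeter, spacing, lamin=vol.lamin,
                           surface_mesh=dil_mesh)
    # footprints live on the dilated perimeter; report areas projected back
    # onto the nuclear surface where the lamina actually sits
    dilated_area = float(mesh_surface_area(*dil_mesh))
    if dilated_area > 0:
        scale = morph.surface_area_um2 / dilated_area
        for gap in putative:
            gap.area_um2 *= scale
    result["putative_gaps"] = putative

    cloud = None
    if compute_curvature and putative:
        cloud = build_surface_cloud(vol.nucleus, spacing,
                                    density=params.cloud_density,
                                    k=params.curvature_k)
    result["cloud"] = cloud
    result["gaps"] = filter_gaps(putative, params, lamin_volume=vol.lamin,
                                 cloud=cloud, spacing=spacing)
    result["gap_bin"] = bin_gap_count(len(result["gaps"]))
    return result
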