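"""3D object assembly from plane-wise segmentations.

Implements the second stage of slice-wise 3D cytometry: 2D objects from
consecutive planes are connected into 3D objects by optimal bipartite
matching under a maximum lateral displacement ("connect by best match"),
the whole spheroid is detected as a single 3D region, and 3D
morphometrics are measured in physical units on the anisotropic voxel
grid (XY pixel size != Z step).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure, morphology

from .seg2d import PlaneObject, gaussian_smooth
from .stackio import ImageStack

logger = logging.getLogger(__name__)

# midpoints of the displacement ranges appropriate for nuclei (5-10 μm)
# and cytoplasm (20-30 μm)
DEFAULT_NUCLEI_DISPLACEMENT_UM = 7.5
DEFAULT_CYTO_DISPLACEMENT_UM = 25.0


def equivalent_diameter(volume_um3: float) -> float:
    """Diameter of the sphere with the given volume, (6V/π)^(1/3)."""
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


@dataclass
class Object3D:
    """A chain of plane objects linked across consecutive Z planes."""

    label: int
    members: list[PlaneObject]
    z_step_um: float
    volume_um3: float = 0.0
    centroid_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mean_intensity: dict = field(default_factory=dict)
    integrated_intensity: dict = field(default_factory=dict)
    compartment: str = "nucleus"

    @property
    def equivalent_diameter_um(self) -> float:
        return equivalent_diameter(self.volume_um3)

    @property
    def z_indices(self) -> list[int]:
        return [m.z_index for m in self.members]

    @property
    def n_planes(self) -> int:
        return len(self.members)


def _aggregate(members: list[PlaneObject], label: int, z_step_um: float) -> Object3D:
    areas = np.array([m.area_um2 for m in members])
    vol = float(areas.sum() * z_step_um)
    xs = np.array([m.centroid_um[0] for m in members])
    ys = np.array([m.centroid_um[1] for m in members])
    zs = np.array([m.z_index * z_step_um for m in members])
    w = areas / areas.sum()
    obj = Object3D(
        label=label,
        members=members,
        z_step_um=z_step_um,
        volume_um3=vol,
        centroid_um=(float(xs @ w), float(ys @ w), float(zs @ w)),
        compartment=members[0].compartment,
    )
    names = set().union(*(m.mean_intensity.keys() for m in members))
    for name in names:
        means = np.array([m.mean_intensity.get(name, 0.0) for m in members])
        integ = np.array([m.integrated_intensity.get(name, 0.0) for m in members])
        obj.mean_intensity[name] = float(means @ w)
        obj.integrated_intensity[name] = float(integ.sum() * z_step_um)
    return obj


def connect_by_best_match(
    planes: Sequence[Sequence[PlaneObject]],
    z_step_um: float,
    max_displacement_um: float = DEFAULT_NUCLEI_DISPLACEMENT_UM,
    max_gap_planes: int = 0,
    max_span_planes: int | None = None,
) -> list[Object3D]:
    """Link per-plane 2D objects into 3D objects.

    For each pair of (gap-tolerant) consecutive planes an optimal
    one-to-one assignment minimizing total lateral centroid distance is
    computed, with pairs farther apart than ``max_displacement_um``
    infeasible. Unmatched objects start or terminate chains, so no 2D
    object is ever used twice and none is silently dropped; a chain
    spanning a single plane is still a valid 3D object (a small nucleus
    can intersect only one optical section).

    ``max_span_planes`` bounds the number of sections one chain may
    collect — the axial analogue of the object size window. Without it,
    a column of distinct objects stacked within the lateral displacement
    cap is absorbed into a single chain whenever one intermediate
    section drops below the detection floor; with it, a saturated chain
    stops competing and the next object starts its own chain.
    """
    if max_displacement_um <= 0:
        raise ValueError("max_displacement_um must be > 0")
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0 (anisotropy must be known)")
    if max_span_planes is not None and max_span_planes < 1:
        raise ValueError("max_span_planes must be >= 1")
    finished: list[list[PlaneObject]] = []
    active: list[list[PlaneObject]] = []
    big = 1e12
    for z, objs in enumerate(planes):
        objs = list(objs)
        # retire chains that can no longer be extended
        still = []
        for chain in active:
            saturated = (max_span_planes is not None
                         and len(chain) >= max_span_planes)
            if saturated or z - chain[-1].z_index - 1 > max_gap_planes:
                finished.append(chain)
            else:
                still.append(chain)
        active = still
        if not objs:
            continue
        if not active:
            active = [[o] for o in objs]
            continue
        cost = np.full((len(active), len(objs)), big)
        for i, chain in enumerate(active):
            cx, cy = chain[-1].centroid_um
            for j, o in enumerate(objs):
                d = math.hypot(o.centroid_um[0] - cx, o.centroid_um[1] - cy)
                if d <= max_displacement_um:
                    cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        matched_new = set()
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                active[i].append(objs[j])
                matched_new.add(j)
        for j, o in enumerate(objs):
            if j not in matched_new:
                active.append([o])
    finished.extend(active)
    return [
        _aggregate(chain, label, z_step_um)
        for label, chain in enumerate(finished, start=1)
    ]


def measure_object3d(obj: Object3D, stack: ImageStack) -> Object3D:
    """(Re)populate an Object3D's measurements from stack voxels.

    Volume is Σ member-area x z-step; integrated intensity is Σ voxel
    intensity x voxel volume; the mean is over member voxels.
    """
    px_area = stack.pixel_size_um**2
    voxel_vol = px_area * stack.z_step_um
    total_px = sum(m.n_pixels for m in obj.members)
    obj.volume_um3 = float(sum(m.area_um2 for m in obj.members) * stack.z_step_um)
    xs = ys = zs = 0.0
    for m in obj.members:
        w = m.n_pixels / total_px
        xs += m.centroid_um[0] * w
        ys += m.centroid_um[1] * w
        zs += m.z_index * stack.z_step_um * w
    obj.centroid_um = (xs, ys, zs)
    for name in stack.channel_names:
        vol = stack.channel(name)
        tot = 0.0
        for m in obj.members:
            rr, cc = m.coords[:, 0], m.coords[:, 1]
            tot += float(vol[m.z_index][rr, cc].sum())
        obj.mean_intensity[name] = tot / total_px
        obj.integrated_intensity[name] = tot * voxel_vol
    return obj


@dataclass
class SpheroidRegion:
    """The whole spheroid as a single 3D object."""

    mask: np.ndarray  # (Z, Y, X) bool
    volume_um3: float
    centroid_um: tuple[float, float, float]
    mean_intensity: dict
    sphericity: float
    n_candidates: int = 1

    @property
    def equivalent_diameter_um(self) -> float:
        return equivalent_diameter(self.volume_um3)


@dataclass(frozen=True)
class FindSpheroidParams:
    min_diameter_um: float = 50.0
    max_diameter_um: float = 800.0
    smooth_sigma_um: float = 2.0
    close_radius_um: float = 12.0
    intensity_threshold: float | None = None  # None -> Otsu on the volume

    def __post_init__(self) -> None:
        if self.min_diameter_um >= self.max_diameter_um:
            raise ValueError("min_diameter_um must be < max_diameter_um")


def find_spherical_object(
    stack: ImageStack,
    channel: str = "DAPI",
    params: FindSpheroidParams | None = None,
) -> SpheroidRegion | None:
    """Detect the spheroid as the largest connected 3D region of
    above-threshold nuclear signal within the size window.

    Per-plane morphological closing and hole filling bridge the spaces
    between packed nuclei so the region approximates the solid spheroid
    cross-section. Returns ``None`` ("no spheroid found") when nothing
    falls inside the size window — an expected outcome for blank wells,
    distinct from an error.
    """
    if params is None:
        params = FindSpheroidParams()
    vol = np.asarray(stack.channel(channel), dtype=float)
    px = stack.pixel_size_um
    sm = np.stack([gaussian_smooth(p, params.smooth_sigma_um, px) for p in vol])
    if params.intensity_threshold is not None:
        thr = params.intensity_threshold
    else:
        if np.ptp(sm) == 0:
            return None
        thr = filters.threshold_otsu(sm)
    mask = sm > thr
    if not mask.any():
        return None
    selem = morphology.disk(max(1, int(round(params.close_radius_um / px))))
    closed = np.stack([
        ndimage.binary_fill_holes(ndimage.binary_closing(m, structure=selem))
        for m in mask
    ])
    labels, n = ndimage.label(closed, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return None
    voxel_vol = px * px * stack.z_step_um
    candidates = []
    for lab in range(1, n + 1):
        v = float((labels == lab).sum() * voxel_vol)
        d = equivalent_diameter(v)
        if params.min_diameter_um <= d <= params.max_diameter_um:
            candidates.append((v, lab))
    if not candidates:
        return None
    if len(candidates) > 1:
        logger.info("find_spherical_object: %d candidate regions in window, "
                    "keeping the largest", len(candidates))
    _, lab = max(candidates)
    region = labels == lab
    # spheroid cross-sections are convex: take the per-plane convex hull
    # of the selected component so sparse nuclear signal does not carve
    # bays out of the region
    region = np.stack([
        morphology.convex_hull_image(m) if m.any() else m for m in region
    ])
    volume = float(region.sum() * voxel_vol)
    zz, yy, xx = np.nonzero(region)
    centroid = (
        float((xx + 0.5).mean() * px),
        float((yy + 0.5).mean() * px),
        float(zz.mean() * stack.z_step_um),
    )
    means = {
        name: float(np.asarray(stack.channel(name), dtype=float)[region].mean())
        for name in stack.channel_names
    }
    sphericity = _sphericity(region, volume, px, stack.z_step_um)
    return SpheroidRegion(
        mask=region,
        volume_um3=volume,
        centroid_um=centroid,
        mean_intensity=means,
        sphericity=sphericity,
        n_candidates=len(candidates),
    )


def _sphericity(region: np.ndarray, volume_um3: float, px: float,
                z_step: float) -> float:
    """π^(1/3) (6V)^(2/3) / A with the surface area A estimated by
    marching cubes on the padded mask (1 for a perfect sphere)."""
    padded = np.pad(region, 1).astype(float)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=(z_step, px, px)
        )
        area = measure.mesh_surface_area(verts, faces)
    except (ValueError, RuntimeError):
        return float("nan")
    if area <= 0:
        return float("nan")
    s = math.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area
    return float(min(s, 1.0))


def max_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection: per-pixel maximum along z."""
    vol = stack.channel(channel)
    if vol.shape[0] < 1:
        raise ValueError("stack has no planes")
    return vol.max(axis=0)
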