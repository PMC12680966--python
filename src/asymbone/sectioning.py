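"""Bone alignment, biomechanical length, and cross-section extraction.

Percent-length convention (recorded in every output): **0 % = distal end,
100 % = proximal end**, with the proximal end identified as the larger one.
The default sectioning scheme extracts 28 sections in two intervals —
12.5–25.0 % and 37.5–90 % at 2.5 % steps — excluding the band where the
two bones of the lower-leg complex are fused (25–37.5 %).

Input geometry is either a :class:`~asymbone.synthetic.ContourStack`
(generated aligned, z ascending from the distal end) or a watertight
triangulated mesh (any pose; aligned here by principal axes of the vertex
scatter).  Left-side specimens should be mirrored to right-hand orientation
(``ContourStack.mirror`` / ``mirror_mesh``) before any shape comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import (ensure_ccw, is_simple_polygon, polygon_centroid,
                        polygon_contains, resample_arclength, signed_area)
from .errors import (AlignmentError, ConfigurationError, SectioningError,
                     SolidSectionError)
from .synthetic import ContourStack

__all__ = [
    "SectionLevels",
    "SectionContours",
    "default_section_levels",
    "section_levels",
    "align_bone",
    "extract_section",
    "mirror_mesh",
]

DEFAULT_INTERVALS = ((12.5, 25.0), (37.5, 90.0))
DEFAULT_EXCLUDED_BAND = (25.0, 37.5)
DEFAULT_STEP = 2.5


@dataclass(frozen=True)
class SectionLevels:
    """Ordered percent-of-length section levels with the excluded fused band."""

    levels: tuple[float, ...]
    excluded_band: tuple[float, float] = DEFAULT_EXCLUDED_BAND

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if len(lv) == 0 or np.any(np.diff(lv) <= 0):
            raise ConfigurationError("levels must be strictly increasing")
        if np.any((lv <= 0) | (lv >= 100)):
            raise ConfigurationError("levels must lie strictly inside (0, 100)")
        lo, hi = self.excluded_band
        if np.any((lv > lo) & (lv < hi)):
            raise ConfigurationError(
                f"levels fall inside the excluded band ({lo}, {hi})")

    def __len__(self):
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


def section_levels(step_percent: float = DEFAULT_STEP,
                   intervals=DEFAULT_INTERVALS,
                   excluded_band=DEFAULT_EXCLUDED_BAND) -> SectionLevels:
    """Levels at ``step_percent`` increments across each interval, endpoints
    inclusive; intervals must be disjoint from the excluded band."""
    lo, hi = excluded_band
    levels = []
    for a, b in intervals:
        if a < hi and b > lo:
            raise ConfigurationError(
                f"interval [{a}, {b}] overlaps the excluded band ({lo}, {hi})")
        n = int(np.floor((b - a) / step_percent + 1e-9))
        levels.extend(np.round(a + step_percent * np.arange(n + 1), 10))
    return SectionLevels(tuple(sorted(levels)), tuple(excluded_band))


def default_section_levels() -> SectionLevels:
    """The 28-section scheme: 6 sections in 12.5–25 %, 22 in 37.5–90 %."""
    return section_levels()


@dataclass
class SectionContours:
    """One extracted cross-section: paired closed planar contours.

    Both polylines are ordered counter-clockwise with positive signed area;
    the endosteal polygon lies strictly inside the periosteal one.
    ``center`` is the area centroid (centre of gravity) of the periosteal
    polygon, the origin of all equiangular ray sampling.
    """

    level_percent: float
    periosteal: np.ndarray
    endosteal: np.ndarray
    center: np.ndarray = field(default=None)
    z_mm: float = 0.0
    frame: str = "aligned: +z proximal, 0% distal, in-plane axes from the bone alignment"

    def __post_init__(self):
        self.periosteal = ensure_ccw(np.asarray(self.periosteal, dtype=float))
        self.endosteal = ensure_ccw(np.asarray(self.endosteal, dtype=float))
        if self.center is None:
            self.center = polygon_centroid(self.periosteal)

    def validate(self):
        if not is_simple_polygon(self.periosteal) or not is_simple_polygon(self.endosteal):
            raise SectioningError(
                f"self-intersecting contour at level {self.level_percent:.1f}%")
        if signed_area(self.periosteal) <= 0 or signed_area(self.endosteal) <= 0:
            raise SectioningError(
                f"non-positive contour area at level {self.level_percent:.1f}%")
        if not polygon_contains(self.periosteal, self.endosteal):
            raise SectioningError(
                f"endosteal contour not inside periosteal at level {self.level_percent:.1f}%")
        return self


# --------------------------------------------------------------------------
# alignment

def _principal_frame(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and right-handed principal axes (columns x, y, z) of a vertex
    cloud; z is the long (largest-scatter / smallest-inertia) axis."""
    c = vertices.mean(axis=0)
    v = vertices - c
    cov = v.T @ v / len(v)
    w, e = np.linalg.eigh(cov)          # ascending eigenvalues
    axes = e[:, ::-1]                    # columns: z-candidate, x, y by scatter
    frame = np.column_stack([axes[:, 1], axes[:, 2], axes[:, 0]])  # x, y, z
    if np.linalg.det(frame) < 0:
        frame[:, 1] *= -1.0
    return c, frame


def align_bone(geometry):
    """Align the long axis with z and measure biomechanical length L (mm).

    Returns ``(aligned_geometry, L)``.  Contour stacks are generated aligned
    and are passed through (re-zeroed so the distal end sits at z = 0).
    Meshes are rotated into the principal frame of their vertex scatter; the
    end with the larger cross-sectional extent is taken as proximal (+z),
    the in-plane x sign fixed by the third moment of the x distribution.
    """
    if isinstance(geometry, ContourStack):
        L = geometry.length_mm
        if L <= 0:
            raise AlignmentError("contour stack has zero axial extent")
        z0 = geometry.z_mm[0]
        if z0 != 0.0:
            geometry = ContourStack(geometry.levels_percent, geometry.z_mm - z0,
                                    geometry.periosteal, geometry.endosteal)
        return geometry, L

    import trimesh

    if not isinstance(geometry, trimesh.Trimesh):
        raise AlignmentError(f"unsupported geometry type {type(geometry)!r}")
    verts = np.asarray(geometry.vertices, dtype=float)
    if len(verts) < 4:
        raise AlignmentError("degenerate mesh: too few vertices")
    c, frame = _principal_frame(verts)
    local = (verts - c) @ frame
    zmin, zmax = local[:, 2].min(), local[:, 2].max()
    L = float(zmax - zmin)
    if L <= 0:
        raise AlignmentError("degenerate geometry: zero axial extent")

    # proximal = larger end: compare mean in-plane radius in the end slabs
    slab = 0.10 * L
    lo = local[local[:, 2] < zmin + slab]
    hi = local[local[:, 2] > zmax - slab]
    r_lo = np.hypot(lo[:, 0], lo[:, 1]).mean()
    r_hi = np.hypot(hi[:, 0], hi[:, 1]).mean()
    if r_lo > r_hi:                       # big end at -z: flip about x-axis
        local[:, 2] *= -1.0
        local[:, 1] *= -1.0
    # deterministic in-plane sign: positive third moment of x
    if np.mean(local[:, 0] ** 3) < 0:
        local[:, 0] *= -1.0
        local[:, 1] *= -1.0
    local[:, 2] -= local[:, 2].min()
    aligned = trimesh.Trimesh(vertices=local, faces=geometry.faces, process=False)
    return aligned, L


def mirror_mesh(mesh):
    """Reflect a mesh across the sagittal (x = 0) plane, fixing face winding."""
    import trimesh

    verts = np.asarray(mesh.vertices, dtype=float).copy()
    verts[:, 0] *= -1.0
    faces = np.asarray(mesh.faces)[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# --------------------------------------------------------------------------
# section extraction

def _interp_stack_contours(stack: ContourStack, level_percent: float):
    """Vertex-wise linear interpolation of the stack at a percent level."""
    L = stack.length_mm
    z = level_percent / 100.0 * L + stack.z_mm[0]
    zs = stack.z_mm
    i = int(np.clip(np.searchsorted(zs, z) - 1, 0, len(zs) - 2))
    t = (z - zs[i]) / (zs[i + 1] - zs[i])
    t = float(np.clip(t, 0.0, 1.0))
    peri = (1 - t) * stack.periosteal[i] + t * stack.periosteal[i + 1]
    endo = (1 - t) * stack.endosteal[i] + t * stack.endosteal[i + 1]
    return peri, endo, float(z - stack.z_mm[0])


def _mesh_section_loops(mesh, z: float):
    """Closed planar loops of the mesh-plane intersection at height z."""
    sec = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if sec is None:
        raise SectioningError(f"no intersection at z = {z:.3f} mm")
    loops = []
    for d in sec.discrete:
        pts = np.asarray(d, dtype=float)[:, :2]
        if len(pts) >= 4 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) >= 3:
            loops.append(pts)
    if not loops:
        raise SectioningError(f"no closed intersection curve at z = {z:.3f} mm")
    return loops


def extract_section(aligned_geometry, level_percent: float,
                    n_resample: int = 1000,
                    excluded_band=DEFAULT_EXCLUDED_BAND) -> SectionContours:
    """Extract the periosteal/endosteal contour pair at a percent level.

    The periosteal contour is the largest-area closed intersection curve and
    the endosteal the largest-area curve strictly inside it; any additional
    disjoint curves (e.g. the second bone of the complex outside the fused
    band) are discarded.  Contours are resampled by arc length to
    ``n_resample`` counter-clockwise vertices.
    """
    if excluded_band is not None:
        lo, hi = excluded_band
        if lo < level_percent < hi:
            raise ConfigurationError(
                f"level {level_percent}% lies inside the excluded band ({lo}, {hi})")

    if isinstance(aligned_geometry, ContourStack):
        peri, endo, z = _interp_stack_contours(aligned_geometry, level_percent)
    else:
        zmax = float(np.asarray(aligned_geometry.vertices)[:, 2].max())
        z = level_percent / 100.0 * zmax
        loops = _mesh_section_loops(aligned_geometry, z)
        loops = [ensure_ccw(lp) for lp in loops]
        areas = [abs(signed_area(lp)) for lp in loops]
        peri = loops[int(np.argmax(areas))]
        inner = [(a, lp) for a, lp in zip(areas, loops)
                 if lp is not peri and polygon_contains(peri, lp)]
        if not inner:
            raise SolidSectionError(
                f"no interior (endosteal) curve at level {level_percent}%")
        endo = max(inner, key=lambda t: t[0])[1]

    peri = resample_arclength(ensure_ccw(peri), n_resample)
    endo = resample_arclength(ensure_ccw(endo), n_resample)
    return SectionContours(level_percent=float(level_percent),
                           periosteal=peri, endosteal=endo, z_mm=z)
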