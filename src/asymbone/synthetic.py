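"""Seeded generator of paired left/right diaphyseal geometries.

The generator emulates a loading experiment on paired hind-limb long bones:
a cohort of individuals, a subset of which received unilateral stimulation
of the left limb.  Each bone is a tubular diaphysis represented as a stack
of periosteal/endosteal contours whose radii are smooth functions of axial
position and polar angle (sums of low-order Fourier harmonics about a
level-specific centre, so every section is star-shaped and equiangular ray
sampling is single-valued).

Percent-length convention: 0 % is the *distal* end, 100 % the proximal end.

Sources of variation, by design:

* ``individual_sd`` — a per-individual **isometric size** factor shared by
  both limbs.  Size is removed downstream (Procrustes scaling, length
  standardisation, dimensionless thickness ratios), so at zero effect the
  limbs are exchangeable in shape space and free-permutation tests are
  calibrated.
* ``noise_sd`` — per-limb variation: a smooth low-order harmonic field
  (biological fluctuating asymmetry / positioning error) plus independent
  per-vertex radial noise, both scaled by the local radius.
* ``effect_magnitude`` (δ) — the lateralised treatment effect, applied only
  to the stimulated limb inside an axial × angular window: periosteal
  expansion plus inward endosteal displacement (cortical thickening),
  mimicking a distal periosteal response with medial-posterior thickening.

Side is encoded by mirroring the x-axis; the field is applied before the
mirror, on the stimulated (left) side only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._geometry import polygon_contains, signed_area
from .errors import GenerationError, ParameterError

__all__ = [
    "CohortParams",
    "AsymmetryField",
    "DiaphysisProfile",
    "ContourStack",
    "Specimen",
    "base_diaphysis",
    "generate_cohort",
    "generate_entheseal_areas",
    "stack_to_mesh",
    "write_cohort",
]


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the emulated experiment: nine individuals, six with a
    stimulated (left) limb and three bilaterally symmetric controls.
    """

    n_stimulated: int = 6
    n_control: int = 3
    effect_magnitude: float = 1.0
    individual_sd: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_stimulated < 0 or self.n_control < 0:
            raise ParameterError("group counts must be non-negative")
        if self.n_stimulated + self.n_control < 1:
            raise ParameterError("cohort must contain at least one individual")
        if self.effect_magnitude < 0:
            raise ParameterError("effect_magnitude must be >= 0")
        if self.individual_sd < 0 or self.noise_sd < 0:
            raise ParameterError("standard deviations must be >= 0")


@dataclass(frozen=True)
class AsymmetryField:
    """Localised left-limb effect: where it acts and how strongly at δ = 1.

    ``axial_window`` is in percent of biomechanical length measured from the
    distal end; ``angular_window`` in degrees in the section-local polar
    frame (may wrap through 0°).  The default window is distal (covering the
    20 % level, excluding the 50 % midshaft) and spans the medial-posterior
    quadrant.
    """

    axial_window: tuple[float, float] = (10.0, 40.0)
    angular_window: tuple[float, float] = (180.0, 270.0)
    periosteal_gain: float = 0.10
    endosteal_shift: float = 0.15

    def __post_init__(self):
        lo, hi = self.axial_window
        if not (0.0 <= lo < hi <= 100.0):
            raise ParameterError(f"axial_window {self.axial_window} outside [0, 100]")
        a, b = self.angular_window
        if not (0.0 <= a < 360.0 and 0.0 <= b < 360.0):
            raise ParameterError(f"angular_window {self.angular_window} outside [0, 360)")
        if not (np.isfinite(self.periosteal_gain) and np.isfinite(self.endosteal_shift)):
            raise ParameterError("field gains must be finite")

    def bump(self, percent: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
        """Smooth [0, 1] weight field, broadcast over percent × theta.

        Raised-cosine tapers inside each window; identically zero outside.
        """
        lo, hi = self.axial_window
        p = np.asarray(percent, dtype=float)
        u = np.clip((p - lo) / (hi - lo), 0.0, 1.0)
        axial = np.sin(np.pi * u) ** 2
        axial = np.where((p > lo) & (p < hi), axial, 0.0)

        a, b = np.radians(self.angular_window)
        span = (b - a) % (2 * np.pi)
        if span == 0.0:
            span = 2 * np.pi
        t = (np.asarray(theta_rad, dtype=float) - a) % (2 * np.pi)
        v = np.clip(t / span, 0.0, 1.0)
        angular = np.where(t < span, np.sin(np.pi * v) ** 2, 0.0)
        return np.atleast_1d(axial)[:, None] * np.atleast_1d(angular)[None, :]

    def window_mask(self, percent, angles_deg) -> np.ndarray:
        """Boolean (n_levels, k) mask of section × ray cells strictly inside
        both effect windows (ground truth for localisation checks)."""
        return self.bump(np.asarray(percent, dtype=float),
                         np.radians(np.asarray(angles_deg, dtype=float))) > 0.0


@dataclass(frozen=True)
class DiaphysisProfile:
    """Smooth template for a tubular diaphysis.

    Radii in mm; the shaft flares at both ends (more proximally, which is
    how the proximal end is recognised during alignment), the cortex is
    thickest near midshaft, sections are mildly elliptical with a slow
    axial twist, plus a third harmonic for the triangular shaft outline.
    """

    length_mm: float = 40.0
    radius_mm: float = 1.4
    distal_flare: float = 0.15
    proximal_flare: float = 0.45
    flare_width_distal: float = 18.0
    flare_width_proximal: float = 15.0
    endosteal_fraction_mid: float = 0.62
    endosteal_fraction_dip: float = 0.12
    ellipticity: float = 0.12
    triangularity: float = 0.05
    twist_deg_per_percent: float = 0.15
    curvature_mm: float = 0.3
    endosteal_offset_fraction: float = 0.06
    endosteal_offset_angle_deg: float = 200.0

    def periosteal_radius_profile(self, percent: np.ndarray) -> np.ndarray:
        p = np.asarray(percent, dtype=float)
        return self.radius_mm * (
            1.0
            + self.distal_flare * np.exp(-((p / self.flare_width_distal) ** 2))
            + self.proximal_flare * np.exp(-(((100.0 - p) / self.flare_width_proximal) ** 2))
        )

    def endosteal_fraction(self, percent: np.ndarray) -> np.ndarray:
        p = np.asarray(percent, dtype=float)
        return self.endosteal_fraction_mid - self.endosteal_fraction_dip * np.exp(
            -(((p - 50.0) / 30.0) ** 2))


@dataclass
class ContourStack:
    """Ordered stack of paired periosteal/endosteal contours along the shaft.

    ``periosteal``/``endosteal`` have shape (n_levels, n_vertices, 2) in mm,
    ``z_mm`` is ascending with 0 at the distal end.  Corresponding vertices
    across levels share the generating polar angle, so contours at
    intermediate levels may be linearly interpolated vertex-wise.
    """

    levels_percent: np.ndarray
    z_mm: np.ndarray
    periosteal: np.ndarray
    endosteal: np.ndarray

    @property
    def length_mm(self) -> float:
        return float(self.z_mm[-1] - self.z_mm[0])

    @property
    def n_levels(self) -> int:
        return len(self.levels_percent)

    def mirror(self) -> "ContourStack":
        """Reflect across the sagittal plane (x -> -x), restoring CCW order."""
        peri = self.periosteal.copy()
        endo = self.endosteal.copy()
        peri[..., 0] *= -1.0
        endo[..., 0] *= -1.0
        return ContourStack(self.levels_percent.copy(), self.z_mm.copy(),
                            peri[:, ::-1].copy(), endo[:, ::-1].copy())

    def scaled(self, factor: float) -> "ContourStack":
        return ContourStack(self.levels_percent.copy(), self.z_mm * factor,
                            self.periosteal * factor, self.endosteal * factor)

    def validate(self) -> None:
        """Check CCW orientation and strict endosteal enclosure at all levels."""
        for i in range(self.n_levels):
            if signed_area(self.periosteal[i]) <= 0 or signed_area(self.endosteal[i]) <= 0:
                raise GenerationError(f"non-CCW contour at level {self.levels_percent[i]:.1f}%")
            if not polygon_contains(self.periosteal[i], self.endosteal[i]):
                raise GenerationError(
                    "endosteal contour not strictly inside periosteal contour "
                    f"at level {self.levels_percent[i]:.1f}%")

    # ---- contour CSV format: level_percent, contour, vertex_index, x, y, z
    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for name, arr in (("periosteal", self.periosteal), ("endosteal", self.endosteal)):
            nl, nv, _ = arr.shape
            frames.append(pd.DataFrame({
                "level_percent": np.repeat(self.levels_percent, nv),
                "contour": name,
                "vertex_index": np.tile(np.arange(nv), nl),
                "x": arr[..., 0].ravel(),
                "y": arr[..., 1].ravel(),
                "z": np.repeat(self.z_mm, nv),
            }))
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContourStack":
        levels = np.sort(df["level_percent"].unique())
        stacks = {}
        z = np.empty(len(levels))
        for name in ("periosteal", "endosteal"):
            sub = df[df["contour"] == name]
            arrs = []
            for i, lev in enumerate(levels):
                at = sub[sub["level_percent"] == lev].sort_values("vertex_index")
                arrs.append(at[["x", "y"]].to_numpy(dtype=float))
                z[i] = float(at["z"].iloc[0])
            stacks[name] = np.stack(arrs)
        return cls(np.asarray(levels, dtype=float), z,
                   stacks["periosteal"], stacks["endosteal"])

    @classmethod
    def read_csv(cls, path) -> "ContourStack":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class Specimen:
    """One limb of one individual: geometry plus experimental metadata.

    ``stimulated`` flags the *limb* (true only for the stimulated side of a
    stimulated individual); ``stimulated_individual`` flags the animal.
    """

    individual_id: str
    side: Literal["left", "right"]
    stimulated: bool
    geometry: object  # ContourStack or trimesh.Trimesh
    stimulated_individual: bool = False
    length_units: str = "mm"

    @property
    def label(self) -> str:
        return f"{self.individual_id}_{self.side}"


# --------------------------------------------------------------------------
# generation

_DEFAULT_LEVELS = np.linspace(0.0, 100.0, 51)


def _template_stack(profile: DiaphysisProfile, levels_percent: np.ndarray,
                    n_vertices: int) -> ContourStack:
    """Noise-free template geometry on the given percent levels."""
    p = np.asarray(levels_percent, dtype=float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r0 = profile.periosteal_radius_profile(p)[:, None]
    twist = np.radians(profile.twist_deg_per_percent * p)[:, None]
    shape2 = profile.ellipticity * np.cos(2.0 * (theta[None, :] - twist))
    shape3 = profile.triangularity * np.cos(3.0 * theta[None, :] - 0.7)
    r_peri = r0 * (1.0 + shape2 + shape3)
    r_endo = r0 * profile.endosteal_fraction(p)[:, None] * (1.0 + 0.8 * shape2)

    cx = profile.curvature_mm * np.sin(np.pi * p / 100.0)
    cy = 0.4 * profile.curvature_mm * np.sin(2.0 * np.pi * p / 100.0)
    center = np.column_stack([cx, cy])
    off_ang = np.radians(profile.endosteal_offset_angle_deg)
    endo_center = center + profile.endosteal_offset_fraction * r0 * np.array(
        [np.cos(off_ang), np.sin(off_ang)])

    cs, sn = np.cos(theta), np.sin(theta)
    peri = np.stack([center[:, :1] + r_peri * cs[None, :],
                     center[:, 1:] + r_peri * sn[None, :]], axis=-1)
    endo = np.stack([endo_center[:, :1] + r_endo * cs[None, :],
                     endo_center[:, 1:] + r_endo * sn[None, :]], axis=-1)
    z = p / 100.0 * profile.length_mm
    return ContourStack(p.copy(), z, peri, endo)


def base_diaphysis(n_levels: int = 51, n_vertices: int = 192,
                   profile_params: DiaphysisProfile | None = None) -> ContourStack:
    """Noise-free tubular diaphysis as a contour stack.

    Raises :class:`GenerationError` if the profile parameters produce
    self-intersecting contours or break strict endosteal enclosure.
    """
    if n_levels < 2:
        raise ParameterError("n_levels must be >= 2")
    profile = profile_params or DiaphysisProfile()
    levels = np.linspace(0.0, 100.0, n_levels)
    stack = _template_stack(profile, levels, n_vertices)
    stack.validate()
    return stack


def _limb_geometry(profile, levels, n_vertices, rng, params, field, delta,
                   size_factor, side):
    """One limb's contour stack: template × smooth jitter × effect × noise."""
    stack = _template_stack(profile, levels, n_vertices)
    p = stack.levels_percent
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)

    # smooth per-limb harmonic jitter: shared multiplicative field on both
    # contours, so enclosure is preserved
    if params.noise_sd > 0:
        jitter = np.zeros((len(p), n_vertices))
        coefs = rng.normal(size=(3, 3)) / 3.0
        phases_t = rng.uniform(0, 2 * np.pi, size=3)
        phases_a = rng.uniform(0, 2 * np.pi, size=3)
        for m in range(1, 4):
            for nax in range(3):
                jitter += coefs[m - 1, nax] * np.outer(
                    np.cos(nax * np.pi * p / 100.0 + phases_a[nax]),
                    np.cos(m * theta + phases_t[m - 1]))
        jitter *= params.noise_sd
        factor = 1.0 + jitter
    else:
        factor = np.ones((len(p), n_vertices))

    # localized stimulated-limb effect, applied pre-mirror
    if delta > 0 and field is not None:
        bump = field.bump(p, theta)
        peri_gain = 1.0 + delta * field.periosteal_gain * bump
        endo_gain = 1.0 - delta * field.endosteal_shift * bump
    else:
        peri_gain = endo_gain = 1.0

    center_p = stack.periosteal.mean(axis=1, keepdims=True)
    center_e = stack.endosteal.mean(axis=1, keepdims=True)
    peri = center_p + (stack.periosteal - center_p) * (factor * peri_gain)[..., None]
    endo = center_e + (stack.endosteal - center_e) * (factor * endo_gain)[..., None]

    # per-vertex radial measurement noise, relative to the mean radius
    if params.noise_sd > 0:
        for arr, ctr in ((peri, center_p), (endo, center_e)):
            v = arr - ctr
            r = np.hypot(v[..., 0], v[..., 1])
            rbar = r.mean()
            noise = rng.normal(scale=0.5 * params.noise_sd * rbar, size=r.shape)
            arr += v / r[..., None] * noise[..., None]

    out = ContourStack(stack.levels_percent, stack.z_mm, peri, endo)
    out = out.scaled(size_factor)
    if side == "left":
        out = out.mirror()
    return out


def generate_cohort(params: CohortParams | None = None,
                    field: AsymmetryField | None = None,
                    levels_percent: np.ndarray | None = None,
                    n_vertices: int = 192,
                    profile: DiaphysisProfile | None = None,
                    validate: bool = False) -> list[Specimen]:
    """Generate the paired-limb cohort.

    Returns ``2 * (n_stimulated + n_control)`` specimens.  In stimulated
    individuals the left limb carries the asymmetry field at magnitude
    ``params.effect_magnitude``; controls are bilaterally symmetric up to
    noise.  Fully reproducible from ``params.seed`` (one seed sequence per
    cohort; per-specimen substreams spawned deterministically).
    """
    params = params or CohortParams()
    field = field if field is not None else AsymmetryField()
    levels = np.asarray(levels_percent if levels_percent is not None
                        else _DEFAULT_LEVELS, dtype=float)
    profile = profile or DiaphysisProfile()

    n_ind = params.n_stimulated + params.n_control
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(n_ind)
    specimens: list[Specimen] = []
    for i in range(n_ind):
        ind_stim = i < params.n_stimulated
        ind_id = f"{'stim' if ind_stim else 'ctrl'}{i + 1:02d}"
        ind_rng = np.random.default_rng(streams[i])
        size_factor = float(np.exp(ind_rng.normal(scale=params.individual_sd)))
        limb_seeds = streams[i].spawn(2)
        for side, sseq in zip(("left", "right"), limb_seeds):
            limb_stim = ind_stim and side == "left"
            delta = params.effect_magnitude if limb_stim else 0.0
            geom = _limb_geometry(profile, levels, n_vertices,
                                  np.random.default_rng(sseq), params, field,
                                  delta, size_factor, side)
            if validate:
                geom.validate()
            specimens.append(Specimen(ind_id, side, limb_stim, geom,
                                      stimulated_individual=ind_stim))
    return specimens


def generate_entheseal_areas(params: CohortParams | None = None,
                             structures: tuple[str, ...] = ("CAL TUB", "TA ORIGIN", "EDL ORIGIN"),
                             base_areas_mm2: tuple[float, ...] = (8.0, 5.0, 4.0),
                             stimulated_inflation: tuple[float, ...] = (0.0, 0.15, 0.20),
                             cv: float = 0.05) -> pd.DataFrame:
    """Synthetic 3D entheseal surface areas (mm²) per limb.

    Stand-in for externally measured muscle-attachment areas: stimulated
    limbs inflate the attachment sites of the stimulated muscles by
    ``effect_magnitude × stimulated_inflation``; the first structure (a
    muscle not involved in the stimulation) is unaffected.  Lognormal
    measurement noise with coefficient of variation ``cv``.
    """
    params = params or CohortParams()
    root = np.random.SeedSequence([params.seed, 917])
    rng = np.random.default_rng(root)
    rows = []
    n_ind = params.n_stimulated + params.n_control
    sigma = np.sqrt(np.log1p(cv ** 2))
    for i in range(n_ind):
        ind_stim = i < params.n_stimulated
        ind_id = f"{'stim' if ind_stim else 'ctrl'}{i + 1:02d}"
        size2 = float(np.exp(rng.normal(scale=params.individual_sd))) ** 2
        for side in ("left", "right"):
            limb_stim = ind_stim and side == "left"
            row = {"individual_id": ind_id, "side": side, "stimulated": limb_stim,
                   "stimulated_individual": ind_stim}
            for name, base, infl in zip(structures, base_areas_mm2, stimulated_inflation):
                gain = 1.0 + params.effect_magnitude * infl if limb_stim else 1.0
                row[name] = base * size2 * gain * float(np.exp(rng.normal(scale=sigma)))
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# export

def stack_to_mesh(stack: ContourStack):
    """Triangulate a contour stack into a watertight solid (trimesh.Trimesh).

    Outer and inner tube surfaces plus annular end caps; outward-facing
    normals.  Requires equal vertex counts on all contours.
    """
    import trimesh

    nl, nv, _ = stack.periosteal.shape
    peri3 = np.dstack([stack.periosteal, np.repeat(stack.z_mm, nv).reshape(nl, nv, 1)[..., 0]])
    endo3 = np.dstack([stack.endosteal, np.repeat(stack.z_mm, nv).reshape(nl, nv, 1)[..., 0]])
    verts = np.vstack([peri3.reshape(-1, 3), endo3.reshape(-1, 3)])
    off = nl * nv

    def ring(level, inner):
        base = off + level * nv if inner else level * nv
        return np.arange(base, base + nv)

    faces = []

    def tube(get_ring, flip):
        for lev in range(nl - 1):
            a, b = get_ring(lev), get_ring(lev + 1)
            for j in range(nv):
                jn = (j + 1) % nv
                f1 = [a[j], a[jn], b[j]]
                f2 = [a[jn], b[jn], b[j]]
                if flip:
                    f1, f2 = f1[::-1], f2[::-1]
                faces.append(f1)
                faces.append(f2)

    tube(lambda l: ring(l, False), flip=False)   # outer wall, normals out
    tube(lambda l: ring(l, True), flip=True)     # inner wall, normals into cavity

    def cap(level, flip):
        a, b = ring(level, False), ring(level, True)
        for j in range(nv):
            jn = (j + 1) % nv
            f1 = [a[j], b[j], a[jn]]
            f2 = [a[jn], b[j], b[jn]]
            if flip:
                f1, f2 = f1[::-1], f2[::-1]
            faces.append(f1)
            faces.append(f2)

    cap(0, flip=False)       # distal cap faces -z
    cap(nl - 1, flip=True)   # proximal cap faces +z
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def write_cohort(specimens: list[Specimen], outdir, params: CohortParams | None = None,
                 mode: str = "contours") -> None:
    """Write per-specimen geometry (contour CSV or PLY) and cohort metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for sp in specimens:
        stem = sp.label
        if mode == "contours":
            sp.geometry.write_csv(outdir / f"{stem}.csv")
        elif mode == "mesh":
            stack_to_mesh(sp.geometry).export(outdir / f"{stem}.ply", encoding="ascii")
        else:
            raise ParameterError(f"unknown write mode {mode!r}")
        meta.append({"individual_id": sp.individual_id, "side": sp.side,
                     "stimulated": sp.stimulated,
                     "stimulated_individual": sp.stimulated_individual,
                     "file": f"{stem}.csv" if mode == "contours" else f"{stem}.ply"})
    payload = {"specimens": meta}
    if params is not None:
        payload["params"] = {
            "n_stimulated": params.n_stimulated, "n_control": params.n_control,
            "effect_magnitude": params.effect_magnitude,
            "individual_sd": params.individual_sd, "noise_sd": params.noise_sd,
            "seed": params.seed,
        }
    (outdir / "cohort.json").write_text(json.dumps(payload, indent=2))
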