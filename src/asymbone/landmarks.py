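"""Equiangular paired semilandmarks on cross-sections.

On each section, ``k`` rays leave the periosteal area centroid at angles
θ₀ + i·360/k (θ₀ on the section frame's +x axis); each ray crosses the
periosteal and the endosteal contour exactly once (sections must be
star-shaped about that centre), giving ``k`` paired points per section.
The reference scheme — 28 sections × 24 rays × 2 surfaces — yields 1344
semilandmarks per bone, homologous across specimens by construction: the
index order (section-major, then ray, periosteal before endosteal) is
identical everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import ray_intersections
from .errors import AggregationError, ParameterError
from .sectioning import SectionContours, SectionLevels, align_bone, extract_section

__all__ = ["LandmarkConfiguration", "equiangular_sample", "build_configuration"]


@dataclass
class LandmarkConfiguration:
    """Ordered 3D semilandmark array for one specimen.

    ``coords`` has shape (n_sections, k_per_contour, 2, 3): axis 2 indexes
    the surface (0 = periosteal, 1 = endosteal).  ``flat`` gives the
    (n_landmarks, 3) view in the canonical flat order.
    """

    coords: np.ndarray
    levels_percent: np.ndarray
    angles_deg: np.ndarray
    specimen: object = None

    @property
    def n_sections(self) -> int:
        return self.coords.shape[0]

    @property
    def k_per_contour(self) -> int:
        return self.coords.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.n_sections * self.k_per_contour * 2

    @property
    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)

    def labels(self) -> pd.DataFrame:
        """One row per landmark in flat order: section level, ray angle, surface."""
        ns, k = self.n_sections, self.k_per_contour
        return pd.DataFrame({
            "landmark_index": np.arange(self.n_landmarks),
            "section_level_percent": np.repeat(self.levels_percent, 2 * k),
            "angle_deg": np.tile(np.repeat(self.angles_deg, 2), ns),
            "surface": np.tile(["periosteal", "endosteal"], ns * k),
        })

    def to_wide_row(self) -> pd.Series:
        flat = self.flat
        data = {}
        for i in range(len(flat)):
            data[f"lm{i}_x"], data[f"lm{i}_y"], data[f"lm{i}_z"] = flat[i]
        return pd.Series(data)

    def to_long_dataframe(self) -> pd.DataFrame:
        lab = self.labels()
        lab[["x", "y", "z"]] = self.flat
        return lab


def equiangular_sample(section: SectionContours, k: int,
                       theta0_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Paired periosteal/endosteal points on ``k`` equiangular rays.

    Rays originate at the periosteal area centroid.  Returns two (k, 2)
    arrays (periosteal, endosteal) in section-plane coordinates; raises
    :class:`NonStarShapeError` (with section id and angle) if either contour
    crosses a ray more than once.
    """
    if k < 3:
        raise ParameterError("k must be >= 3")
    angles = np.radians(theta0_deg) + 2.0 * np.pi * np.arange(k) / k
    peri = ray_intersections(section.periosteal, section.center, angles,
                             level_percent=section.level_percent)
    endo = ray_intersections(section.endosteal, section.center, angles,
                             level_percent=section.level_percent)
    return peri, endo


def build_configuration(specimen_or_geometry, levels: SectionLevels, k: int = 24,
                        theta0_deg: float = 0.0,
                        n_resample: int = 1000) -> LandmarkConfiguration:
    """Section a specimen at all levels and assemble its landmark configuration.

    Deterministic ordering: section-major, ray-minor, periosteal before
    endosteal.  Any failed section aborts with an
    :class:`AggregationError` listing the failed levels.
    """
    specimen = None
    geometry = specimen_or_geometry
    if hasattr(specimen_or_geometry, "geometry"):
        specimen = specimen_or_geometry
        geometry = specimen_or_geometry.geometry
    aligned, L = align_bone(geometry)

    lv = np.asarray(list(levels), dtype=float)
    coords = np.empty((len(lv), k, 2, 3))
    failed = []
    for i, level in enumerate(lv):
        try:
            sec = extract_section(aligned, level, n_resample=n_resample,
                                  excluded_band=getattr(levels, "excluded_band", None))
            peri, endo = equiangular_sample(sec, k, theta0_deg)
        except Exception as exc:  # noqa: BLE001 - aggregated below
            failed.append((float(level), str(exc)))
            continue
        coords[i, :, 0, :2] = peri
        coords[i, :, 1, :2] = endo
        coords[i, :, :, 2] = sec.z_mm
    if failed:
        raise AggregationError(
            "sectioning failed at levels: "
            + ", ".join(f"{lv:.1f}% ({msg})" for lv, msg in failed),
            failed_levels=[lv for lv, _ in failed])
    return LandmarkConfiguration(coords=coords, levels_percent=lv,
                                 angles_deg=np.degrees(
                                     np.radians(theta0_deg) + 2 * np.pi * np.arange(k) / k) % 360.0,
                                 specimen=specimen)
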