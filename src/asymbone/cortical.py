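"""Relative cortical-thickness maps along the diaphysis.

For each retained section, 1000 equiangular rays from the periosteal
centroid give paired periosteal/endosteal crossings; the map entry for ray
i is t_i / r_i, the cortical thickness (distance between the paired
crossings) normalised by the local periosteal radius (distance from the
periosteal crossing to the centre of gravity).  Rows are section levels in
order (the fused band absent), columns the 1000 ray angles; values are
dimensionless and invariant to global scaling of the specimen.

Maps are compared across specimens by PCA of the row-major flattened
matrices, and map variations reconstructed at chosen PC scores for
warm/cold rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .landmarks import equiangular_sample
from .sectioning import SectionContours, SectionLevels, align_bone, extract_section
from .shape import PCAResult, pca

__all__ = ["ThicknessMap", "thickness_profile", "build_map", "map_pca",
           "map_at_pc_extreme"]


@dataclass
class ThicknessMap:
    """Sections × angles matrix of relative cortical thickness."""

    values: np.ndarray          # (n_levels, m), each in (0, 1) for ring sections
    levels_percent: np.ndarray
    angles_deg: np.ndarray
    specimen: object = None

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        """Mean relative cortical thickness per section level."""
        return self.values.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=np.round(self.angles_deg, 6))
        df.insert(0, "level_percent", self.levels_percent)
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def thickness_profile(section: SectionContours, m: int = 1000,
                      theta0_deg: float = 0.0) -> np.ndarray:
    """One map row: relative cortical thickness on ``m`` equiangular rays."""
    peri, endo = equiangular_sample(section, m, theta0_deg)
    t = np.linalg.norm(peri - endo, axis=1)
    r = np.linalg.norm(peri - section.center, axis=1)
    return t / r


def build_map(specimen_or_geometry, levels: SectionLevels, m: int = 1000,
              theta0_deg: float = 0.0, n_resample: int = 1000) -> ThicknessMap:
    """Stack thickness profiles at all retained levels, in level order."""
    specimen = None
    geometry = specimen_or_geometry
    if hasattr(specimen_or_geometry, "geometry"):
        specimen = specimen_or_geometry
        geometry = specimen_or_geometry.geometry
    aligned, _ = align_bone(geometry)
    lv = np.asarray(list(levels), dtype=float)
    rows = np.empty((len(lv), m))
    for i, level in enumerate(lv):
        sec = extract_section(aligned, level, n_resample=n_resample,
                              excluded_band=getattr(levels, "excluded_band", None))
        rows[i] = thickness_profile(sec, m, theta0_deg)
    angles = np.degrees(np.radians(theta0_deg) + 2 * np.pi * np.arange(m) / m) % 360.0
    return ThicknessMap(values=rows, levels_percent=lv, angles_deg=angles,
                        specimen=specimen)


def map_pca(maps: list[ThicknessMap]) -> PCAResult:
    """Covariance-based PCA of row-major flattened maps (values are already
    dimensionless and commensurate)."""
    if len(maps) < 2:
        raise InputError("need >= 2 maps")
    shapes = {mp.values.shape for mp in maps}
    if len(shapes) > 1:
        raise InputError(f"map dimension mismatch: {shapes}")
    x = np.stack([mp.values.ravel() for mp in maps])
    return pca(x)


def map_at_pc_extreme(pca_result: PCAResult, component: int, score: float,
                      like: ThicknessMap) -> ThicknessMap:
    """Map variation ``mean + score × loading`` reshaped to map form."""
    if not 0 <= component < pca_result.n_components:
        raise IndexError(f"component {component} out of range")
    vec = pca_result.center + score * pca_result.loadings[component]
    return ThicknessMap(values=vec.reshape(like.values.shape),
                        levels_percent=like.levels_percent,
                        angles_deg=like.angles_deg)
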