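"""Cross-sectional geometry: beam-theory parameters of diaphyseal sections.

Eight parameters per section describe the load-bearing cortical ring:

* TotA — total (periosteal) area, mm²
* MedA — medullary (endosteal) area, mm²
* CorA — cortical area, TotA − MedA, mm²
* TotP / MedP — periosteal / endosteal perimeters, mm
* Imin / Imax — principal second moments of area of the cortical ring, mm⁴
  (eigenvalues of the 2×2 area-moment tensor about the ring centroid)
* J — polar second moment, Imin + Imax, mm⁴ (torsional rigidity summary)

All integrals use the exact Green's-theorem polygon formulas; ring moments
are periosteal-polygon integrals minus endosteal-polygon integrals,
referred to the centroid of the cortical (ring) area — the mechanical
convention for bending of the actual load-bearing ring.

Parameters are standardised by powers of biomechanical length L (body-size
proxy).  The default exponent set is isometric (areas/L², perimeters/L,
moments/L⁴); a mass-proxy alternative (areas/L³, perimeters/L^1.5,
moments/L^5.33) is selectable and the choice travels in the table metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import is_simple_polygon, perimeter, polygon_raw_moments
from .errors import InputError, ParameterError
from .sectioning import SectionContours
from .shape import PCAResult, pca

__all__ = [
    "CSG_PARAMETERS",
    "STANDARDIZATION_EXPONENTS",
    "CSGRecord",
    "CSGTable",
    "csg_parameters",
    "standardize_csg",
    "csg_region_pca",
]

CSG_PARAMETERS = ("TotA", "MedA", "CorA", "TotP", "MedP", "Imin", "Imax", "J")

#: exponent of L dividing each parameter class, by preset name
STANDARDIZATION_EXPONENTS = {
    "isometric": {"area": 2.0, "perimeter": 1.0, "moment": 4.0},
    "mass_proxy": {"area": 3.0, "perimeter": 1.5, "moment": 5.33},
}

_PARAM_CLASS = {"TotA": "area", "MedA": "area", "CorA": "area",
                "TotP": "perimeter", "MedP": "perimeter",
                "Imin": "moment", "Imax": "moment", "J": "moment"}


@dataclass
class CSGRecord:
    """The eight beam-theory parameters of one cross-section."""

    TotA: float
    MedA: float
    CorA: float
    TotP: float
    MedP: float
    Imin: float
    Imax: float
    J: float
    level_percent: float = np.nan
    specimen: object = None
    theta_max_deg: float = np.nan  # orientation of the Imax principal axis

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in CSG_PARAMETERS}


def csg_parameters(section: SectionContours) -> CSGRecord:
    """Compute the eight CSG parameters from a nested contour pair."""
    peri, endo = section.periosteal, section.endosteal
    if not (is_simple_polygon(peri) and is_simple_polygon(endo)):
        raise InputError(
            f"self-intersecting polygon at level {section.level_percent:.1f}%")
    mp = polygon_raw_moments(peri)
    me = polygon_raw_moments(endo)
    tot_a, med_a = mp["A"], me["A"]
    cor_a = tot_a - med_a
    if not (tot_a > med_a >= 0):
        raise InputError("periosteal area must exceed medullary area")
    # ring centroid and raw ring moments about the origin
    cx = (mp["Sx"] - me["Sx"]) / cor_a
    cy = (mp["Sy"] - me["Sy"]) / cor_a
    ixx = (mp["Ixx"] - me["Ixx"]) - cor_a * cy * cy
    iyy = (mp["Iyy"] - me["Iyy"]) - cor_a * cx * cx
    ixy = (mp["Ixy"] - me["Ixy"]) - cor_a * cx * cy
    tensor = np.array([[ixx, -ixy], [-ixy, iyy]])
    w, v = np.linalg.eigh(tensor)
    imin, imax = float(w[0]), float(w[1])
    ax = v[:, 1]
    theta_max = float(np.degrees(np.arctan2(ax[1], ax[0])) % 180.0)
    return CSGRecord(TotA=tot_a, MedA=med_a, CorA=cor_a,
                     TotP=perimeter(peri), MedP=perimeter(endo),
                     Imin=imin, Imax=imax, J=imin + imax,
                     level_percent=section.level_percent,
                     theta_max_deg=theta_max)


@dataclass
class CSGTable:
    """Tidy table of CSG records for all sections of all specimens.

    ``data`` columns: specimen, individual_id, side, stimulated,
    stimulated_individual, level_percent, parameter, value.
    """

    data: pd.DataFrame
    standardized: bool = False
    exponents: dict | None = None

    @property
    def n_variables_per_specimen(self) -> int:
        per = self.data.groupby("specimen").size().unique()
        if len(per) != 1:
            raise InputError("ragged CSG table: unequal section counts")
        return int(per[0])

    def wide(self, level_percent: float | None = None) -> pd.DataFrame:
        """Specimens × parameters matrix, optionally restricted to one level."""
        df = self.data
        if level_percent is not None:
            df = df[np.isclose(df["level_percent"], level_percent)]
            if df.empty:
                raise InputError(f"level {level_percent}% not present in CSG table")
            wide = df.pivot(index="specimen", columns="parameter", values="value")
        else:
            wide = df.pivot(index="specimen",
                            columns=["level_percent", "parameter"], values="value")
        return wide

    def specimen_metadata(self) -> pd.DataFrame:
        cols = ["specimen", "individual_id", "side", "stimulated", "stimulated_individual"]
        cols = [c for c in cols if c in self.data.columns]
        return self.data[cols].drop_duplicates().set_index("specimen")

    @classmethod
    def from_records(cls, records_by_specimen: dict, metadata: dict | None = None) -> "CSGTable":
        """Build from {specimen_label: [CSGRecord, ...]} plus optional
        per-specimen metadata dicts."""
        rows = []
        for label, records in records_by_specimen.items():
            meta = (metadata or {}).get(label, {})
            for rec in records:
                for param in CSG_PARAMETERS:
                    rows.append({"specimen": label, **meta,
                                 "level_percent": rec.level_percent,
                                 "parameter": param,
                                 "value": getattr(rec, param)})
        return cls(pd.DataFrame(rows))


def standardize_csg(table: CSGTable, lengths: dict,
                    exponents="isometric") -> CSGTable:
    """Divide each parameter by L^e, L the specimen's biomechanical length.

    ``lengths`` maps specimen label to L (mm); ``exponents`` is a preset
    name from :data:`STANDARDIZATION_EXPONENTS` or a {class: exponent}
    mapping with keys area/perimeter/moment.
    """
    if isinstance(exponents, str):
        try:
            exps = STANDARDIZATION_EXPONENTS[exponents]
        except KeyError:
            raise ParameterError(f"unknown exponent preset {exponents!r}") from None
    else:
        exps = dict(exponents)
    missing = {"area", "perimeter", "moment"} - set(exps)
    if missing:
        raise ParameterError(f"missing exponent classes: {sorted(missing)}")
    df = table.data.copy()
    for label, L in lengths.items():
        if L <= 0:
            raise ParameterError(f"non-positive length for specimen {label!r}")
    ls = df["specimen"].map(lengths)
    if ls.isna().any():
        raise ParameterError("length missing for some specimens")
    e = df["parameter"].map(_PARAM_CLASS).map(exps)
    df["value"] = df["value"] / np.power(ls.to_numpy(dtype=float), e.to_numpy(dtype=float))
    return CSGTable(df, standardized=True, exponents=exps)


def csg_region_pca(table: CSGTable, level_percent: float) -> tuple[PCAResult, pd.DataFrame]:
    """Correlation-matrix PCA of the 8 parameters at one section level.

    Unit-variance scaling is used because the parameters span mm¹–mm⁴.
    Returns the PCA result (``degenerate`` flagged when all specimens are
    identical) and a loading table (parameters × components).
    """
    wide = table.wide(level_percent)[list(CSG_PARAMETERS)]
    x = wide.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.all(sd <= 0):
        res = pca(x)  # degenerate path
        loadings = pd.DataFrame(index=list(CSG_PARAMETERS))
        res.column_names = list(wide.index)
        return res, loadings
    scale = np.where(sd > 0, sd, 1.0)
    res = pca((x - x.mean(axis=0)) / scale)
    res.column_names = list(wide.index)
    loadings = pd.DataFrame(
        res.loadings.T, index=list(CSG_PARAMETERS),
        columns=[f"PC{i + 1}" for i in range(res.n_components)])
    return res, loadings
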