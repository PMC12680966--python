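"""Model/Results interface for the four-channel bilateral-asymmetry analysis.

:class:`BilateralAsymmetryStudy` is built from a cohort of paired-limb
specimens (plus, optionally, an externally measured entheseal-area table);
``fit()`` runs the full pipeline — alignment, sectioning, equiangular
semilandmarks, then four parallel analysis channels —

* **gm** — global GPA + PCA of the full semilandmark configuration,
  permutation multivariate regression of the PC scores (to 90 % cumulative
  variance) on the stimulation label, and per-PC permutation ANOVA;
* **targeted** — the local N-core variance map, third-quartile selection,
  and GPA + PCA restricted to the selected semilandmarks;
* **csg** — length-standardised cross-sectional geometry with
  correlation-matrix PCA at the distal (20 %), midshaft (50 %) and
  proximal (80 %) levels;
* **cortical** — PCA of relative cortical-thickness maps;
* **entheseal** — correlation-matrix PCA of 3D muscle-attachment areas and
  left/right percent asymmetry (when an area table is supplied)

— and returns an :class:`AsymmetryResults` with per-channel R², permutation
p-values, variance percentages and a ``summary()`` table.  Identical
config + seed give identical numeric output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import csg as csg_mod
from .cortical import ThicknessMap, map_pca, thickness_profile
from .errors import AsymboneError, InputError, ParameterError
from .landmarks import LandmarkConfiguration, equiangular_sample
from .sectioning import (DEFAULT_EXCLUDED_BAND, DEFAULT_INTERVALS, DEFAULT_STEP,
                         SectionLevels, align_bone, extract_section,
                         mirror_mesh, section_levels)
from .shape import PCAResult, ProcrustesFit, gpa, pca
from .stats import (PermRegressionResult, correlation_pca, per_pc_anova,
                    percent_asymmetry, perm_regression, select_pcs_90)
from .synthetic import (AsymmetryField, CohortParams, ContourStack, Specimen,
                        generate_cohort, generate_entheseal_areas)
from .targeted import VarianceMap, local_variance_map, ncore_neighborhoods, targeted_pca

__all__ = ["RunConfig", "ChannelResult", "AsymmetryResults",
           "BilateralAsymmetryStudy", "validate_inputs"]

CSG_REGIONS = {"distal": 20.0, "midshaft": 50.0, "proximal": 80.0}


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline configuration.

    The defaults reproduce the reference scheme exactly: 28 section levels
    (6 + 22), 24 semilandmark pairs per section (1344 semilandmarks),
    8 × 28 = 224 CSG variables, 1000-ray thickness maps, N-core of 15,
    third-quartile threshold, 90 % cumulative-variance PC selection.
    """

    step_percent: float = DEFAULT_STEP
    intervals: tuple = DEFAULT_INTERVALS
    excluded_band: tuple = DEFAULT_EXCLUDED_BAND
    k_gm: int = 24
    k_map: int = 1000
    core_size: int = 15
    quantile_p: float = 0.75
    exponents: str = "isometric"
    n_permutations: int = 999
    seed: int = 0
    coding: str = "limb"          # "limb" or "animal" stimulation coding
    n_resample: int = 1000
    theta0_deg: float = 0.0
    pc_threshold_percent: float = 90.0
    csg_region_levels: tuple = (20.0, 50.0, 80.0)

    def section_scheme(self) -> SectionLevels:
        return section_levels(self.step_percent, self.intervals, self.excluded_band)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ChannelResult:
    """One analysis channel: its PCA, regression and any channel extras."""

    name: str
    pca: PCAResult
    regression: PermRegressionResult | None = None
    selected_components: list = field(default_factory=list)
    anova: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def row(self) -> dict:
        r = {"channel": self.name,
             "pc1_percent": float(self.pca.variance_percent[0]),
             "pc2_percent": float(self.pca.variance_percent[1])
             if self.pca.n_components > 1 else np.nan,
             "n_pcs_90": len(self.selected_components)}
        if self.regression is not None:
            r["r_squared"] = self.regression.r_squared
            r["p_value"] = self.regression.p_value
        return r


@dataclass
class AsymmetryResults:
    """Fitted results of the four-channel analysis."""

    gm: ChannelResult
    targeted: ChannelResult
    csg: dict
    cortical: ChannelResult
    entheseal: ChannelResult | None
    variance_map: VarianceMap
    procrustes_fit: ProcrustesFit
    configurations: list
    csg_table: csg_mod.CSGTable
    thickness_maps: list
    asymmetry_table: pd.DataFrame | None
    labels: np.ndarray
    specimen_labels: list
    config: RunConfig
    counts: dict

    def channels(self):
        out = [self.gm, self.targeted]
        out += [self.csg[k] for k in sorted(self.csg)]
        out.append(self.cortical)
        if self.entheseal is not None:
            out.append(self.entheseal)
        return out

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.row() for c in self.channels()])

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Bilateral asymmetry analysis",
            "=" * 64,
            f"specimens: {len(self.specimen_labels)}  "
            f"(stimulated limbs: {int(np.sum(self.labels))})",
            f"sections: {self.counts['n_sections']}   "
            f"semilandmarks: {self.counts['n_semilandmarks']}   "
            f"CSG variables: {self.counts['n_csg_variables']}",
            f"targeted threshold (Q{int(self.config.quantile_p * 100)}): "
            f"{self.variance_map.threshold:.3f}  "
            f"({len(self.variance_map.selected)} semilandmarks selected)",
            "-" * 64,
            df.to_string(index=False,
                         formatters={"pc1_percent": "{:.2f}".format,
                                     "pc2_percent": "{:.2f}".format,
                                     "r_squared": "{:.3f}".format,
                                     "p_value": "{:.4f}".format}),
            "-" * 64,
            f"permutations: {self.config.n_permutations}   "
            f"coding: {self.config.coding}   seed: {self.config.seed}",
        ]
        return "\n".join(lines)

    def plot_scores(self, channel: str = "targeted", components=(0, 1), ax=None):
        """PC score scatter for one channel (see :mod:`asymbone.plotting`)."""
        from .plotting import plot_scores

        ch = {"gm": self.gm, "targeted": self.targeted,
              "cortical": self.cortical, "entheseal": self.entheseal,
              **self.csg}[channel]
        labels = self.labels if len(ch.pca.scores) == len(self.labels) else None
        return plot_scores(ch, labels, self.specimen_labels, components, ax)

    def plot_percent_asymmetry(self, structure=None, ax=None):
        from .plotting import plot_percent_asymmetry

        if self.asymmetry_table is None:
            raise InputError("no entheseal-area table was supplied")
        return plot_percent_asymmetry(self.asymmetry_table, structure, ax)

    def normality(self, channel: str = "gm", alpha: float = 0.05):
        """Multivariate normality diagnostic of a channel's selected PC
        scores (delegated to pingouin's Henze-Zirkler test)."""
        import pingouin as pg

        ch = {"gm": self.gm, "targeted": self.targeted,
              "cortical": self.cortical}.get(channel)
        if ch is None:
            ch = self.csg[channel]
        scores = ch.pca.scores[:, ch.selected_components]
        return pg.multivariate_normality(scores, alpha=alpha)

    def save(self, outdir) -> None:
        """Write the machine-readable summary plus per-channel artifacts."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {"config": self.config.as_dict(), "counts": self.counts,
                   "channels": {}}
        for ch in self.channels():
            entry = {"variance_percent": [float(v) for v in ch.pca.variance_percent],
                     "selected_components": list(map(int, ch.selected_components))}
            if ch.regression is not None:
                entry.update(ch.regression.as_dict())
            payload["channels"][ch.name] = entry
            pd.DataFrame(ch.pca.scores,
                         index=self.specimen_labels
                         if len(ch.pca.scores) == len(self.specimen_labels) else None,
                         columns=[f"PC{i+1}" for i in range(ch.pca.n_components)]
                         ).to_csv(outdir / f"scores_{ch.name}.csv")
        payload["targeted_threshold"] = float(self.variance_map.threshold)
        (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
        lab = self.configurations[0].labels()
        self.variance_map.to_dataframe(lab).to_csv(
            outdir / "variance_map.csv", index=False)
        self.csg_table.data.to_csv(outdir / "csg_table.csv", index=False)
        if self.asymmetry_table is not None:
            self.asymmetry_table.to_csv(outdir / "entheseal_asymmetry.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def _group_labels(specimens, coding: str) -> np.ndarray:
    if coding == "limb":
        return np.array([bool(sp.stimulated) for sp in specimens])
    if coding == "animal":
        return np.array([bool(sp.stimulated_individual) for sp in specimens])
    raise ParameterError(f"unknown stimulation coding {coding!r}")


class BilateralAsymmetryStudy:
    """The four-method asymmetry analysis, as a fittable model object.

    Parameters
    ----------
    specimens : list of Specimen
        Paired left/right limbs; left specimens are mirrored to right-hand
        orientation internally before any shape comparison.
    entheseal_areas : DataFrame, optional
        Per-limb 3D entheseal surface areas (mm²) with columns
        ``individual_id``, ``side``, ``stimulated`` plus one numeric column
        per structure.
    config : RunConfig
    """

    def __init__(self, specimens, entheseal_areas: pd.DataFrame | None = None,
                 config: RunConfig | None = None):
        if not specimens:
            raise InputError("no specimens supplied")
        self.specimens = list(specimens)
        self.entheseal_areas = entheseal_areas
        self.config = config or RunConfig()

    # ---- constructors -----------------------------------------------------
    @classmethod
    def from_synthetic(cls, params: CohortParams | None = None,
                       field_: AsymmetryField | None = None,
                       config: RunConfig | None = None,
                       with_entheseal: bool = True,
                       **cohort_kwargs) -> "BilateralAsymmetryStudy":
        """Generate a seeded synthetic cohort and wrap it as a study."""
        params = params or CohortParams()
        specimens = generate_cohort(params, field_, **cohort_kwargs)
        areas = generate_entheseal_areas(params) if with_entheseal else None
        return cls(specimens, entheseal_areas=areas, config=config)

    @classmethod
    def from_directory(cls, path, entheseal_csv=None,
                       config: RunConfig | None = None) -> "BilateralAsymmetryStudy":
        """Load a cohort written by :func:`asymbone.synthetic.write_cohort`
        (contour CSVs + cohort.json), or PLY meshes listed there."""
        path = Path(path)
        meta = json.loads((path / "cohort.json").read_text())
        specimens = []
        for m in meta["specimens"]:
            f = path / m["file"]
            if f.suffix == ".csv":
                geom = ContourStack.read_csv(f)
            else:
                import trimesh
                geom = trimesh.load_mesh(f)
            specimens.append(Specimen(m["individual_id"], m["side"],
                                      m["stimulated"], geom,
                                      stimulated_individual=m.get(
                                          "stimulated_individual", m["stimulated"])))
        areas = pd.read_csv(entheseal_csv) if entheseal_csv else None
        return cls(specimens, entheseal_areas=areas, config=config)

    # ---- pipeline ---------------------------------------------------------
    def _oriented_geometry(self, sp: Specimen):
        if sp.side == "left":
            if isinstance(sp.geometry, ContourStack):
                return sp.geometry.mirror()
            return mirror_mesh(sp.geometry)
        return sp.geometry

    def _sections_for(self, sp: Specimen, levels: SectionLevels):
        aligned, L = align_bone(self._oriented_geometry(sp))
        secs = {}
        for level in levels:
            secs[level] = extract_section(aligned, level,
                                          n_resample=self.config.n_resample,
                                          excluded_band=levels.excluded_band)
        return secs, L

    def fit(self, n_permutations: int | None = None,
            seed: int | None = None) -> AsymmetryResults:
        cfg = self.config
        n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
        seed = seed if seed is not None else cfg.seed
        seeds = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)
        levels = cfg.section_scheme()
        lv = np.asarray(list(levels), dtype=float)
        labels = _group_labels(self.specimens, cfg.coding)
        spec_labels = [sp.label for sp in self.specimens]

        # one sectioning pass per specimen, shared by all channels
        configs, maps, records, lengths = [], [], {}, {}
        angles_gm = np.degrees(2 * np.pi * np.arange(cfg.k_gm) / cfg.k_gm
                               + np.radians(cfg.theta0_deg)) % 360.0
        angles_map = np.degrees(2 * np.pi * np.arange(cfg.k_map) / cfg.k_map
                                + np.radians(cfg.theta0_deg)) % 360.0
        for sp in self.specimens:
            secs, L = self._sections_for(sp, levels)
            lengths[sp.label] = L
            coords = np.empty((len(lv), cfg.k_gm, 2, 3))
            rows = np.empty((len(lv), cfg.k_map))
            recs = []
            for i, level in enumerate(lv):
                sec = secs[level]
                peri, endo = equiangular_sample(sec, cfg.k_gm, cfg.theta0_deg)
                coords[i, :, 0, :2] = peri
                coords[i, :, 1, :2] = endo
                coords[i, :, :, 2] = sec.z_mm
                rows[i] = thickness_profile(sec, cfg.k_map, cfg.theta0_deg)
                rec = csg_mod.csg_parameters(sec)
                rec.specimen = sp.label
                recs.append(rec)
            configs.append(LandmarkConfiguration(coords, lv, angles_gm, sp))
            maps.append(ThicknessMap(rows, lv, angles_map, sp))
            records[sp.label] = recs

        meta = {sp.label: {"individual_id": sp.individual_id, "side": sp.side,
                           "stimulated": sp.stimulated,
                           "stimulated_individual": sp.stimulated_individual}
                for sp in self.specimens}

        # --- channel 1: global geometric morphometrics
        fit = gpa(configs)
        gm_pca = pca(fit)
        gm_sel = select_pcs_90(gm_pca, cfg.pc_threshold_percent)
        gm_reg = perm_regression(gm_pca.scores[:, gm_sel], labels, n_perm,
                                 seed=int(seeds[0]), coding=cfg.coding)
        gm_anova = per_pc_anova(gm_pca.scores[:, gm_sel], labels, n_perm,
                                seed=int(seeds[1]), coding=cfg.coding)
        gm = ChannelResult("gm", gm_pca, gm_reg, gm_sel, gm_anova,
                           extras={"procrustes_fit": fit})

        # --- channel 2: targeted geometric morphometrics
        cores = ncore_neighborhoods(fit.mean_shape, cfg.core_size)
        vmap = local_variance_map(configs, labels, cores, cfg.quantile_p)
        t_fit, t_pca = targeted_pca(configs, vmap.selected)
        t_sel = select_pcs_90(t_pca, cfg.pc_threshold_percent)
        t_reg = perm_regression(t_pca.scores[:, t_sel], labels, n_perm,
                                seed=int(seeds[2]), coding=cfg.coding)
        targeted = ChannelResult("targeted", t_pca, t_reg, t_sel,
                                 extras={"procrustes_fit": t_fit,
                                         "n_selected": len(vmap.selected)})

        # --- channel 3: cross-sectional geometry per region
        table = csg_mod.CSGTable.from_records(records, meta)
        table = csg_mod.standardize_csg(table, lengths, cfg.exponents)
        region_levels = [l for l in cfg.csg_region_levels
                         if np.any(np.isclose(lv, l))]
        if not region_levels:
            raise ParameterError(
                "none of the requested CSG region levels are in the section scheme")
        order = table.wide(region_levels[0]).index
        csg_labels = np.array([meta[s]["stimulated"] if cfg.coding == "limb"
                               else meta[s]["stimulated_individual"] for s in order])
        csg_channels = {}
        region_names = {v: k for k, v in CSG_REGIONS.items()}
        for j, level in enumerate(region_levels):
            name = region_names.get(level, f"csg_{level:g}")
            res, loadings = csg_mod.csg_region_pca(table, level)
            sel = select_pcs_90(res, cfg.pc_threshold_percent)
            reg = perm_regression(res.scores[:, sel], csg_labels, n_perm,
                                  seed=int(seeds[3] + j), coding=cfg.coding)
            csg_channels[f"csg_{name}"] = ChannelResult(
                f"csg_{name}", res, reg, sel,
                extras={"level_percent": level, "loadings": loadings})

        # --- channel 4: relative cortical-thickness maps
        m_pca = map_pca(maps)
        m_sel = select_pcs_90(m_pca, cfg.pc_threshold_percent)
        m_reg = perm_regression(m_pca.scores[:, m_sel], labels, n_perm,
                                seed=int(seeds[6]), coding=cfg.coding)
        cortical = ChannelResult("cortical", m_pca, m_reg, m_sel)

        # --- channel 5 (downstream): entheseal areas
        entheseal = None
        asym_table = None
        if self.entheseal_areas is not None:
            areas = self.entheseal_areas
            struct_cols = [c for c in areas.columns
                           if c not in ("individual_id", "side", "stimulated",
                                        "stimulated_individual")
                           and np.issubdtype(areas[c].dtype, np.number)]
            e_pca = correlation_pca(areas[struct_cols])
            e_sel = select_pcs_90(e_pca, cfg.pc_threshold_percent)
            e_labels = (areas["stimulated"] if cfg.coding == "limb"
                        else areas["stimulated_individual"]).to_numpy(dtype=bool)
            e_reg = perm_regression(e_pca.scores[:, e_sel], e_labels, n_perm,
                                    seed=int(seeds[7]), coding=cfg.coding)
            entheseal = ChannelResult("entheseal", e_pca, e_reg, e_sel,
                                      extras={"structures": struct_cols})
            rows = []
            for ind, grp in areas.groupby("individual_id"):
                left = grp[grp["side"] == "left"]
                right = grp[grp["side"] == "right"]
                if len(left) != 1 or len(right) != 1:
                    continue
                for c in struct_cols:
                    rows.append({
                        "individual_id": ind, "structure": c,
                        "stimulated_individual": bool(
                            grp["stimulated"].any() if "stimulated_individual"
                            not in grp else grp["stimulated_individual"].iloc[0]),
                        "percent_asymmetry": percent_asymmetry(
                            float(left[c].iloc[0]), float(right[c].iloc[0]))})
            asym_table = pd.DataFrame(rows)

        counts = {"n_sections": len(lv),
                  "n_semilandmarks": int(configs[0].n_landmarks),
                  "n_csg_variables": int(len(lv) * len(csg_mod.CSG_PARAMETERS))}
        return AsymmetryResults(
            gm=gm, targeted=targeted, csg=csg_channels, cortical=cortical,
            entheseal=entheseal, variance_map=vmap, procrustes_fit=fit,
            configurations=configs, csg_table=table, thickness_maps=maps,
            asymmetry_table=asym_table, labels=labels,
            specimen_labels=spec_labels, config=cfg, counts=counts)


def validate_inputs(specimens_or_path, entheseal_areas: pd.DataFrame | None = None):
    """Validate a cohort before fitting: geometry integrity and pairing.

    Accepts a list of :class:`Specimen` or a cohort directory.  Issues are
    *reported* (list of dicts with ``specimen``/``issue`` keys), not raised.
    """
    if isinstance(specimens_or_path, (str, Path)):
        study = BilateralAsymmetryStudy.from_directory(specimens_or_path)
        specimens = study.specimens
    else:
        specimens = list(specimens_or_path)
    issues = []
    sides = {}
    for sp in specimens:
        sides.setdefault(sp.individual_id, set()).add(sp.side)
        geom = sp.geometry
        try:
            if isinstance(geom, ContourStack):
                geom.validate()
            else:
                if not bool(geom.is_watertight):
                    issues.append({"specimen": sp.label,
                                   "issue": "mesh not watertight "
                                   f"({len(geom.vertices)} vertices, "
                                   f"{len(geom.faces)} faces)"})
        except AsymboneError as exc:
            issues.append({"specimen": sp.label, "issue": str(exc)})
    for ind, got in sorted(sides.items()):
        missing = {"left", "right"} - got
        for side in sorted(missing):
            issues.append({"specimen": ind, "issue": f"missing {side} limb"})
    if entheseal_areas is not None:
        for col in ("individual_id", "side"):
            if col not in entheseal_areas.columns:
                issues.append({"specimen": "<areas>",
                               "issue": f"entheseal table missing column {col!r}"})
    return issues
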