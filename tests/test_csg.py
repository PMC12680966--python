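"""Cross-sectional geometry against closed forms and a pixel-integration oracle."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from asymbone.csg import (CSG_PARAMETERS, CSGTable, csg_parameters,
                          csg_region_pca, standardize_csg)
from asymbone.errors import ParameterError
from asymbone.sectioning import SectionContours

from conftest import annulus_section, circle, ellipse, star_polygon


def raster_oracle(section, n_grid=1500):
    """Independent CSG estimate: pixel integration for areas/moments,
    shapely for perimeters."""
    peri, endo = section.periosteal, section.endosteal
    lo = peri.min(axis=0) - 0.05
    hi = peri.max(axis=0) + 0.05
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    dx, dy = xs[1] - xs[0], ys[1] - ys[0]
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_peri = MplPath(peri).contains_points(pts)
    in_endo = MplPath(endo).contains_points(pts)
    ring = in_peri & ~in_endo
    da = dx * dy
    x, y = pts[ring, 0], pts[ring, 1]
    cor_a = ring.sum() * da
    cx, cy = x.mean(), y.mean()
    out = {
        "TotA": in_peri.sum() * da,
        "MedA": in_endo.sum() * da,
        "CorA": cor_a,
        "TotP": ShapelyPolygon(peri).length,
        "MedP": ShapelyPolygon(endo).length,
    }
    ixx = np.sum((y - cy) ** 2) * da
    iyy = np.sum((x - cx) ** 2) * da
    ixy = np.sum((x - cx) * (y - cy)) * da
    w = np.linalg.eigvalsh(np.array([[ixx, -ixy], [-ixy, iyy]]))
    out["Imin"], out["Imax"] = float(w[0]), float(w[1])
    out["J"] = out["Imin"] + out["Imax"]
    return out


class TestClosedForms:
    def test_concentric_annulus(self):
        # r_out=2, r_in=1 at 1000-vertex polygons, all within 0.2%
        rec = csg_parameters(annulus_section(2.0, 1.0, n=1000))
        expect = {"TotA": 4 * np.pi, "MedA": np.pi, "CorA": 3 * np.pi,
                  "TotP": 4 * np.pi, "MedP": 2 * np.pi,
                  "Imin": np.pi / 4 * 15, "Imax": np.pi / 4 * 15,
                  "J": np.pi / 2 * 15}
        for name, val in expect.items():
            assert getattr(rec, name) == pytest.approx(val, rel=0.002), name

    def test_solid_ellipse_like_ring_moment_ratio(self):
        # thin ring limit of an ellipse keeps Imax/Imin = (a/b)²
        sec = SectionContours(50.0, ellipse(2.0, 1.0, 2000),
                              ellipse(2.0 * 1e-3, 1.0e-3, 2000))
        rec = csg_parameters(sec)
        assert rec.Imax / rec.Imin == pytest.approx(4.0, rel=0.005)
        assert rec.Imax == pytest.approx(np.pi * 2.0 ** 3 * 1.0 / 4, rel=0.005)
        assert rec.Imin == pytest.approx(np.pi * 2.0 * 1.0 ** 3 / 4, rel=0.005)

    def test_eccentric_annulus_matches_raster_oracle(self):
        sec = annulus_section(2.0, 1.0, n=800, inner_center=(0.5, 0.0))
        rec = csg_parameters(sec)
        oracle = raster_oracle(sec)
        for name in CSG_PARAMETERS:
            assert getattr(rec, name) == pytest.approx(oracle[name], rel=0.005), name


class TestInvariants:
    def test_j_identity_and_rotation_invariance_on_random_sections(self, rng):
        for _ in range(5):
            peri = star_polygon(rng, r=2.0, n=500)
            endo = 0.45 * star_polygon(rng, r=2.0, n=500, max_amp=0.15)
            sec = SectionContours(50.0, peri, endo)
            rec = csg_parameters(sec)
            assert rec.J == pytest.approx(rec.Imin + rec.Imax, rel=1e-12)
            assert rec.CorA == pytest.approx(rec.TotA - rec.MedA, rel=1e-12)
            ang = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])
            rot = csg_parameters(SectionContours(50.0, peri @ R.T, endo @ R.T))
            for name in CSG_PARAMETERS:
                assert getattr(rot, name) == pytest.approx(
                    getattr(rec, name), rel=1e-9), name

    def test_oracle_equivalence_on_random_star_sections(self, rng):
        # all 8 parameters within 0.5% of the pixel-integration oracle
        for _ in range(4):
            peri = star_polygon(rng, r=2.0, n=400)
            endo = 0.45 * star_polygon(rng, r=2.0, n=400, max_amp=0.15)
            sec = SectionContours(50.0, peri, endo)
            rec = csg_parameters(sec)
            oracle = raster_oracle(sec, n_grid=1200)
            for name in CSG_PARAMETERS:
                assert getattr(rec, name) == pytest.approx(
                    oracle[name], rel=0.005), name


def _toy_table():
    recs = {}
    meta = {}
    for label, scale in (("a_left", 1.0), ("a_right", 1.0)):
        rec = csg_parameters(annulus_section(2.0 * scale, 1.0 * scale))
        rec.level_percent = 50.0
        recs[label] = [rec]
        meta[label] = {"individual_id": "a", "side": label.split("_")[1],
                       "stimulated": False, "stimulated_individual": False}
    return CSGTable.from_records(recs, meta)


class TestStandardization:
    def test_direct_isometric_example(self):
        table = _toy_table()
        out = standardize_csg(table, {"a_left": 2.0, "a_right": 2.0})
        row = out.data[(out.data.specimen == "a_left")
                       & (out.data.parameter == "TotA")]
        raw = table.data[(table.data.specimen == "a_left")
                         & (table.data.parameter == "TotA")]["value"].iloc[0]
        assert row["value"].iloc[0] == pytest.approx(raw / 4.0)

    def test_similar_bones_standardize_identically(self):
        s = 1.7
        rec1 = csg_parameters(annulus_section(2.0, 1.0, n=800))
        rec2 = csg_parameters(annulus_section(2.0 * s, 1.0 * s, n=800))
        for rec in (rec1, rec2):
            rec.level_percent = 50.0
        table = CSGTable.from_records({"u": [rec1], "v": [rec2]})
        out = standardize_csg(table, {"u": 10.0, "v": 10.0 * s})
        wide = out.wide(50.0)
        assert np.allclose(wide.loc["u"], wide.loc["v"], rtol=1e-9)

    def test_mass_proxy_exponents_hand_computation(self):
        table = _toy_table()
        out = standardize_csg(table, {"a_left": 2.0, "a_right": 2.0},
                              exponents="mass_proxy")
        got = out.wide(50.0).loc["a_left"]
        raw = table.wide(50.0).loc["a_left"]
        assert got["TotA"] == pytest.approx(raw["TotA"] / 2.0 ** 3)
        assert got["TotP"] == pytest.approx(raw["TotP"] / 2.0 ** 1.5)
        assert got["J"] == pytest.approx(raw["J"] / 2.0 ** 5.33)

    def test_invalid_length_rejected(self):
        with pytest.raises(ParameterError):
            standardize_csg(_toy_table(), {"a_left": 0.0, "a_right": 1.0})


class TestRegionPCA:
    def test_identical_specimens_flagged_degenerate(self):
        table = _toy_table()
        res, _ = csg_region_pca(table, 50.0)
        assert res.degenerate

    def test_perfectly_correlated_parameters_give_pc1_100(self, rng):
        rows = []
        sizes = rng.uniform(0.8, 1.2, size=6)
        for i, s in enumerate(sizes):
            for param in CSG_PARAMETERS:
                rows.append({"specimen": f"s{i}", "level_percent": 20.0,
                             "parameter": param, "value": s})
        table = CSGTable(pd.DataFrame(rows))
        res, loadings = csg_region_pca(table, 20.0)
        assert res.variance_percent[0] == pytest.approx(100.0, abs=1e-6)
        assert list(loadings.index) == list(CSG_PARAMETERS)

    def test_missing_level_rejected(self):
        from asymbone.errors import InputError
        with pytest.raises(InputError):
            csg_region_pca(_toy_table(), 20.0)
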