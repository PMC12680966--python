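"""Shared fixtures and small geometric constructors for the test suite."""

import numpy as np
import pytest

from asymbone.sectioning import SectionContours


def circle(r=1.0, n=1000, center=(0.0, 0.0), phase=0.0):
    t = phase + np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def ellipse(a=2.0, b=1.0, n=1000, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def star_polygon(rng, r=2.0, n=400, max_amp=0.25, center=(0.0, 0.0)):
    """Random smooth star-shaped polygon: r(θ) = R(1 + Σ a_m cos(mθ+φ_m))."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    radii = np.full(n, 1.0)
    amps = rng.uniform(0, 1, size=4)
    amps *= max_amp / max(amps.sum(), 1e-12) * rng.uniform(0.5, 1.0)
    for m, a in zip(range(1, 5), amps):
        radii += a * np.cos(m * t + rng.uniform(0, 2 * np.pi))
    radii *= r
    return np.column_stack([center[0] + radii * np.cos(t),
                            center[1] + radii * np.sin(t)])


def annulus_section(r_out=2.0, r_in=1.0, n=1000, inner_center=(0.0, 0.0),
                    level=50.0) -> SectionContours:
    return SectionContours(level_percent=level,
                           periosteal=circle(r_out, n),
                           endosteal=circle(r_in, n, center=inner_center))


def brute_force_ray_crossings(poly, center, angle):
    """Independent ray-polygon intersection: test every edge."""
    c = np.asarray(center, dtype=float)
    u = np.array([np.cos(angle), np.sin(angle)])
    pts = []
    n = len(poly)
    for i in range(n):
        p1, p2 = poly[i], poly[(i + 1) % n]
        w = p2 - p1
        denom = u[0] * w[1] - u[1] * w[0]
        if abs(denom) < 1e-14:
            continue
        b = p1 - c
        t = (b[0] * w[1] - b[1] * w[0]) / denom
        s = (b[0] * u[1] - b[1] * u[0]) / denom
        if t > 0 and 0.0 <= s < 1.0:
            pts.append(c + t * u)
    return pts


def cohort_configs(params, field, levels, k, n_vertices=96, stack_levels=None):
    """Generate a cohort and assemble mirrored landmark configurations.

    Returns (configs, limb_labels); left limbs are mirrored to right-hand
    orientation before sampling so antimeres are superimposable.
    """
    from asymbone.landmarks import build_configuration
    from asymbone.synthetic import generate_cohort

    if stack_levels is None:
        stack_levels = np.linspace(0.0, 100.0, 21)
    specimens = generate_cohort(params, field, levels_percent=stack_levels,
                                n_vertices=n_vertices)
    configs, labels = [], []
    for sp in specimens:
        geom = sp.geometry.mirror() if sp.side == "left" else sp.geometry
        configs.append(build_configuration(geom, levels, k=k, n_resample=300))
        labels.append(sp.stimulated)
    return configs, np.array(labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
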