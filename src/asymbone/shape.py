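"""Generalized Procrustes superimposition and shape-space PCA.

GPA iteratively centres every configuration, scales it to unit centroid
size, rotates it onto the current mean shape (proper rotations only —
antimeres are mirrored to a common orientation beforehand), and
re-estimates the mean until it stops changing.  Shape variables are the
flattened aligned coordinates (no tangent-space projection; at the shape
distances involved the difference is negligible and a projection switch is
available in :func:`pca`).

The PCA wrapper fixes a reproducible sign convention (each component's
largest-magnitude loading element is positive) and flags degenerate
(zero-variance) inputs explicitly instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InputError, MapError
from .landmarks import LandmarkConfiguration

__all__ = [
    "ProcrustesFit",
    "PCAResult",
    "gpa",
    "pca",
    "procrustes_distance",
    "shape_at_pc_extreme",
    "expansion_map",
]


def _as_config_array(configs) -> np.ndarray:
    """Stack configurations into (n_specimens, n_landmarks, 3)."""
    if isinstance(configs, np.ndarray):
        arr = configs
    else:
        rows = []
        for c in configs:
            if isinstance(c, LandmarkConfiguration):
                rows.append(c.flat)
            else:
                rows.append(np.asarray(c, dtype=float).reshape(-1, 3))
        if len({r.shape for r in rows}) > 1:
            raise InputError("configurations have mismatched landmark counts")
        arr = np.stack(rows)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3:
        raise InputError(f"expected (n, p, dim) configurations, got shape {arr.shape}")
    return arr


def _center_and_scale(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre each configuration at the origin and scale to unit centroid size."""
    centered = arr - arr.mean(axis=1, keepdims=True)
    cs = np.sqrt(np.sum(centered ** 2, axis=(1, 2)))
    if np.any(cs <= 0):
        raise InputError("configuration with zero centroid size")
    return centered / cs[:, None, None], cs


def _rotate_onto(arr: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation of each configuration onto ``target`` (batched).

    ``target`` is either one (p, 3) shape or a per-configuration (n, p, 3)
    stack.
    """
    if target.ndim == 2:
        c = np.einsum("npi,pj->nij", arr, target)
    else:
        c = np.einsum("npi,npj->nij", arr, target)
    u, _, vt = np.linalg.svd(c)
    det = np.linalg.det(np.einsum("nij,njk->nik", u, vt))
    d = np.ones((len(arr), 3))
    d[:, -1] = np.sign(det)
    r = np.einsum("nij,nj,njk->nik", u, d, vt)
    return np.einsum("npi,nik->npk", arr, r)


@dataclass
class ProcrustesFit:
    """Result of generalized Procrustes superimposition."""

    aligned: np.ndarray               # (n, p, 3), unit centroid size each
    centroid_sizes: np.ndarray        # (n,), the removed size measure
    mean_shape: np.ndarray            # (p, 3)
    n_iterations: int
    final_change: float

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    @property
    def shape_variables(self) -> np.ndarray:
        """(n, 3p) flattened aligned coordinates."""
        return self.aligned.reshape(self.n_specimens, -1)


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesFit:
    """Generalized Procrustes analysis of ≥ 2 landmark configurations."""
    arr = _as_config_array(configs)
    if arr.shape[0] < 2:
        raise InputError("GPA needs at least two configurations")
    x, cs = _center_and_scale(arr)
    mean = x[0].copy()
    mean /= np.sqrt(np.sum(mean ** 2))
    change = np.inf
    n = len(x)
    for it in range(1, max_iter + 1):
        # rotate each configuration onto the mean of the *others*: exact
        # block ascent on the joint Procrustes criterion (rotating onto the
        # including-self mean stalls slightly short of the optimum for small n)
        if n > 2:
            x = _rotate_onto(x, x.sum(axis=0)[None] - x)
        else:
            x = _rotate_onto(x, mean)
        new_mean = x.mean(axis=0)
        new_mean -= new_mean.mean(axis=0, keepdims=True)
        norm = np.sqrt(np.sum(new_mean ** 2))
        if norm <= 0:
            raise InputError("degenerate mean shape")
        new_mean /= norm
        # remove global rotational drift: re-orient the whole solution so
        # the new mean sits on the old one, keeping the frame stable
        c = new_mean.T @ mean
        u, _, vt = np.linalg.svd(c)
        d = np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))])
        r = u @ d @ vt
        new_mean = new_mean @ r
        x = x @ r
        change = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (change {change:.3e})")
    # canonical orientation: principal axes of the mean shape with a
    # deterministic sign rule, so output frames are reproducible and
    # invariant to similarity transforms of the inputs
    w, v = np.linalg.eigh(mean.T @ mean)
    v = v[:, ::-1]
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(3)])
    flip[flip == 0] = 1.0
    v = v * flip[None, :]
    if np.linalg.det(v) < 0:
        v[:, -1] *= -1.0
    mean = mean @ v
    x = x @ v
    return ProcrustesFit(aligned=x, centroid_sizes=cs, mean_shape=mean,
                         n_iterations=it, final_change=change)


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two configurations (centre, unit
    scale, optimal proper rotation)."""
    arr = _as_config_array([a, b])
    x, _ = _center_and_scale(arr)
    y = _rotate_onto(x[1:2], x[0])
    return float(np.sqrt(np.sum((y[0] - x[0]) ** 2)))


@dataclass
class PCAResult:
    """Principal components of a (possibly shape-variable) data matrix."""

    scores: np.ndarray                # (n, m)
    loadings: np.ndarray              # (m, d), orthonormal rows
    variance_percent: np.ndarray      # (m,), sums to 100 for non-degenerate data
    center: np.ndarray                # (d,) column means
    degenerate: bool = False
    column_names: list = field(default=None)

    @property
    def cumulative_percent(self) -> np.ndarray:
        return np.cumsum(self.variance_percent)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(data, tangent: bool = False) -> PCAResult:
    """PCA via SVD of the column-centred data matrix.

    ``data`` is an (n, d) matrix or a :class:`ProcrustesFit` (in which case
    the flattened aligned coordinates are used; ``tangent=True`` projects
    them into the tangent space at the mean shape first).  Constant data
    yields an explicit degenerate result (``degenerate=True``, NaN variance
    percentages) rather than an error.
    """
    if isinstance(data, ProcrustesFit):
        x = data.shape_variables
        if tangent:
            m = data.mean_shape.ravel()
            m = m / np.linalg.norm(m)
            x = x - np.outer(x @ m, m) + m  # orthogonal projection at the mean
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InputError("PCA needs an (n >= 2, d) data matrix")
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total <= np.finfo(float).eps * x.size:
        return PCAResult(scores=np.zeros((x.shape[0], 1)),
                         loadings=np.zeros((1, x.shape[1])),
                         variance_percent=np.array([np.nan]),
                         center=center, degenerate=True)
    keep = s > s[0] * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # reproducible sign: largest-|loading| element of each component positive
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = (u * s) * flip[None, :]
    variance_percent = 100.0 * s ** 2 / total
    return PCAResult(scores=scores, loadings=vt, variance_percent=variance_percent,
                     center=center)


def shape_at_pc_extreme(pca_result: PCAResult, component: int, score_value: float,
                        like: LandmarkConfiguration | None = None):
    """Reconstruct the shape at a given score along one component.

    Returns the (p, 3) landmark array ``mean + score × loading``; if a
    template configuration is given, a :class:`LandmarkConfiguration` with
    its indexing metadata is returned instead.
    """
    if not 0 <= component < pca_result.n_components:
        raise IndexError(f"component {component} out of range "
                         f"(rank {pca_result.n_components})")
    if not np.isfinite(score_value):
        raise InputError("score_value must be finite")
    vec = pca_result.center + score_value * pca_result.loadings[component]
    coords = vec.reshape(-1, 3)
    if like is not None:
        return LandmarkConfiguration(
            coords=coords.reshape(like.coords.shape),
            levels_percent=like.levels_percent, angles_deg=like.angles_deg)
    return coords


def _neighbor_mean_distances(coords: np.ndarray) -> np.ndarray:
    """Per-landmark mean distance to topological neighbours.

    ``coords`` has shape (n_sections, k, 2, 3); neighbours are the
    same-surface adjacent rays (wrapping) and adjacent sections (clipped).
    """
    ns, k, _, _ = coords.shape
    sums = np.zeros((ns, k, 2))
    counts = np.zeros((ns, k, 2))

    def add(d):
        sums[...] += d
        counts[...] += 1.0

    for shift in (1, -1):
        d = np.linalg.norm(coords - np.roll(coords, shift, axis=1), axis=-1)
        add(d)
    if ns > 1:
        d = np.linalg.norm(coords[1:] - coords[:-1], axis=-1)
        sums[1:] += d
        counts[1:] += 1.0
        sums[:-1] += d
        counts[:-1] += 1.0
    return (sums / counts).reshape(-1)


def expansion_map(reference, target) -> np.ndarray:
    """Per-landmark signed surface expansion of ``target`` relative to
    ``reference``: log ratio of mean neighbour distances (positive =
    local expansion, negative = contraction)."""
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference)
    tgt = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target)
    if ref.shape != tgt.shape:
        raise InputError("reference and target landmark schemes differ")
    dr = _neighbor_mean_distances(ref)
    dt = _neighbor_mean_distances(tgt)
    if np.any(dr <= 0) or np.any(dt <= 0):
        raise MapError("degenerate neighbour distance of zero")
    return np.log(dt / dr)
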