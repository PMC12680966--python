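"""Targeted geometric morphometrics: local variance attribution per
semilandmark and PCA on the selected subset.

For every semilandmark a local neighbourhood of ``core_size`` landmarks
(the *N-core*, default 15: the focal landmark plus its 14 nearest
neighbours on the mean shape) is superimposed by its own GPA; the
between-group fraction of variance (trace R²) of the resulting shape
variables with respect to the binary stimulation label is computed, and
each landmark is assigned the average R² over every core that contains it.
Landmarks at or above the third quartile of that averaged map form the
targeted set, which is converted to shape variables by a restricted GPA
and analysed by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InferenceError, ParameterError
from .shape import PCAResult, ProcrustesFit, gpa, pca, _as_config_array
from .stats import group_r_squared

__all__ = [
    "NCoreSet",
    "VarianceMap",
    "ncore_neighborhoods",
    "local_variance_map",
    "threshold_quartile",
    "targeted_pca",
]


@dataclass
class NCoreSet:
    """Per-landmark neighbourhood index sets defined once on the mean shape."""

    cores: np.ndarray       # (n_landmarks, core_size) int indices; row j contains j
    core_size: int

    def covering(self, j: int) -> np.ndarray:
        """Indices of the cores that contain landmark j."""
        return np.nonzero(np.any(self.cores == j, axis=1))[0]


@dataclass
class VarianceMap:
    """Averaged per-semilandmark R̄² with the selection threshold applied."""

    r2_mean: np.ndarray
    threshold: float
    selected: np.ndarray    # sorted landmark indices with r2_mean >= threshold
    core_r2: np.ndarray = None

    def to_dataframe(self, labels: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"landmark_index": np.arange(len(self.r2_mean)),
                           "r2_mean": self.r2_mean})
        df["selected"] = df["landmark_index"].isin(self.selected)
        if labels is not None:
            df = labels.merge(df, on="landmark_index")
        return df


def ncore_neighborhoods(mean_shape: np.ndarray, core_size: int = 15) -> NCoreSet:
    """N-core of each landmark: itself plus its ``core_size - 1`` nearest
    landmarks by Euclidean distance on the mean shape; ties broken by lower
    index."""
    pts = np.asarray(mean_shape, dtype=float).reshape(-1, 3)
    n = len(pts)
    if core_size < 2:
        raise ParameterError("core_size must be >= 2")
    if core_size > n:
        raise ParameterError(f"core_size {core_size} exceeds landmark count {n}")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    # stable lexicographic order: distance, then index (deterministic ties)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    cores = np.sort(order[:, :core_size], axis=1)
    return NCoreSet(cores=cores, core_size=core_size)


def local_variance_map(configs, groups, cores: NCoreSet,
                       quantile_p: float = 0.75) -> VarianceMap:
    """Averaged per-semilandmark variance fraction for a binary grouping.

    For each core: restrict all configurations to the core's landmarks, run
    GPA on the subset, and compute the trace R² of the shape variables with
    respect to the labels.  A landmark's value is the mean R² over all
    cores containing it.  Cores whose subset is geometrically degenerate
    (all specimens identical) contribute R² = 0.
    """
    arr = _as_config_array(configs)
    g = np.asarray(groups)
    if len(g) != len(arr):
        raise InferenceError("one label per configuration required")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) != 2 or counts.min() < 2:
        raise InferenceError("need a binary grouping with >= 2 specimens per group")

    n_lm = arr.shape[1]
    core_r2 = np.empty(n_lm)
    for j in range(n_lm):
        sub = arr[:, cores.cores[j], :]
        if np.allclose(sub, sub[0], atol=1e-12):
            core_r2[j] = 0.0
            continue
        fit = gpa(sub)
        core_r2[j] = group_r_squared(fit.shape_variables, g)

    counts = np.zeros(n_lm)
    sums = np.zeros(n_lm)
    np.add.at(sums, cores.cores.ravel(), np.repeat(core_r2, cores.core_size))
    np.add.at(counts, cores.cores.ravel(), 1.0)
    r2_mean = sums / counts
    thr, selected = threshold_quartile(r2_mean, quantile_p)
    return VarianceMap(r2_mean=r2_mean, threshold=thr, selected=selected,
                       core_r2=core_r2)


def threshold_quartile(values, quantile_p: float = 0.75):
    """Empirical quantile threshold (linear interpolation between order
    statistics) and the index set of values at or above it."""
    if isinstance(values, VarianceMap):
        values = values.r2_mean
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty variance map")
    thr = float(np.quantile(v, quantile_p))
    return thr, np.nonzero(v >= thr)[0]


def targeted_pca(configs, selected) -> tuple[ProcrustesFit, PCAResult]:
    """GPA restricted to the selected landmarks followed by PCA of the
    resulting shape variables."""
    arr = _as_config_array(configs)
    sel = np.asarray(selected, dtype=int)
    if len(sel) < 3:
        raise ParameterError("need >= 3 selected landmarks for 3D alignment")
    fit = gpa(arr[:, sel, :])
    return fit, pca(fit)
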