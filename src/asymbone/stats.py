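"""Permutation inference and downstream entheseal-area statistics.

The central statistic is the multivariate coefficient of determination of a
binary grouping variable: R² = trace(SS_model)/trace(SS_total) from the
regression of a score matrix on the group indicator (equivalently, the
between-group fraction of total sum of squares).  Significance is assessed
by permuting the group labels without replacement; the reported p-value
uses the add-one convention p = (#{R²_perm ≥ R²_obs} + 1)/(B + 1), so it is
never exactly zero.  For small samples an exhaustive enumeration over all
distinct label assignments is available and the p-value is then the exact
permutation tail fraction.

Limbs are treated as exchangeable observations (labels permuted freely,
ignoring the pairing of antimeres within individuals); the resulting
non-independence caveat for real paired data is recorded in result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import InferenceError, InputError
from .shape import PCAResult, pca

__all__ = [
    "PermRegressionResult",
    "group_r_squared",
    "select_pcs_90",
    "perm_regression",
    "per_pc_anova",
    "correlation_pca",
    "percent_asymmetry",
]


def _as_binary(groups) -> np.ndarray:
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise InferenceError(f"grouping variable must be binary, got {len(uniq)} levels")
    return (g == uniq[1]).astype(bool)


def group_r_squared(x: np.ndarray, groups) -> float:
    """Between-group fraction of total sum of squares (trace-based R²).

    Returns 0 for data with zero total variance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    g = _as_binary(groups)
    xc = x - x.mean(axis=0)
    ss_total = float(np.sum(xc ** 2))
    if ss_total <= 0:
        return 0.0
    n1 = int(g.sum())
    n0 = len(g) - n1
    m1 = xc[g].mean(axis=0)
    m0 = xc[~g].mean(axis=0)
    ss_model = n1 * float(np.sum(m1 ** 2)) + n0 * float(np.sum(m0 ** 2))
    return min(ss_model / ss_total, 1.0)


@dataclass
class PermRegressionResult:
    """Observed R² and its permutation p-value."""

    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_components_used: int
    exhaustive: bool = False
    coding: str = "limb"

    note: str = ("labels permuted freely across limbs; antimere pairing "
                 "within individuals is ignored (non-independence caveat)")

    def as_dict(self) -> dict:
        return {"r_squared": self.r_squared, "p_value": self.p_value,
                "n_permutations": self.n_permutations, "seed": self.seed,
                "n_components_used": self.n_components_used,
                "exhaustive": self.exhaustive, "coding": self.coding}


def select_pcs_90(pca_result: PCAResult, threshold_percent: float = 90.0) -> list[int]:
    """Smallest prefix of components whose cumulative variance reaches the
    threshold (inclusive)."""
    cum = pca_result.cumulative_percent
    if np.any(np.isnan(cum)):
        return [0]
    idx = int(np.searchsorted(cum, threshold_percent - 1e-9))
    idx = min(idx, len(cum) - 1)
    return list(range(idx + 1))


def _permutation_r2(x: np.ndarray, g: np.ndarray, n_permutations: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorised R² over Monte-Carlo label permutations."""
    n, _ = x.shape
    xc = x - x.mean(axis=0)
    ss_total = float(np.sum(xc ** 2))
    n1 = int(g.sum())
    n0 = n - n1
    # permuted group-1 membership masks, (B, n)
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    masks = order < n1
    s1 = masks @ xc                       # (B, d) group-1 sums
    tot = xc.sum(axis=0)
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    ss_model = n1 * np.sum(m1 ** 2, axis=1) + n0 * np.sum(m0 ** 2, axis=1)
    return ss_model / ss_total


def _exhaustive_r2(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    n = len(g)
    n1 = int(g.sum())
    out = np.empty(comb(n, n1))
    mask = np.zeros(n, dtype=bool)
    for i, idx in enumerate(combinations(range(n), n1)):
        mask[:] = False
        mask[list(idx)] = True
        out[i] = group_r_squared(x, mask)
    return out


def perm_regression(scores, groups, n_permutations: int = 999,
                    seed: int | None = 0, exhaustive: bool = False,
                    coding: str = "limb") -> PermRegressionResult:
    """Permutation multivariate regression of scores on a binary group.

    Constant scores give R² = 0 with p = 1.  With ``exhaustive=True`` all
    distinct label assignments are enumerated (p = exact tail fraction,
    observed labelling included); otherwise ``n_permutations`` Monte-Carlo
    resamples are drawn from ``seed``.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    g = _as_binary(groups)
    if g.sum() < 2 or (~g).sum() < 2:
        raise InferenceError("each group needs at least two members")
    if n_permutations < 99 and not exhaustive:
        raise InferenceError("n_permutations must be >= 99")
    obs = group_r_squared(x, g)
    if np.sum((x - x.mean(axis=0)) ** 2) <= 0:
        return PermRegressionResult(0.0, 1.0, 0, seed, x.shape[1],
                                    exhaustive=exhaustive, coding=coding)
    if exhaustive:
        null = _exhaustive_r2(x, g)
        p = float(np.sum(null >= obs - 1e-12) / len(null))
        return PermRegressionResult(obs, p, len(null), seed, x.shape[1],
                                    exhaustive=True, coding=coding)
    rng = np.random.default_rng(seed)
    null = _permutation_r2(x, g, n_permutations, rng)
    p = float((np.sum(null >= obs - 1e-12) + 1) / (n_permutations + 1))
    return PermRegressionResult(obs, p, n_permutations, seed, x.shape[1],
                                coding=coding)


def per_pc_anova(scores, groups, n_permutations: int = 999,
                 seed: int | None = 0, coding: str = "limb") -> pd.DataFrame:
    """One-way permutation ANOVA per component (no multiplicity correction).

    Returns a DataFrame with columns ``component`` (0-based), ``r_squared``
    and ``p_value``.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    rows = []
    g = _as_binary(groups)
    if g.sum() < 2 or (~g).sum() < 2:
        raise InferenceError("each group needs at least two members")
    root = np.random.SeedSequence(seed)
    for j, child in enumerate(root.spawn(x.shape[1])):
        rng = np.random.default_rng(child)
        obs = group_r_squared(x[:, j:j + 1], g)
        if np.sum((x[:, j] - x[:, j].mean()) ** 2) <= 0:
            rows.append({"component": j, "r_squared": 0.0, "p_value": 1.0})
            continue
        null = _permutation_r2(x[:, j:j + 1], g, n_permutations, rng)
        p = float((np.sum(null >= obs - 1e-12) + 1) / (n_permutations + 1))
        rows.append({"component": j, "r_squared": obs, "p_value": p})
    return pd.DataFrame(rows)


def correlation_pca(areas) -> PCAResult:
    """Correlation-matrix PCA of an entheseal-area table.

    ``areas`` is a DataFrame whose numeric columns are per-structure 3D
    surface areas (mm², unadjusted for individual size).  Columns are
    standardised to unit variance; a zero-variance structure is an error
    naming the column.
    """
    if isinstance(areas, pd.DataFrame):
        num = areas.select_dtypes(include=[np.number])
        names = list(num.columns)
        x = num.to_numpy(dtype=float)
    else:
        x = np.asarray(areas, dtype=float)
        names = [f"var{j}" for j in range(x.shape[1])]
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need >= 2 specimens and >= 2 structures")
    sd = x.std(axis=0, ddof=1)
    for name, s in zip(names, sd):
        if s <= 0:
            raise InputError(f"structure {name!r} has zero variance")
    res = pca((x - x.mean(axis=0)) / sd)
    res.column_names = names
    return res


def percent_asymmetry(left_value: float, right_value: float) -> float:
    """Signed left/right percent difference, 100·(L − R)/((L + R)/2).

    Positive = left larger (the stimulated side in the emulated experiment).
    """
    if left_value <= 0 or right_value <= 0:
        raise InputError("percent_asymmetry requires strictly positive values")
    return 100.0 * (left_value - right_value) / ((left_value + right_value) / 2.0)
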