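"""Mantel and partial Mantel permutation tests on distance matrices.

The Mantel statistic is the Pearson correlation over the n(n-1)/2 distinct
pairs of two distance matrices; its null distribution is built by jointly
permuting rows and columns of one matrix (which preserves the dependence
structure within each matrix). The partial statistic conditions a third
matrix out of both via the first-order partial correlation formula and is
recomputed for every permutation of the first matrix. The alternative is
one-tailed (greater): the analyses here only ask whether distances covary
positively.

p includes the observed statistic: p = (1 + #{r_perm >= r_obs}) / (1 + N),
so p is never below 1/(N+1) and never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_permutations
from math import factorial

import numpy as np
import pandas as pd

from .distances import DistanceMatrix


@dataclass
class MantelResult:
    r_observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    partial: bool = False
    conditioned_on: str | None = None


def _condensed_checked(*mats: DistanceMatrix) -> list[np.ndarray]:
    n = mats[0].n
    ids = mats[0].sample_ids
    if n < 4:
        raise ValueError("Mantel tests need at least 4 samples")
    vecs = []
    for m in mats:
        if m.n != n or m.sample_ids != ids:
            raise ValueError("distance matrices have mismatched samples")
        v = m.condensed()
        if np.ptp(v) == 0:
            raise ValueError(f"constant upper triangle in matrix {m.label!r}")
        vecs.append(v)
    return vecs


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _pearson_many(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise correlation of each row of A with b."""
    A = A - A.mean(axis=1, keepdims=True)
    b = b - b.mean()
    num = A @ b
    den = np.sqrt((A * A).sum(axis=1) * (b @ b))
    return num / den


def _permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator, exact: bool
) -> np.ndarray:
    if exact:
        if factorial(n) > 50000:
            raise ValueError("exact enumeration is limited to small n")
        return np.array(list(_all_permutations(range(n))), dtype=int)
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def _permuted_condensed(D: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Upper-triangle vectors of D under each simultaneous row/col relabeling."""
    iu, ju = np.triu_indices(D.shape[0], k=1)
    return D[perms[:, iu], perms[:, ju]]


def mantel(
    Dx: DistanceMatrix,
    Dy: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """One-tailed (greater) Mantel test; permutes ``Dy``.

    ``exact`` enumerates all n! relabelings instead of sampling (small n
    only); the observed identity relabeling is then part of the null set.
    """
    x, y = _condensed_checked(Dx, Dy)
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    perms = _permutation_indices(Dx.n, n_perm, rng, exact)
    y_perm = _permuted_condensed(Dy.values, perms)
    r_perm = _pearson_many(y_perm, x)
    if exact:
        # every relabeling incl. identity forms the null; no +1 correction
        p = float(np.mean(r_perm >= r_obs - 1e-12))
        n_used = len(perms)
    else:
        p = (1.0 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1.0 + len(perms))
        n_used = len(perms)
    return MantelResult(r_obs, p, n_used, seed)


def partial_pearson(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z."""
    den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if den == 0:
        raise ValueError("degenerate conditioning: |r_xz| or |r_yz| is 1")
    return float((r_xy - r_xz * r_yz) / den)


def partial_mantel(
    Dx: DistanceMatrix,
    Dy: DistanceMatrix,
    Dz: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Partial Mantel test of Dx ~ Dy conditioned on Dz; permutes ``Dx``.

    The partial statistic is recomputed for every permutation (r_yz is
    unaffected by relabeling Dx and stays fixed).
    """
    x, y, z = _condensed_checked(Dx, Dy, Dz)
    r_yz = _pearson(y, z)
    r_obs = partial_pearson(_pearson(x, y), _pearson(x, z), r_yz)
    rng = np.random.default_rng(seed)
    perms = _permutation_indices(Dx.n, n_perm, rng, exact)
    x_perm = _permuted_condensed(Dx.values, perms)
    r_xy_p = _pearson_many(x_perm, y)
    r_xz_p = _pearson_many(x_perm, z)
    den = np.sqrt((1.0 - r_xz_p**2) * (1.0 - r_yz**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_perm = (r_xy_p - r_xz_p * r_yz) / den
    r_perm = r_perm[np.isfinite(r_perm)]
    if exact:
        p = float(np.mean(r_perm >= r_obs - 1e-12))
    else:
        p = (1.0 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1.0 + len(perms))
    return MantelResult(
        r_obs, p, len(perms), seed, partial=True, conditioned_on=Dz.label or "z"
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_bonferroni(p_values) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def apply_decision_rule(
    results: pd.DataFrame, r_min: float = 0.65, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag correlations strong enough to be reckoned biologically linked.

    A result is flagged iff r > r_min AND BH-adjusted p < alpha. ``results``
    needs columns ``r`` and ``p_adjusted``; a boolean ``linked`` column is
    added (copy returned).
    """
    out = results.copy()
    out["linked"] = (out["r"] > r_min) & (out["p_adjusted"] < alpha)
    return out
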