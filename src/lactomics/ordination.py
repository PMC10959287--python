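"""Bray–Curtis dissimilarity, principal coordinates, and PERMANOVA.

PERMANOVA is the one-factor (group) pseudo-F formulation on a distance
matrix, with the p-value from label permutations (exact enumeration when
the number of distinct assignments is small enough).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import FeatureTable, ValidationError


@dataclass
class OrdinationResult:
    coordinates: np.ndarray          # n × k
    eigenvalues: np.ndarray          # descending, positive ones retained
    proportion_explained: np.ndarray
    has_negative_eigenvalues: bool
    sample_ids: list[str]


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    exact: bool


def bray_curtis(table: FeatureTable) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, d = Σ|u−v| / Σ(u+v)."""
    x = table.values.to_numpy(dtype=float)
    zero = np.where(x.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    return squareform(pdist(x, metric="braycurtis"))


def pcoa(d: np.ndarray, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean distances) are flagged and their
    axes dropped; each retained axis has its sign fixed so the
    largest-magnitude coordinate is positive.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals).max(), 1.0)
    has_negative = bool(evals.min() < -tol)
    pos = evals > tol
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    if k is not None:
        k = min(k, coords.shape[1])
        coords = coords[:, :k]
        evals_pos = evals_pos[:k]
    total = evals[evals > tol].sum()
    prop = evals_pos / total if total > 0 else np.zeros_like(evals_pos)
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=evals_pos,
        proportion_explained=prop,
        has_negative_eigenvalues=has_negative,
        sample_ids=[],
    )


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances for a one-factor design."""
    n = d2.shape[0]
    levels, inv = np.unique(groups, return_inverse=True)
    a = len(levels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.where(inv == g)[0]
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    d: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with label-permutation p-value.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) for sampled permutations;
    when all distinct group assignments number at most n_perm they are
    enumerated exactly and p = #{F_perm >= F_obs} / #assignments.
    """
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    n = d.shape[0]
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValidationError("every group needs >= 2 samples")
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, groups)

    n_total = 1
    remaining = n
    for c in counts:
        n_total *= comb(remaining, int(c))
        remaining -= int(c)
    if len(levels) == 2 and n_total <= n_perm:
        na = int(counts[0])
        count = 0
        for idx in combinations(range(n), na):
            labels = np.full(n, levels[1], dtype=groups.dtype)
            labels[list(idx)] = levels[0]
            if _pseudo_f(d2, labels)[0] >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(f_obs, r2, count / n_total, n_total, True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(groups))[0] >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(f_obs, r2, (1 + count) / (1 + n_perm), n_perm, False)
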