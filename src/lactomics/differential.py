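"""Two-group differential-feature screens.

Three screens are provided, mirroring common practice for processed
microbiome/metabolome tables:

* Welch t-tests with HH/LL fold changes (traits, VFAs, per-feature gates);
* a Metastats-style per-feature permutation test (two-sample t statistic,
  label permutations) with Benjamini–Hochberg FDR across features;
* a simplified two-class LDA effect-size screen in the LEfSe tradition:
  per-million rescaling, rank-sum test, log10 absolute mean-difference
  effect size with the conventional threshold of 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .datamodel import FeatureTable, ValidationError


@dataclass
class DifferentialFeatureRecord:
    feature_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean_a / mean_b; NaN when mean_b == 0
    p: float
    q: float = float("nan")
    lda_score: float = float("nan")
    direction: int = 0  # +1 higher in group A, -1 higher in group B
    significant: bool = False


def welch_t_test(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Two-sided Welch t-test plus HH/LL-style fold change.

    Returns (t, df, p, fold_change).  Two constant equal groups give
    t = 0, p = 1; a zero group-B mean gives fold_change = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        t, df, p = (0.0, float(len(x) + len(y) - 2), 1.0) if x.mean() == y.mean() else (
            np.inf * np.sign(x.mean() - y.mean()),
            float(len(x) + len(y) - 2),
            0.0,
        )
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    my = y.mean()
    fc = x.mean() / my if my != 0 else float("nan")
    return t, df, p, fc


def _t_stat(x: np.ndarray, mask_a: np.ndarray) -> float:
    """Welch t for one label assignment; 0 when both groups are constant."""
    a, b = x[mask_a], x[~mask_a]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = va / len(a) + vb / len(b)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def permutation_test(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for a two-group mean difference (|t| statistic).

    When the number of distinct label assignments C(n, n_a) is at most
    ``n_perm`` the null distribution is enumerated exactly and
    p = #{|t_perm| >= |t_obs|} / #assignments; otherwise ``n_perm`` random
    assignments are drawn and p = (1 + #{>=}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValidationError("n_perm < 99 gives too coarse a p-value")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(levels)}")
    mask_a = groups == levels[0]
    n, na = len(values), int(mask_a.sum())
    if na < 2 or n - na < 2:
        raise ValidationError("each group needs >= 2 samples")

    t_obs = abs(_t_stat(values, mask_a))
    n_total = comb(n, na)
    if n_total <= n_perm:
        count = 0
        for idx in combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            if abs(_t_stat(values, m)) >= t_obs - 1e-12:
                count += 1
        return count / n_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=na, replace=False)] = True
        if abs(_t_stat(values, m)) >= t_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rescale_per_million(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=1, keepdims=True)
    return x / totals * 1e6


def lda_effect_size(
    table: FeatureTable,
    groups: np.ndarray,
    alpha: float = 0.05,
    lda_min: float = 2.0,
) -> list[DifferentialFeatureRecord]:
    """Two-class LDA effect-size screen.

    Samples are rescaled to one million total; each feature gets a
    two-sided Wilcoxon rank-sum p-value and an effect size
    log10(|mean_A - mean_B|) on the rescaled scale, floored at 0.
    Significant iff p < alpha and effect size > lda_min.  All-zero
    features are excluded (and still returned, flagged by NaN scores).
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(levels)}")
    x = _rescale_per_million(table.values.to_numpy(dtype=float))
    mask_a = groups == levels[0]
    records: list[DifferentialFeatureRecord] = []
    for j, feat in enumerate(table.feature_ids):
        col = x[:, j]
        if np.all(col == 0):
            records.append(
                DifferentialFeatureRecord(feat, 0.0, 0.0, float("nan"), float("nan"))
            )
            continue
        a, b = col[mask_a], col[~mask_a]
        if np.all(col == col[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        diff = a.mean() - b.mean()
        score = max(np.log10(abs(diff)), 0.0) if diff != 0 else 0.0
        mb = b.mean()
        records.append(
            DifferentialFeatureRecord(
                feature_id=feat,
                mean_a=float(a.mean()),
                mean_b=float(mb),
                fold_change=float(a.mean() / mb) if mb != 0 else float("nan"),
                p=p,
                lda_score=float(score),
                direction=int(np.sign(diff)),
                significant=bool(p < alpha and score > lda_min),
            )
        )
    return records


def metastats_screen(
    table: FeatureTable,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    q_max: float = 0.05,
    pooled: bool = True,
) -> list[DifferentialFeatureRecord]:
    """Metastats-style screen: permutation t-tests per feature, BH FDR.

    All features share one set of label permutations (drawn once from
    ``seed``).  With ``pooled`` (the default, following the Metastats
    practice for modest permutation counts) the permuted |t| statistics of
    all features form one null distribution, giving p-value resolution
    1/(B·m) instead of 1/B — without it, strongly differential features
    all tie at the floor 1/(B+1) and Benjamini–Hochberg at large m cannot
    rank them.  The t statistic is scale-free, making the pooled null
    exchangeable across features.  Significant iff q < q_max.
    """
    if n_perm < 99:
        raise ValidationError("n_perm < 99 gives too coarse a p-value")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(levels)}")
    x = table.values.to_numpy(dtype=float)
    n, p_feat = x.shape
    if p_feat == 0:
        return []
    mask_a = groups == levels[0]
    na, nb = int(mask_a.sum()), n - int(mask_a.sum())
    if na < 2 or nb < 2:
        raise ValidationError("each group needs >= 2 samples")

    def t_all(masks: np.ndarray) -> np.ndarray:
        # masks: n_masks × n boolean; returns n_masks × p_feat |t| matrix
        t_out = np.empty((masks.shape[0], p_feat))
        for i, m in enumerate(masks):
            a, b = x[m], x[~m]
            va = a.var(axis=0, ddof=1)
            vb = b.var(axis=0, ddof=1)
            denom = np.sqrt(va / na + vb / nb)
            diff = a.mean(axis=0) - b.mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(denom > 0, diff / denom, 0.0)
            t_out[i] = np.abs(t)
        return t_out

    t_obs = t_all(mask_a[None, :])[0]

    n_total = comb(n, na)
    if n_total <= n_perm:
        masks = np.zeros((n_total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), na)):
            masks[i, list(idx)] = True
        t_perm = t_all(masks)
        pvals = (t_perm >= t_obs[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, size=na, replace=False)] = True
        t_perm = t_all(masks)
        if pooled:
            null = np.sort(t_perm.ravel())
            exceed = len(null) - np.searchsorted(null, t_obs - 1e-12, side="left")
            pvals = (1 + exceed) / (1 + null.size)
        else:
            exceed = (t_perm >= t_obs[None, :] - 1e-12).sum(axis=0)
            pvals = (1 + exceed) / (1 + n_perm)

    qvals = bh_fdr(pvals)
    mean_a = x[mask_a].mean(axis=0)
    mean_b = x[~mask_a].mean(axis=0)
    records = []
    for j, feat in enumerate(table.feature_ids):
        mb = mean_b[j]
        records.append(
            DifferentialFeatureRecord(
                feature_id=feat,
                mean_a=float(mean_a[j]),
                mean_b=float(mb),
                fold_change=float(mean_a[j] / mb) if mb != 0 else float("nan"),
                p=float(pvals[j]),
                q=float(qvals[j]),
                direction=int(np.sign(mean_a[j] - mb)),
                significant=bool(qvals[j] < q_max),
            )
        )
    return records
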