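"""OPLS-DA for two-class metabolome comparisons, VIP selection, and
hypergeometric pathway enrichment.

The model follows the orthogonal-projections-to-latent-structures scheme:
variation in X orthogonal to the class vector y is stripped component by
component, then a single predictive latent component is fit to the
filtered X.  Features are selected by the usual metabolomics double gate,
VIP > 1 together with an FDR-adjusted univariate p < 0.05, and selected
metabolites are tested for pathway over-representation with the
hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import FeatureTable, PathwayAnnotation, ValidationError
from .differential import bh_fdr, welch_t_test


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA with one predictive component."""

    weights: np.ndarray          # p, unit norm, predictive
    scores: np.ndarray           # n, predictive
    loadings: np.ndarray         # p, predictive
    q_loading: float             # y-loading of the predictive component
    ortho_weights: np.ndarray    # p × n_ortho
    ortho_scores: np.ndarray     # n × n_ortho
    ortho_loadings: np.ndarray   # p × n_ortho
    r2y: float
    q2: float
    n_orthogonal: int
    y: np.ndarray
    x_filtered: np.ndarray = field(repr=False)
    permutation_p: float = float("nan")

    @property
    def n_features(self) -> int:
        return len(self.weights)


def log2_center(table: FeatureTable, pseudocount: float | None = None) -> np.ndarray:
    """Elementwise log2 then per-feature mean-centering.

    Zero or negative values are an error unless a positive pseudocount is
    configured, in which case it is added before the log.
    """
    x = table.values.to_numpy(dtype=float)
    if pseudocount is not None:
        if pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        x = x + pseudocount
    bad = np.argwhere(x <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-positive value at sample {table.sample_ids[r]!r}, feature "
            f"{table.feature_ids[c]!r}; enable a pseudocount to log-transform"
        )
    lx = np.log2(x)
    return lx - lx.mean(axis=0)


def _encode_classes(y: np.ndarray) -> np.ndarray:
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValidationError(f"OPLS-DA needs two classes, got {list(levels)}")
    for lev in levels:
        if (y == lev).sum() < 3:
            raise ValidationError(f"class {lev!r} has fewer than 3 samples")
    return np.where(y == levels[0], 1.0, -1.0)


def _fit_core(x: np.ndarray, yc: np.ndarray, n_orthogonal: int):
    """One OPLS pass: strip y-orthogonal components, fit predictive one."""
    yc = yc - yc.mean()
    xf = x.copy()
    ow, os_, ol = [], [], []
    for _ in range(n_orthogonal):
        w = xf.T @ yc / (yc @ yc)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = xf @ w
        p_load = xf.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no orthogonal variation left
            break
        w_o /= n_o
        t_o = xf @ w_o
        p_o = xf.T @ t_o / (t_o @ t_o)
        xf = xf - np.outer(t_o, p_o)
        ow.append(w_o)
        os_.append(t_o)
        ol.append(p_o)

    w = xf.T @ yc / (yc @ yc)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValidationError("X carries no class-predictive variation")
    w /= nw
    t = xf @ w
    p_load = xf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    stack = lambda v: np.array(v).T if v else np.zeros((x.shape[1], 0))
    return w, t, p_load, q, stack(ow), stack(os_), stack(ol), xf


def _venetian_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Venetian-blind fold assignment over a seeded sample shuffle."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def _q2(x: np.ndarray, yc: np.ndarray, n_orthogonal: int, folds: np.ndarray) -> float:
    ycc = yc - yc.mean()
    press, ssy = 0.0, float(ycc @ ycc)
    for f in np.unique(folds):
        test = folds == f
        if test.all() or (~test).all():
            continue
        xtr, ytr = x[~test], yc[~test]
        try:
            w, t, p_load, q, ow, os_, ol, _ = _fit_core(xtr, ytr, n_orthogonal)
        except ValidationError:
            return -np.inf
        xte = x[test].copy()
        for a in range(ow.shape[1]):
            t_o = xte @ ow[:, a]
            xte = xte - np.outer(t_o, ol[:, a])
        y_pred = (xte @ w) * q + ytr.mean()
        press += float(((yc[test] - y_pred) ** 2).sum())
    return 1.0 - press / ssy


def fit_oplsda(
    xmat: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    seed: int = 0,
    n_folds: int = 7,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA on a centered matrix.

    Class labels are coded +1 (first level in sorted order, HH before LL)
    and -1.  Q2 comes from seeded venetian-blind cross-validation with
    ``n_folds`` folds (capped at n).
    """
    xmat = np.asarray(xmat, dtype=float)
    if xmat.shape[0] < 6:
        raise ValidationError("OPLS-DA needs at least 6 samples")
    if np.allclose(xmat.std(axis=0), 0):
        raise ValidationError("X has zero variance")
    yc = _encode_classes(np.asarray(y))

    w, t, p_load, q, ow, os_, ol, xf = _fit_core(xmat, yc, n_orthogonal)
    ycc = yc - yc.mean()
    resid = ycc - t * q
    r2y = 1.0 - float(resid @ resid) / float(ycc @ ycc)

    rng = np.random.default_rng(seed)
    folds = _venetian_folds(len(yc), min(n_folds, len(yc)), rng)
    q2 = _q2(xmat, yc, n_orthogonal, folds)

    return OplsdaModel(
        weights=w,
        scores=t,
        loadings=p_load,
        q_loading=q,
        ortho_weights=ow,
        ortho_scores=os_,
        ortho_loadings=ol,
        r2y=r2y,
        q2=q2,
        n_orthogonal=ow.shape[1],
        y=yc,
        x_filtered=xf,
    )


def vip_scores(model: OplsdaModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    With unit-norm weights and a single predictive component this reduces
    to sqrt(p) * |w_j|, which satisfies mean(VIP^2) = 1 exactly.
    """
    if model.weights is None:
        raise ValidationError("model is not fitted")
    p = model.n_features
    ssy = float((model.scores @ model.scores) * model.q_loading**2)
    return np.sqrt(p * ssy * model.weights**2 / ssy)


def permutation_validate(
    xmat: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    n_orthogonal: int = 1,
) -> float:
    """Label-permutation validation of the OPLS-DA Q2.

    Refits the model on permuted class labels; p = (1 + #{Q2_perm >=
    Q2_obs}) / (1 + n_perm), so the best attainable p is 1/(n_perm+1).
    """
    if n_perm < 20:
        raise ValidationError("n_perm < 20 gives too coarse a validation p")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    model = fit_oplsda(xmat, y, n_orthogonal=n_orthogonal, seed=seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        try:
            mp = fit_oplsda(xmat, yp, n_orthogonal=n_orthogonal, seed=seed)
            q2p = mp.q2
        except ValidationError:
            q2p = -np.inf
        if q2p >= model.q2:
            count += 1
    return (1 + count) / (1 + n_perm)


def select_metabolites(
    vip: np.ndarray,
    qvals: np.ndarray,
    feature_ids: list[str],
    mean_diff: np.ndarray,
    vip_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Double-gate selection: VIP > vip_min AND q < q_max (strict).

    ``mean_diff`` (group A minus group B) annotates direction.
    """
    vip = np.asarray(vip, dtype=float)
    qvals = np.asarray(qvals, dtype=float)
    mean_diff = np.asarray(mean_diff, dtype=float)
    if not (len(vip) == len(qvals) == len(feature_ids) == len(mean_diff)):
        raise ValidationError("vip, q, mean_diff and feature ids length mismatch")
    selected = (vip > vip_min) & (qvals < q_max)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "vip": vip,
            "q": qvals,
            "direction": np.where(mean_diff > 0, "higher_in_A", "higher_in_B"),
            "selected": selected,
        }
    )


def univariate_gate(
    table: FeatureTable, groups: np.ndarray, use_ranksum: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature p (Welch t on log2 data, or rank-sum), BH q, mean diff."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need two groups, got {list(levels)}")
    lx = log2_center(table)
    mask_a = groups == levels[0]
    pvals = np.empty(table.n_features)
    for j in range(table.n_features):
        a, b = lx[mask_a, j], lx[~mask_a, j]
        if use_ranksum:
            pvals[j] = (
                1.0
                if np.all(lx[:, j] == lx[0, j])
                else float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            )
        else:
            pvals[j] = welch_t_test(a, b)[2]
    qvals = bh_fdr(pvals)
    mean_diff = lx[mask_a].mean(axis=0) - lx[~mask_a].mean(axis=0)
    return pvals, qvals, mean_diff


def hypergeom_enrichment(
    selected: set[str], annotation: PathwayAnnotation
) -> pd.DataFrame:
    """Pathway over-representation by the hypergeometric upper tail.

    Universe N = annotated features, K = pathway members, n = selected
    features inside the universe, k = overlap; p = P(X >= k).  Selected
    features outside the universe are dropped.  Rows sorted by p, BH q
    across pathways appended.
    """
    universe = annotation.universe
    sel_in = set(selected) & universe
    n_univ, n_sel = len(universe), len(sel_in)
    rows = []
    for pw, members in sorted(annotation.pathways().items()):
        k_members = len(members)
        overlap = len(members & sel_in)
        if n_sel == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_univ, k_members, n_sel))
        rows.append(
            {
                "pathway_id": pw,
                "pathway_size": k_members,
                "overlap": overlap,
                "n_selected": n_sel,
                "n_universe": n_univ,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df
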