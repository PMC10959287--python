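"""Thresholded Spearman correlation analyses across omics layers and traits.

An edge is "significant" under the double gate used throughout the
downstream figures: |rho| > 0.5 and p < 0.05, both strict.  Features whose
significant correlation with a trait is positive (negative) form the
positively (negatively) "phenotype-associated" set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import FeatureTable, PhenotypeTable, ValidationError
from .differential import bh_fdr


@dataclass
class PhenotypeAssociatedSet:
    positive: list[str]
    negative: list[str]
    layer: str
    trait: str


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks; p from the large-sample
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("spearman needs equal-length vectors, n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def _spearman_block(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and t-approximation p between column blocks."""
    n = a.shape[0]
    ra, rb = _rank_matrix(a), _rank_matrix(b)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def correlate_blocks(
    a: pd.DataFrame,
    b: pd.DataFrame,
    a_layer: str,
    b_layer: str,
    alpha: float = 0.05,
    rho_min: float = 0.5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pairwise Spearman between every column of A and every column of B.

    Returns the full edge list; ``significant`` marks |rho| > rho_min and
    p < alpha (both strict).  Optional BH correction replaces p with q in
    the gate (off by default).
    """
    if not a.index.equals(b.index):
        raise ValidationError("blocks are not sample-aligned")
    if len(a.index) < 4:
        raise ValidationError("need >= 4 samples for correlation")
    rho, p = _spearman_block(
        a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    )
    src, tgt = np.meshgrid(
        np.arange(a.shape[1]), np.arange(b.shape[1]), indexing="ij"
    )
    edges = pd.DataFrame(
        {
            "source": np.asarray(a.columns)[src.ravel()],
            "source_layer": a_layer,
            "target": np.asarray(b.columns)[tgt.ravel()],
            "target_layer": b_layer,
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    gate_p = bh_fdr(edges["p"].to_numpy()) if bh_correct else edges["p"].to_numpy()
    edges["significant"] = (np.abs(edges["rho"]) > rho_min) & (gate_p < alpha)
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    return edges


def phenotype_associated(
    features: FeatureTable,
    phenotypes: PhenotypeTable,
    trait: str,
    alpha: float = 0.05,
    rho_min: float = 0.5,
) -> PhenotypeAssociatedSet:
    """Split a layer's features by the sign of their significant Spearman
    correlation with a trait."""
    order = phenotypes.sample_ids
    vals = features.reorder(order).values
    traits = pd.DataFrame(
        {trait: phenotypes.trait(trait)}, index=order
    )
    edges = correlate_blocks(
        vals, traits, features.layer, f"phenotype:{trait}", alpha, rho_min
    )
    sig = edges[edges["significant"]]
    return PhenotypeAssociatedSet(
        positive=sorted(sig.loc[sig["rho"] > 0, "source"]),
        negative=sorted(sig.loc[sig["rho"] < 0, "source"]),
        layer=features.layer,
        trait=trait,
    )


def shared_features(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Venn-style partition: (shared, only in A, only in B)."""
    set_a, set_b = set(set_a), set(set_b)
    return set_a & set_b, set_a - set_b, set_b - set_a
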