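"""Omics sample-relationship matrices.

Each omics layer is column-standardized (z-score per feature, sample
variance with denominator n-1) and turned into an n × n similarity matrix
Z Zᵀ / p — the construction used for "microbiability"-style variance
components, analogous to a genomic relationship matrix.  Under the n-1
variance convention the matrix has trace exactly n-1 and zero row sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureTable, ValidationError


@dataclass
class StandardizedMatrix:
    """Column-standardized layer matrix with zero-variance features dropped."""

    values: np.ndarray  # n_samples × p_kept
    sample_ids: list[str]
    kept_feature_ids: list[str]
    dropped_feature_ids: list[str]

    @property
    def p_used(self) -> int:
        return len(self.kept_feature_ids)


@dataclass
class RelationshipMatrix:
    """Symmetric PSD sample-similarity matrix for one omics layer."""

    values: np.ndarray  # n × n
    sample_ids: list[str]
    layer: str
    p_used: int


def standardize_columns(
    table: FeatureTable, log2_first: bool = False, pseudocount: float = 0.0
) -> StandardizedMatrix:
    """Z-score each feature across samples; drop zero-variance features.

    Parameters
    ----------
    table
        Input layer.
    log2_first
        Apply log2(x + pseudocount) before z-scoring.  Off by default:
        concentrations/abundances are standardized on their raw scale, the
        log transform being reserved for the multivariate metabolome stage.
    """
    if table.n_samples < 3:
        raise ValidationError("standardization requires >= 3 samples")
    x = table.values.to_numpy(dtype=float)
    if log2_first:
        if np.any(x + pseudocount <= 0):
            raise ValidationError(
                "log2 transform requires positive values (or a pseudocount)"
            )
        x = np.log2(x + pseudocount)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValidationError("no informative features: all are zero-variance")
    z = (x[:, keep] - mean[keep]) / sd[keep]
    feats = np.asarray(table.feature_ids)
    return StandardizedMatrix(
        values=z,
        sample_ids=table.sample_ids,
        kept_feature_ids=list(feats[keep]),
        dropped_feature_ids=list(feats[~keep]),
    )


def build_relationship_matrix(
    z: StandardizedMatrix, layer: str | None = None
) -> RelationshipMatrix:
    """Compute Z Zᵀ / p from a standardized layer.

    The result is symmetric, positive semidefinite, has zero row sums
    (columns of Z are centered) and trace n-1 (unit sample variance per
    column).
    """
    if z.p_used == 0:
        raise ValidationError("cannot build relationship matrix: p_used = 0")
    k = z.values @ z.values.T / z.p_used
    k = (k + k.T) / 2.0  # enforce exact symmetry against FP round-off
    return RelationshipMatrix(
        values=k,
        sample_ids=list(z.sample_ids),
        layer=layer or "unknown",
        p_used=z.p_used,
    )


def relationship_matrix_from_table(
    table: FeatureTable, log2_first: bool = False, pseudocount: float = 0.0
) -> RelationshipMatrix:
    """Convenience: standardize a layer and build its relationship matrix."""
    z = standardize_columns(table, log2_first=log2_first, pseudocount=pseudocount)
    return build_relationship_matrix(z, layer=table.layer)
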