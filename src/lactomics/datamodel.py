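"""Core tabular data model for the multi-omics milk-trait analysis.

Four omics layers are handled: species-level rumen microbial composition,
rumen microbial function (KEGG orthologs), rumen metabolome and serum
metabolome.  Feature tables are samples-by-features matrices of non-negative
relative abundances or concentrations; phenotypes carry the two milk traits
plus the fixed-effect covariates (parity, lactation days) and the HH/LL
yield-group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LAYERS = (
    "microbial_composition",
    "microbial_function",
    "rumen_metabolome",
    "serum_metabolome",
)

TRAITS = ("milk_yield", "milk_fat_yield")

PHENOTYPE_COLUMNS = (
    "milk_yield",
    "milk_fat_yield",
    "group",
    "parity",
    "lactation_days",
)


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {', '.join(dups)}")
    return ids


@dataclass
class FeatureTable:
    """Samples × features matrix of non-negative abundances/concentrations.

    ``values`` is a pandas DataFrame with sample ids as index and feature ids
    as columns; ``layer`` tags which omics layer the table belongs to.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "feature")
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise ValidationError(
                f"feature table must have >= 2 samples and >= 1 feature, "
                f"got shape {self.values.shape}"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at sample {self.values.index[r]!r}, "
                f"feature {self.values.columns[c]!r}"
            )
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value {arr[r, c]} at sample "
                f"{self.values.index[r]!r}, feature {self.values.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def reorder(self, sample_ids: list[str]) -> "FeatureTable":
        """Return a copy with samples in the given canonical order."""
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise ValidationError(
                f"layer {self.layer}: samples not present: {', '.join(missing)}"
            )
        return FeatureTable(self.values.loc[sample_ids].copy(), self.layer)


@dataclass
class PhenotypeTable:
    """Per-sample traits and covariates.

    Columns: milk_yield and milk_fat_yield (kg/day), group (HH/LL), parity
    (positive integer) and lactation_days (positive real, days).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(
                f"phenotype table missing column(s): {', '.join(missing)}"
            )
        _check_unique(self.data.index, "sample")
        for trait in TRAITS:
            vals = self.data[trait].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"non-finite value in trait {trait!r}")
        parity = self.data["parity"].to_numpy()
        if not np.all(parity == parity.astype(int)) or np.any(parity < 1):
            raise ValidationError("parity must be an integer >= 1")
        ld = self.data["lactation_days"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ld)) or np.any(ld <= 0):
            raise ValidationError("lactation_days must be positive and finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def group_levels(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def require_two_groups(self) -> tuple[str, str]:
        levels = self.group_levels()
        if len(levels) != 2:
            raise ValidationError(
                f"two-group stage requires exactly 2 group levels, "
                f"found {levels}"
            )
        return levels[0], levels[1]

    def trait(self, name: str) -> np.ndarray:
        if name not in TRAITS:
            raise ValidationError(f"unknown trait {name!r}; expected {TRAITS}")
        return self.data[name].to_numpy(dtype=float)


@dataclass
class PathwayAnnotation:
    """Feature-to-pathway map for hypergeometric enrichment.

    ``mapping`` sends a feature id to the set of pathway ids it belongs to;
    the ``universe`` is the set of all annotated features (the background
    population of the hypergeometric test).
    """

    mapping: Mapping[str, frozenset[str]]
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.mapping = {
            str(f): frozenset(str(p) for p in ps) for f, ps in self.mapping.items()
        }
        self.universe = frozenset(self.mapping)
        if not self.universe:
            raise ValidationError("empty pathway annotation")

    def pathways(self) -> dict[str, frozenset[str]]:
        """Invert the map: pathway id -> member feature ids."""
        inv: dict[str, set[str]] = {}
        for feat, ps in self.mapping.items():
            for p in ps:
                inv.setdefault(p, set()).add(feat)
        return {p: frozenset(members) for p, members in inv.items()}


@dataclass
class RunConfig:
    """Run configuration: input paths, thresholds and permutation counts."""

    layer_paths: dict[str, str]
    phenotype_path: str
    annotation_path: str | None = None
    traits: tuple[str, ...] = TRAITS
    lda_min: float = 2.0
    vip_min: float = 1.0
    alpha: float = 0.05
    rho_min: float = 0.5
    q_max: float = 0.05
    n_perm_differential: int = 1000
    n_perm_oplsda: int = 200
    n_perm_permanova: int = 999
    seed: int = 0
    output_dir: str = "results"
    transposed_input: bool = False

    def __post_init__(self) -> None:
        for name in ("lda_min", "vip_min", "alpha", "rho_min", "q_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        for name in ("n_perm_differential", "n_perm_oplsda", "n_perm_permanova"):
            if getattr(self, name) < 99:
                raise ValidationError(
                    f"{name} must be >= 99 for usable p-value resolution"
                )
        unknown = [l for l in self.layer_paths if l not in LAYERS]
        if unknown:
            raise ValidationError(f"unknown layer(s) in config: {unknown}")
        bad = [t for t in self.traits if t not in TRAITS]
        if bad:
            raise ValidationError(f"unknown trait(s) in config: {bad}")
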