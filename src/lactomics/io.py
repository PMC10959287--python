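"""Readers and writers for the TSV/YAML interchange formats.

All tables are tab-separated text with a header row.  Feature tables are
samples-in-rows by default (first column = sample id, remaining columns =
feature ids); a ``transposed`` flag accepts features-in-rows files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    FeatureTable,
    PathwayAnnotation,
    PhenotypeTable,
    RunConfig,
    ValidationError,
)


def read_feature_table(
    path: str | Path, layer: str, transposed: bool = False
) -> FeatureTable:
    """Read a TSV abundance/concentration table into a FeatureTable.

    Non-numeric cells raise a parse error; negative values and duplicate ids
    raise :class:`ValidationError` naming the offending cell or id.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureTable(df, layer)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample_id")


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_pathway_annotation(path: str | Path) -> PathwayAnnotation:
    """Read a two-column feature_id <tab> pathway_id map (no header needed).

    A header line whose first field is 'feature_id' is skipped.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            feat, pw = parts
            if lineno == 1 and feat == "feature_id":
                continue
            mapping.setdefault(feat, set()).add(pw)
    return PathwayAnnotation(mapping)


def write_pathway_annotation(ann: PathwayAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tpathway_id\n")
        for feat in sorted(ann.mapping):
            for pw in sorted(ann.mapping[feat]):
                fh.write(f"{feat}\t{pw}\n")


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a YAML mapping")
    if "traits" in raw:
        raw["traits"] = tuple(raw["traits"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValidationError(f"bad config key: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    d = dict(config.__dict__)
    d["traits"] = list(d["traits"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def write_matrix(
    values: np.ndarray, ids: list[str], path: str | Path
) -> None:
    """Write a square sample-by-sample matrix with ids on both axes."""
    pd.DataFrame(values, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
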