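"""End-to-end orchestration of the analysis stages.

Given a :class:`~lactomics.datamodel.RunConfig`, the pipeline reads every
configured layer, joins all tables on the phenotype table's sample order
(the canonical order for every downstream stage), and runs:

1. omics-explainability (REML variance components) per layer and trait;
2. differential screens (Metastats-style and LDA effect size) on the
   microbial layers;
3. OPLS-DA / VIP selection and, when an annotation map is configured,
   hypergeometric pathway enrichment on the metabolome layers;
4. Bray–Curtis / PCoA / PERMANOVA ordination per layer;
5. Spearman correlation networks: phenotype-associated metabolites and
   microbe–metabolite edges, plus the rumen/serum shared-metabolite
   comparison.

All outputs are TSV files plus a JSON manifest recording config, seed and
package version.  Two runs with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    FeatureTable,
    PhenotypeTable,
    RunConfig,
    ValidationError,
)
from .differential import lda_effect_size, metastats_screen
from .explainability import explainability_table
from .io import (
    read_feature_table,
    read_pathway_annotation,
    read_phenotype_table,
    write_manifest,
)
from .network import correlate_blocks, phenotype_associated, shared_features
from .oplsda import (
    fit_oplsda,
    hypergeom_enrichment,
    log2_center,
    permutation_validate,
    select_metabolites,
    univariate_gate,
    vip_scores,
)
from .ordination import bray_curtis, pcoa, permanova

_MICROBIAL = ("microbial_composition", "microbial_function")
_METABOLOME = ("rumen_metabolome", "serum_metabolome")


def _load_inputs(
    config: RunConfig,
) -> tuple[dict[str, FeatureTable], PhenotypeTable]:
    phenotypes = read_phenotype_table(config.phenotype_path)
    order = phenotypes.sample_ids
    layers: dict[str, FeatureTable] = {}
    for layer, path in config.layer_paths.items():
        table = read_feature_table(path, layer, transposed=config.transposed_input)
        orphans = sorted(set(order) - set(table.sample_ids))
        extra = sorted(set(table.sample_ids) - set(order))
        if orphans or extra:
            raise ValidationError(
                f"sample-id mismatch for layer {layer}: "
                f"missing from layer: {orphans}; not in phenotypes: {extra}"
            )
        layers[layer] = table.reorder(order)
    return layers, phenotypes


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> dict:
    """Run the configured stages and write results under the output dir.

    ``stages`` is a subset of {"explain", "differential", "metabolome",
    "ordination", "network"}; None means all.  Returns the manifest dict.
    """
    all_stages = {"explain", "differential", "metabolome", "ordination", "network"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    layers, phenotypes = _load_inputs(config)
    groups = phenotypes.groups.to_numpy()
    outputs: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        outputs.append(name)

    if "explain" in stages:
        save(
            explainability_table(layers, phenotypes, config.traits),
            "explainability.tsv",
        )

    if "differential" in stages:
        phenotypes.require_two_groups()
        for layer in _MICROBIAL:
            if layer not in layers:
                continue
            recs = metastats_screen(
                layers[layer],
                groups,
                n_perm=config.n_perm_differential,
                seed=config.seed,
                q_max=config.q_max,
            )
            save(_records_to_frame(recs), f"metastats_{layer}.tsv")
            recs = lda_effect_size(
                layers[layer], groups, alpha=config.alpha, lda_min=config.lda_min
            )
            save(_records_to_frame(recs), f"lefse_{layer}.tsv")

    selected_by_layer: dict[str, pd.DataFrame] = {}
    if "metabolome" in stages:
        phenotypes.require_two_groups()
        annotation = (
            read_pathway_annotation(config.annotation_path)
            if config.annotation_path
            else None
        )
        summaries = []
        for layer in _METABOLOME:
            if layer not in layers:
                continue
            table = layers[layer]
            x = log2_center(table)
            model = fit_oplsda(x, groups, seed=config.seed)
            model.permutation_p = permutation_validate(
                x, groups, n_perm=config.n_perm_oplsda, seed=config.seed
            )
            vip = vip_scores(model)
            _, qvals, mean_diff = univariate_gate(table, groups)
            sel = select_metabolites(
                vip,
                qvals,
                table.feature_ids,
                mean_diff,
                vip_min=config.vip_min,
                q_max=config.q_max,
            )
            save(sel, f"oplsda_features_{layer}.tsv")
            selected_by_layer[layer] = sel
            summaries.append(
                {
                    "layer": layer,
                    "r2y": model.r2y,
                    "q2": model.q2,
                    "permutation_p": model.permutation_p,
                    "n_orthogonal": model.n_orthogonal,
                    "n_selected": int(sel["selected"].sum()),
                }
            )
            if annotation is not None:
                chosen = set(sel.loc[sel["selected"], "feature_id"])
                save(
                    hypergeom_enrichment(chosen, annotation),
                    f"enrichment_{layer}.tsv",
                )
        save(pd.DataFrame(summaries), "oplsda_summary.tsv")
        if all(l in selected_by_layer for l in _METABOLOME):
            sets = {
                l: set(
                    selected_by_layer[l].loc[
                        selected_by_layer[l]["selected"], "feature_id"
                    ]
                )
                for l in _METABOLOME
            }
            shared, only_r, only_s = shared_features(
                sets["rumen_metabolome"], sets["serum_metabolome"]
            )
            save(
                pd.DataFrame(
                    {
                        "feature_id": sorted(shared) + sorted(only_r) + sorted(only_s),
                        "membership": ["shared"] * len(shared)
                        + ["rumen_only"] * len(only_r)
                        + ["serum_only"] * len(only_s),
                    }
                ),
                "shared_metabolites.tsv",
            )

    if "ordination" in stages:
        phenotypes.require_two_groups()
        rows = []
        for layer, table in layers.items():
            d = bray_curtis(table)
            res = pcoa(d, k=2)
            coords = pd.DataFrame(
                res.coordinates,
                index=table.sample_ids,
                columns=[f"PCo{i + 1}" for i in range(res.coordinates.shape[1])],
            )
            coords.insert(0, "sample_id", coords.index)
            save(coords, f"pcoa_{layer}.tsv")
            perma = permanova(
                d, groups, n_perm=config.n_perm_permanova, seed=config.seed
            )
            rows.append(
                {
                    "layer": layer,
                    "pseudo_F": perma.pseudo_f,
                    "R2": perma.r2,
                    "p": perma.p,
                    "n_perm": perma.n_perm,
                    "exact": perma.exact,
                }
            )
        save(pd.DataFrame(rows), "permanova.tsv")

    if "network" in stages:
        phenotypes.require_two_groups()
        assoc_rows = []
        assoc_features: dict[str, set[str]] = {}
        for layer in _METABOLOME:
            if layer not in layers:
                continue
            for trait in config.traits:
                pa = phenotype_associated(
                    layers[layer],
                    phenotypes,
                    trait,
                    alpha=config.alpha,
                    rho_min=config.rho_min,
                )
                for feat in pa.positive:
                    assoc_rows.append(
                        {"layer": layer, "trait": trait, "feature_id": feat,
                         "association": "positive"}
                    )
                for feat in pa.negative:
                    assoc_rows.append(
                        {"layer": layer, "trait": trait, "feature_id": feat,
                         "association": "negative"}
                    )
                assoc_features.setdefault(layer, set()).update(
                    pa.positive + pa.negative
                )
        save(pd.DataFrame(assoc_rows), "phenotype_associated.tsv")

        if "microbial_composition" in layers:
            mc = layers["microbial_composition"]
            edge_frames = []
            for layer in _METABOLOME:
                if layer not in layers or not assoc_features.get(layer):
                    continue
                sub = layers[layer].values[sorted(assoc_features[layer])]
                edges = correlate_blocks(
                    mc.values,
                    sub,
                    "microbial_composition",
                    layer,
                    alpha=config.alpha,
                    rho_min=config.rho_min,
                )
                edge_frames.append(edges[edges["significant"]])
            if edge_frames:
                save(
                    pd.concat(edge_frames, ignore_index=True),
                    "correlation_edges.tsv",
                )

    manifest = {
        "package": "lactomics",
        "version": __version__,
        "seed": config.seed,
        "stages": sorted(stages),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        "outputs": sorted(outputs),
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest
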