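"""Synthetic multi-omics study generator with known ground truth.

The generator emulates the processed-table structure of a two-group
(HH/LL, 12 + 12) dairy-buffalo milk-production study: four omics layers —
species-level rumen microbial relative abundances, KEGG-ortholog functional
abundances, rumen metabolite and serum metabolite concentrations — plus a
phenotype table with milk yield and milk fat yield (kg/day), parity and
lactation days.

Abundances are drawn log-normally; microbial layers are closed to sum 1
per sample (compositional).  "Planted" differential features have their
group-specific mean multiplied by a configured fold-change before closure.
Phenotypes follow the mixed-model law the estimator assumes:

    y = mu + parity + slope * lactation_days + g + e,
    g = Z a / sqrt(p),  a ~ N(0, sigma2_omics),  e ~ N(0, sigma2_resid)

so that Cov(g) = (Z Zt / p) * sigma2_omics and the target explainability
m2 = sigma2_omics / (sigma2_omics + sigma2_resid) is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import LAYERS, TRAITS, FeatureTable, PhenotypeTable, ValidationError

_LAYER_PREFIX = {
    "microbial_composition": "sp",
    "microbial_function": "ko",
    "rumen_metabolome": "rmet",
    "serum_metabolome": "smet",
}

#: microbial layers are compositional (closed to 1); metabolomes are not
_COMPOSITIONAL = ("microbial_composition", "microbial_function")


def _default_n_features() -> dict[str, int]:
    # species and KO counts scaled down from catalogue scale to keep
    # matrices small; metabolite counts match typical panel sizes
    return {
        "microbial_composition": 500,
        "microbial_function": 2000,
        "rumen_metabolome": 1714,
        "serum_metabolome": 1356,
    }


def _default_explainability() -> dict[str, float]:
    return {
        "microbial_composition": 0.34,
        "microbial_function": 0.47,
        "rumen_metabolome": 0.39,
        "serum_metabolome": 0.50,
    }


def _default_planted() -> dict[str, dict[str, float]]:
    # 20 planted differential features per layer, 3-fold enriched in HH
    planted: dict[str, dict[str, float]] = {}
    for layer, prefix in _LAYER_PREFIX.items():
        planted[layer] = {f"{prefix}{j:04d}": 3.0 for j in range(20)}
    return planted


def _default_phenotype_associated() -> dict[str, int]:
    return {"rumen_metabolome": 10, "serum_metabolome": 10}


def _default_trait_means() -> dict[str, float]:
    return {"milk_yield": 9.0, "milk_fat_yield": 0.65}


def _default_trait_variances() -> dict[str, float]:
    return {"milk_yield": 4.0, "milk_fat_yield": 0.04}


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    ``explainability`` holds the per-layer target m2.  In ``driving`` mode
    the phenotype's random effect comes from ``driving_layer`` alone at that
    layer's m2; in ``combined`` mode every layer contributes and the
    per-layer m2 values must sum to at most 1.
    """

    n_samples: int = 24
    n_hh: int = 12
    n_ll: int = 12
    n_features: dict[str, int] = field(default_factory=_default_n_features)
    explainability: dict[str, float] = field(default_factory=_default_explainability)
    mode: Literal["driving", "combined"] = "driving"
    driving_layer: str = "microbial_composition"
    planted: dict[str, dict[str, float]] = field(default_factory=_default_planted)
    n_phenotype_associated: dict[str, int] = field(
        default_factory=_default_phenotype_associated
    )
    parity_levels: int = 3
    parity_effects_sd_units: tuple[float, ...] = (0.0, 0.1, 0.2)
    lactation_day_range: tuple[float, float] = (50.0, 250.0)
    lactation_slope_sd_per_100d: float = 0.1
    trait_means: dict[str, float] = field(default_factory=_default_trait_means)
    trait_variances: dict[str, float] = field(default_factory=_default_trait_variances)
    feature_log_mu_sd: float = 2.0
    feature_log_noise_sd: float = 0.5
    assoc_strength: float = 1.0
    assoc_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hh + self.n_ll != self.n_samples:
            raise ValidationError(
                f"group sizes {self.n_hh}+{self.n_ll} != n_samples {self.n_samples}"
            )
        for layer, m2 in self.explainability.items():
            if not 0.0 <= m2 <= 1.0:
                raise ValidationError(f"m2 for {layer} must be in [0, 1], got {m2}")
        if self.mode == "combined" and sum(self.explainability.values()) > 1.0:
            raise ValidationError(
                "combined mode: per-layer m2 values sum above 1 "
                f"({sum(self.explainability.values()):.3f})"
            )
        if self.driving_layer not in LAYERS:
            raise ValidationError(f"unknown driving layer {self.driving_layer!r}")
        for layer, fc_map in self.planted.items():
            for feat, fc in fc_map.items():
                if fc <= 0:
                    raise ValidationError(
                        f"fold-change for {feat} must be > 0, got {fc}"
                    )

    def sample_ids(self) -> list[str]:
        return [f"B{i + 1:03d}" for i in range(self.n_samples)]

    def group_labels(self) -> np.ndarray:
        return np.array(["HH"] * self.n_hh + ["LL"] * self.n_ll)

    def feature_ids(self, layer: str) -> list[str]:
        prefix = _LAYER_PREFIX[layer]
        return [f"{prefix}{j:04d}" for j in range(self.n_features[layer])]


@dataclass
class GroundTruth:
    """What the generator actually planted, serialized alongside the data."""

    target_m2: dict[str, float]
    mode: str
    driving_layer: str
    contributions: dict[str, float]  # realized per-layer m2 in the phenotype
    planted: dict[str, dict[str, float]]
    phenotype_associated: dict[str, list[str]]
    fixed_effects: dict[str, dict[str, float]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "target_m2": self.target_m2,
            "mode": self.mode,
            "driving_layer": self.driving_layer,
            "contributions": self.contributions,
            "planted": self.planted,
            "phenotype_associated": self.phenotype_associated,
            "fixed_effects": self.fixed_effects,
            "seed": self.seed,
        }


@dataclass
class SyntheticStudy:
    layers: dict[str, FeatureTable]
    phenotypes: PhenotypeTable
    truth: GroundTruth


def _layer_seed(seed: int, layer: str) -> np.random.Generator:
    idx = LAYERS.index(layer)
    return np.random.default_rng(np.random.SeedSequence([seed, idx]))


def simulate_layer(params: SimulationParams, layer: str, seed: int) -> FeatureTable:
    """Draw one omics layer.

    Log-normal intensities with per-feature baselines (heavy-tailed
    abundance distribution); planted features get their HH-group mean
    multiplied by the fold-change; microbial layers are then closed to
    relative abundances summing to 1 per sample.
    """
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}")
    rng = _layer_seed(seed, layer)
    n, p = params.n_samples, params.n_features[layer]
    feats = params.feature_ids(layer)
    feat_index = {f: j for j, f in enumerate(feats)}

    base = rng.normal(0.0, params.feature_log_mu_sd, size=p)
    log_x = base[None, :] + rng.normal(0.0, params.feature_log_noise_sd, size=(n, p))

    groups = params.group_labels()
    for feat, fc in params.planted.get(layer, {}).items():
        if feat not in feat_index:
            raise ValidationError(f"planted feature {feat!r} not in layer {layer}")
        j = feat_index[feat]
        log_x[groups == "HH", j] += np.log(fc)

    x = np.exp(log_x)
    if layer in _COMPOSITIONAL:
        x = x / x.sum(axis=1, keepdims=True)
    df = pd.DataFrame(x, index=params.sample_ids(), columns=feats)
    return FeatureTable(df, layer)


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    return (x[:, keep] - mean[keep]) / sd[keep]


def _fixed_effects(
    params: SimulationParams, trait: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Parity assignment, lactation days and the fixed part of the trait."""
    n = params.n_samples
    sd = float(np.sqrt(params.trait_variances[trait]))
    parity = 1 + rng.integers(0, params.parity_levels, size=n)
    days = rng.uniform(*params.lactation_day_range, size=n)
    effects = np.array(params.parity_effects_sd_units) * sd
    slope = params.lactation_slope_sd_per_100d * sd / 100.0
    fixed = (
        params.trait_means[trait]
        + effects[parity - 1]
        + slope * (days - days.mean())
    )
    coef = {f"parity{lev + 1}": float(effects[lev]) for lev in range(len(effects))}
    coef["lactation_slope_per_day"] = float(slope)
    coef["intercept"] = params.trait_means[trait]
    return parity, days, fixed, coef


def simulate_phenotypes(
    z: np.ndarray | dict[str, np.ndarray],
    params: SimulationParams,
    seed: int,
    return_components: bool = False,
) -> tuple[PhenotypeTable, dict]:
    """Generate both traits under the mixed-model law.

    ``z`` is a column-standardized matrix (driving mode) or a dict of such
    matrices keyed by layer (combined mode).  Each trait gets independent
    random-effect coefficients and residuals; the variance split per layer
    follows ``params.explainability`` so the target m2 holds exactly in
    expectation.  Returns the table and a record of realized contributions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1001]))
    n = params.n_samples

    if params.mode == "combined":
        if not isinstance(z, dict):
            raise ValidationError("combined mode requires one Z per layer")
        z_by_layer = z
        m2_by_layer = dict(params.explainability)
    else:
        zmat = z[params.driving_layer] if isinstance(z, dict) else z
        z_by_layer = {params.driving_layer: zmat}
        m2_by_layer = {
            params.driving_layer: params.explainability[params.driving_layer]
        }
    m2_total = sum(m2_by_layer.values())
    if m2_total > 1.0:
        raise ValidationError(f"total m2 {m2_total:.3f} exceeds 1")

    data: dict[str, np.ndarray] = {}
    fixed_coefs: dict[str, dict[str, float]] = {}
    components: dict[str, dict[str, np.ndarray]] = {}
    parity = days = None
    for trait in TRAITS:
        var_tot = params.trait_variances[trait]
        parity, days, fixed, coef = _fixed_effects(params, trait, rng)
        g = np.zeros(n)
        for layer, zmat in z_by_layer.items():
            m2 = m2_by_layer[layer]
            if m2 > 0:
                p_l = zmat.shape[1]
                a = rng.normal(0.0, np.sqrt(m2 * var_tot), size=p_l)
                g = g + zmat @ a / np.sqrt(p_l)
        sigma_e = np.sqrt((1.0 - m2_total) * var_tot)
        e = rng.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
        data[trait] = fixed + g + e
        fixed_coefs[trait] = coef
        components[trait] = {"fixed": fixed, "g": g, "e": e}

    table = PhenotypeTable(
        pd.DataFrame(
            {
                "milk_yield": data["milk_yield"],
                "milk_fat_yield": data["milk_fat_yield"],
                "group": params.group_labels(),
                "parity": parity,
                "lactation_days": days,
            },
            index=params.sample_ids(),
        )
    )
    info = {"contributions": m2_by_layer, "fixed_effects": fixed_coefs}
    if return_components:
        info["components"] = components
    return table, info


def generate_study(params: SimulationParams | None = None) -> SyntheticStudy:
    """Full synthetic study: four layers, phenotypes and ground truth.

    After phenotype generation, a configurable number of metabolome
    features are rewritten as noisy monotone functions of milk yield —
    emulating "phenotype-associated metabolites" with a known answer for
    the correlation-network stage.
    """
    params = params or SimulationParams()
    layers = {layer: simulate_layer(params, layer, params.seed) for layer in LAYERS}

    if params.mode == "combined":
        z: np.ndarray | dict[str, np.ndarray] = {
            layer: _standardize(layers[layer].values.to_numpy()) for layer in LAYERS
        }
    else:
        z = _standardize(layers[params.driving_layer].values.to_numpy())

    phenotypes, info = simulate_phenotypes(z, params, params.seed)

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2002]))
    y = phenotypes.trait("milk_yield")
    y_std = (y - y.mean()) / y.std(ddof=1)
    assoc: dict[str, list[str]] = {}
    for layer, n_assoc in params.n_phenotype_associated.items():
        if n_assoc == 0 or layer in _COMPOSITIONAL:
            continue
        n_planted = len(params.planted.get(layer, {}))
        feats = layers[layer].feature_ids[n_planted : n_planted + n_assoc]
        vals = layers[layer].values
        for feat in feats:
            noise = rng.normal(0.0, params.assoc_noise_sd, size=params.n_samples)
            vals[feat] = np.exp(params.assoc_strength * y_std + noise)
        assoc[layer] = feats
        layers[layer] = FeatureTable(vals, layer)

    truth = GroundTruth(
        target_m2=dict(params.explainability),
        mode=params.mode,
        driving_layer=params.driving_layer,
        contributions=info["contributions"],
        planted={l: dict(m) for l, m in params.planted.items()},
        phenotype_associated=assoc,
        fixed_effects=info["fixed_effects"],
        seed=params.seed,
    )
    return SyntheticStudy(layers=layers, phenotypes=phenotypes, truth=truth)
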