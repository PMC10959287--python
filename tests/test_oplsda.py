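from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from lactomics.datamodel import FeatureTable, PathwayAnnotation, ValidationError
from lactomics.oplsda import (
    fit_oplsda,
    hypergeom_enrichment,
    log2_center,
    permutation_validate,
    select_metabolites,
    vip_scores,
)


def _table(values):
    arr = np.asarray(values, dtype=float)
    return FeatureTable(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"m{j}" for j in range(arr.shape[1])],
        ),
        "rumen_metabolome",
    )


def _planted_data(rng, n=24, p=40, noise=0.1):
    y = np.array(["HH"] * (n // 2) + ["LL"] * (n - n // 2))
    yc = np.where(y == "HH", 1.0, -1.0)
    c = rng.standard_normal(p)
    c /= np.linalg.norm(c)
    x = np.outer(yc, c) + noise * rng.standard_normal((n, p))
    return x - x.mean(0), y, c


class TestLog2Center:
    def test_hand_case(self):
        out = log2_center(_table([[1.0], [2.0], [4.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_feature_centers_to_zero(self):
        out = log2_center(_table([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(out, 0.0)

    def test_zero_without_pseudocount_errors(self):
        with pytest.raises(ValidationError, match="m0"):
            log2_center(_table([[0.0], [1.0], [2.0]]))

    def test_pseudocount_permits_zeros(self):
        out = log2_center(_table([[0.0], [1.0], [3.0]]), pseudocount=1.0)
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])


class TestOplsda:
    def test_planted_direction_recovered(self, rng):
        x, y, c = _planted_data(rng, noise=0.05)
        model = fit_oplsda(x, y, seed=0)
        cosine = abs(model.weights @ c)
        assert cosine > 0.99

    def test_predictive_and_orthogonal_scores_orthogonal(self, rng):
        x, y, _ = _planted_data(rng, noise=0.5)
        x = x + np.outer(rng.standard_normal(len(y)), rng.standard_normal(x.shape[1]))
        x = x - x.mean(0)
        model = fit_oplsda(x, y, n_orthogonal=2, seed=0)
        for a in range(model.ortho_scores.shape[1]):
            assert abs(model.scores @ model.ortho_scores[:, a]) < 1e-6

    def test_null_q2_stays_low(self, rng):
        q2s = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            x = local.standard_normal((24, 30))
            y = np.array(["HH"] * 12 + ["LL"] * 12)
            q2s.append(fit_oplsda(x - x.mean(0), y, seed=seed).q2)
        assert np.median(q2s) <= 0.2

    def test_orthogonal_variation_removed(self, rng):
        x, y, _ = _planted_data(rng, noise=0.1)
        base = fit_oplsda(x, y, seed=0)
        yc = np.where(y == "HH", 1.0, -1.0)
        ortho_dir = rng.standard_normal(x.shape[1])
        t_ortho = rng.standard_normal(len(y))
        t_ortho -= t_ortho @ yc / (yc @ yc) * yc  # strictly y-orthogonal
        x2 = x + 5.0 * np.outer(t_ortho, ortho_dir)
        aug = fit_oplsda(x2 - x2.mean(0), y, seed=0)
        r_base = abs(np.corrcoef(base.scores, yc)[0, 1])
        r_aug = abs(np.corrcoef(aug.scores, yc)[0, 1])
        assert abs(r_base - r_aug) < 0.02

    def test_small_class_rejected(self, rng):
        x = rng.standard_normal((6, 5))
        with pytest.raises(ValidationError, match="fewer than 3"):
            fit_oplsda(x, np.array(["A"] * 2 + ["B"] * 4), seed=0)

    def test_scores_sign_invariant_to_sample_reordering(self, rng):
        x, y, _ = _planted_data(rng, noise=0.3)
        model = fit_oplsda(x, y, seed=0)
        perm = rng.permutation(len(y))
        model_p = fit_oplsda(x[perm], y[perm], seed=0)
        agreement = np.corrcoef(model.scores[perm], model_p.scores)[0, 1]
        assert abs(agreement) > 0.999


class TestVip:
    def test_single_component_closed_form(self, rng):
        x, y, _ = _planted_data(rng, p=2, noise=0.0)
        # overwrite weights to the closed-form case (1, 0)
        model = fit_oplsda(x, y, seed=0)
        model.weights = np.array([1.0, 0.0])
        np.testing.assert_allclose(vip_scores(model), [np.sqrt(2), 0.0])

    def test_equal_weights_give_unit_vip(self, rng):
        x, y, _ = _planted_data(rng, p=5, noise=0.0)
        model = fit_oplsda(x, y, seed=0)
        model.weights = np.full(5, 1.0 / np.sqrt(5))
        np.testing.assert_allclose(vip_scores(model), 1.0)

    def test_mean_squared_vip_is_one(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            x = local.standard_normal((20, 15))
            y = np.array(["HH"] * 10 + ["LL"] * 10)
            vip = vip_scores(fit_oplsda(x - x.mean(0), y, seed=seed))
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)


class TestPermutationValidate:
    def test_separable_data_attains_lower_bound(self, rng):
        x, y, _ = _planted_data(rng, noise=0.02)
        p = permutation_validate(x, y, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_deterministic_under_seed(self, rng):
        x, y, _ = _planted_data(rng, noise=1.0)
        assert permutation_validate(x, y, n_perm=50, seed=3) == permutation_validate(
            x, y, n_perm=50, seed=3
        )

    def test_minimum_permutations_enforced(self, rng):
        x, y, _ = _planted_data(rng)
        with pytest.raises(ValidationError, match="20"):
            permutation_validate(x, y, n_perm=10, seed=0)


class TestSelection:
    def test_double_gate(self):
        df = select_metabolites(
            vip=[1.5, 0.9, 1.5],
            qvals=[0.01, 0.001, 0.2],
            feature_ids=["a", "b", "c"],
            mean_diff=[1.0, -1.0, 1.0],
        )
        assert list(df["selected"]) == [True, False, False]
        assert df.loc[0, "direction"] == "higher_in_A"

    def test_monotone_in_thresholds(self, rng):
        vip = rng.uniform(0, 2, 50)
        q = rng.uniform(0, 0.2, 50)
        md = rng.standard_normal(50)
        ids = [f"m{j}" for j in range(50)]
        loose = select_metabolites(vip, q, ids, md, vip_min=1.0, q_max=0.05)
        tight = select_metabolites(vip, q, ids, md, vip_min=1.3, q_max=0.01)
        assert set(tight.loc[tight["selected"], "feature_id"]) <= set(
            loose.loc[loose["selected"], "feature_id"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            select_metabolites([1.0], [0.01, 0.02], ["a"], [0.5])


def _hypergeom_oracle(n_univ, k_members, n_sel, k_overlap):
    """Exhaustive tail sum over binomial coefficients."""
    total = comb(n_univ, n_sel)
    return (
        sum(
            comb(k_members, i) * comb(n_univ - k_members, n_sel - i)
            for i in range(k_overlap, min(k_members, n_sel) + 1)
        )
        / total
    )


class TestEnrichment:
    def _annotation(self, n_univ, k_members):
        mapping = {f"m{i}": {"pw"} for i in range(k_members)}
        mapping.update({f"m{i}": set() for i in range(k_members, n_univ)})
        return PathwayAnnotation(mapping)

    def test_closed_form_count_case(self):
        # N=10, K=2, n=5, k=2 -> C(2,2) C(8,3) / C(10,5) = 56/252
        ann = self._annotation(10, 2)
        df = hypergeom_enrichment({f"m{i}" for i in [0, 1, 4, 5, 6]}, ann)
        row = df[df["pathway_id"] == "pw"].iloc[0]
        assert row["p"] == pytest.approx(56 / 252, abs=1e-12)

    def test_tail_sum_case(self):
        # N=20, K=5, n=8, k=4
        ann = self._annotation(20, 5)
        sel = {f"m{i}" for i in [0, 1, 2, 3, 7, 8, 9, 10]}
        df = hypergeom_enrichment(sel, ann)
        row = df[df["pathway_id"] == "pw"].iloc[0]
        oracle = _hypergeom_oracle(20, 5, 8, 4)
        assert oracle == pytest.approx(0.0578, abs=5e-4)
        assert row["p"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        ann = self._annotation(10, 3)
        df = hypergeom_enrichment({"m5", "m6"}, ann)
        assert df[df["pathway_id"] == "pw"].iloc[0]["p"] == 1.0

    def test_empty_selection_all_p_one(self):
        ann = self._annotation(8, 2)
        df = hypergeom_enrichment(set(), ann)
        assert (df["p"] == 1.0).all()

    def test_matches_enumeration_over_all_selections(self):
        # exhaustive check of P(X >= k) on a small universe
        n_univ, k_members, n_sel = 9, 4, 4
        ann = self._annotation(n_univ, k_members)
        members = {f"m{i}" for i in range(k_members)}
        universe = [f"m{i}" for i in range(n_univ)]
        for k_overlap in range(0, k_members + 1):
            count = sum(
                1
                for sel in combinations(universe, n_sel)
                if len(set(sel) & members) >= k_overlap
            )
            enum_p = count / comb(n_univ, n_sel)
            sel_example = next(
                set(s)
                for s in combinations(universe, n_sel)
                if len(set(s) & members) == k_overlap
            )
            df = hypergeom_enrichment(sel_example, ann)
            row = df[df["pathway_id"] == "pw"].iloc[0]
            assert row["p"] == pytest.approx(enum_p, abs=1e-12)
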