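"""Noise filtering, duplicate collapsing, fold-change computation."""

import numpy as np
import pandas as pd
import pytest

from mirimpact.exceptions import ConfigurationError, DataError, InvalidArgumentError
from mirimpact.expression import (
    ExpressionMatrix,
    apply_noise_filter,
    collapse_duplicates,
    compute_fold_change,
    fit_noise_model,
)


def _mixture_summary(n_low, n_high, mean_low=2.0, mean_high=8.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [rng.normal(mean_low, sd, n_low), rng.normal(mean_high, sd, n_high)]
    )
    ids = [f"low{i}" for i in range(n_low)] + [f"high{i}" for i in range(n_high)]
    return pd.Series(values, index=ids)


def _expr_matrix(values: pd.Series) -> ExpressionMatrix:
    frame = pd.DataFrame({"s1": values, "s2": values})
    meta = pd.DataFrame(
        {"condition": ["control", "irradiated"], "time_h": [1.0, 1.0]},
        index=["s1", "s2"],
    )
    return ExpressionMatrix(frame, meta)


class TestNoiseModel:
    def test_two_component_threshold_near_intersection(self):
        # equal-weight equal-variance Gaussians at 2 and 8 intersect at 5
        summary = _mixture_summary(3000, 3000)
        res = fit_noise_model(summary, k_max=4, n_starts=10)
        assert res.n_components == 2
        assert abs(res.threshold - 5.0) < 0.25
        assert all(summary[f] >= res.threshold for f in res.kept_ids)

    def test_rules_agree_on_separated_mixture(self):
        summary = _mixture_summary(2000, 2000)
        a = fit_noise_model(summary, k_max=4, n_starts=10, rule="top_three")
        b = fit_noise_model(summary, k_max=4, n_starts=10, rule="kmeans")
        assert a.threshold == pytest.approx(b.threshold, abs=1e-9)

    def test_single_component_forced_removes_nothing(self):
        summary = _mixture_summary(200, 0, mean_low=6.0, sd=0.3)
        res = fit_noise_model(summary, k_min=1, k_max=1, n_starts=5)
        assert res.threshold < summary.min()
        assert not res.removed_ids

    def test_deterministic_given_seed(self):
        summary = _mixture_summary(500, 500)
        a = fit_noise_model(summary, k_max=3, n_starts=5, random_state=1)
        b = fit_noise_model(summary, k_max=3, n_starts=5, random_state=1)
        assert a.threshold == b.threshold
        assert a.kept_ids == b.kept_ids

    def test_threshold_invariant_to_feature_order(self):
        summary = _mixture_summary(500, 500)
        shuffled = summary.sample(frac=1.0, random_state=3)
        a = fit_noise_model(summary, k_max=3, n_starts=5)
        b = fit_noise_model(shuffled, k_max=3, n_starts=5)
        assert a.threshold == pytest.approx(b.threshold, abs=1e-6)

    def test_removes_most_low_component_when_well_separated(self):
        # components >= 4 SD apart: > 95% of the low component must go
        summary = _mixture_summary(2000, 2000, mean_low=2, mean_high=8, sd=1.0)
        res = fit_noise_model(summary, k_max=4, n_starts=10)
        removed_low = sum(1 for f in res.removed_ids if f.startswith("low"))
        assert removed_low / 2000 > 0.95

    def test_too_few_features_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_noise_model(np.arange(10.0), k_max=8)

    def test_manual_threshold_override(self):
        summary = _mixture_summary(100, 100)
        res = fit_noise_model(summary, k_max=3, n_starts=5, threshold_override=4.0)
        assert res.threshold == 4.0


class TestApplyFilter:
    def test_threshold_below_min_is_identity(self):
        summary = _mixture_summary(0, 50)
        expr = _expr_matrix(summary)
        res = fit_noise_model(summary, k_min=1, k_max=1, n_starts=5)
        out = apply_noise_filter(expr, res)
        assert out.feature_ids == expr.feature_ids

    def test_threshold_above_max_empties_with_warning(self):
        summary = _mixture_summary(0, 50)
        expr = _expr_matrix(summary)
        res = fit_noise_model(
            summary, k_min=1, k_max=1, n_starts=5, threshold_override=summary.max() + 1
        )
        with pytest.warns(UserWarning):
            out = apply_noise_filter(expr, res)
        assert out.feature_ids == []

    def test_kept_set_equals_per_feature_oracle(self):
        summary = _mixture_summary(40, 40, seed=5)
        expr = _expr_matrix(summary)
        res = fit_noise_model(summary, k_max=2, n_starts=5, threshold_override=5.2)
        out = apply_noise_filter(expr, res)
        expected = [f for f in expr.feature_ids if summary[f] >= 5.2]
        assert out.feature_ids == expected

    def test_mismatched_feature_set_rejected(self):
        summary = _mixture_summary(30, 30)
        res = fit_noise_model(summary, k_max=2, n_starts=5)
        other = _expr_matrix(_mixture_summary(10, 10).rename(lambda s: "x" + s))
        with pytest.raises(DataError):
            apply_noise_filter(other, res)


class TestCollapseDuplicates:
    def _expr(self, probe_values, gene_of):
        values = pd.DataFrame({"s1": probe_values, "s2": probe_values})
        meta = pd.DataFrame(
            {"condition": ["control", "irradiated"], "time_h": [1, 1]},
            index=["s1", "s2"],
        )
        return ExpressionMatrix(values, meta, pd.Series(gene_of))

    def test_highest_mean_probe_kept(self):
        expr = self._expr(
            pd.Series({"p1": 6.1, "p2": 5.9}), {"p1": "g", "p2": "g"}
        )
        out = collapse_duplicates(expr)
        assert out.feature_ids == ["p1"]

    def test_tie_broken_lexicographically(self):
        expr = self._expr(
            pd.Series({"pB": 6.0, "pA": 6.0}), {"pB": "g", "pA": "g"}
        )
        assert collapse_duplicates(expr).feature_ids == ["pA"]

    def test_single_probe_genes_identity(self):
        expr = self._expr(
            pd.Series({"p1": 6.0, "p2": 7.0}), {"p1": "g1", "p2": "g2"}
        )
        assert collapse_duplicates(expr).feature_ids == ["p1", "p2"]

    def test_matches_groupby_argmax_oracle(self, rng):
        probes = [f"p{i:02d}" for i in range(30)]
        genes = {p: f"g{rng.integers(0, 8)}" for p in probes}
        values = pd.Series(rng.normal(6, 2, 30).round(6), index=probes)
        expr = self._expr(values, genes)
        out = collapse_duplicates(expr)
        expected = set()
        for g in set(genes.values()):
            members = [p for p in probes if genes[p] == g]
            best = sorted(members, key=lambda p: (-values[p], p))[0]
            expected.add(best)
        assert set(out.feature_ids) == expected

    def test_missing_gene_map_rejected(self):
        expr = _expr_matrix(pd.Series({"p1": 6.0}))
        with pytest.raises(ConfigurationError):
            collapse_duplicates(expr)


class TestFoldChange:
    def _expr(self):
        values = pd.DataFrame(
            {
                "c1": [5.0, 4.0],
                "c2": [5.0, 4.2],
                "t1": [6.0, 3.5],
                "t2": [6.0, 3.7],
            },
            index=["f1", "f2"],
        )
        meta = pd.DataFrame(
            {
                "condition": ["control", "control", "irradiated", "irradiated"],
                "time_h": [1.0, 1.0, 1.0, 1.0],
            },
            index=values.columns,
        )
        return ExpressionMatrix(values, meta)

    def test_simple_arithmetic(self):
        fc = compute_fold_change(self._expr(), ["c1", "c2"], ["t1", "t2"])
        assert fc.fc[0] == pytest.approx(1.0)
        assert fc.fc[1] == pytest.approx(3.6 - 4.1)

    def test_identical_groups_give_zero(self):
        fc = compute_fold_change(self._expr(), ["c1"], ["c1"])
        np.testing.assert_allclose(fc.fc, 0.0)

    def test_antisymmetric_under_selector_swap(self):
        expr = self._expr()
        fwd = compute_fold_change(expr, {"condition": "control"}, {"condition": "irradiated"})
        rev = compute_fold_change(expr, {"condition": "irradiated"}, {"condition": "control"})
        np.testing.assert_allclose(fwd.fc, -rev.fc)

    def test_matches_loop_oracle(self, rng):
        values = pd.DataFrame(
            rng.normal(6, 1, (10, 6)), index=[f"f{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame(
            {"condition": ["control"] * 3 + ["irradiated"] * 3, "time_h": [1.0] * 6},
            index=values.columns,
        )
        expr = ExpressionMatrix(values, meta)
        fc = compute_fold_change(expr, {"condition": "control"}, {"condition": "irradiated"})
        for j, f in enumerate(values.index):
            pre = np.mean([values.loc[f, s] for s in ["s0", "s1", "s2"]])
            post = np.mean([values.loc[f, s] for s in ["s3", "s4", "s5"]])
            assert fc.fc[j] == pytest.approx(post - pre)

    def test_empty_selection_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_fold_change(self._expr(), {"condition": "mock"}, {"condition": "irradiated"})
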