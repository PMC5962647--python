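"""ANOVA partition, design validation and preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gasca
from gasca.exceptions import DataError, DesignError

from conftest import make_balanced_dataset


def one_factor_dataset(values_by_level, var_names=None):
    """Tiny one-factor dataset from {level: list of row vectors}."""
    rows, labels, ids = [], [], []
    k = 0
    for lv, mat in values_by_level.items():
        for row in mat:
            rows.append(row)
            labels.append(lv)
            ids.append(f"o{k}")
            k += 1
    X = pd.DataFrame(np.asarray(rows, dtype=float), index=ids)
    if var_names:
        X.columns = var_names
    design = pd.DataFrame({"f": labels}, index=ids)
    return gasca.DesignedDataset(X=X, design=design)


class TestValidateDesign:
    def test_balanced_two_factor_annotates_replicates(self):
        ds = make_balanced_dataset([4, 3], 8, 5, seed=1)
        out = gasca.validate_design(ds)
        assert out.replicates == 8
        assert out.level_counts == {"factor1": 4, "factor2": 3}
        assert out.n_obs == 96

    def test_removing_one_observation_breaks_balance(self):
        ds = make_balanced_dataset([4, 3], 8, 5, seed=1)
        ds2 = gasca.DesignedDataset(X=ds.X.iloc[1:], design=ds.design.iloc[1:])
        with pytest.raises(DesignError, match="unbalanced"):
            gasca.validate_design(ds2)

    def test_one_factor_two_levels_37_replicates(self):
        # the layout of a two-subject repeated-urine-profile experiment
        rng = np.random.default_rng(0)
        values = {"s1": rng.normal(size=(37, 206)), "s2": rng.normal(size=(37, 206))}
        ds = one_factor_dataset(values)
        out = gasca.validate_design(ds)
        assert out.replicates == 37
        assert out.n_obs == 74 and out.n_vars == 206

    def test_missing_values_direct_to_imputation(self):
        ds = make_balanced_dataset([2, 2], 2, 3, seed=0)
        ds.X.iloc[0, 0] = np.nan
        with pytest.raises(DataError, match="impute_missing"):
            gasca.validate_design(ds)

    def test_single_level_factor_rejected(self):
        X = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
        design = pd.DataFrame({"f": ["x"] * 4}, index=list("abcd"))
        with pytest.raises(DesignError, match="single level"):
            gasca.validate_design(gasca.DesignedDataset(X=X, design=design))


class TestImputeMissing:
    def test_no_missing_is_identity(self):
        ds = make_balanced_dataset([2, 3], 2, 4, seed=3)
        out = gasca.impute_missing(ds.X, ds.design, seed=0)
        assert np.allclose(out.to_numpy(), ds.X.to_numpy())

    def test_zero_variance_cell_imputes_the_mean_exactly(self):
        ds = one_factor_dataset({"a": [[2, 1], [2, 2], [np.nan, 3]],
                                 "b": [[5, 1], [5, 2], [5, 3]]})
        out = gasca.impute_missing(ds.X, ds.design, seed=7)
        assert out.iloc[2, 0] == pytest.approx(2.0, abs=1e-12)

    def test_imputation_distribution_matches_cell_mean_and_variance(self):
        # cell {1, 3, missing}: imputed = 2 + Normal(0, var([1,3])=2).
        # Monte-Carlo over 10^4 seeds via 10^4 independent variables in one cell.
        n_rep = 10_000
        X = np.tile([[1.0], [3.0], [np.nan]], (1, n_rep))
        ds = one_factor_dataset({"a": X, "b": np.zeros((3, n_rep))})
        out = gasca.impute_missing(ds.X, ds.design, seed=11)
        imputed = out.iloc[2, :].to_numpy()
        assert imputed.mean() == pytest.approx(2.0, abs=0.06)
        assert imputed.var(ddof=1) == pytest.approx(2.0, rel=0.06)

    def test_deterministic_given_seed(self):
        ds = make_balanced_dataset([2, 2], 3, 4, seed=5)
        ds.X.iloc[[0, 5], [1, 2]] = np.nan
        a = gasca.impute_missing(ds.X, ds.design, seed=42)
        b = gasca.impute_missing(ds.X, ds.design, seed=42)
        c = gasca.impute_missing(ds.X, ds.design, seed=43)
        assert a.equals(b)
        assert not a.equals(c)

    def test_all_missing_cell_errors(self):
        ds = one_factor_dataset({"a": [[np.nan], [np.nan]], "b": [[1.0], [2.0]]})
        with pytest.raises(DataError, match="all values missing"):
            gasca.impute_missing(ds.X, ds.design, seed=0)


class TestMedianNormalize:
    def test_example_column(self):
        X = pd.DataFrame({"v": [2.0, 4.0, 6.0], "w": [1.0, 1.0, 1.0]})
        out = gasca.median_normalize(X)
        assert np.allclose(out["v"], [0.5, 1.0, 1.5])
        assert np.allclose(out["w"], 1.0)

    def test_output_median_is_one(self, rng):
        X = pd.DataFrame(rng.uniform(0.1, 10, size=(25, 6)))
        out = gasca.median_normalize(X)
        assert np.allclose(out.median(axis=0), 1.0)

    def test_zero_median_names_variable(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "bad": [-1.0, 0.0, 1.0]})
        with pytest.raises(DataError, match="bad"):
            gasca.median_normalize(X)


class TestDecompose:
    def test_constant_data_has_zero_effects(self):
        ds = make_balanced_dataset([2, 2], 2, 3, seed=0)
        ds.X.iloc[:, :] = 7.5
        d = gasca.decompose(ds)
        assert np.allclose(d.grand_mean, 7.5)
        for eff in d.effects.values():
            assert np.allclose(eff.to_numpy(), 0.0, atol=1e-12)
        assert np.allclose(d.residual.to_numpy(), 0.0, atol=1e-12)

    def test_noiseless_two_level_offsets(self):
        ds = one_factor_dataset({"lo": [[-2.0, -3.0]] * 3, "hi": [[2.0, 3.0]] * 3})
        d = gasca.decompose(ds)
        eff = d.effects["f"].to_numpy()
        assert np.allclose(np.abs(eff[:, 0]), 2.0)
        assert np.allclose(np.abs(eff[:, 1]), 3.0)
        assert np.allclose(d.residual.to_numpy(), 0.0, atol=1e-12)
        assert d.ssq["f"] + d.ssq["mean"] == pytest.approx(d.ssq["total"], rel=1e-12)

    def test_matches_groupby_mean_oracle(self):
        ds = make_balanced_dataset([4, 3], 2, 5, seed=9, effect_sizes=[1.0, 2.0])
        d = gasca.decompose(ds)
        X, design = ds.X, ds.design
        grand = X.mean(axis=0)
        for f in ["factor1", "factor2"]:
            oracle = X.groupby(design[f], observed=True).transform("mean") - grand
            assert np.allclose(
                d.effects[f].to_numpy(), oracle.to_numpy(), atol=1e-10
            )
        cell = X.groupby([design["factor1"], design["factor2"]], observed=True).transform("mean")
        oracle_int = (
            cell
            - X.groupby(design["factor1"], observed=True).transform("mean")
            - X.groupby(design["factor2"], observed=True).transform("mean")
            + grand
        )
        assert np.allclose(
            d.effects["factor1:factor2"].to_numpy(), oracle_int.to_numpy(), atol=1e-10
        )
        parts = sum(v for k, v in d.ssq.items() if k != "total")
        assert parts == pytest.approx(d.ssq["total"], rel=1e-8)

    def test_main_effects_constant_within_level_and_centered(self, planted_decomp):
        d = planted_decomp
        design = d.dataset.design
        for f in ["factor1", "factor2"]:
            eff = d.effects[f]
            assert np.allclose(eff.to_numpy().mean(axis=0), 0.0, atol=1e-10)
            for _, block in eff.groupby(design[f], observed=True):
                assert np.allclose(block.to_numpy(), block.to_numpy()[0], atol=1e-12)

    def test_unknown_interaction_rejected(self):
        ds = make_balanced_dataset([2, 2], 2, 3, seed=0)
        with pytest.raises(DesignError, match="unknown factor"):
            gasca.decompose(ds, include_interactions=[("factor1", "nosuch")])

    def test_idempotent_on_its_own_fit(self, planted_decomp):
        d = planted_decomp
        fitted = pd.DataFrame(
            d.grand_mean.to_numpy() + d.effects["factor1"].to_numpy(),
            index=d.dataset.X.index,
            columns=d.dataset.X.columns,
        )
        ds2 = gasca.DesignedDataset(X=fitted, design=d.dataset.design)
        d2 = gasca.decompose(ds2)
        assert np.allclose(d2.grand_mean, d.grand_mean, atol=1e-10)
        assert np.allclose(
            d2.effects["factor1"].to_numpy(), d.effects["factor1"].to_numpy(), atol=1e-10
        )
        assert np.allclose(d2.residual.to_numpy(), 0.0, atol=1e-10)

    def test_row_permutation_equivariance(self):
        ds = make_balanced_dataset([3, 2], 2, 4, seed=21, effect_sizes=[1.5, 0.5])
        d = gasca.decompose(ds)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_obs)
        ds_p = gasca.DesignedDataset(X=ds.X.iloc[perm], design=ds.design.iloc[perm])
        d_p = gasca.decompose(ds_p)
        for k in d.effects:
            assert np.allclose(
                d_p.effects[k].to_numpy(), d.effects[k].to_numpy()[perm], atol=1e-10
            )


class TestSsqTable:
    def test_fractions_sum_to_one_and_lie_in_unit_interval(self, planted_decomp):
        t = gasca.ssq_table(planted_decomp)
        assert t.sum() == pytest.approx(1.0, abs=1e-8)
        assert ((t >= 0) & (t <= 1)).all()

    def test_noiseless_one_effect_split(self):
        ds = one_factor_dataset({"lo": [[1.0, 4.0]] * 2, "hi": [[3.0, 8.0]] * 2})
        t = gasca.ssq_table(gasca.decompose(ds))
        assert t["mean"] + t["f"] == pytest.approx(1.0, abs=1e-12)
        assert t["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_null_effect_fraction_near_df_share(self):
        # for pure noise, E[effect SSQ] / E[centered total SSQ] = df / (N - 1)
        ds = gasca.simulate_null(levels=(4, 3), replicates=10, n_vars=400, seed=2)
        d = gasca.decompose(ds)
        centered = d.ssq["total"] - d.ssq["mean"]
        share = d.ssq["factor1"] / centered
        assert share == pytest.approx(3 / 119, rel=0.15)


class TestEffectResidualMatrix:
    def test_one_way_equals_centered_data(self):
        rngl = np.random.default_rng(5)
        ds = one_factor_dataset({"a": rngl.normal(size=(3, 4)), "b": rngl.normal(size=(3, 4))})
        d = gasca.decompose(ds)
        aug = gasca.effect_residual_matrix(d, "f")
        centered = ds.X - ds.X.mean(axis=0)
        assert np.allclose(aug.to_numpy(), centered.to_numpy(), atol=1e-12)

    def test_zero_residual_returns_effect_exactly(self):
        ds = one_factor_dataset({"lo": [[-1.0, 2.0]] * 2, "hi": [[1.0, -2.0]] * 2})
        d = gasca.decompose(ds)
        aug = gasca.effect_residual_matrix(d, "f")
        assert np.allclose(aug.to_numpy(), d.effects["f"].to_numpy(), atol=1e-12)

    def test_two_way_explicit_subtraction_oracle(self, planted_decomp):
        d = planted_decomp
        X = d.dataset.X.to_numpy()
        oracle = (
            X
            - d.grand_mean.to_numpy()
            - d.effects["factor2"].to_numpy()
            - d.effects["factor1:factor2"].to_numpy()
        )
        aug = gasca.effect_residual_matrix(d, "factor1")
        assert np.allclose(aug.to_numpy(), oracle, atol=1e-10)
        assert np.allclose(
            aug.to_numpy(),
            d.effects["factor1"].to_numpy() + d.residual.to_numpy(),
            atol=1e-10,
        )

    def test_unknown_effect(self, planted_decomp):
        with pytest.raises(DesignError, match="unknown effect"):
            gasca.effect_residual_matrix(planted_decomp, "nosuch")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n_a=st.integers(2, 4),
    n_b=st.integers(2, 3),
    reps=st.integers(1, 3),
    n_vars=st.integers(2, 6),
    seed=st.integers(0, 10_000),
)
def test_reconstruction_and_ssq_additivity_fuzz(n_a, n_b, reps, n_vars, seed):
    """The partition reconstructs X and its SSQ parts add up, on random balanced designs."""
    ds = make_balanced_dataset([n_a, n_b], reps, n_vars, seed=seed)
    ds.X.iloc[:, :] += np.random.default_rng(seed).normal(1.0, 2.0)
    d = gasca.decompose(ds)
    recon = (
        d.grand_mean.to_numpy()
        + sum(e.to_numpy() for e in d.effects.values())
        + d.residual.to_numpy()
    )
    X = ds.X.to_numpy()
    scale = max(1.0, np.abs(X).max())
    assert np.abs(recon - X).max() < 1e-10 * scale
    parts = sum(v for k, v in d.ssq.items() if k != "total")
    assert parts == pytest.approx(d.ssq["total"], rel=1e-8)
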