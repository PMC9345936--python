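"""Imputation, normalisation, fold changes, volcano, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from endoflux.metabolomics import (
    MetaboliteTable,
    fold_changes,
    impute_missing,
    normalize,
    pca_variance,
    read_table,
    volcano,
    write_table,
)


def make_table(values, groups, columns=None):
    values = np.asarray(values, float)
    columns = columns or [f"m{j}" for j in range(values.shape[1])]
    idx = [f"s{i}" for i in range(values.shape[0])]
    return MetaboliteTable(
        values=pd.DataFrame(values, index=idx, columns=columns),
        group=pd.Series(groups, index=idx),
    )


def two_group_table(rng, n_pat=35, n_ctl=20, n_met=8, shift=None):
    base = rng.lognormal(mean=2.0, sigma=0.3, size=(n_pat + n_ctl, n_met))
    if shift is not None:
        base[:n_pat] *= shift
    return make_table(base, ["patient"] * n_pat + ["control"] * n_ctl)


class TestImpute:
    def test_no_missing_returned_unchanged(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]], ["patient", "control"])
        assert impute_missing(t, "median", seed=0) is t

    @pytest.mark.parametrize("method", ["median", "forest"])
    def test_constant_column_limit(self, method):
        vals = np.column_stack([np.full(6, 7.0), np.arange(1.0, 7.0)])
        vals[2, 0] = np.nan
        t = make_table(vals, ["patient"] * 3 + ["control"] * 3)
        out = impute_missing(t, method, seed=1)
        assert not out.values.isna().to_numpy().any()
        assert out.values.iloc[2, 0] == pytest.approx(7.0, abs=1e-6)
        # observed entries untouched
        mask = ~t.values.isna()
        pd.testing.assert_frame_equal(out.values[mask], t.values[mask])

    def test_forest_beats_column_mean_on_correlated_data(self):
        rng = np.random.default_rng(0)
        z = rng.lognormal(0.0, 0.4, size=(60, 1))
        full = z * rng.uniform(0.8, 1.2, size=(60, 6)) + rng.normal(
            0, 0.02, size=(60, 6)
        )
        full = np.abs(full) + 0.01
        mask = rng.random(full.shape) < 0.05
        holed = full.copy()
        holed[mask] = np.nan
        t = make_table(holed, ["patient"] * 30 + ["control"] * 30)
        forest = impute_missing(t, "forest", seed=2).values.to_numpy()
        col_mean = np.where(
            np.isnan(holed), np.nanmean(holed, axis=0, keepdims=True), holed
        )
        rmse = lambda x: np.sqrt(np.mean((x[mask] - full[mask]) ** 2))
        assert rmse(forest) <= rmse(col_mean)

    def test_all_missing_column_named(self):
        vals = np.arange(1.0, 37.0).reshape(3, 12)
        t = make_table(vals, ["patient"] * 3)
        t.values.iloc[:, 1] = np.nan  # post-construction: isolates the error path
        with pytest.raises(ValueError, match="m1"):
            impute_missing(t, "median", seed=0)


class TestNormalize:
    def test_columns_centred(self):
        rng = np.random.default_rng(1)
        t = two_group_table(rng)
        out = normalize(t)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)

    def test_pareto_scales_sd_to_sqrt_sd(self):
        # construct a column whose log10 values have sd exactly 4
        n = 8
        logs = np.array([0.0, 8.0] * (n // 2))
        logs = (logs - logs.mean()) / logs.std(ddof=1) * 4.0
        vals = np.column_stack([10.0**logs, np.full(n, 2.0)])
        t = make_table(vals, ["patient"] * n)
        out = normalize(t)
        assert out.values.iloc[:, 0].std(ddof=1) == pytest.approx(2.0)

    def test_zero_concentration_identified(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]], ["patient", "control"])
        t.values.iloc[1, 0] = 0.0
        with pytest.raises(ValueError, match="s1.*m0"):
            normalize(t)


class TestFoldChanges:
    def test_identical_groups_give_unity(self):
        vals = np.tile([[2.0, 5.0]], (6, 1))
        t = make_table(vals, ["patient"] * 3 + ["control"] * 3)
        np.testing.assert_allclose(fold_changes(t, "patient", "control"), 1.0)

    def test_mean_ratio(self):
        vals = np.array([[3.0], [3.0], [2.0], [2.0]])
        t = make_table(vals, ["patient", "patient", "control", "control"])
        assert fold_changes(t, "patient", "control")["m0"] == pytest.approx(1.5)

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(2)
        t = two_group_table(rng)
        ab = fold_changes(t, "patient", "control")
        ba = fold_changes(t, "control", "patient")
        np.testing.assert_allclose(ab * ba, 1.0)


class TestVolcano:
    def test_fold_change_gate_blocks_small_effects(self):
        rng = np.random.default_rng(3)
        # huge significance but fc = 1.4 < 1.5: must not be flagged
        t = two_group_table(rng, n_met=4, shift=None)
        t.values.iloc[:, 0] = np.where(
            (t.group == "patient").to_numpy(), 1.4, 1.0
        ) * (1 + 1e-4 * rng.standard_normal(len(t.values)))
        res = volcano(t)
        assert res.loc["m0", "q"] < 1e-6
        assert 1.35 < res.loc["m0", "fc"] < 1.45
        assert not res.loc["m0", "flagged"]

    def test_null_simulation_type_I_error(self):
        rng = np.random.default_rng(4)
        raw_ps, flags = [], 0
        for _ in range(30):
            t = two_group_table(rng, n_met=20)
            res = volcano(t)
            raw_ps.extend(res["p"])
            flags += int(res["flagged"].sum())
        frac = np.mean(np.array(raw_ps) < 0.05)
        assert 0.01 <= frac <= 0.10  # ~5% raw positives under the null
        assert flags <= 2  # FDR keeps flags near zero

    def test_planted_threefold_shift_flagged(self):
        rng = np.random.default_rng(5)
        t = two_group_table(rng, n_met=6)
        t.values.iloc[:, 2] = np.where(
            (t.group == "patient").to_numpy(), 3.0, 1.0
        ) * rng.lognormal(0, 0.05, len(t.values))
        res = volcano(t)
        assert res.loc["m2", "flagged"]

    def test_q_at_least_p(self):
        rng = np.random.default_rng(6)
        res = volcano(two_group_table(rng, n_met=25))
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_flags_invariant_to_metabolite_order(self):
        rng = np.random.default_rng(7)
        t = two_group_table(rng, n_met=10, shift=1.8)
        res = volcano(t)
        rev = MetaboliteTable(
            values=t.values.iloc[:, ::-1], group=t.group
        )
        res_rev = volcano(rev)
        assert set(res.index[res["flagged"]]) == set(
            res_rev.index[res_rev["flagged"]]
        )

    def test_single_sample_group_rejected(self):
        t = make_table([[1.0], [2.0], [3.0]], ["patient", "control", "control"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            volcano(t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    ps=st.lists(
        st.floats(min_value=1e-8, max_value=1.0), min_size=3, max_size=40
    ),
    seed=st.integers(0, 10_000),
)
def test_bh_adjustment_is_permutation_invariant(ps, seed):
    """BH q-values: q >= p and the multiset survives reordering."""
    p = np.array(ps)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    assert np.all(q >= p - 1e-12)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(p))
    _, q2, _, _ = multipletests(p[perm], method="fdr_bh")
    np.testing.assert_allclose(np.sort(q), np.sort(q2))


class TestPCA:
    @staticmethod
    def _raw_table(X):
        # bypass the positivity validator: PCA operates on normalised data
        t = MetaboliteTable.__new__(MetaboliteTable)
        t.values = pd.DataFrame(np.asarray(X, float))
        t.group = pd.Series(["p"] * len(X))
        t.diagnosis = None
        t.missing_threshold = 0.1
        return t

    def test_rank_two_plane(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2)) @ rng.normal(size=(2, 5))
        frac = pca_variance(self._raw_table(X), 4)
        assert frac[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_decomposition_sums_to_one(self):
        rng = np.random.default_rng(9)
        t = two_group_table(rng, n_met=5)
        assert pca_variance(normalize(t), 5).sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_fractions(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 3))
        np.testing.assert_allclose(
            pca_variance(self._raw_table(X), 3), 1 / 3, atol=0.03
        )

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(11)
        t = two_group_table(rng, n_pat=3, n_ctl=2, n_met=4)
        with pytest.raises(ValueError, match="n_components"):
            pca_variance(t, 5)


class TestIO:
    def test_csv_roundtrip_with_missing(self, tmp_path):
        rng = np.random.default_rng(12)
        t = two_group_table(rng, n_met=4)
        t.values.iloc[0, 0] = np.nan
        t = MetaboliteTable(values=t.values, group=t.group)
        path = tmp_path / "cohort.csv"
        write_table(t, str(path))
        back = read_table(str(path))
        pd.testing.assert_frame_equal(back.values, t.values.rename_axis("sample_id"))
        pd.testing.assert_series_equal(
            back.group, t.group.rename_axis("sample_id"), check_names=False
        )
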