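"""Indices, imputation, PCA and morphotype grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA as SKPCA

from ichnometry import (
    FootprintTable,
    arch_angle,
    foot_index,
    group_morphotypes,
    impute_missing,
    log_transform,
    minimum_individuals,
    pca,
)
from ichnometry.records import PCA_VARIABLES
from ichnometry.utils import round_half_up


class TestFootIndex:
    @pytest.mark.parametrize(
        "fw, fl, expected", [(6, 13, 0.46), (7, 20.5, 0.34), (9.9, 9.9, 1.00)]
    )
    def test_printed_ratios(self, fw, fl, expected):
        assert round_half_up(foot_index(fw, fl)) == expected

    def test_scale100_option(self):
        assert foot_index(6, 13, scale100=True) == pytest.approx(100 * 6 / 13)

    @given(st.floats(1, 30), st.floats(1, 30), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_uniform_scaling(self, fw, fl, k):
        assert foot_index(k * fw, k * fl) == pytest.approx(foot_index(fw, fl))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            foot_index(0, 13)


class TestArchAngle:
    def test_right_angle_configuration(self):
        # border along +y, apex line at 45 degrees from the shared vertex
        ang = arch_angle([(0, 0), (0, 1)], (1, 1))
        assert ang == pytest.approx(45.0)

    def test_matches_dot_product_oracle_under_rigid_motion(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p0, p1, apex = rng.uniform(-5, 5, size=(3, 2))
            u, v = p1 - p0, apex - p0
            cross = abs(u[0] * v[1] - u[1] * v[0])
            if cross < 1e-3:  # skip near-collinear draws
                continue
            oracle = np.degrees(
                np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            )
            oracle = min(oracle, 180 - oracle)
            assert arch_angle([p0, p1], apex) == pytest.approx(oracle, abs=1e-9)
            # similarity transform: rotate by 30 degrees, scale by 2.5
            th = np.radians(30)
            R = 2.5 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            q0, q1, qa = (R @ p0, R @ p1, R @ apex)
            assert arch_angle([q0, q1], qa) == pytest.approx(
                arch_angle([p0, p1], apex), abs=1e-9
            )

    def test_collinear_and_duplicate_rejected(self):
        with pytest.raises(ValueError):
            arch_angle([(0, 0), (0, 1)], (0, 2))
        with pytest.raises(ValueError):
            arch_angle([(0, 0), (0, 0)], (1, 1))


class TestLogTransform:
    def test_unit_and_e_entries(self):
        M = pd.DataFrame({"a": [1.0, np.e]})
        out = log_transform(M)
        assert out["a"].tolist() == pytest.approx([0.0, 1.0])

    def test_mask_unchanged_on_fixture(self, table4):
        M = table4.measurement_matrix()
        out = log_transform(M)
        assert out.shape == (23, 9)
        pd.testing.assert_frame_equal(out.isna(), M.isna())

    def test_nonpositive_entry_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"a": [1.0, -2.0]}))


class TestIterativeImputation:
    def test_complete_matrix_returned_unchanged(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.uniform(1, 2, size=(8, 4)))
        out = impute_missing(M, k=2)
        pd.testing.assert_frame_equal(out, M)

    def test_rank1_deleted_cell_recovered(self):
        # rows are scalar multiples of one profile -> rank-1 completion is exact
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        scales = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        M = pd.DataFrame(np.outer(scales, profile))
        truth = M.iloc[2, 1]
        M.iloc[2, 1] = np.nan
        out = impute_missing(M, k=1, tol=1e-12, max_iter=500)
        assert out.iloc[2, 1] == pytest.approx(truth, abs=1e-6)

    def test_present_cells_never_altered(self, table4):
        L = log_transform(table4.measurement_matrix())
        out = impute_missing(L, k=3)
        mask = L.notna()
        assert np.array_equal(out.to_numpy()[mask], L.to_numpy()[mask])

    def test_fixture_imputations_within_column_range(self, table4):
        L = log_transform(table4.measurement_matrix())
        out = impute_missing(L, k=3)
        for col in L.columns:
            obs = L[col].dropna()
            lo = obs.min() - 3 * obs.std(ddof=1)
            hi = obs.max() + 3 * obs.std(ddof=1)
            filled = out.loc[L[col].isna(), col]
            assert ((filled >= lo) & (filled <= hi)).all()

    def test_deterministic(self, table4):
        L = log_transform(table4.measurement_matrix())
        a = impute_missing(L, k=3)
        b = impute_missing(L, k=3)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_rank_and_all_missing_column_rejected(self):
        M = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError, match="n_components"):
            impute_missing(M, k=3)
        M.iloc[:, 0] = np.nan
        with pytest.raises(ValueError, match="fewer than 2"):
            impute_missing(M, k=1)


class TestPCA:
    def test_two_mirror_points_give_single_axis(self):
        M = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [2.0, 3.0]])
        res = pca(M)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_matches_sklearn_oracle_up_to_sign(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            M = pd.DataFrame(rng.normal(size=(10, 4)))
            res = pca(M)
            sk = SKPCA().fit(M.to_numpy())
            for j in range(4):
                ours = res.loadings.iloc[:, j].to_numpy()
                ref = sk.components_[j]
                sign = np.sign(np.dot(ours, ref))
                assert np.allclose(ours, sign * ref, atol=1e-8)
                assert np.allclose(
                    res.scores.iloc[:, j], sign * sk.transform(M.to_numpy())[:, j],
                    atol=1e-8,
                )
            assert np.allclose(
                res.explained_variance, sk.explained_variance_ratio_, atol=1e-10
            )

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(11)
        M = pd.DataFrame(rng.normal(size=(12, 5)))
        res = pca(M)
        col_var = M.var(ddof=1).sum()
        assert res.explained_variance_abs.sum() == pytest.approx(
            col_var, rel=1e-10
        )

    def test_scores_centered_and_loadings_orthonormal(self, table4):
        L = impute_missing(log_transform(table4.measurement_matrix()), k=3)
        res = pca(L)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        Q = res.loadings.to_numpy()
        assert np.allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-10)

    def test_fixture_pc1_is_a_size_axis(self, table4):
        # positively correlated length measurements: PC1 loadings of one sign
        L = impute_missing(log_transform(table4.measurement_matrix()), k=3)
        res = pca(L)
        assert (res.loadings["PC1"] > 0).all()

    def test_missing_cells_rejected(self, table4):
        with pytest.raises(ValueError, match="missing"):
            pca(log_transform(table4.measurement_matrix()))


class TestGrouping:
    def test_fixture_yields_five_morphotypes(self, table4):
        a = group_morphotypes(table4)
        assert a.n_groups == 5
        assert minimum_individuals(a) == 5

    def test_fixture_size_class_extremes_isolated(self, table4):
        a = group_morphotypes(table4)
        small = {a.labels[i] for i in ("SM3", "SM4", "SM43", "SM17")}
        large = {a.labels[i] for i in ("C60", "C37", "C35b")}
        assert len(small) == 1 and len(large) == 1
        assert small != large

    def test_identical_rows_form_one_group(self):
        df = pd.DataFrame(
            {"footprint_id": [f"F{i}" for i in range(6)],
             **{c: [10.0] * 6 for c in PCA_VARIABLES}}
        )
        assert group_morphotypes(FootprintTable(df)).n_groups == 1

    def test_two_size_classes_zero_noise_give_two_groups(self):
        base = np.linspace(2, 20, len(PCA_VARIABLES))
        rows = [base] * 4 + [1.5 * base] * 4
        df = pd.DataFrame(rows, columns=PCA_VARIABLES)
        df.insert(0, "footprint_id", [f"F{i}" for i in range(8)])
        a = group_morphotypes(FootprintTable(df))
        assert a.n_groups == 2
        assert len({a.labels[f"F{i}"] for i in range(4)}) == 1

    def test_invariant_to_row_permutation_and_units(self, table4):
        a = group_morphotypes(table4)
        shuffled = FootprintTable(
            table4.data.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        assert group_morphotypes(shuffled).labels == a.labels
        mm = table4.data.copy()
        for c in PCA_VARIABLES:
            mm[c] = mm[c] * 10.0  # cm -> mm
        assert group_morphotypes(FootprintTable(mm)).labels == a.labels

    def test_group_spread_diagnostic_reported(self, table4):
        a = group_morphotypes(table4)
        assert set(a.spread) == set(range(1, 6))
        assert all(s >= 0 for s in a.spread.values())

    def test_empty_table_rejected(self):
        df = pd.DataFrame({"footprint_id": [], "max_FL": []})
        with pytest.raises(ValueError, match="empty"):
            group_morphotypes(FootprintTable(df))
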