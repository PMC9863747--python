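"""Quasi-Poisson fitting, BH adjustment, fold changes, and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from orthospec.countmerge import JointCountMatrix, JointRow
from orthospec.diffexpr import (
    bh_adjust,
    build_design,
    classify,
    filter_min_spectra,
    fit_all,
    log2_fold_changes,
    quasipoisson_fit,
)
from orthospec.synthdata import sample_ids


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min_{j>=rank(i)} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for out_rank, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(out_rank, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def _matrix_from_rows(rows_dict, n_rep=2):
    maize_samples, sorghum_samples, design = sample_ids(n_rep)
    rows = [
        JointRow(
            maize_accessions=(f"M{i}",),
            sorghum_accessions=(f"S{i}",),
            maize_counts=np.asarray(mc, dtype=np.int64),
            sorghum_counts=np.asarray(sc, dtype=np.int64),
            pairs=((f"M{i}", f"S{i}"),),
            sources=(f"maize:M{i}", f"sorghum:S{i}"),
        )
        for i, (mc, sc) in enumerate(rows_dict)
    ]
    return (
        JointCountMatrix(
            rows=rows, maize_samples=maize_samples, sorghum_samples=sorghum_samples
        ),
        design,
    )


class TestFilter:
    def test_boundary_inclusive_at_ten(self):
        matrix, _ = _matrix_from_rows(
            [([3, 3, 2, 2], [0, 0, 0, 0]),  # total 10 -> kept
             ([3, 3, 2, 1], [0, 0, 0, 0])]  # total 9 -> dropped
        )
        kept = filter_min_spectra(matrix, 10)
        assert len(kept) == 1
        assert kept.rows[0].total == 10

    def test_all_zero_matrix_empties(self):
        matrix, _ = _matrix_from_rows([([0] * 4, [0] * 4)] * 3)
        assert len(filter_min_spectra(matrix)) == 0

    def test_matches_brute_force_on_fixture(self, small_matrix):
        kept = filter_min_spectra(small_matrix, 10)
        expected = {
            r.key()
            for r in small_matrix.rows
            if r.maize_counts.sum() + r.sorghum_counts.sum() >= 10
        }
        assert {r.key() for r in kept.rows} == expected


class TestQuasiPoissonFit:
    def test_constant_response_intercept_only(self):
        fit = quasipoisson_fit(np.array([7, 7, 7, 7]), np.ones((4, 1)))
        assert fit.beta[0] == pytest.approx(np.log(7), abs=1e-10)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_two_group_closed_form(self):
        # saturated two-group Poisson MLE: betas are log group means
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=float)
        fit = quasipoisson_fit(np.array([2, 4, 6, 6]), X)
        assert fit.beta[0] == pytest.approx(np.log(3), abs=1e-8)
        assert fit.beta[1] == pytest.approx(np.log(2), abs=1e-8)

    def test_agrees_with_reference_glm(self):
        rng = np.random.default_rng(8)
        maize_samples, sorghum_samples, design = sample_ids(5)
        X, _ = build_design(design, maize_samples, sorghum_samples)
        for _ in range(20):
            mu = np.exp(X @ np.array([2.0, rng.normal(0, 0.5), rng.normal(0, 1)]))
            y = rng.negative_binomial(mu, 0.5)  # phi = 2
            fit = quasipoisson_fit(y.astype(float), X)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                scale="X2", use_t=True
            )
            np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6, atol=1e-8)
            np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-6, atol=1e-8)
            np.testing.assert_allclose(
                fit.pvalues, ref.pvalues, rtol=1e-5, atol=1e-10
            )
            assert fit.dispersion == pytest.approx(float(ref.scale), rel=1e-6)

    def test_dispersion_estimate_near_one_on_poisson_data(self):
        rng = np.random.default_rng(9)
        maize_samples, sorghum_samples, design = sample_ids(25)
        X, _ = build_design(design, maize_samples, sorghum_samples)
        phis = []
        for _ in range(200):
            y = rng.poisson(np.exp(X @ np.array([2.5, 0.3, -0.4])))
            phis.append(quasipoisson_fit(y.astype(float), X).dispersion)
        assert np.mean(phis) == pytest.approx(1.0, abs=0.05)

    def test_separation_flagged_not_patched(self):
        # one design cell entirely zero: no finite MLE for that contrast
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=float)
        fit = quasipoisson_fit(np.array([5, 7, 0, 0]), X)
        assert fit.separation

    def test_input_validation(self):
        with pytest.raises(ValueError):
            quasipoisson_fit(np.array([1.0, -2.0]), np.ones((2, 1)))
        with pytest.raises(ValueError):
            quasipoisson_fit(np.array([1.0, 2.0]), np.ones((3, 1)))


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.02], [0.02]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([-0.1]))

    def test_matches_brute_force_and_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_monotone_on_sorted_input(self, p):
        q = bh_adjust(np.sort(np.array(p)))
        assert (np.diff(q) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestFoldChangesAndClassify:
    def test_equal_means_give_zero(self):
        matrix, design = _matrix_from_rows([([4, 4, 4, 4], [2, 2, 2, 2])])
        m, s = log2_fold_changes(
            matrix.rows[0], design, matrix.maize_samples, matrix.sorghum_samples
        )
        assert m == 0.0 and s == 0.0

    def test_fourfold_increase_no_pseudocount(self):
        matrix, design = _matrix_from_rows([([4, 4, 16, 16], [1, 1, 1, 1])])
        m, _ = log2_fold_changes(
            matrix.rows[0],
            design,
            matrix.maize_samples,
            matrix.sorghum_samples,
            pseudocount=0.0,
        )
        assert m == pytest.approx(2.0)

    def test_all_zero_species_symmetric_with_pseudocount(self):
        matrix, design = _matrix_from_rows([([0, 0, 0, 0], [1, 1, 1, 1])])
        m, _ = log2_fold_changes(
            matrix.rows[0], design, matrix.maize_samples, matrix.sorghum_samples
        )
        assert m == 0.0

    def test_absent_species_undefined_not_zero(self):
        matrix, design = _matrix_from_rows([([1, 1, 2, 2], [0, 0, 0, 0])])
        row = matrix.rows[0]
        row.sorghum_accessions = ()
        _, s = log2_fold_changes(
            row, design, matrix.maize_samples, matrix.sorghum_samples
        )
        assert np.isnan(s)

    def test_classification_rule(self):
        fits = pd.DataFrame(
            {
                "p_species": [1e-6, 0.5, 1e-6],
                "p_treatment": [1e-6, 1e-6, 0.5],
            }
        )
        res = classify(fits, alpha=0.05)
        assert res.significant_both.tolist() == [True, False, False]
        assert res.significant_species.tolist() == [True, False, True]
        assert res.significant_treatment.tolist() == [True, True, False]

    def test_q_at_alpha_not_significant(self):
        # a single p of exactly 0.05 yields q = 0.05: strict inequality fails
        fits = pd.DataFrame({"p_species": [0.05], "p_treatment": [0.01]})
        res = classify(fits, alpha=0.05)
        assert res.q_species.iloc[0] == pytest.approx(0.05)
        assert not bool(res.significant_species.iloc[0])
        assert not bool(res.significant_both.iloc[0])

    def test_reported_qvalues_classify_like_published_row(self):
        # a species q-value of 1.87e-4 and treatment q of 4.4e-2 at alpha 0.05
        assert (0.000187049 < 0.05) and (0.044375583 < 0.05)
        fits = pd.DataFrame(
            {"p_species": [0.000187049], "p_treatment": [0.044375583]}
        )
        res = classify(fits)
        assert bool(res.significant_both.iloc[0])

    def test_fit_all_on_fixture(self, small_matrix, small_world):
        kept = filter_min_spectra(small_matrix)
        res = classify(fit_all(kept, small_world["design"]))
        assert len(res) == len(kept)
        valid_q = res.q_treatment.dropna()
        assert ((valid_q >= 0) & (valid_q <= 1)).all()
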