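from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosig.assoc import (
    COVARIATE_PRESETS,
    CandidateCriteria,
    CovariateSpec,
    SeparationError,
    bh_adjust,
    count_significant,
    linear_assoc,
    logistic_assoc,
    mann_whitney,
    run_battery,
    select_candidates,
    spearman,
)


def exact_mw_pvalue(a, b):
    """Enumeration oracle: two-sided p over all label assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    m_full = len(pooled)
    mean_u = n * (len(b)) / 2

    def u_stat(idx):
        aa = pooled[list(idx)]
        bb = pooled[[i for i in range(m_full) if i not in idx]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = u_stat(range(n))
    us = [u_stat(c) for c in combinations(range(m_full), n)]
    return sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us) / len(us)


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        U, diff, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0 and diff == -3.0
        assert p == pytest.approx(0.10)

    def test_identical_samples(self):
        _, diff, p = mann_whitney([1, 2], [1, 2])
        assert diff == 0.0 and p == pytest.approx(1.0)

    def test_singletons(self):
        _, _, p = mann_whitney([1], [2])
        assert p == pytest.approx(1.0)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 4), (4, 4), (5, 5), (3, 8)])
    def test_exact_branch_matches_enumeration(self, n, m, rng):
        for _ in range(5):
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            _, _, p = mann_whitney(a, b)
            assert p == pytest.approx(exact_mw_pvalue(a, b), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 90])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_worked_rank_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)  # 1 - 6*6/(3*8)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestLogisticAssoc:
    def test_closed_form_2x2(self):
        x = pd.Series([1.0] * 10 + [0.0] * 10)
        y = pd.Series([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        beta, p = logistic_assoc(x, y)
        assert beta == pytest.approx(np.log(16), abs=1e-8)
        assert 0 < p < 1

    def test_closed_form_random_tables(self, rng):
        """Single binary predictor slope equals the log odds ratio."""
        for _ in range(100):
            cells = rng.integers(2, 30, size=4)  # a,b,c,d all >= 2
            a, b, c, d = (int(v) for v in cells)
            x = pd.Series([1.0] * (a + b) + [0.0] * (c + d))
            y = pd.Series([1] * a + [0] * b + [1] * c + [0] * d)
            beta, _ = logistic_assoc(x, y)
            assert beta == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_null_feature_near_zero(self, rng):
        x = pd.Series(rng.normal(size=400))
        y = pd.Series(rng.integers(0, 2, size=400))
        beta, p = logistic_assoc(x, y)
        assert abs(beta) < 0.3

    def test_separation_flagged(self):
        x = pd.Series(np.arange(10, dtype=float))
        y = pd.Series([0] * 5 + [1] * 5)
        with pytest.raises(SeparationError):
            logistic_assoc(x, y)

    def test_covariate_adjustment_changes_estimate(self, rng):
        n = 300
        z = rng.normal(size=n)
        y = pd.Series((z + rng.normal(0, 1, n) > 0).astype(int))
        x = pd.Series(z + rng.normal(0, 0.5, n))  # proxy for z only
        b_unadj, _ = logistic_assoc(x, y)
        b_adj, p_adj = logistic_assoc(x, y, pd.DataFrame({"z": z}))
        assert abs(b_adj) < abs(b_unadj)


class TestLinearAssoc:
    def test_exact_slope(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        beta, p = linear_assoc(x, 2 * x)
        assert beta == pytest.approx(2.0)
        assert p < 1e-10

    def test_outcome_explained_by_covariate(self, rng):
        n = 200
        z = rng.normal(size=n)
        y = pd.Series(3 * z + rng.normal(0, 1e-8, n))
        x = pd.Series(rng.normal(size=n))
        beta, _ = linear_assoc(x, y, pd.DataFrame({"z": z}))
        assert abs(beta) < 1e-6

    def test_collinear_design_errors(self, rng):
        x = pd.Series(rng.normal(size=50))
        cov = pd.DataFrame({"c1": x, "c2": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            linear_assoc(x, pd.Series(rng.normal(size=50)), cov)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.05, 1.0]), [0.10, 1.0])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_and_dominates_p(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestBattery:
    def test_battery_on_synthetic_cohort(self, small_cohort):
        subjects, matrix, truth = small_cohort
        from endosig.endotype import dichotomize, pathology_score
        from endosig.quantify import log10_and_clean

        x = pathology_score(subjects["ttau"], subjects["abeta42"])
        groups = pd.Series(dichotomize(x), index=subjects.index)
        cont = pd.Series(x, index=subjects.index)
        cov = COVARIATE_PRESETS["discovery"].design(subjects)
        logged, _ = log10_and_clean(matrix)
        table = run_battery(logged, groups, cont, cov)
        assert len(table) == len(matrix)
        pcols = [c for c in table.columns if c.endswith("_p") or c.endswith("_q")]
        assert ((table[pcols] >= 0) & (table[pcols] <= 1)).all().all()
        assert table["n_sig"].between(0, 4).all()
        expected = sum((table[f"{t}_p"] < 0.05).astype(int)
                       for t in ("logistic", "mw", "linear", "spearman"))
        assert (table["n_sig"] == expected).all()

    def test_count_significant_worked_example(self):
        assert count_significant([0.040, 0.099, 0.075, 0.019]) == 2
        assert count_significant([0.2, 0.6, 0.9, 0.08]) == 0

    def test_small_group_errors(self, rng):
        mat = pd.DataFrame(rng.normal(size=(2, 6)), index=["f1", "f2"],
                           columns=list("abcdef"))
        groups = pd.Series(["low"] * 5 + ["high"], index=list("abcdef"))
        cont = pd.Series(rng.normal(size=6), index=list("abcdef"))
        with pytest.raises(ValueError, match="fewer than 2"):
            run_battery(mat, groups, cont)


class TestSelectCandidates:
    @pytest.fixture
    def assoc_table(self):
        return pd.DataFrame({
            "logistic_p": [0.04, 0.04, 0.20],
            "mw_p": [0.5, 0.5, 0.5],
            "linear_p": [0.5, 0.5, 0.5],
            "spearman_p": [0.5, 0.5, 0.5],
        }, index=["sig_multi", "sig_single_pep", "nonsig"])

    def test_three_criteria(self, assoc_table):
        peptides = pd.Series([3, 1, 5], index=assoc_table.index)
        native = pd.Series([True, True, True], index=assoc_table.index)
        assert select_candidates(assoc_table, peptides, native) == ["sig_multi"]

    def test_toggle_peptide_criterion(self, assoc_table):
        peptides = pd.Series([3, 1, 5], index=assoc_table.index)
        native = pd.Series([True, True, True], index=assoc_table.index)
        got = select_candidates(assoc_table, peptides, native,
                                CandidateCriteria(require_peptides=False))
        assert got == ["sig_multi", "sig_single_pep"]

    def test_missing_annotation_lists_features(self, assoc_table):
        peptides = pd.Series([3, 1], index=assoc_table.index[:2])
        native = pd.Series(True, index=assoc_table.index)
        with pytest.raises(KeyError, match="nonsig"):
            select_candidates(assoc_table, peptides, native)


def test_covariate_spec_categorical_expansion():
    subjects = pd.DataFrame({"age": [60.0, 70.0, 80.0],
                             "center": ["A", "B", "C"]})
    spec = CovariateSpec(("age", "center"), ("continuous", "categorical"))
    design = spec.design(subjects)
    assert list(design.columns) == ["age", "center_B", "center_C"]
    with pytest.raises(KeyError):
        CovariateSpec(("bmi",), ("continuous",)).design(subjects)
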