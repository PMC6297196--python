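"""Univariate association battery with covariate adjustment and FDR control.

Each feature (a protein or MW isoform, on the log10 scale for immunoassay
data) is tested four ways against the CSF-pathology endophenotype:

1. Mann-Whitney U (unadjusted) — dichotomized low vs high pathology groups;
2. logistic regression (covariate-adjusted) — the same dichotomy;
3. linear regression (covariate-adjusted) — the continuous pathology score;
4. Spearman rank correlation (unadjusted) — the continuous score.

The nonparametric tests are run unadjusted; covariates enter only the
regression models. Benjamini-Hochberg q-values are computed per test type
across features, and ``n_sig`` counts, per feature, how many of the four
tests reach nominal p < 0.05. Missing data are handled per-feature by
complete-case exclusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic model."""


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered covariates with kinds; categorical ones expand to indicators."""

    names: tuple[str, ...] = ()
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must align")
        bad = set(self.kinds) - {"continuous", "binary", "categorical"}
        if bad:
            raise ValueError(f"unknown covariate kinds: {sorted(bad)}")

    def design(self, subjects: pd.DataFrame) -> pd.DataFrame:
        """Numeric design-matrix columns (no intercept) from a subject table."""
        missing = [n for n in self.names if n not in subjects.columns]
        if missing:
            raise KeyError(f"covariates absent from subject table: {missing}")
        cols = []
        for name, kind in zip(self.names, self.kinds):
            col = subjects[name]
            if kind == "categorical":
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                cols.append(dummies)
            elif kind == "binary":
                vals = col
                if vals.dtype == object or str(vals.dtype) == "category":
                    levels = sorted(pd.unique(vals.dropna()))
                    if len(levels) > 2:
                        raise ValueError(f"binary covariate {name!r} has >2 levels")
                    vals = vals.map({lev: i for i, lev in enumerate(levels)})
                cols.append(vals.astype(float).rename(name))
            else:
                cols.append(col.astype(float).rename(name))
        if not cols:
            return pd.DataFrame(index=subjects.index)
        return pd.concat(cols, axis=1)


#: Cohort-specific covariate presets mirroring each analysis phase.
COVARIATE_PRESETS: dict[str, CovariateSpec] = {
    "discovery": CovariateSpec(
        ("age", "sex", "apoe_e4", "storage_years"),
        ("continuous", "binary", "binary", "continuous")),
    "replication": CovariateSpec(
        ("age", "sex", "apoe_e4", "batch", "storage_years"),
        ("continuous", "binary", "binary", "categorical", "continuous")),
    "ge067": CovariateSpec(
        ("age", "sex", "apoe_e4", "bmi", "diabetes", "center", "batch", "storage_years"),
        ("continuous", "binary", "binary", "continuous", "binary", "categorical",
         "categorical", "continuous")),
    "emif": CovariateSpec(
        ("age", "sex", "apoe_e4", "center", "batch"),
        ("continuous", "binary", "binary", "categorical", "categorical")),
}


def mann_whitney(a, b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test; returns (U, median difference, p).

    Exact enumeration when min(n, m) <= 8 and there are no ties across the
    pooled sample; otherwise the midrank normal approximation with tie and
    continuity corrections. The effect size is the difference of group
    medians, median(a) - median(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(np.median(a) - np.median(b)), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _complete_design(feature: pd.Series, outcome: pd.Series,
                     covariates: pd.DataFrame | None):
    df = pd.DataFrame({"feature": feature.astype(float)})
    if covariates is not None and covariates.shape[1] > 0:
        df = df.join(covariates.astype(float))
    df["__y"] = outcome
    df = df.dropna()
    y = df.pop("__y")
    X = sm.add_constant(df, has_constant="add")
    return X, y


def logistic_assoc(feature: pd.Series, outcome: pd.Series,
                   covariates: pd.DataFrame | None = None) -> tuple[float, float]:
    """ML logistic slope for the feature adjusting for covariates; Wald p.

    ``outcome`` is binary (0/1 or two labels). Complete-case only. Raises
    :class:`SeparationError` on complete or quasi-complete separation rather
    than returning a silently divergent estimate.
    """
    y = _binarize(outcome)
    X, y = _complete_design(feature, y, covariates)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present after exclusions")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("rank-deficient logistic design matrix")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # statsmodels >= 0.14 warns on separation instead of raising
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation detected: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge: {fit.mle_retvals}")
    beta = float(fit.params["feature"])
    se = float(fit.bse["feature"])
    if not np.isfinite(se) or se > 1e4 or abs(beta) > 1e3:
        raise SeparationError("quasi-complete separation: unbounded slope estimate")
    return beta, float(fit.pvalues["feature"])


def linear_assoc(feature: pd.Series, outcome: pd.Series,
                 covariates: pd.DataFrame | None = None) -> tuple[float, float]:
    """Least-squares slope of the outcome on the feature given covariates; t-test p."""
    X, y = _complete_design(feature, outcome.astype(float), covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("n must exceed the number of parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack()[lambda s: s > 0.999].index.tolist()
        raise ValueError(f"rank-deficient design; near-collinear columns: {pairs}")
    fit = sm.OLS(y, X).fit()
    return float(fit.params["feature"]), float(fit.pvalues["feature"])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _binarize(labels: pd.Series) -> pd.Series:
    """Map a two-level series to 0/1 ('high' is 1 when labels are low/high)."""
    s = pd.Series(labels)
    vals = pd.unique(s.dropna())
    if set(vals) <= {0, 1} or set(vals) <= {0.0, 1.0} or set(vals) <= {False, True}:
        return s.astype(float)
    if set(vals) == {"low", "high"}:
        return s.map({"low": 0.0, "high": 1.0})
    if len(vals) != 2:
        raise ValueError(f"expected a binary outcome, got levels {sorted(map(str, vals))}")
    lv = sorted(map(str, vals))
    return s.astype(str).map({lv[0]: 0.0, lv[1]: 1.0})


TESTS = ("logistic", "mw", "linear", "spearman")


def run_battery(features: pd.DataFrame, groups: pd.Series,
                continuous: pd.Series, covariates: pd.DataFrame | None = None,
                alpha: float = 0.05) -> pd.DataFrame:
    """Run the four-test battery on every feature; BH per test across features.

    ``features`` is features x samples; ``groups`` the dichotomized
    endophenotype; ``continuous`` the continuous endophenotype; ``covariates``
    a numeric design block aligned on samples (regressions only). Returns one
    row per feature with effect sizes, p-values, per-test q-values and
    ``n_sig`` (tests with p < ``alpha``).
    """
    groups = _binarize(groups.reindex(features.columns))
    continuous = continuous.reindex(features.columns).astype(float)
    if covariates is not None:
        covariates = covariates.reindex(features.columns)
    rows = []
    for feat, vals in features.iterrows():
        vals = vals.astype(float)
        mask = vals.notna() & groups.notna()
        g0 = vals[mask & (groups == 0)]
        g1 = vals[mask & (groups == 1)]
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError(f"feature {feat!r}: fewer than 2 samples in a group")
        U, med_diff, mw_p = mann_whitney(g1, g0)  # high minus low
        log_beta, log_p = logistic_assoc(vals, groups, covariates)
        lin_beta, lin_p = linear_assoc(vals, continuous, covariates)
        cmask = vals.notna() & continuous.notna()
        rho, sp_p = spearman(vals[cmask], continuous[cmask])
        rows.append({"feature": feat,
                     "logistic_beta": log_beta, "logistic_p": log_p,
                     "mw_U": U, "mw_median_diff": med_diff, "mw_p": mw_p,
                     "linear_beta": lin_beta, "linear_p": lin_p,
                     "spearman_rho": rho, "spearman_p": sp_p})
    table = pd.DataFrame(rows).set_index("feature")
    for test in TESTS:
        table[f"{test}_q"] = bh_adjust(table[f"{test}_p"].to_numpy())
    table["n_sig"] = sum((table[f"{t}_p"] < alpha).astype(int) for t in TESTS)
    return table


def count_significant(pvalues, alpha: float = 0.05) -> int:
    """How many of a feature's battery p-values fall below ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return int(np.sum(p < alpha))


@dataclass
class CandidateCriteria:
    """Replication-candidate criteria; each toggleable."""

    alpha: float = 0.05
    min_peptides: int = 2
    require_significance: bool = True
    require_peptides: bool = True
    require_native_mw: bool = True


def select_candidates(table: pd.DataFrame, peptide_counts: pd.Series,
                      native_mw: pd.Series,
                      criteria: CandidateCriteria | None = None) -> list:
    """Features passing the replication-candidate criteria.

    A candidate must (1) be nominally significant in >= 1 battery test,
    (2) be quantified by >= 2 peptides, and (3) have been detected in the
    molecular-weight range of the native protein. Each criterion can be
    toggled via ``criteria``.
    """
    criteria = criteria or CandidateCriteria()
    missing = [f for f in table.index
               if f not in peptide_counts.index or f not in native_mw.index]
    if missing:
        raise KeyError(f"features lacking annotations: {missing}")
    keep = pd.Series(True, index=table.index)
    if criteria.require_significance:
        pcols = [f"{t}_p" for t in TESTS if f"{t}_p" in table.columns]
        keep &= (table[pcols] < criteria.alpha).any(axis=1)
    if criteria.require_peptides:
        keep &= peptide_counts.reindex(table.index) >= criteria.min_peptides
    if criteria.require_native_mw:
        keep &= native_mw.reindex(table.index).astype(bool)
    return table.index[keep].tolist()
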