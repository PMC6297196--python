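"""CSF pathology endophenotype: scoring, stratification and cross-cohort harmonization.

The central quantity is the CSF pathology score

    x = (373 + 0.82 * tTau) / Abeta42

computed from total tau and amyloid-beta 1-42 concentrations in pg/mL. Higher
x means a more AD-like CSF profile (high tau, low Abeta42). Subjects can be
dichotomized on x, or extreme-stratified (the k lowest vs k highest scores),
which is the design the association battery consumes.

For multi-center cohorts, per-center clinical cutoffs assign categorical
amyloid/tau pathology (low Abeta42 = amyloid pathology; high tau = tau
pathology), and raw CSF values are harmonized across centers by within-cohort
z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Discrimination-line constants (pg/mL scale).
SCORE_INTERCEPT = 373.0
SCORE_TAU_SLOPE = 0.82


@dataclass(frozen=True)
class CohortCutoffs:
    """Per-cohort CSF cutoffs in pg/mL.

    Amyloid pathology is called when Abeta42 falls strictly below the Abeta42
    cutoff; tau pathology when tTau (pTau) rises strictly above its cutoff.
    """

    abeta42: float
    ttau: float
    ptau: float

    def __post_init__(self) -> None:
        if min(self.abeta42, self.ttau, self.ptau) <= 0:
            raise ValueError("CSF cutoffs must be positive (pg/mL)")


#: Published per-center cutoffs for the three validation centers.
EMIF_CUTOFFS: dict[str, CohortCutoffs] = {
    "Perugia": CohortCutoffs(abeta42=800.0, ttau=300.0, ptau=60.0),
    "Barcelona": CohortCutoffs(abeta42=550.0, ttau=350.0, ptau=61.0),
    "Milan": CohortCutoffs(abeta42=600.0, ttau=450.0, ptau=61.0),
}


def pathology_score(ttau, abeta42):
    """CSF pathology score x = (373 + 0.82*tTau) / Abeta42.

    Parameters are in pg/mL; accepts scalars or array-likes. Strictly
    increasing in tTau and strictly decreasing in Abeta42.
    """
    ttau = np.asarray(ttau, dtype=float)
    abeta42 = np.asarray(abeta42, dtype=float)
    if np.any(abeta42 <= 0):
        raise ValueError("abeta42 must be > 0 pg/mL")
    if np.any(ttau < 0):
        raise ValueError("ttau must be >= 0 pg/mL")
    x = (SCORE_INTERCEPT + SCORE_TAU_SLOPE * ttau) / abeta42
    return float(x) if x.ndim == 0 else x


def dichotomize(x, threshold: float = 1.0):
    """Assign 'high' iff x > threshold else 'low' (boundary goes to 'low').

    The default threshold 1.0 is the natural boundary of the discrimination
    line (a subject exactly on the line scores x = 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("pathology score must be > 0")
    out = np.where(x > threshold, "high", "low")
    return str(out[()]) if out.ndim == 0 else out


def select_extremes(scores: pd.Series, k: int) -> tuple[list, list]:
    """Pick the k lowest- and k highest-scoring subject ids.

    ``scores`` is indexed by subject id. Ties are broken by subject id order
    (lexical) for determinism; a warning is logged when ties straddle a group
    boundary.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = len(scores)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the number of subjects ({n})")
    if k == 0:
        return [], []
    frame = pd.DataFrame({"x": scores.astype(float)}).sort_index(kind="mergesort")
    frame = frame.sort_values("x", kind="mergesort")  # stable: id order within ties
    ordered = frame.index.to_list()
    low = ordered[:k]
    high = ordered[-k:]
    xs = frame["x"].to_numpy()
    if (k < n and xs[k - 1] == xs[k]) or (xs[n - k] == xs[n - k - 1]):
        logger.warning("tied pathology scores at an extreme-group boundary; "
                       "ties broken by subject id order")
    return low, high


def apply_cutoffs(profile: pd.DataFrame, cutoffs: dict[str, CohortCutoffs] | None = None
                  ) -> pd.DataFrame:
    """Per-measure pathology labels from cohort-specific CSF cutoffs.

    ``profile`` needs columns ``cohort``, ``abeta42``, ``ttau`` and optionally
    ``ptau``. Amyloid pathology is 'high' iff Abeta42 < cutoff (strict); tau
    and pTau pathology are 'high' iff the value > cutoff (strict); values
    exactly at a cutoff are labelled 'low'.
    """
    cutoffs = EMIF_CUTOFFS if cutoffs is None else cutoffs
    unknown = set(profile["cohort"]) - set(cutoffs)
    if unknown:
        raise KeyError(f"no cutoffs for cohort(s): {sorted(unknown)}")
    rows = {}
    for sid, row in profile.iterrows():
        c = cutoffs[row["cohort"]]
        labels = {"amyloid_pathology": "high" if row["abeta42"] < c.abeta42 else "low",
                  "ttau_pathology": "high" if row["ttau"] > c.ttau else "low"}
        if "ptau" in profile.columns and pd.notna(row.get("ptau")):
            labels["ptau_pathology"] = "high" if row["ptau"] > c.ptau else "low"
        rows[sid] = labels
    return pd.DataFrame.from_dict(rows, orient="index").reindex(profile.index)


def harmonize_zscores(values: pd.Series, cohorts: pd.Series) -> pd.Series:
    """Within-cohort z-scores combined into one cross-cohort variable.

    Each cohort's values are centered and scaled by that cohort's own mean and
    sample standard deviation (ddof=1), so the combined variable is comparable
    across centers regardless of assay scale.
    """
    values = values.astype(float)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for cohort, idx in values.groupby(cohorts).groups.items():
        v = values.loc[idx]
        if len(v) < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 subjects")
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cohort {cohort!r} has zero within-cohort spread")
        out.loc[idx] = (v - v.mean()) / sd
    return out


@dataclass
class EndotypeResult:
    """Per-subject pathology score, group and harmonized CSF measures."""

    table: pd.DataFrame
    low_ids: list = field(default_factory=list)
    high_ids: list = field(default_factory=list)


def endotype_subjects(subjects: pd.DataFrame, threshold: float = 1.0,
                      k_extreme: int | None = None,
                      cutoffs: dict[str, CohortCutoffs] | None = None) -> EndotypeResult:
    """Full endotyping pass over a subject table.

    Expects columns ``ttau`` and ``abeta42`` (pg/mL); uses ``cohort`` for
    per-center cutoffs and z-score harmonization when present. When
    ``k_extreme`` is given, subjects are additionally extreme-stratified and
    the ``group`` column marks only the selected extremes (others
    'unassigned'); otherwise every subject is dichotomized at ``threshold``.
    """
    x = pathology_score(subjects["ttau"], subjects["abeta42"])
    table = pd.DataFrame({"x": x}, index=subjects.index)
    low_ids: list = []
    high_ids: list = []
    if k_extreme is not None:
        low_ids, high_ids = select_extremes(table["x"], k_extreme)
        group = pd.Series("unassigned", index=subjects.index)
        group.loc[low_ids] = "low"
        group.loc[high_ids] = "high"
        table["group"] = group
    else:
        table["group"] = dichotomize(table["x"].to_numpy(), threshold)
    if "cohort" in subjects.columns:
        have = [c for c in ("abeta42", "ttau", "ptau") if c in subjects.columns]
        prof = subjects[["cohort"] + have]
        if cutoffs is not None or set(subjects["cohort"]) <= set(EMIF_CUTOFFS):
            table = table.join(apply_cutoffs(prof, cutoffs))
        for col in have:
            table[f"z_{col}"] = harmonize_zscores(subjects[col], subjects["cohort"])
    return EndotypeResult(table=table, low_ids=low_ids, high_ids=high_ids)
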