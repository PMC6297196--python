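"""From raw quantification to analysis-ready feature matrices.

Two acquisition routes are supported:

* **Isobaric (TMT) peptide data** — each 6-plex run carries five study
  samples plus a pooled reference channel. Peptide intensities are expressed
  as log2 ratios to the reference, median-ratio normalized per channel,
  rolled up to molecular-weight isoform level (median or mean over peptides),
  and filtered on the fraction of plexes in which an isoform was detected.

* **Immunoassay (ELISA) data** — absorbances are converted to concentrations
  through a 5-parameter logistic (5PL) standard curve

      y = d + (a - d) / (1 + (x / c)^b)^g

  with ``a`` the zero-concentration asymptote, ``d`` the infinite-
  concentration asymptote, ``c`` the midpoint concentration, ``b`` the slope
  and ``g`` the asymmetry. Intra-/inter-assay %CV summarize technical
  precision; concentrations are log10-transformed and extreme outliers
  (beyond ``k`` inter-quartile ranges from the quartiles) are set to missing.

Missing values propagate as missing throughout; there is no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

PEPTIDE_COLUMNS = ["plex", "channel", "protein", "isoform", "peptide", "intensity"]


@dataclass
class PeptideQuantSet:
    """Peptide-level TMT intensities with a designated reference channel.

    ``records`` has columns plex, channel, protein, isoform, peptide,
    intensity (> 0), and optionally ``sample`` mapping plex x channel to a
    subject id. Absent rows are missing observations.
    """

    records: pd.DataFrame
    ref_channel: str

    def __post_init__(self) -> None:
        missing = [c for c in PEPTIDE_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"peptide records lack columns: {missing}")
        if (self.records["intensity"] <= 0).any():
            raise ValueError("peptide intensities must be > 0")
        for plex, grp in self.records.groupby("plex"):
            if self.ref_channel not in set(grp["channel"]):
                raise ValueError(f"plex {plex!r} lacks reference channel {self.ref_channel!r}")

    def sample_ids(self) -> pd.Series:
        """Sample id per record: the ``sample`` column or '<plex>:<channel>'."""
        if "sample" in self.records.columns:
            return self.records["sample"]
        return self.records["plex"].astype(str) + ":" + self.records["channel"].astype(str)

    def log2_ratios(self) -> pd.DataFrame:
        """Study-channel records augmented with log2 ratio to the plex reference."""
        rec = self.records
        key = ["plex", "protein", "isoform", "peptide"]
        ref = (rec[rec["channel"] == self.ref_channel]
               .set_index(key)["intensity"].rename("ref_intensity"))
        if ref.index.has_duplicates:
            ref = ref.groupby(level=list(range(len(key)))).mean()
        study = rec[rec["channel"] != self.ref_channel].join(ref, on=key)
        study = study.dropna(subset=["ref_intensity"])
        study = study.assign(log2_ratio=np.log2(study["intensity"] / study["ref_intensity"]))
        return study


def median_ratio_normalize(pq: PeptideQuantSet) -> PeptideQuantSet:
    """Shift each plex x channel so the median peptide log2 ratio is zero.

    Implemented as a per-channel intensity rescaling (by 2**-median), so the
    result is again a valid :class:`PeptideQuantSet` and the operation is
    idempotent. Reference-channel intensities are untouched.
    """
    study = pq.log2_ratios()
    med = study.groupby(["plex", "channel"])["log2_ratio"].median()
    rec = pq.records.copy()
    factors = pd.MultiIndex.from_frame(rec[["plex", "channel"]]).map(med)
    factors = pd.Series(np.asarray(factors, dtype=float), index=rec.index).fillna(0.0)
    rec["intensity"] = rec["intensity"] * np.power(2.0, -factors)
    return PeptideQuantSet(records=rec, ref_channel=pq.ref_channel)


@dataclass
class IsoformMatrix:
    """MW-isoform x sample log2 ratios with per-isoform plex detection fractions."""

    values: pd.DataFrame
    detection_fraction: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate isoform row ids")
        frac = self.detection_fraction
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("detection fractions must lie in [0, 1]")


def isoform_row_id(protein, isoform) -> str:
    return f"{protein}|{isoform}"


def rollup_isoforms(pq: PeptideQuantSet, method: str = "median") -> IsoformMatrix:
    """Roll peptide log2 ratios up to one value per MW isoform per sample.

    ``method`` is ``"median"`` or ``"mean"`` over the isoform's peptides
    within a sample. Detection fraction is the share of plexes in which the
    isoform was observed by at least one peptide.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown roll-up method {method!r}; use 'median' or 'mean'")
    study = pq.log2_ratios()
    study = study.assign(
        row=[isoform_row_id(p, i) for p, i in zip(study["protein"], study["isoform"])],
        sample=pq.sample_ids().loc[study.index],
    )
    grouped = study.groupby(["row", "sample"])["log2_ratio"]
    agg = grouped.median() if method == "median" else grouped.mean()
    values = agg.unstack("sample")
    n_plexes = pq.records["plex"].nunique()
    detect = (study.groupby("row")["plex"].nunique() / n_plexes).reindex(values.index)
    return IsoformMatrix(values=values, detection_fraction=detect)


def filter_detection(m: IsoformMatrix, min_fraction: float = 0.8) -> IsoformMatrix:
    """Keep isoforms detected in at least ``min_fraction`` of plexes (inclusive)."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    keep = m.detection_fraction >= min_fraction
    return IsoformMatrix(values=m.values.loc[keep],
                         detection_fraction=m.detection_fraction.loc[keep])


# ---------------------------------------------------------------------------
# 5-parameter logistic standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FivePLCurve:
    """5PL parameters: y = d + (a - d) / (1 + (x / c)^b)^g."""

    a: float
    d: float
    c: float
    b: float
    g: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("midpoint concentration c must be > 0")
        if self.g <= 0:
            raise ValueError("asymmetry g must be > 0")
        if self.b == 0:
            raise ValueError("slope b must be nonzero")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        y = self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b) ** self.g
        return float(y) if y.ndim == 0 else y


def _5pl(x, a, d, c, b, g):
    return d + (a - d) / (1.0 + (x / c) ** b) ** g


def fit_5pl(standards) -> FivePLCurve:
    """Least-squares 5PL fit to (concentration, absorbance) standards.

    Needs at least 6 standards with positive concentrations spanning the
    curve. Raises on constant absorbances or failure to converge.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, absorbance) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(x) < 6:
        raise ValueError("need at least 6 standards for a 5PL fit")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be > 0")
    if np.ptp(y) == 0:
        raise ValueError("degenerate standards: constant absorbance")
    # Canonical parameterization: b > 0, so y -> a as x -> 0 and y -> d as
    # x -> infinity; curve direction is carried by the a/d ordering. (b < 0
    # swaps the asymptote roles and makes the fit non-identifiable.)
    a0 = float(y[np.argmin(x)])
    d0 = float(y[np.argmax(x)])
    c0 = float(np.exp(np.mean(np.log(x))))
    p0 = (a0, d0, c0, 1.0, 1.0)
    lo = (-np.inf, -np.inf, 1e-12, 1e-6, 1e-6)
    hi = (np.inf, np.inf, np.inf, np.inf, np.inf)
    try:
        popt, _ = optimize.curve_fit(_5pl, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:  # no convergence
        raise RuntimeError(f"5PL fit did not converge (initial iterate {p0})") from exc
    resid = y - _5pl(x, *popt)
    rsd = float(np.sqrt(np.mean(resid ** 2)))
    a, d, c, b, g = popt
    return FivePLCurve(a=float(a), d=float(d), c=float(c), b=float(b), g=float(g),
                       residual_sd=rsd)


def invert_5pl(curve: FivePLCurve, absorbance: float) -> float:
    """Closed-form inverse of the 5PL: the unique x with forward(x) = y.

    The absorbance must lie strictly between the two asymptotes; values at or
    beyond an asymptote are reported as out of range, never clamped.
    """
    y = float(absorbance)
    lo, hi = sorted((curve.a, curve.d))
    if not lo < y < hi:
        raise ValueError(f"absorbance {y} outside the open asymptote interval ({lo}, {hi})")
    ratio = (curve.a - curve.d) / (y - curve.d)
    return float(curve.c * (ratio ** (1.0 / curve.g) - 1.0) ** (1.0 / curve.b))


# ---------------------------------------------------------------------------
# Assay precision and cleaning
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Intra-/inter-assay percentage coefficients of variation."""

    intra_cv: float
    inter_cv: float
    per_sample_cv: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def compute_cv(duplicates: pd.DataFrame, control: pd.Series | None = None) -> CvReport:
    """%CV from duplicate wells (intra) and a cross-plate control (inter).

    ``duplicates``: one row per sample, columns are replicate measurements.
    Intra-assay CV is the mean over samples of 100*sd/mean of each sample's
    replicates (sample sd, ddof=1). ``control`` holds the control sample's
    value on each plate; inter-assay CV is 100*sd/mean across plates.
    """
    if duplicates.shape[1] < 2:
        raise ValueError("need >= 2 replicate columns for intra-assay CV")
    means = duplicates.mean(axis=1)
    if (means == 0).any():
        raise ValueError("zero duplicate mean; CV undefined")
    per_sample = 100.0 * duplicates.std(axis=1, ddof=1) / means
    intra = float(per_sample.mean())
    inter = float("nan")
    if control is not None:
        if len(control) < 2:
            raise ValueError("control sample must be measured on >= 2 plates")
        if control.mean() == 0:
            raise ValueError("zero control mean; CV undefined")
        inter = float(100.0 * control.std(ddof=1) / control.mean())
    return CvReport(intra_cv=intra, inter_cv=inter, per_sample_cv=per_sample)


def log10_and_clean(matrix: pd.DataFrame, iqr_multiplier: float = 3.0,
                    scale: str = "log10") -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10-transform a concentration matrix and blank extreme outliers.

    ``matrix`` is features x samples, strictly positive where present. Per
    feature, values outside [Q1 - k*IQR, Q3 + k*IQR] are set to missing
    (quartiles by linear interpolation). ``scale`` picks whether fences are
    computed on the transformed values (``"log10"``, default — the scale the
    downstream statistics use) or on the raw concentrations (``"raw"``).
    Returns the cleaned log10 matrix plus a removal log with columns
    feature, sample, value (the raw value removed).
    """
    if scale not in ("log10", "raw"):
        raise ValueError(f"unknown cleaning scale {scale!r}")
    if iqr_multiplier < 0:
        raise ValueError("iqr_multiplier must be >= 0")
    vals = matrix.astype(float)
    if (vals <= 0).any().any():
        bad = vals.where(vals <= 0).stack()
        raise ValueError(f"non-positive values cannot be log10-transformed: "
                         f"{bad.index.tolist()[:5]}")
    logged = np.log10(vals)
    basis = logged if scale == "log10" else vals
    removals = []
    cleaned = logged.copy()
    for feat, row in basis.iterrows():
        obs = row.dropna()
        if obs.empty or np.isinf(iqr_multiplier):
            continue
        q1, q3 = np.percentile(obs, [25, 75])
        lo = q1 - iqr_multiplier * (q3 - q1)
        hi = q3 + iqr_multiplier * (q3 - q1)
        out = obs[(obs < lo) | (obs > hi)]
        for sample in out.index:
            removals.append({"feature": feat, "sample": sample,
                             "value": float(vals.at[feat, sample])})
            cleaned.at[feat, sample] = np.nan
    log = pd.DataFrame(removals, columns=["feature", "sample", "value"])
    if len(log):
        logger.info("outlier cleaning removed %d value(s)", len(log))
    return cleaned, log
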