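"""Confound correction, reference z-scoring, clinical grouping, selection.

Biomarkers are corrected for age, sex and education trends estimated in the
reference (healthy-control) population only: one ordinary-least-squares model
per biomarker, fitted on reference subjects, applied to everyone.  Residuals
are centred on the reference residual mean and divided by the reference
residual SD, so corrected reference values have mean 0 and SD 1 by
construction.  Biomarkers with no reference values (lesion loads) cannot be
anchored this way and fall back to a robust patient-only standardisation
(median / scaled MAD), flagged ``anchored=False`` so the mixture stage
treats them accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import COGNITIVE_DOMAINS, EDSS_COL, GROUP_COL, HC, ID_COL, PATIENT

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates the SD of a normal


@dataclass
class ZScoredTable:
    """Corrected z-scores plus the per-biomarker fit records that produced them."""

    frame: pd.DataFrame  # id/group/covariates + z-scored biomarker columns
    fit_records: pd.DataFrame  # per biomarker: intercept, betas, residual mean/SD, anchored
    biomarkers: tuple[str, ...]

    def zscores(self) -> pd.DataFrame:
        return self.frame.set_index(ID_COL)[list(self.biomarkers)]

    def anchored(self, biomarker: str) -> bool:
        return bool(self.fit_records.loc[biomarker, "anchored"])


class ConfoundZScorer(TransformerMixin, BaseEstimator):
    """Reference-population confound regression and z-scoring.

    Parameters
    ----------
    covariates : tuple of str
        Covariate columns entering each linear model (sex coded 0/1,
        education numeric 1-7).
    reference_group : str
        Group label whose rows define the normal anchor.
    biomarkers : tuple of str or None
        Columns to correct; default: every known biomarker column present.

    Fitted attributes
    -----------------
    fit_records_ : DataFrame indexed by biomarker with the OLS coefficients,
        reference residual mean/SD and the ``anchored`` flag.
    """

    def __init__(self, covariates=("age", "sex", "education"),
                 reference_group: str = HC, biomarkers=None):
        self.covariates = covariates
        self.reference_group = reference_group
        self.biomarkers = biomarkers

    def _columns(self, frame: pd.DataFrame) -> list[str]:
        if self.biomarkers is not None:
            return list(self.biomarkers)
        from . import schema
        return [c for c in frame.columns if c in schema.BIOMARKERS]

    def fit(self, X: pd.DataFrame, y=None):
        frame = X
        ref = frame[frame[GROUP_COL] == self.reference_group]
        if len(ref) == 0:
            raise ValueError(f"reference group {self.reference_group!r} is empty")
        for cov in self.covariates:
            if cov not in frame.columns:
                raise ValueError(f"covariate column missing: {cov}")
            if ref[cov].nunique(dropna=True) < 2:
                raise ValueError(
                    f"singular design: covariate {cov!r} is constant in the reference group")

        records = {}
        for b in self._columns(frame):
            ref_vals = ref[b].dropna()
            if len(ref_vals) == 0:
                # lesion-class path: no reference anchor available
                warnings.warn(
                    f"biomarker {b!r} has no values in the reference group; "
                    "standardising on patients (median/MAD), unanchored")
                pat = frame.loc[frame[GROUP_COL] != self.reference_group, b].dropna()
                if len(pat) == 0:
                    warnings.warn(f"biomarker {b!r} has no values in any group; skipped")
                    continue
                med = float(pat.median())
                mad = float(np.median(np.abs(pat - med))) * MAD_SCALE
                if mad == 0:
                    mad = float(pat.std(ddof=1)) or 1.0
                records[b] = {"intercept": med,
                              **{f"beta_{c}": 0.0 for c in self.covariates},
                              "resid_mean": 0.0, "resid_sd": mad, "anchored": False}
                continue
            sub = ref[[b, *self.covariates]].dropna()
            design = np.column_stack([np.ones(len(sub)),
                                      sub[list(self.covariates)].to_numpy(float)])
            coef, *_ = np.linalg.lstsq(design, sub[b].to_numpy(float), rcond=None)
            resid = sub[b].to_numpy(float) - design @ coef
            resid_sd = float(np.std(resid, ddof=1))
            if resid_sd == 0:
                raise ValueError(f"biomarker {b!r} has zero residual variance in reference")
            records[b] = {"intercept": float(coef[0]),
                          **{f"beta_{c}": float(v) for c, v in zip(self.covariates, coef[1:])},
                          "resid_mean": float(resid.mean()), "resid_sd": resid_sd,
                          "anchored": True}
        self.fit_records_ = pd.DataFrame.from_dict(records, orient="index")
        self.fit_records_.index.name = "biomarker"
        self.biomarkers_ = tuple(records)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for b in self.biomarkers_:
            rec = self.fit_records_.loc[b]
            if rec["anchored"]:
                pred = rec["intercept"] + sum(
                    rec[f"beta_{c}"] * X[c].to_numpy(float) for c in self.covariates)
                resid = X[b].to_numpy(float) - pred
                out[b] = (resid - rec["resid_mean"]) / rec["resid_sd"]
            else:
                out[b] = (X[b].to_numpy(float) - rec["intercept"]) / rec["resid_sd"]
        return out


def regress_confounds(cohort: pd.DataFrame, covariates=("age", "sex", "education"),
                      reference: str = HC, biomarkers=None) -> ZScoredTable:
    """Fit-and-apply reference confound correction; returns the z-scored table."""
    scorer = ConfoundZScorer(covariates=covariates, reference_group=reference,
                             biomarkers=biomarkers)
    frame = scorer.fit(cohort).transform(cohort)
    return ZScoredTable(frame=frame, fit_records=scorer.fit_records_,
                        biomarkers=scorer.biomarkers_)


# ---------------------------------------------------------------- clinical groups

DISABILITY_BANDS = ("minimal", "moderate", "severe")
COGNITION_CLASSES = ("CP", "MCI", "CI")


def classify_disability(edss: float) -> str:
    """EDSS band: minimal (0.0-2.5), moderate (3.0-3.5), severe (>= 4.0)."""
    e = float(edss)
    if not (0.0 <= e <= 10.0) or abs(e * 2 - round(e * 2)) > 1e-9:
        raise ValueError(f"EDSS must be in [0, 10] in half-point steps, got {edss}")
    if e <= 2.5:
        return "minimal"
    if e <= 3.5:
        return "moderate"
    return "severe"


def classify_cognition(domain_z) -> str:
    """Cognitive class from 7 domain z-scores.

    CI when z <= -2 on at least 2 domains; otherwise MCI when z <= -1.5 on
    at least 2 domains; otherwise CP (cognitively preserved).
    """
    z = np.asarray(domain_z, dtype=float)
    if z.shape != (7,):
        raise ValueError(f"expected exactly 7 cognitive-domain z-scores, got shape {z.shape}")
    if np.isnan(z).any():
        raise ValueError("missing cognitive-domain z-score")
    if (z <= -2.0).sum() >= 2:
        return "CI"
    if (z <= -1.5).sum() >= 2:
        return "MCI"
    return "CP"


def assign_groups(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-patient disability band and cognitive class.

    Expects corrected cognitive-domain z-scores in the table.  Returns a
    frame indexed by subject id with ``disability`` and ``cognition``
    columns (controls are excluded: the bands partition patients).
    """
    patients = frame[frame[GROUP_COL] == PATIENT]
    out = pd.DataFrame(index=pd.Index(patients[ID_COL], name=ID_COL))
    out["disability"] = [classify_disability(e) for e in patients[EDSS_COL]]
    out["cognition"] = [
        classify_cognition(row) for row in patients[list(COGNITIVE_DOMAINS)].to_numpy(float)
    ]
    return out


# ---------------------------------------------------------------- post-selection

def select_biomarkers(z: ZScoredTable | pd.DataFrame, group_a: pd.Index, group_b: pd.Index,
                      alpha: float = 0.1, biomarkers=None) -> pd.DataFrame:
    """Two-sided Welch t-test screen between two named subject groups.

    Returns a per-biomarker report with the p-value and a ``retained`` flag
    (p <= alpha).  Biomarkers unavailable or constant in a group are
    excluded with a warning rather than crashing the screen.
    """
    if isinstance(z, ZScoredTable):
        zmat = z.zscores()
        biomarkers = biomarkers or list(z.biomarkers)
    else:
        zmat = z
        biomarkers = biomarkers or list(z.columns)
    rows = []
    for b in biomarkers:
        a_vals = zmat.loc[zmat.index.intersection(group_a), b].dropna()
        b_vals = zmat.loc[zmat.index.intersection(group_b), b].dropna()
        if len(a_vals) < 2 or len(b_vals) < 2:
            warnings.warn(f"biomarker {b!r}: fewer than 2 values in a group; excluded")
            rows.append({"biomarker": b, "p_value": np.nan, "retained": False,
                         "reason": "insufficient data"})
            continue
        if a_vals.std(ddof=1) == 0 and b_vals.std(ddof=1) == 0:
            warnings.warn(f"biomarker {b!r}: zero variance in both groups; excluded")
            rows.append({"biomarker": b, "p_value": np.nan, "retained": False,
                         "reason": "zero variance"})
            continue
        p = float(stats.ttest_ind(a_vals, b_vals, equal_var=False).pvalue)
        rows.append({"biomarker": b, "p_value": p, "retained": bool(p <= alpha),
                     "reason": ""})
    return pd.DataFrame(rows).set_index("biomarker")


def normality_report(z: ZScoredTable, group: str = PATIENT) -> pd.DataFrame:
    """Kolmogorov-Smirnov normality diagnostic per biomarker (reported only;
    nothing downstream is gated on it)."""
    frame = z.frame[z.frame[GROUP_COL] == group]
    rows = []
    for b in z.biomarkers:
        vals = frame[b].dropna().to_numpy(float)
        if len(vals) < 3:
            rows.append({"biomarker": b, "ks_stat": np.nan, "ks_p": np.nan})
            continue
        stat, p = stats.kstest(vals, "norm", args=(vals.mean(), vals.std(ddof=1)))
        rows.append({"biomarker": b, "ks_stat": float(stat), "ks_p": float(p)})
    return pd.DataFrame(rows).set_index("biomarker")
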