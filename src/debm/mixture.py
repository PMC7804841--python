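"""Two-component normal/abnormal Gaussian mixtures per biomarker.

Each selected biomarker is modelled, in z-score units, as a mixture of a
*normal* and an *abnormal* Gaussian component.  The normal component is
anchored on the reference population: it is initialised at the reference
mean/SD and its mean is constrained to stay within half a reference SD of
the reference mean during expectation-maximisation, so that "normal" keeps
its meaning while patients are free to populate both components.  Biomarkers
with no reference values (lesion loads) are fitted unanchored, with the
normal component initialised from the least-abnormal quartile of patient
values.

The mixing fraction reported is the abnormality prevalence *in the disease
group* (the mean abnormal responsibility over disease subjects); reference
subjects inform the component shapes but not the prevalence.  The posterior
probability that an event has occurred for a subject with observation x is

    P(abnormal | x) = pi * phi_abn(x) / (pi * phi_abn(x) + (1 - pi) * phi_norm(x)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .preprocess import ZScoredTable

SD_FLOOR = 1e-3  # z-units
EM_TOL = 1e-6  # relative log-likelihood change
EM_MAX_ITER = 500
ANCHOR_HALF_WIDTH = 0.5  # normal mean stays within this many reference SDs

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _norm_logpdf(x, mu, sd):
    # inline Gaussian log-density: the EM loop calls this thousands of times
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


@dataclass
class BiomarkerMixture:
    """Converged two-component mixture for one biomarker."""

    normal_mean: float
    normal_sd: float
    abnormal_mean: float
    abnormal_sd: float
    mixing_fraction: float  # P(abnormal) in the disease group
    direction: str  # "decreasing" or "increasing"
    anchored: bool
    log_likelihood: float = float("nan")
    converged: bool = True
    separable: bool = True

    def __post_init__(self):
        if self.normal_sd <= 0 or self.abnormal_sd <= 0:
            raise ValueError("component SDs must be strictly positive")
        if not (0.0 <= self.mixing_fraction <= 1.0):
            raise ValueError("mixing_fraction must be in [0, 1]")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError(f"invalid direction {self.direction!r}")
        delta = self.abnormal_mean - self.normal_mean
        if self.separable and (
                (self.direction == "decreasing" and delta > 0)
                or (self.direction == "increasing" and delta < 0)):
            raise ValueError("abnormal mean lies on the wrong side of normal mean "
                             f"for direction {self.direction!r}")

    def posterior_abnormal(self, value):
        """P(event occurred | value); total function on the reals."""
        x = np.asarray(value, dtype=float)
        la = norm.logpdf(x, self.abnormal_mean, self.abnormal_sd)
        ln = norm.logpdf(x, self.normal_mean, self.normal_sd)
        pi = np.clip(self.mixing_fraction, 1e-12, 1 - 1e-12)
        # overflow-safe logistic of the log-odds
        log_odds = np.log(pi) - np.log1p(-pi) + la - ln
        out = expit(log_odds)
        return float(out) if np.isscalar(value) else out

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "normal_mean", "normal_sd", "abnormal_mean", "abnormal_sd",
            "mixing_fraction", "direction", "anchored", "log_likelihood",
            "converged", "separable")}


def infer_direction(z: ZScoredTable, event: str, disease_group: pd.Index,
                    reference_group: pd.Index, override: str | None = None) -> str:
    """Abnormality direction: increasing if the disease mean exceeds the
    reference mean, else decreasing.  An explicit override wins; exactly
    equal means (or an empty reference) demand one."""
    if override is not None:
        if override not in ("decreasing", "increasing"):
            raise ValueError(f"invalid direction override {override!r}")
        return override
    zmat = z.zscores() if isinstance(z, ZScoredTable) else z
    d = zmat.loc[zmat.index.intersection(disease_group), event].dropna()
    r = zmat.loc[zmat.index.intersection(reference_group), event].dropna()
    if len(d) == 0:
        raise ValueError(f"no disease values for {event!r}")
    if len(r) == 0:
        raise ValueError(
            f"{event!r} has no reference values; an explicit direction override is required")
    if d.mean() == r.mean():
        raise ValueError(
            f"{event!r}: disease and reference means exactly equal; override required")
    return "increasing" if d.mean() > r.mean() else "decreasing"


class AbnormalityMixture(BaseEstimator):
    """Constrained EM for one biomarker's normal/abnormal mixture.

    Parameters
    ----------
    direction : {"decreasing", "increasing"}
        Which side of the normal component is abnormal.
    sd_floor, tol, max_iter : EM numerics (z-units / relative log-likelihood).

    ``fit(x, y)`` takes observation values ``x`` and labels ``y`` with 1 for
    disease and 0 for reference subjects; the reference part may be empty,
    in which case the fit is unanchored.
    """

    def __init__(self, direction: str = "decreasing", sd_floor: float = SD_FLOOR,
                 tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
                 reference_prior: float = 0.01):
        self.direction = direction
        self.sd_floor = sd_floor
        self.tol = tol
        self.max_iter = max_iter
        self.reference_prior = reference_prior

    # -- helpers ---------------------------------------------------------
    def _abnormal_side(self, x: np.ndarray, q: float) -> np.ndarray:
        """The fraction q of x lying furthest in the abnormal direction."""
        k = max(1, int(np.ceil(q * len(x))))
        xs = np.sort(x)
        return xs[-k:] if self.direction == "increasing" else xs[:k]

    def _normal_side(self, x: np.ndarray, q: float) -> np.ndarray:
        k = max(2, int(np.ceil(q * len(x))))
        xs = np.sort(x)
        return xs[:k] if self.direction == "increasing" else xs[-k:]

    def _two_means_split(self, x: np.ndarray) -> tuple | None:
        """Deterministic 1-d 2-means initialisation candidate."""
        lo, hi = np.percentile(x, [10, 90])
        if lo == hi:
            return None
        c = np.array([lo, hi], dtype=float)
        for _ in range(50):
            assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
            if assign.all() or not assign.any():
                return None
            new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
            if np.allclose(new, c):
                break
            c = new
        low, high = x[assign == 0], x[assign == 1]
        if self.direction == "decreasing":
            normal, abnormal = high, low
        else:
            normal, abnormal = low, high
        if len(normal) < 2 or len(abnormal) < 2:
            return None
        return (float(normal.mean()), float(normal.std(ddof=1)),
                float(abnormal.mean()), float(abnormal.std(ddof=1)),
                float(len(abnormal) / len(x)))

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y).ravel()
        disease = x[y == 1]
        reference = x[y == 0]
        disease = disease[~np.isnan(disease)]
        reference = reference[~np.isnan(reference)]
        if len(disease) < 10:
            raise ValueError(f"need at least 10 disease values, got {len(disease)}")
        anchored = len(reference) > 0

        if anchored:
            ref_mu, ref_sd = float(reference.mean()), float(reference.std(ddof=1))
        else:
            low_q = self._normal_side(disease, 0.25)
            ref_mu, ref_sd = float(low_q.mean()), float(low_q.std(ddof=1))
        abn = self._abnormal_side(disease, 0.10)
        s1_init = max(float(abn.std(ddof=1)) if len(abn) > 1 else ref_sd, ref_sd * 0.5)
        inits = [(ref_mu, max(ref_sd, self.sd_floor), float(abn.mean()),
                  max(s1_init, self.sd_floor), 0.5)]
        split = self._two_means_split(disease)
        if split is not None:
            mu0s, s0s, mu1s, s1s, pis = split
            if anchored:
                mu0s, s0s = ref_mu, ref_sd  # anchor still owns the normal part
            inits.append((mu0s, max(s0s, self.sd_floor), mu1s,
                          max(s1s, self.sd_floor), min(max(pis, 0.05), 0.95)))

        pooled = np.concatenate([disease, reference])
        is_disease = np.concatenate([np.ones(len(disease), bool),
                                     np.zeros(len(reference), bool)])

        best = None
        for init in inits:
            run = self._em(pooled, is_disease, init, anchored, ref_mu, ref_sd)
            if best is None or run["ll"] > best["ll"]:
                best = run
        mu0, s0 = best["mu0"], best["s0"]
        mu1, s1 = best["mu1"], best["s1"]
        pi = best["pi"]
        converged, floored, ll = best["converged"], best["floored"], best["ll"]
        if not converged:
            warnings.warn("mixture EM did not converge; returning best iterate")
        if floored:
            warnings.warn("mixture component SD hit the floor; clamped")

        # separability: the two-component fit must beat a single Gaussian by
        # more than its BIC penalty (3 extra parameters), else the data carry
        # no second mode and the abnormal component is collapsed onto the
        # normal one so that posteriors reduce to the prior
        single_mu, single_sd = float(pooled.mean()), float(pooled.std(ddof=0))
        ll1 = float(_norm_logpdf(pooled, single_mu, max(single_sd, self.sd_floor)).sum())
        separable = bool(ll - ll1 > 1.5 * np.log(len(pooled)))
        if not separable:
            warnings.warn("mixture components are not separable; posteriors ~ prior")
            mu1, s1 = mu0, s0

        self.normal_mean_, self.normal_sd_ = mu0, s0
        self.abnormal_mean_, self.abnormal_sd_ = mu1, s1
        self.mixing_fraction_ = pi
        self.anchored_ = anchored
        self.log_likelihood_ = ll
        self.converged_ = converged
        self.separable_ = separable
        return self

    def _em(self, pooled, is_disease, init, anchored, ref_mu, ref_sd) -> dict:
        mu0, s0, mu1, s1, pi = init
        prev_ll = -np.inf
        converged = False
        floored = False
        ll = -np.inf
        for _ in range(self.max_iter):
            # per-point abnormality prior: fitted prevalence for disease
            # subjects, a small fixed prior for reference subjects (they are
            # the normal anchor but may contain the odd outlier)
            prior = np.where(is_disease, pi, self.reference_prior)
            l1 = np.log(prior + 1e-300) + _norm_logpdf(pooled, mu1, s1)
            l0 = np.log(1 - prior + 1e-300) + _norm_logpdf(pooled, mu0, s0)
            m = np.maximum(l0, l1)
            denom = m + np.log(np.exp(l0 - m) + np.exp(l1 - m))
            r1 = np.exp(l1 - denom)
            ll = float(denom.sum())

            w1 = r1.sum()
            w0 = (1 - r1).sum()
            if w1 > 1e-12:
                mu1 = float((r1 * pooled).sum() / w1)
                s1 = float(np.sqrt((r1 * (pooled - mu1) ** 2).sum() / w1))
            if w0 > 1e-12:
                mu0 = float(((1 - r1) * pooled).sum() / w0)
                s0 = float(np.sqrt(((1 - r1) * (pooled - mu0) ** 2).sum() / w0))
            pi = float(np.clip(r1[is_disease].mean(), 1e-6, 1 - 1e-6))

            if not anchored:
                # without a reference anchor the two free SDs let one
                # component swallow the other; model the two states as a
                # mean shift with common scatter instead
                s_common = float(np.sqrt(
                    ((1 - r1) * (pooled - mu0) ** 2 + r1 * (pooled - mu1) ** 2).sum()
                    / len(pooled)))
                s0 = s1 = s_common
            if anchored:
                lo, hi = ref_mu - ANCHOR_HALF_WIDTH * ref_sd, ref_mu + ANCHOR_HALF_WIDTH * ref_sd
                mu0 = float(np.clip(mu0, lo, hi))
                # the normal spread must stay commensurate with the reference
                # spread, else the abnormal component absorbs the reference
                s0 = float(np.clip(s0, 0.5 * ref_sd, 1.5 * ref_sd))
            # both components describe scatter of the same measurement: a
            # component much wider than its counterpart is modelling the
            # mixture, not a state
            s1 = float(np.clip(s1, 0.5 * s0, 1.5 * s0))
            if self.direction == "decreasing" and mu1 > mu0:
                mu1 = mu0
            elif self.direction == "increasing" and mu1 < mu0:
                mu1 = mu0
            if s0 < self.sd_floor or s1 < self.sd_floor:
                floored = True
            s0 = max(s0, self.sd_floor)
            s1 = max(s1, self.sd_floor)

            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= self.tol * (abs(prev_ll) + 1e-12):
                converged = True
                break
            prev_ll = ll
        return {"mu0": mu0, "s0": s0, "mu1": mu1, "s1": s1, "pi": pi,
                "ll": ll, "converged": converged, "floored": floored}

    def mixture_(self) -> BiomarkerMixture:
        return BiomarkerMixture(
            normal_mean=self.normal_mean_, normal_sd=self.normal_sd_,
            abnormal_mean=self.abnormal_mean_, abnormal_sd=self.abnormal_sd_,
            mixing_fraction=self.mixing_fraction_, direction=self.direction,
            anchored=self.anchored_, log_likelihood=self.log_likelihood_,
            converged=self.converged_, separable=self.separable_)

    def predict_proba(self, x):
        """(n, 2) array of [P(normal | x), P(abnormal | x)]."""
        p_abn = self.mixture_().posterior_abnormal(np.asarray(x, float).ravel())
        return np.column_stack([1 - p_abn, p_abn])


def fit_mixture(values_disease, values_reference=None, direction: str = "decreasing",
                **em_kwargs) -> BiomarkerMixture:
    """Fit one biomarker's mixture from disease and (optional) reference values."""
    d = np.asarray(values_disease, dtype=float)
    r = np.asarray([] if values_reference is None else values_reference, dtype=float)
    x = np.concatenate([d, r])
    y = np.concatenate([np.ones(len(d)), np.zeros(len(r))])
    est = AbnormalityMixture(direction=direction, **em_kwargs).fit(x, y)
    return est.mixture_()


def posterior_abnormal(mix: BiomarkerMixture, value):
    return mix.posterior_abnormal(value)


def fit_all_mixtures(z: ZScoredTable, events, disease_group: pd.Index,
                     reference_group: pd.Index,
                     directions: dict[str, str] | None = None) -> dict[str, BiomarkerMixture]:
    """Fit a mixture per event.  Events absent in the reference are fitted
    unanchored; their direction must come from ``directions`` or the
    biomarker-class default (increasing for lesion loads)."""
    from . import schema
    zmat = z.zscores()
    directions = directions or {}
    mixtures = {}
    for e in events:
        ref_vals = zmat.loc[zmat.index.intersection(reference_group), e].dropna()
        if e in directions:
            direction = directions[e]
        elif len(ref_vals) == 0:
            direction = schema.default_direction(e) if e in schema.BIOMARKERS else "increasing"
        else:
            direction = infer_direction(z, e, disease_group, reference_group)
        dis_vals = zmat.loc[zmat.index.intersection(disease_group), e].dropna()
        mixtures[e] = fit_mixture(dis_vals, ref_vals if len(ref_vals) else None, direction)
    return mixtures


def build_posterior_matrix(z: ZScoredTable, mixtures: dict[str, BiomarkerMixture],
                           subjects: pd.Index) -> pd.DataFrame:
    """Subjects x events matrix of P(event occurred | observation).

    Subjects held out of mixture initialisation (e.g. intermediate-EDSS or
    MCI patients) are deliberately includable here: staging and ordering see
    every subject passed in.  A missing biomarker value for an included
    subject is an error.
    """
    zmat = z.zscores() if isinstance(z, ZScoredTable) else z
    events = list(mixtures)
    missing_subj = [s for s in subjects if s not in zmat.index]
    if missing_subj:
        raise ValueError(f"subjects not in table: {missing_subj[:5]}")
    sub = zmat.loc[subjects, events]
    if sub.isna().any().any():
        bad = [(s, e) for s, e in zip(*np.where(sub.isna().to_numpy()))]
        pairs = [(sub.index[i], events[j]) for i, j in bad[:10]]
        raise ValueError(f"missing biomarker values for included subjects: {pairs}")
    P = pd.DataFrame(index=sub.index, columns=events, dtype=float)
    for e in events:
        P[e] = mixtures[e].posterior_abnormal(sub[e].to_numpy())
    return P
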