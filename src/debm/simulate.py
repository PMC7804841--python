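"""Synthetic cross-sectional cohorts with a known event cascade.

The generator emulates a case/control biomarker study in which patients sit
at a latent discrete stage along a fixed ordering of biomarker "events".  A
biomarker is drawn from its *abnormal* Gaussian component when the subject's
stage has reached the event's position in the ordering, and from its
*normal* component otherwise.  Controls sit at stage 0 (the reference
population is the normal anchor; no control abnormality is modelled).
Linear age/sex/education effects are added to every biomarker so that the
confound-regression step downstream has something real to remove, and
lesion-type biomarkers are blanked for controls, mirroring cohorts in which
lesion segmentations exist only for patients.

Because every subject's generating components are returned alongside the
table, each downstream stage (z-scoring, mixture fitting, ordering,
staging) has an exact parameter-recovery target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import COGNITIVE_DOMAINS, EDSS_COL, GROUP_COL, HC, ID_COL, PATIENT


class SimConfigError(ValueError):
    """Invalid simulator configuration; the message names the offending field."""


# 12 canonical biomarkers with mixed classes: decreasing volumes/FA,
# increasing centralities, and two patient-only lesion bands.
DEFAULT_EVENTS = (
    "fa_cst",
    "vol_cerebellar_gm",
    "vol_thalamus",
    "ec_dmn",
    "vol_occipital",
    "lesion_inner",
    "vol_parietal",
    "mucca",
    "lesion_deep",
    "ec_basal_ganglia",
    "fa_cingulum",
    "vol_insula",
)


@dataclass
class SimConfig:
    """Generative settings for one synthetic cohort.

    Defaults encode the reference simulation used throughout: 12 events,
    300 patients with stages uniform on {0..12}, 100 controls, and a
    2.5-SD shift between the normal and abnormal component of every
    biomarker (in observation units, both SDs equal to 1).
    """

    n_patients: int = 300
    n_controls: int = 100
    event_labels: tuple[str, ...] = DEFAULT_EVENTS
    true_ordering: tuple[str, ...] = DEFAULT_EVENTS  # position 1 = earliest
    stage_distribution: np.ndarray | None = None  # categorical over 0..N, default uniform
    normal_mean: np.ndarray | None = None  # per event, default 0
    normal_sd: np.ndarray | None = None  # default 1
    abnormal_mean: np.ndarray | None = None  # default normal_mean +/- separation
    abnormal_sd: np.ndarray | None = None  # default 1
    separation: float = 2.5  # |abnormal - normal| in SD units when abnormal_mean is None
    direction: tuple[str, ...] | None = None  # default per biomarker class
    confound_betas: dict[str, np.ndarray] | None = None  # age/sex/education, per event
    age_range: tuple[float, float] = (25.0, 65.0)
    sex_p_female: float = 0.65
    education_range: tuple[int, int] = (1, 7)
    missing_in_controls: tuple[str, ...] | None = None  # default: lesion-class events
    seed: int = 0

    @property
    def n_events(self) -> int:
        return len(self.event_labels)

    def resolved(self) -> "SimConfig":
        """Return a copy with every defaulted field filled in and validated."""
        n = self.n_events
        if n == 0:
            raise SimConfigError("event_labels: empty")
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise SimConfigError("n_patients/n_controls: groups must be non-empty")
        if sorted(self.true_ordering) != sorted(self.event_labels):
            raise SimConfigError("true_ordering: not a permutation of event_labels")

        stage_p = self.stage_distribution
        if stage_p is None:
            stage_p = np.full(n + 1, 1.0 / (n + 1))
        stage_p = np.asarray(stage_p, dtype=float)
        if stage_p.shape != (n + 1,) or not np.isclose(stage_p.sum(), 1.0):
            raise SimConfigError("stage_distribution: must be length n_events+1 and sum to 1")

        direction = self.direction
        if direction is None:
            direction = tuple(schema.default_direction(e) for e in self.event_labels)
        if len(direction) != n or set(direction) - {"decreasing", "increasing"}:
            raise SimConfigError("direction: one of decreasing/increasing per event")

        mu0 = np.zeros(n) if self.normal_mean is None else np.asarray(self.normal_mean, float)
        sd0 = np.ones(n) if self.normal_sd is None else np.asarray(self.normal_sd, float)
        sd1 = np.ones(n) if self.abnormal_sd is None else np.asarray(self.abnormal_sd, float)
        if self.abnormal_mean is None:
            sign = np.where(np.asarray(direction) == "increasing", 1.0, -1.0)
            mu1 = mu0 + sign * self.separation * sd0
        else:
            mu1 = np.asarray(self.abnormal_mean, float)
        for name, arr in (("normal_mean", mu0), ("normal_sd", sd0),
                          ("abnormal_mean", mu1), ("abnormal_sd", sd1)):
            if arr.shape != (n,):
                raise SimConfigError(f"{name}: expected {n} values")
        if (sd0 <= 0).any() or (sd1 <= 0).any():
            raise SimConfigError("normal_sd/abnormal_sd: SDs must be strictly positive")
        for i, d in enumerate(direction):
            if d == "increasing" and mu1[i] < mu0[i]:
                raise SimConfigError(
                    f"abnormal_mean: event {self.event_labels[i]} declared increasing "
                    "but abnormal mean is below normal mean")
            if d == "decreasing" and mu1[i] > mu0[i]:
                raise SimConfigError(
                    f"abnormal_mean: event {self.event_labels[i]} declared decreasing "
                    "but abnormal mean is above normal mean")

        betas = self.confound_betas
        if betas is None:
            betas = {
                "age": np.full(n, -0.02),
                "sex": np.full(n, 0.20),
                "education": np.full(n, 0.05),
            }
        for cov in ("age", "sex", "education"):
            if cov not in betas or np.asarray(betas[cov], float).shape != (n,):
                raise SimConfigError(f"confound_betas: need {n} values for {cov}")

        missing = self.missing_in_controls
        if missing is None:
            missing = tuple(e for e in self.event_labels if schema.is_lesion_class(e))
        if set(missing) - set(self.event_labels):
            raise SimConfigError("missing_in_controls: not a subset of event_labels")

        return SimConfig(
            n_patients=self.n_patients, n_controls=self.n_controls,
            event_labels=tuple(self.event_labels), true_ordering=tuple(self.true_ordering),
            stage_distribution=stage_p, normal_mean=mu0, normal_sd=sd0,
            abnormal_mean=mu1, abnormal_sd=sd1, separation=self.separation,
            direction=tuple(direction),
            confound_betas={k: np.asarray(v, float) for k, v in betas.items()},
            age_range=self.age_range, sex_p_female=self.sex_p_female,
            education_range=self.education_range, missing_in_controls=tuple(missing),
            seed=self.seed,
        )


@dataclass
class GroundTruth:
    """What the generator actually did: the latent order, stages and components."""

    true_ordering: tuple[str, ...]
    true_stage: pd.Series  # indexed by subject_id, integers 0..N
    component_params: pd.DataFrame  # per event: normal/abnormal mean and SD, direction

    def event_position(self, event: str) -> int:
        """1-based position of an event in the true ordering."""
        return self.true_ordering.index(event) + 1

    def abnormal_mask(self, subjects: pd.Index | None = None) -> pd.DataFrame:
        """Boolean subjects x events frame: True where the generating component
        was the abnormal one (stage >= event position)."""
        stages = self.true_stage if subjects is None else self.true_stage.loc[subjects]
        pos = np.array([self.event_position(e) for e in self.component_params.index])
        return pd.DataFrame(
            stages.to_numpy()[:, None] >= pos[None, :],
            index=stages.index, columns=self.component_params.index,
        )

    def to_json(self, path) -> None:
        payload = {
            "true_ordering": list(self.true_ordering),
            "true_stage": {str(k): int(v) for k, v in self.true_stage.items()},
            "component_params": self.component_params.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort table (standard schema) plus its ground truth.

    Clinical columns (EDSS, cognitive domains) are emitted as missing;
    :func:`derive_clinical_labels` fills them from the latent stage.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_events
    n_total = cfg.n_patients + cfg.n_controls

    ids = [f"P{i:04d}" for i in range(cfg.n_patients)] + [f"C{i:04d}" for i in range(cfg.n_controls)]
    groups = [PATIENT] * cfg.n_patients + [HC] * cfg.n_controls

    age = rng.uniform(*cfg.age_range, size=n_total)
    sex = rng.binomial(1, cfg.sex_p_female, size=n_total)  # 1 = female
    education = rng.integers(cfg.education_range[0], cfg.education_range[1] + 1, size=n_total)

    stages = np.zeros(n_total, dtype=int)  # controls stay at 0 exactly
    stages[: cfg.n_patients] = rng.choice(n + 1, size=cfg.n_patients, p=cfg.stage_distribution)

    positions = np.array([cfg.true_ordering.index(e) + 1 for e in cfg.event_labels])
    abnormal = stages[:, None] >= positions[None, :]  # (n_total, n_events)

    means = np.where(abnormal, cfg.abnormal_mean, cfg.normal_mean)
    sds = np.where(abnormal, cfg.abnormal_sd, cfg.normal_sd)
    values = rng.normal(means, sds)
    values = (values
              + np.outer(age, np.ones(n)) * cfg.confound_betas["age"]
              + np.outer(sex, np.ones(n)) * cfg.confound_betas["sex"]
              + np.outer(education, np.ones(n)) * cfg.confound_betas["education"])

    frame = pd.DataFrame({ID_COL: ids, GROUP_COL: groups,
                          "age": age, "sex": sex, "education": education,
                          EDSS_COL: np.nan})
    for d in COGNITIVE_DOMAINS:
        frame[d] = np.nan
    for j, e in enumerate(cfg.event_labels):
        frame[e] = values[:, j]
    is_hc = frame[GROUP_COL] == HC
    for e in cfg.missing_in_controls:
        frame.loc[is_hc, e] = np.nan  # explicit missing marker, never zero

    params = pd.DataFrame({
        "normal_mean": cfg.normal_mean, "normal_sd": cfg.normal_sd,
        "abnormal_mean": cfg.abnormal_mean, "abnormal_sd": cfg.abnormal_sd,
        "direction": list(cfg.direction),
    }, index=pd.Index(cfg.event_labels, name="event"))
    truth = GroundTruth(
        true_ordering=tuple(cfg.true_ordering),
        true_stage=pd.Series(stages, index=pd.Index(ids, name=ID_COL), name="true_stage"),
        component_params=params,
    )
    return frame, truth


@dataclass
class LabelRule:
    """Stage -> clinical-score mapping used to paint EDSS and cognition onto
    a simulated cohort.  EDSS rises linearly with stage (then rounds to the
    half-point grid); cognitive-domain z-scores fall linearly with stage."""

    edss_intercept: float = 1.0
    edss_slope_per_stage: float = 0.6  # EDSS points per latent stage
    edss_noise_sd: float = 0.75
    cog_intercept: float = 0.0
    cog_slope_per_stage: float = -0.25  # z per latent stage
    cog_noise_sd: float = 1.0
    seed: int = 0

    def validate(self, n_events: int) -> None:
        lo = self.edss_intercept
        hi = self.edss_intercept + self.edss_slope_per_stage * n_events
        if not (0 <= lo <= 10 and 0 <= hi <= 10):
            raise SimConfigError(
                f"LabelRule: stage-0..{n_events} mean EDSS spans [{lo}, {hi}], outside [0, 10]")


def derive_clinical_labels(cohort: pd.DataFrame, truth: GroundTruth,
                           rule: LabelRule | None = None) -> pd.DataFrame:
    """Fill EDSS (patients) and cognitive-domain columns from the true stage.

    Higher latent stage stochastically yields higher EDSS and lower
    cognitive z-scores; controls receive the stage-0 cognitive distribution
    and no EDSS (it is a patient-only score).
    """
    rule = rule or LabelRule()
    n_events = len(truth.true_ordering)
    rule.validate(n_events)
    rng = np.random.default_rng(rule.seed)

    out = cohort.copy()
    stage = truth.true_stage.loc[out[ID_COL]].to_numpy()
    is_patient = (out[GROUP_COL] == PATIENT).to_numpy()

    edss_raw = (rule.edss_intercept + rule.edss_slope_per_stage * stage
                + rng.normal(0, rule.edss_noise_sd, size=len(out)))
    edss = np.clip(np.round(edss_raw * 2) / 2, 0.0, 10.0)
    out[EDSS_COL] = np.where(is_patient, edss, np.nan)

    for d in COGNITIVE_DOMAINS:
        z = (rule.cog_intercept + rule.cog_slope_per_stage * stage
             + rng.normal(0, rule.cog_noise_sd, size=len(out)))
        out[d] = z
    return out
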