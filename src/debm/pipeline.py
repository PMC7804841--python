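"""Model recipes and the end-to-end run.

Three standard recipes mirror the study designs this toolkit is built for:

* ``model1`` — disease progression relative to healthy controls: mixtures
  anchored on HC, ordering estimated from all patients, everyone staged.
* ``model2`` — progression from low (EDSS 0.0-2.5) to high (EDSS >= 4.0)
  disability: controls excluded; intermediate patients (EDSS 3.0-3.5) are
  held out of mixture initialisation but included in ordering and staging.
* ``model3`` — progression from cognitively preserved to cognitively
  impaired: controls excluded; MCI patients held out of initialisation but
  included downstream.  Cognitive-domain scores are excluded from the
  candidate list by default because they define the CP/CI split itself.

Confound correction is always anchored on the healthy controls when they
are present, whichever recipe runs afterwards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .ebm import estimate_ordering, stage_subjects, stage_summary
from .mixture import build_posterior_matrix, fit_all_mixtures, infer_direction
from .preprocess import assign_groups, regress_confounds, select_biomarkers
from .pvd import bootstrap_pvd, render_pvd
from .schema import (
    COGNITIVE_DOMAINS, EDSS_COL, GROUP_COL, HC, ID_COL, PATIENT,
    CohortSchema, CohortValidationError, read_cohort, validate_cohort_frame,
)

RECIPE_NAMES = ("model1", "model2", "model3")


@dataclass
class ModelRecipe:
    """Which subjects initialise the mixtures, which are held out, and the
    selection / bootstrap settings."""

    name: str = "model1"
    alpha: float = 0.1  # selection threshold, two-sided t-test
    n_bootstraps: int = 1000
    seed: int = 0
    candidates: tuple[str, ...] | None = None  # None = recipe default
    force_include: tuple[str, ...] = ()  # bypass selection (e.g. lesions vs HC)
    exclude: tuple[str, ...] = ()  # pre-selection exclusions

    def roles(self, frame: pd.DataFrame, groups: pd.DataFrame) -> dict[str, pd.Index]:
        """Reference / disease / held-out subject ids for this recipe.

        ``groups`` is the per-patient disability/cognition table from
        :func:`debm.preprocess.assign_groups`.
        """
        ids = frame.set_index(ID_COL)
        patients = ids.index[ids[GROUP_COL] == PATIENT]
        hc = ids.index[ids[GROUP_COL] == HC]
        if self.name == "model1":
            if len(hc) == 0:
                raise ValueError("model1 requires healthy controls")
            return {"reference": hc, "disease": patients, "held_out": pd.Index([])}
        if self.name == "model2":
            band = groups["disability"]
            return {"reference": band.index[band == "minimal"],
                    "disease": band.index[band == "severe"],
                    "held_out": band.index[band == "moderate"]}
        if self.name == "model3":
            cog = groups["cognition"]
            return {"reference": cog.index[cog == "CP"],
                    "disease": cog.index[cog == "CI"],
                    "held_out": cog.index[cog == "MCI"]}
        raise ValueError(f"unknown recipe {self.name!r}; use one of {RECIPE_NAMES} "
                         "or construct roles yourself")

    def candidate_biomarkers(self, frame: pd.DataFrame) -> list[str]:
        if self.candidates is not None:
            cands = list(self.candidates)
        else:
            cands = [c for c in frame.columns if c in schema.BIOMARKERS]
            if self.name == "model3":
                cands = [c for c in cands if c not in COGNITIVE_DOMAINS]
        return [c for c in cands if c not in self.exclude]


def validate_cohort(cohort, cohort_schema: CohortSchema | None = None) -> dict:
    """Structured validation report plus group counts and descriptives.

    Never a partial pass: ``errors`` is the complete violation list.
    Side-effect free and idempotent.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else read_cohort(cohort, validate=False)
    errors = validate_cohort_frame(frame, cohort_schema)
    report: dict = {"valid": not errors, "errors": errors, "n_subjects": int(len(frame))}
    if GROUP_COL in frame.columns and "sex" in frame.columns:
        counts, female = {}, {}
        for g, sub in frame.groupby(GROUP_COL):
            counts[g] = int(len(sub))
            n_f = int((sub["sex"] == 1).sum())
            female[g] = {"n_female": n_f,
                         "percent_female": round(100.0 * n_f / len(sub), 1)}
        report["group_counts"] = counts
        report["sex"] = female
    return report


# ------------------------------------------------------------- group summaries

def _chi2_2x2(a: pd.Series, b: pd.Series) -> tuple[float, bool]:
    """Uncorrected chi-square p for a binary variable across two groups.
    Returns (p, small_expected_flag)."""
    table = np.array([[int((a == 1).sum()), int((a == 0).sum())],
                      [int((b == 1).sum()), int((b == 0).sum())]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), True  # degenerate margin: test inapplicable, flagged
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue), bool((res.expected_freq < 5).any())


def summarize_groups(frame: pd.DataFrame, group_col: str = GROUP_COL,
                     groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Two-group descriptive table in the style of a cohort Table 1.

    Continuous variables: mean (SD), Welch t-test.  Ordinal (education,
    EDSS): median (Q1 - Q3), Mann-Whitney U.  Binary (sex): n (%),
    chi-square without continuity correction, flagged when an expected
    cell is below 5.
    """
    labels = groups or tuple(pd.unique(frame[group_col]))[:2]
    if len(labels) != 2:
        raise ValueError("summarize_groups compares exactly two groups")
    a = frame[frame[group_col] == labels[0]]
    b = frame[frame[group_col] == labels[1]]

    ordinal = {"education", EDSS_COL}
    binary = {"sex"}
    numeric = [c for c in frame.columns
               if c == "age" or c in schema.BIOMARKERS or c in ordinal | binary]

    rows = []
    for col in numeric:
        va, vb = a[col].dropna(), b[col].dropna()
        flag = ""
        if col in binary:
            na, nb = int((va == 1).sum()), int((vb == 1).sum())
            stat_a = f"{na} ({100 * na / len(va):.1f})" if len(va) else "NA"
            stat_b = f"{nb} ({100 * nb / len(vb):.1f})" if len(vb) else "NA"
            if len(va) and len(vb):
                p, small = _chi2_2x2(va, vb)
                flag = "expected cell < 5" if small else ""
                test = "chi-square"
            else:
                p, test = np.nan, "chi-square"
        elif col in ordinal:
            def miqr(v):
                if not len(v):
                    return "NA"
                q1, q2, q3 = v.quantile([0.25, 0.5, 0.75])
                return f"{q2:g} ({q1:g} - {q3:g})"
            stat_a, stat_b = miqr(va), miqr(vb)
            if len(va) and len(vb):
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            else:
                p = np.nan
            test = "mann-whitney"
        else:
            stat_a = f"{va.mean():.2f} ({va.std(ddof=1):.2f})" if len(va) > 1 else "NA"
            stat_b = f"{vb.mean():.2f} ({vb.std(ddof=1):.2f})" if len(vb) > 1 else "NA"
            if len(va) > 1 and len(vb) > 1:
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            else:
                p = np.nan
            test = "welch-t"
        rows.append({"variable": col, f"{labels[0]} (n={len(a)})": stat_a,
                     f"{labels[1]} (n={len(b)})": stat_b, "test": test,
                     "p_value": p, "flag": flag})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- run_model

@dataclass
class RunResult:
    """Everything one model run produced, in memory."""

    recipe: ModelRecipe
    selection: pd.DataFrame
    events: list[str]
    mixtures: dict
    ordering: object
    posterior: pd.DataFrame
    pvd: object
    stages: pd.Series
    summaries: pd.DataFrame
    groups: pd.DataFrame
    zscored: object = field(repr=False, default=None)


def run_model(cohort, recipe: ModelRecipe, out_dir=None, render: bool = True) -> RunResult:
    """Execute preprocess -> select -> mixtures -> ordering -> bootstrap -> staging."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else read_cohort(cohort, validate=False)
    errors = validate_cohort_frame(frame)
    if errors:
        raise CohortValidationError(errors)

    reference_for_z = HC if (frame[GROUP_COL] == HC).any() else PATIENT
    z = regress_confounds(frame, reference=reference_for_z)
    if recipe.name in ("model2", "model3"):
        groups = assign_groups(z.frame)  # needs complete EDSS / cognition
    else:
        groups = pd.DataFrame(columns=["disability", "cognition"])
    roles = recipe.roles(frame, groups)

    candidates = recipe.candidate_biomarkers(frame)
    selection = select_biomarkers(z, roles["reference"], roles["disease"],
                                  alpha=recipe.alpha, biomarkers=candidates)
    events = [b for b in selection.index[selection["retained"]]]
    for b in recipe.force_include:
        if b not in events:
            events.append(b)
            warnings.warn(f"biomarker {b!r} force-included past selection")
    if not events:
        raise RuntimeError("no biomarkers survived post-selection; aborting run")

    zmat = z.zscores()
    directions = {}
    for e in events:
        ref_has = zmat.loc[zmat.index.intersection(roles["reference"]), e].notna().any()
        if not ref_has:
            d = schema.default_direction(e) if e in schema.BIOMARKERS else "increasing"
            warnings.warn(f"{e!r} unavailable in reference; unanchored mixture, "
                          f"direction defaulted to {d}")
            directions[e] = d
        else:
            directions[e] = infer_direction(z, e, roles["disease"], roles["reference"])

    mixtures = fit_all_mixtures(z, events, roles["disease"], roles["reference"], directions)
    ordering_subjects = roles["disease"].append(roles["held_out"])
    P = build_posterior_matrix(z, mixtures, ordering_subjects)
    ordering = estimate_ordering(P)

    # staging covers every subject with complete values on the selected events,
    # including controls when the events allow it (model1)
    complete = zmat[events].notna().all(axis=1)
    stage_ids = zmat.index[complete]
    P_stage = build_posterior_matrix(z, mixtures, stage_ids)
    assignment = stage_subjects(P_stage, ordering)

    id_to_group = frame.set_index(ID_COL)[GROUP_COL]
    if recipe.name == "model2":
        labels = groups["disability"].reindex(assignment.stages.index)
    elif recipe.name == "model3":
        labels = groups["cognition"].reindex(assignment.stages.index)
    else:
        labels = id_to_group.reindex(assignment.stages.index)
    summaries = stage_summary(assignment.stages, labels.fillna(HC))

    role_positions = {k: np.array([zmat.index.get_loc(s) for s in v])
                      for k, v in roles.items()}
    pv = bootstrap_pvd(zmat, events, role_positions, directions,
                       B=recipe.n_bootstraps, seed=recipe.seed, full_ordering=ordering)

    result = RunResult(recipe=recipe, selection=selection, events=events,
                       mixtures=mixtures, ordering=ordering, posterior=P, pvd=pv,
                       stages=assignment.stages, summaries=summaries, groups=groups,
                       zscored=z)
    if out_dir is not None:
        _write_outputs(result, out_dir, render=render)
    return result


def _write_outputs(result: RunResult, out_dir, render: bool = True) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.selection.reset_index().to_json(out / "selection.json", orient="records", indent=2)
    with open(out / "mixtures.json", "w") as fh:
        json.dump({e: m.to_dict() for e, m in result.mixtures.items()}, fh, indent=2)
    with open(out / "ordering.json", "w") as fh:
        json.dump({"events": list(result.ordering.events),
                   "log_likelihood": result.ordering.log_likelihood}, fh, indent=2)
    result.pvd.counts.to_csv(out / "pvd.tsv", sep="\t")
    if render:
        render_pvd(result.pvd, png_path=out / "pvd.png",
                   title=f"Positional variance ({result.recipe.name}, "
                         f"B={result.pvd.n_bootstraps})")
    result.stages.rename("stage").to_csv(out / "stages.tsv", sep="\t")
    result.summaries.to_csv(out / "stage_summary.tsv", sep="\t", index=False)
    import sklearn

    manifest = {
        "recipe": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(result.recipe).items()},
        "n_events": len(result.events),
        "events": result.events,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": __import__("scipy").__version__,
                     "sklearn": sklearn.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
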