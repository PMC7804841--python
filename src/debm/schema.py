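"""Cohort table schema: column vocabulary, roles, and validation.

A cohort is a flat table with one row per subject.  Required columns are the
identifier, the diagnostic group, the three covariates used for confound
correction (age, sex, education), the EDSS score, seven cognitive-domain
scores, and at least one numeric biomarker column.  Every biomarker column
carries a *class* (volume, lesion, centrality, fa, cognitive) which fixes its
default abnormality direction and whether it exists in healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Group labels
HC = "HC"
PATIENT = "MS"

# Required non-biomarker columns
ID_COL = "subject_id"
GROUP_COL = "group"
COVARIATES = ("age", "sex", "education")
EDSS_COL = "edss"

COGNITIVE_DOMAINS = (
    "cog_information_processing",
    "cog_executive",
    "cog_working_memory",
    "cog_verbal_memory",
    "cog_verbal_fluency",
    "cog_visuospatial",
    "cog_attention",
)

# Biomarker classes -> (default abnormality direction, present in controls)
# Volumes and FA fall with disease; lesion loads and functional centrality rise.
BIOMARKER_CLASSES = {
    "volume": ("decreasing", True),
    "fa": ("decreasing", True),
    "lesion": ("increasing", False),
    "centrality": ("increasing", True),
    "cognitive": ("decreasing", True),
}

# The 28 candidate biomarkers: 10 regional GM volumes, spinal cord area,
# 3 lesion-load bands (patients only), 3 network centralities, 4 FA tract
# groups, and 7 cognitive domains.
BIOMARKERS: dict[str, str] = {
    "vol_thalamus": "volume",
    "vol_hippocampus": "volume",
    "vol_basal_ganglia": "volume",
    "vol_cerebellar_gm": "volume",
    "vol_cingulate": "volume",
    "vol_frontal": "volume",
    "vol_insula": "volume",
    "vol_occipital": "volume",
    "vol_parietal": "volume",
    "vol_temporal": "volume",
    "mucca": "volume",
    "lesion_inner": "lesion",
    "lesion_deep": "lesion",
    "lesion_outer": "lesion",
    "ec_dmn": "centrality",
    "ec_basal_ganglia": "centrality",
    "ec_sensorimotor": "centrality",
    "fa_atr": "fa",
    "fa_cst": "fa",
    "fa_cingulum": "fa",
    "fa_other_wm": "fa",
    **{d: "cognitive" for d in COGNITIVE_DOMAINS},
}

LESION_BIOMARKERS = tuple(b for b, c in BIOMARKERS.items() if c == "lesion")

MISSING = "NA"  # literal missing marker in CSV files


def default_direction(biomarker: str) -> str:
    """Default abnormality direction for a named biomarker."""
    cls = BIOMARKERS.get(biomarker)
    if cls is None:
        raise KeyError(f"unknown biomarker {biomarker!r}")
    return BIOMARKER_CLASSES[cls][0]


def is_lesion_class(biomarker: str) -> bool:
    return BIOMARKERS.get(biomarker) == "lesion"


@dataclass
class CohortSchema:
    """Column roles for a cohort table.

    ``biomarkers`` maps column name to class; columns outside the required
    set and the biomarker map are rejected by :func:`validate_cohort_frame`
    unless listed in ``extra_columns``.
    """

    biomarkers: dict[str, str] = field(default_factory=lambda: dict(BIOMARKERS))
    extra_columns: tuple[str, ...] = ()

    @property
    def required_columns(self) -> list[str]:
        return [ID_COL, GROUP_COL, *COVARIATES, EDSS_COL, *COGNITIVE_DOMAINS]

    def biomarker_columns(self, frame: pd.DataFrame) -> list[str]:
        return [c for c in frame.columns if c in self.biomarkers]


class CohortValidationError(ValueError):
    """Raised when a cohort table fails schema validation.

    Carries the full structured error list; validation never reports a
    partial pass.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _check_edss(values: pd.Series) -> list[str]:
    errors = []
    v = values.dropna().astype(float)
    bad_range = v[(v < 0) | (v > 10)]
    for idx, x in bad_range.items():
        errors.append(f"edss out of range [0, 10] at row {idx}: {x}")
    off_grid = v[(np.round(v * 2) - v * 2).abs() > 1e-9]
    for idx, x in off_grid.items():
        errors.append(f"edss not in half-point steps at row {idx}: {x}")
    return errors


def validate_cohort_frame(frame: pd.DataFrame, schema: CohortSchema | None = None) -> list[str]:
    """Return the list of schema violations for a cohort table (empty = valid)."""
    schema = schema or CohortSchema()
    errors: list[str] = []
    for col in schema.required_columns:
        if col not in frame.columns:
            errors.append(f"missing required column: {col}")
    if errors:
        return errors

    dup = frame[ID_COL][frame[ID_COL].duplicated()]
    for sid in dup.unique():
        errors.append(f"duplicate subject_id: {sid}")

    bad_groups = set(frame[GROUP_COL].unique()) - {HC, PATIENT}
    for g in sorted(map(str, bad_groups)):
        errors.append(f"unknown group label: {g}")

    edu = frame["education"].dropna()
    if not edu.isin(range(1, 8)).all():
        bad = sorted(edu[~edu.isin(range(1, 8))].unique().tolist())
        errors.append(f"education outside 1..7: {bad}")

    sex = frame["sex"].dropna()
    if not sex.isin([0, 1]).all():
        errors.append("sex must be coded 0/1")

    patients = frame[frame[GROUP_COL] == PATIENT]
    errors.extend(_check_edss(patients[EDSS_COL]))

    if not schema.biomarker_columns(frame):
        errors.append("no biomarker columns present")

    known = set(schema.required_columns) | set(schema.biomarkers) | set(schema.extra_columns)
    for col in frame.columns:
        if col not in known:
            errors.append(f"unknown column (not in schema): {col}")
    return errors


def read_cohort(path, schema: CohortSchema | None = None, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (UTF-8, comma-separated, '.' decimal, 'NA' missing)."""
    frame = pd.read_csv(path, na_values=[MISSING], keep_default_na=True)
    if validate:
        errors = validate_cohort_frame(frame, schema)
        if errors:
            raise CohortValidationError(errors)
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, na_rep=MISSING)
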