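import warnings

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

import debm
from debm.schema import GROUP_COL, HC, ID_COL, PATIENT


@pytest.fixture(scope="session")
def default_cohort():
    """Reference simulation: 12 events, 300 patients (uniform stages),
    100 controls, 2.5-SD separation, clinical labels painted on."""
    cfg = debm.SimConfig(seed=7)
    cohort, truth = debm.generate_cohort(cfg)
    cohort = debm.derive_clinical_labels(cohort, truth, debm.LabelRule(seed=7))
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def zscored(default_cohort):
    _, cohort, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return debm.regress_confounds(cohort)


@pytest.fixture(scope="session")
def groups_idx(default_cohort):
    _, cohort, _ = default_cohort
    pat = pd.Index(cohort[ID_COL][cohort[GROUP_COL] == PATIENT])
    hc = pd.Index(cohort[ID_COL][cohort[GROUP_COL] == HC])
    return pat, hc


@pytest.fixture(scope="session")
def fitted_posteriors(default_cohort, zscored, groups_idx):
    """Mixtures and posterior matrix over all 12 events (lesions unanchored)."""
    cfg, _, _ = default_cohort
    pat, hc = groups_idx
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixtures = debm.fit_all_mixtures(zscored, list(cfg.event_labels), pat, hc)
        P = debm.build_posterior_matrix(zscored, mixtures, pat)
    return mixtures, P


def staircase_posteriors(n_events: int, n_per_stage: int = 3,
                         lo: float = 0.02, hi: float = 0.98) -> np.ndarray:
    """Ideal posterior matrix: one block of subjects per stage, events before
    the stage at probability hi, after at lo.  The generating ordering is
    the identity."""
    rows = []
    for k in range(n_events + 1):
        row = np.full(n_events, lo)
        row[:k] = hi
        rows.extend([row] * n_per_stage)
    return np.array(rows)
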