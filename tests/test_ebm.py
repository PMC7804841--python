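import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, spearmanr

import debm
from debm.ebm import (
    EventOrdering,
    EventSequenceModel,
    borda_ordering,
    estimate_ordering,
    exhaustive_ordering,
    greedy_ascent,
    stage_likelihood,
    stage_subjects,
    stage_summary,
    subject_ordering,
    total_loglik,
)

from conftest import staircase_posteriors


class TestSubjectOrdering:
    def test_sorts_by_posterior_descending(self):
        assert subject_ordering([0.9, 0.2, 0.6]).tolist() == [0, 2, 1]

    def test_ties_fall_back_to_canonical_order(self):
        assert subject_ordering([0.5, 0.5, 0.5, 0.5]).tolist() == [0, 1, 2, 3]

    def test_strictly_decreasing_gives_identity(self):
        assert subject_ordering([0.9, 0.7, 0.5, 0.3]).tolist() == [0, 1, 2, 3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            subject_ordering([0.5, 1.2])


class TestStageLikelihood:
    def test_degenerate_posteriors_pick_exact_stage(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        order = np.arange(4)
        assert stage_likelihood(p, order, 2) == 1.0
        for k in [0, 1, 3, 4]:
            assert stage_likelihood(p, order, k) == 0.0

    def test_uniform_posteriors_flat_profile(self):
        p = np.full(5, 0.5)
        order = np.arange(5)
        for k in range(6):
            assert stage_likelihood(p, order, k) == pytest.approx(0.5 ** 5)

    def test_hand_computed_product(self):
        # first two events occurred (0.9 * 0.8), third did not (1 - 0.1)
        assert stage_likelihood([0.9, 0.8, 0.1], np.arange(3), 2) == pytest.approx(0.648)

    def test_stage_out_of_range(self):
        with pytest.raises(ValueError):
            stage_likelihood([0.5], np.array([0]), 2)


class TestTotalLoglik:
    def test_uniform_posteriors_make_all_orderings_equal(self):
        P = np.full((7, 4), 0.5)
        lls = {total_loglik(P, np.array(p)) for p in itertools.permutations(range(4))}
        assert max(lls) - min(lls) < 1e-12

    def test_staircase_subject_maximised_by_generating_order(self):
        """Exhaustive check at N=4: the ordering that generated degenerate
        staircase posteriors attains the maximum marginal likelihood."""
        P = staircase_posteriors(4, n_per_stage=1)
        best = max(itertools.permutations(range(4)),
                   key=lambda p: total_loglik(P, np.array(p)))
        assert list(best) == [0, 1, 2, 3]

    def test_swap_of_identical_columns_is_neutral(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1, 20)
        P = np.column_stack([col, col, rng.uniform(0, 1, 20)])
        a = total_loglik(P, np.array([0, 1, 2]))
        b = total_loglik(P, np.array([1, 0, 2]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariant_under_subject_permutation(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(0, 1, (30, 5))
        order = np.array([3, 1, 4, 0, 2])
        shuffled = P[rng.permutation(30)]
        assert total_loglik(P, order) == pytest.approx(total_loglik(shuffled, order))


class TestOrderingEstimation:
    def test_staircase_recovers_generating_order(self):
        P = pd.DataFrame(staircase_posteriors(6), columns=list("abcdef"))
        assert estimate_ordering(P).events == tuple("abcdef")

    def test_uniform_posteriors_return_canonical_order(self):
        P = pd.DataFrame(np.full((10, 4), 0.5), columns=list("abcd"))
        assert estimate_ordering(P).events == tuple("abcd")

    def test_ascent_never_below_borda_start(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            P = rng.uniform(0, 1, (25, 6))
            init = borda_ordering(P)
            final, ll = greedy_ascent(P, init)
            assert ll >= total_loglik(P, init) - 1e-9

    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(25):
            P = rng.uniform(0, 1, (rng.integers(8, 30), rng.integers(3, 7)))
            g = estimate_ordering(P)
            e = exhaustive_ordering(P)
            hits += abs(g.log_likelihood - e.log_likelihood) < 1e-9
        assert hits >= 24

    def test_exhaustive_guards_and_trivial_cases(self):
        P = np.full((5, 1), 0.9)
        assert exhaustive_ordering(P).events == (0,)
        P3 = staircase_posteriors(3)
        assert exhaustive_ordering(pd.DataFrame(P3, columns=list("xyz"))).events == tuple("xyz")
        with pytest.raises(ValueError, match="refusing"):
            exhaustive_ordering(np.full((5, 9), 0.5))

    def test_repeated_event_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            EventOrdering(events=("a", "a", "b"))


class TestStaging:
    def test_all_low_posteriors_stage_zero(self):
        P = np.full((4, 6), 0.2)
        assert (stage_subjects(P, np.arange(6)).stages == 0).all()

    def test_all_high_posteriors_stage_n(self):
        P = np.full((4, 6), 0.8)
        assert (stage_subjects(P, np.arange(6)).stages == 6).all()

    def test_ties_resolve_to_lower_stage(self):
        P = np.full((3, 5), 0.5)  # every stage equally likely
        assert (stage_subjects(P, np.arange(5)).stages == 0).all()

    def test_recovery_on_simulated_cohort(self, default_cohort, fitted_posteriors):
        _, cohort, truth = default_cohort
        _, P = fitted_posteriors
        ordering = estimate_ordering(P)
        st = stage_subjects(P, ordering)
        rho = spearmanr(truth.true_stage.loc[P.index], st.stages).statistic
        assert rho >= 0.9

    def test_ordering_recovery_on_simulated_cohort(self, default_cohort,
                                                   fitted_posteriors):
        cfg, _, truth = default_cohort
        _, P = fitted_posteriors
        ordering = estimate_ordering(P)
        est_pos = [truth.event_position(e) for e in ordering.events]
        tau = kendalltau(est_pos, sorted(est_pos)).statistic
        assert tau >= 0.8


class TestStageSummary:
    def test_simple_arithmetic(self):
        stages = pd.Series([1, 2, 9], index=["a", "b", "c"])
        groups = pd.Series(["g", "g", "g"], index=["a", "b", "c"])
        out = stage_summary(stages, groups)
        assert out.loc[0, "median_stage"] == 2
        assert out.loc[0, "mean_stage"] == 4
        assert out.loc[0, "n"] == 3

    def test_identical_groups_identical_summaries(self):
        stages = pd.Series([0, 3, 5, 0, 3, 5], index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        out = stage_summary(stages, groups).set_index("group")
        assert out.loc["x", "median_stage"] == out.loc["y", "median_stage"]
        assert out.loc["x", "mean_stage"] == out.loc["y", "mean_stage"]

    def test_empty_group_warns_and_is_omitted(self):
        stages = pd.Series([1, 2], index=["a", "b"])
        groups = pd.Series(["g", "g", "h"], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="'h'"):
            out = stage_summary(stages, groups)
        assert "h" not in set(out["group"])


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        model = EventSequenceModel()
        params = model.get_params()
        assert "method" in params and "clamp" in params
        clone(model)  # must be clonable pre-fit

    def test_fit_predict_roundtrip(self):
        P = pd.DataFrame(staircase_posteriors(5), columns=list("abcde"))
        model = EventSequenceModel().fit(P)
        assert model.ordering_.events == tuple("abcde")
        stages = model.predict(P)
        assert stages.min() == 0 and stages.max() == 5
        assert model.score(P) > -np.inf

    def test_exhaustive_method_agrees_with_greedy_here(self):
        P = pd.DataFrame(staircase_posteriors(4), columns=list("abcd"))
        g = EventSequenceModel(method="greedy").fit(P)
        e = EventSequenceModel(method="exhaustive").fit(P)
        assert g.ordering_.events == e.ordering_.events
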