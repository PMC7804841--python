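"""Event-ordering estimation and patient staging.

Given a subjects x events matrix P of posterior abnormality probabilities,
the model treats disease progression as a fixed sequence sigma of events.
A subject at stage k has experienced exactly the first k events of sigma, so
their data likelihood is

    L(subject | sigma, k) = prod_{i<=k} p_sigma(i) * prod_{i>k} (1 - p_sigma(i)),

and with a uniform prior over stages 0..N the marginal log-likelihood of an
ordering is

    log L(sigma) = sum_subjects log( (1/(N+1)) sum_k L(subject | sigma, k) ).

The maximum-likelihood ordering is found by rank-aggregating the subjects'
individual orderings (each subject's events sorted by posterior, most
abnormal first) into a Borda consensus, then greedily ascending the marginal
likelihood over pairwise swaps and single-event reinsertions until no move
improves.  For small N an exhaustive enumeration provides the exact optimum.
Subjects are staged at the likelihood-argmax stage, ties resolved to the
lower stage (stage 0 is the null state of no abnormal biomarkers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

CLAMP = 1e-6  # posterior clamp before likelihood evaluation


@dataclass
class EventOrdering:
    """A permutation of the selected events; position 1 = earliest."""

    events: tuple[str, ...]
    log_likelihood: float = float("nan")

    def __post_init__(self):
        if len(set(self.events)) != len(self.events):
            raise ValueError("ordering is not a permutation: repeated events")

    def position(self, event: str) -> int:
        return self.events.index(event) + 1


@dataclass
class StageAssignment:
    """Per-subject maximum-likelihood stage with the full profile retained."""

    stages: pd.Series  # integer stage in 0..N, indexed by subject
    log_profile: pd.DataFrame  # subjects x stages 0..N, log-likelihood of each stage


def _as_matrix(P) -> tuple[np.ndarray, list]:
    if isinstance(P, pd.DataFrame):
        return P.to_numpy(dtype=float), list(P.columns)
    arr = np.asarray(P, dtype=float)
    return arr, list(range(arr.shape[1]))


def subject_ordering(posterior_row) -> np.ndarray:
    """Events sorted by posterior descending; ties keep canonical index order."""
    p = np.asarray(posterior_row, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    return np.argsort(-p, kind="stable")


def stage_loglik_matrix(P: np.ndarray, order: np.ndarray, clamp: float = CLAMP) -> np.ndarray:
    """(n_subjects, N+1) matrix of log L(subject | order, k) for k = 0..N."""
    Q = np.clip(P[:, order], clamp, 1 - clamp)
    n = Q.shape[0]
    lp = np.log(Q)
    l1p = np.log1p(-Q)
    pre = np.concatenate([np.zeros((n, 1)), np.cumsum(lp, axis=1)], axis=1)
    suf = np.concatenate([np.cumsum(l1p[:, ::-1], axis=1)[:, ::-1], np.zeros((n, 1))], axis=1)
    return pre + suf


def stage_likelihood(posterior_row, ordering, k: int, clamp: float = 0.0) -> float:
    """Probability that exactly the first k events of the ordering occurred."""
    p = np.asarray(posterior_row, dtype=float)
    order = np.asarray(ordering)
    if not (0 <= k <= len(order)):
        raise ValueError(f"stage k={k} outside 0..{len(order)}")
    q = p[order]
    if clamp:
        q = np.clip(q, clamp, 1 - clamp)
    return float(np.prod(q[:k]) * np.prod(1 - q[k:]))


def total_loglik(P, order, clamp: float = CLAMP) -> float:
    """Marginal log-likelihood of an ordering under a uniform stage prior."""
    mat, _ = _as_matrix(P)
    order = np.asarray(order)
    M = stage_loglik_matrix(mat, order, clamp)
    return float(np.sum(logsumexp(M, axis=1) - np.log(mat.shape[1] + 1)))


def borda_ordering(P) -> np.ndarray:
    """Consensus by mean position across subjects' individual orderings."""
    mat, _ = _as_matrix(P)
    n, N = mat.shape
    pos = np.empty((n, N))
    for i in range(n):
        order = subject_ordering(mat[i])
        pos[i, order] = np.arange(N)
    return np.argsort(pos.mean(axis=0), kind="stable")


def _candidate_moves(order: np.ndarray) -> np.ndarray:
    """(K, N) stack of all pairwise swaps and single-event reinsertions."""
    N = len(order)
    cands = []
    for i in range(N):
        for j in range(i + 1, N):
            cand = order.copy()
            cand[i], cand[j] = cand[j], cand[i]
            cands.append(cand)
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            cand = np.delete(order, i)
            cands.append(np.insert(cand, j, order[i]))
    return np.array(cands)


def total_loglik_many(P: np.ndarray, orders: np.ndarray, clamp: float = CLAMP,
                      logs: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Marginal log-likelihood of K orderings at once; orders is (K, N).

    ``logs`` optionally carries precomputed (log p, log(1-p)) for the clamped
    posterior matrix so repeated calls over the same data skip them.
    """
    n = P.shape[0]
    K, N = orders.shape
    if logs is None:
        Q = np.clip(P, clamp, 1 - clamp)
        logs = (np.log(Q), np.log1p(-Q))
    lp = logs[0][:, orders]  # (n, K, N)
    l1p = logs[1][:, orders]
    zeros = np.zeros((n, K, 1))
    pre = np.concatenate([zeros, np.cumsum(lp, axis=2)], axis=2)
    suf = np.concatenate([np.cumsum(l1p[:, :, ::-1], axis=2)[:, :, ::-1], zeros], axis=2)
    M = pre + suf
    mx = M.max(axis=2)
    ll = mx + np.log(np.exp(M - mx[:, :, None]).sum(axis=2)) - np.log(N + 1)
    return ll.sum(axis=0)


def greedy_ascent(P, init_order: np.ndarray, clamp: float = CLAMP,
                  min_gain: float = 1e-10) -> tuple[np.ndarray, float]:
    """Best-improvement ascent over swaps and reinsertions; finite and monotone.

    All candidate moves of a pass are scored in one vectorised likelihood
    evaluation; ties between equally-good moves keep the current ordering.
    """
    mat, _ = _as_matrix(P)
    order = np.asarray(init_order).copy()
    ll = total_loglik(mat, order, clamp)
    Q = np.clip(mat, clamp, 1 - clamp)
    logs = (np.log(Q), np.log1p(-Q))
    while True:
        cands = _candidate_moves(order)
        lls = total_loglik_many(mat, cands, clamp, logs=logs)
        best = int(np.argmax(lls))
        if lls[best] <= ll + min_gain:
            return order, ll
        order, ll = cands[best], float(lls[best])


def estimate_ordering(P, clamp: float = CLAMP) -> EventOrdering:
    """Maximum-likelihood ordering: Borda initialisation + greedy ascent."""
    mat, names = _as_matrix(P)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 events")
    init = borda_ordering(mat)
    order, ll = greedy_ascent(mat, init, clamp)
    return EventOrdering(events=tuple(names[i] for i in order), log_likelihood=ll)


def exhaustive_ordering(P, clamp: float = CLAMP, max_events: int = 8) -> EventOrdering:
    """Global maximiser by enumeration; a test oracle, guarded at N <= 8."""
    mat, names = _as_matrix(P)
    N = mat.shape[1]
    if N > max_events:
        raise ValueError(f"refusing exhaustive search over {N}! permutations (N > {max_events})")
    best_ll, best = -np.inf, None
    for perm in permutations(range(N)):
        ll = total_loglik(mat, np.array(perm), clamp)
        if ll > best_ll:
            best_ll, best = ll, perm
    return EventOrdering(events=tuple(names[i] for i in best), log_likelihood=best_ll)


def stage_subjects(P, ordering: EventOrdering | np.ndarray,
                   clamp: float = CLAMP) -> StageAssignment:
    """Likelihood-argmax stage per subject; ties go to the lower stage."""
    mat, names = _as_matrix(P)
    if isinstance(ordering, EventOrdering):
        order = np.array([names.index(e) for e in ordering.events])
    else:
        order = np.asarray(ordering)
    M = stage_loglik_matrix(mat, order, clamp)
    # lowest stage within numerical tolerance of the maximum wins the tie
    mx = M.max(axis=1)
    stages = np.argmax(M >= mx[:, None] - 1e-9, axis=1)
    index = P.index if isinstance(P, pd.DataFrame) else pd.RangeIndex(mat.shape[0])
    return StageAssignment(
        stages=pd.Series(stages, index=index, name="stage"),
        log_profile=pd.DataFrame(M, index=index, columns=range(mat.shape[1] + 1)),
    )


def stage_summary(stages: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group n, median stage and mean stage (the boxplot reporting surface)."""
    aligned = pd.DataFrame({"stage": stages, "group": groups.loc[stages.index]})
    empty = set(groups.unique()) - set(aligned["group"].unique())
    for g in sorted(map(str, empty)):
        warnings.warn(f"group {g!r} has no staged subjects; omitted from summary")
    out = aligned.groupby("group")["stage"].agg(n="size", median_stage="median",
                                                mean_stage="mean")
    return out.reset_index()


class EventSequenceModel(BaseEstimator):
    """Sklearn-style wrapper: fit an event ordering, predict subject stages.

    ``fit(P)`` takes a subjects x events posterior matrix (DataFrame or
    array); ``predict(P)`` returns the maximum-likelihood stage of each row
    under the fitted ordering; ``score(P)`` is the mean marginal
    log-likelihood per subject.
    """

    def __init__(self, method: str = "greedy", clamp: float = CLAMP):
        self.method = method
        self.clamp = clamp

    def fit(self, P, y=None):
        if self.method == "greedy":
            ordering = estimate_ordering(P, self.clamp)
        elif self.method == "exhaustive":
            ordering = exhaustive_ordering(P, self.clamp)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.ordering_ = ordering
        self.event_names_ = list(ordering.events)
        self.log_likelihood_ = ordering.log_likelihood
        self.n_events_ = len(ordering.events)
        return self

    def _order_idx(self, P) -> np.ndarray:
        _, names = _as_matrix(P)
        return np.array([names.index(e) for e in self.ordering_.events])

    def predict(self, P):
        assignment = stage_subjects(P, self._order_idx(P), self.clamp)
        return assignment.stages.to_numpy()

    def predict_profile(self, P) -> StageAssignment:
        return stage_subjects(P, self._order_idx(P), self.clamp)

    def score(self, P, y=None) -> float:
        mat, _ = _as_matrix(P)
        return total_loglik(mat, self._order_idx(P), self.clamp) / mat.shape[0]
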