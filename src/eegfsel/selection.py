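"""Score / order / candidate selection and wrapper search.

Stage 2: each scoring run awards 10..1 points to the ten most discriminant
features of one criterion evaluation; runs are accumulated and the candidate
set is the shortest score-ordered head whose cumulative score fraction
strictly exceeds the threshold ``rho``.

Stage 3 wrappers: Order Selection evaluates every score-ordered prefix of the
candidate list; GMDH selection grows a subset greedily, accepting the best
single-feature extension only while the Regularity Criterion (RC — the mean
held-out success rate over the six (learn, prune, test) session permutations)
strictly improves.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import classifier, criteria
from .criteria import CriterionVector
from .session import FeatureSession, SelectionResult

__all__ = [
    "ScoreTable",
    "score_run",
    "accumulate",
    "select_candidates",
    "evaluate_subset",
    "order_selection",
    "gmdh_selection",
    "unified_model",
]

TOP_K_SCORED = 10


@dataclasses.dataclass
class ScoreTable:
    """Accumulated per-feature relevance scores (1-based feature indexing)."""

    scores: np.ndarray
    runs: int
    top_k_scored: int = TOP_K_SCORED

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if np.any(self.scores < 0):
            raise ValueError("scores must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.scores.size


def score_run(criterion: CriterionVector, top_k: int = TOP_K_SCORED) -> np.ndarray:
    """Scores for one run: positions 1..top_k get top_k..1 points, rest 0.

    Features are sorted most-discriminant-first per the criterion's stated
    direction; ties break toward the lower feature index (stable sort).
    Non-rankable (constant) features never receive points.
    """
    values = np.asarray(criterion.values, dtype=float)
    rankable = criterion.rankable
    keys = values if criterion.low_is_discriminant else -values
    # unrankable features sort last
    keys = np.where(rankable, keys, np.inf)
    order = np.argsort(keys, kind="stable")
    scores = np.zeros(values.size, dtype=int)
    n_rankable = int(np.sum(rankable))
    for pos, feat in enumerate(order[: min(top_k, n_rankable)]):
        scores[feat] = top_k - pos
    return scores


def accumulate(score_runs: Iterable[np.ndarray]) -> ScoreTable:
    """Elementwise sum of per-run score vectors."""
    runs = [np.asarray(r, dtype=int) for r in score_runs]
    if not runs:
        raise ValueError("no score runs")
    arity = runs[0].size
    if any(r.size != arity for r in runs):
        raise ValueError("score runs disagree on feature arity")
    return ScoreTable(scores=np.sum(runs, axis=0), runs=len(runs))


def select_candidates(tbl: ScoreTable, rho: float = 0.85) -> tuple[int, list[int]]:
    """Smallest score-ordered head whose cumulative fraction strictly exceeds rho.

    Returns (K, candidates) where candidates are 1-based feature indices in
    descending accumulated-score order (ties toward the lower index).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    total = int(tbl.scores.sum())
    if total <= 0:
        raise ValueError("total score is zero")
    order = np.argsort(-tbl.scores, kind="stable")  # stable: ties by lower index
    order = order[tbl.scores[order] > 0]
    cum = np.cumsum(tbl.scores[order]) / total
    K = int(np.searchsorted(cum, rho, side="right")) + 1
    K = min(K, order.size)
    return K, [int(f) + 1 for f in order[:K]]


def evaluate_subset(
    features: Sequence[int],
    sessions: Sequence[FeatureSession],
    rho_v: float = 0.75,
    gamma_f: float = 0.1,
    window_len: int = 8,
) -> float:
    """Regularity Criterion of a feature subset, in percent.

    For each of the 6 ordered (learn, prune, test) permutations of the 3
    sessions, a model is fitted on the learn session restricted to the
    subset, pruned on the prune session, and evaluated by majority vote over
    consecutive ``window_len``-vector decision windows of the test session;
    the RC is the mean of the 6 percent accuracies.
    """
    if not features:
        raise ValueError("empty feature subset")
    if len(sessions) != 3:
        raise ValueError("exactly 3 sessions required")
    subset = [s.restrict(features) for s in sessions]
    accs = []
    fitted = {
        i: classifier.fit(subset[i], rho_v=rho_v, gamma_f=gamma_f) for i in range(3)
    }
    for i, j, k in itertools.permutations(range(3)):
        model = classifier.prune(fitted[i], subset[j])
        accs.append(_windowed_accuracy([model], subset[k], window_len))
    return float(np.mean(accs))


def _windowed_accuracy(
    models: Sequence[classifier.Model],
    test: FeatureSession,
    window_len: int = 8,
) -> float:
    """Percent of decision windows whose vote matches the window's label.

    Test vectors are grouped into consecutive non-overlapping windows; each
    window's reference label is the majority label of its vectors (ties to
    the lowest label).  Votes pool all per-model per-vector predictions; vote
    ties resolve to the previous decision.
    """
    n_windows = test.n_windows // window_len
    if n_windows == 0:
        raise ValueError("test session shorter than one decision window")
    preds = np.stack(
        [classifier.predict_batch(m, test.features) for m in models]
    )  # [n_models, n_vectors]
    correct = 0
    previous: int | None = None
    for w in range(n_windows):
        sl = slice(w * window_len, (w + 1) * window_len)
        votes: dict[int, int] = {}
        for p in preds[:, sl].ravel():
            votes[int(p)] = votes.get(int(p), 0) + 1
        top = max(votes.values())
        tied = sorted(c for c, n in votes.items() if n == top)
        if len(tied) > 1 and previous is not None and previous in tied:
            decision = previous
        else:
            decision = tied[0]
        previous = decision
        ref_labels, counts = np.unique(test.labels[sl], return_counts=True)
        ref = int(ref_labels[np.argmax(counts)])
        correct += decision == ref
    return 100.0 * correct / n_windows


Evaluator = Callable[[Sequence[int]], float]


def order_selection(
    candidates: Sequence[int],
    sessions: Sequence[FeatureSession] | None = None,
    rho: float = 0.85,
    scores: Sequence[int] | None = None,
    evaluator: Evaluator | None = None,
    **config,
) -> SelectionResult:
    """Evaluate all score-ordered prefixes of the candidate list, keep the best.

    Ties in evaluated accuracy go to the shorter prefix.  ``evaluator``
    overrides the RC evaluation (used for testing with mock evaluators).
    """
    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate features")
    if evaluator is None:
        if sessions is None:
            raise ValueError("sessions required without an explicit evaluator")
        evaluator = lambda S: evaluate_subset(S, sessions, **config)
    trace = [float(evaluator(candidates[: k + 1])) for k in range(len(candidates))]
    best_k = int(np.argmax(trace))  # first max -> shortest prefix on ties
    return SelectionResult(
        method="order",
        candidates=candidates,
        scores=[int(s) for s in scores] if scores is not None else [],
        selected=candidates[: best_k + 1],
        trace=trace,
        K=len(candidates),
        rho=rho,
    )


def gmdh_selection(
    candidates: Sequence[int],
    sessions: Sequence[FeatureSession] | None = None,
    rho: float = 0.85,
    scores: Sequence[int] | None = None,
    evaluator: Evaluator | None = None,
    **config,
) -> SelectionResult:
    """Greedy forward selection under the Regularity Criterion.

    Starts from the best single-feature model; each iteration evaluates every
    one-feature extension from the remaining candidates and accepts the best
    one iff its RC strictly exceeds the incumbent's; stops otherwise.  The
    trace records the RC of each accepted step (strictly increasing).
    """
    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate features")
    if evaluator is None:
        if sessions is None:
            raise ValueError("sessions required without an explicit evaluator")
        evaluator = lambda S: evaluate_subset(S, sessions, **config)

    def best_extension(current: list[int], pool: list[int]) -> tuple[list[int], float]:
        options = [current + [f] for f in pool]
        values = [float(evaluator(S)) for S in options]
        b = int(np.argmax(values))  # ties: earliest pool order = lower score rank
        return options[b], values[b]

    selected, rc = best_extension([], candidates)
    trace = [rc]
    pool = [f for f in candidates if f not in selected]
    while pool:
        extended, ext_rc = best_extension(selected, pool)
        if ext_rc > rc:
            selected, rc = extended, ext_rc
            trace.append(rc)
            pool = [f for f in pool if f not in selected]
        else:
            break
    return SelectionResult(
        method="gmdh",
        candidates=candidates,
        scores=[int(s) for s in scores] if scores is not None else [],
        selected=selected,
        trace=trace,
        K=len(candidates),
        rho=rho,
    )


def score_runs_statistic(
    sessions: Sequence[FeatureSession],
    use_entropy: bool = False,
) -> list[np.ndarray]:
    """One scoring run per learning session from the statistical criterion."""
    runs = []
    for s in sessions:
        tbl = criteria.normalized_variance(s)
        crit = (
            criteria.entropy_criterion(tbl)
            if use_entropy
            else criteria.product_criterion(tbl)
        )
        runs.append(score_run(crit))
    return runs


def score_runs_fuzzy(
    sessions: Sequence[FeatureSession],
    rho_v: float = 0.75,
    gamma_f: float = 0.1,
    aggregate: str = "min",
    grid_n: int = 1001,
) -> list[np.ndarray]:
    """One scoring run per ordered (learn, prune) session pair — 6 in total.

    Each run fits a model on the learn session, prunes it on the other
    session, collapses it to the per-class intermediate model, and scores the
    fuzzy overlap criterion.
    """
    if len(sessions) != 3:
        raise ValueError("exactly 3 sessions required")
    runs = []
    fitted = [classifier.fit(s, rho_v=rho_v, gamma_f=gamma_f) for s in sessions]
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            pruned = classifier.prune(fitted[i], sessions[j])
            im = classifier.intermediate_model(pruned)
            crit = criteria.fuzzy_feature_scores(im, aggregate=aggregate, grid_n=grid_n)
            runs.append(score_run(crit))
    return runs


def select_features(
    sessions: Sequence[FeatureSession],
    criterion: str = "statistic",
    wrapper: str = "gmdh",
    rho: float = 0.85,
    rho_v: float = 0.75,
    gamma_f: float = 0.1,
    use_entropy: bool = False,
    aggregate: str = "min",
) -> SelectionResult:
    """Full three-stage pipeline on 3 learning sessions.

    Stage 1+2 produce the accumulated score table (3 statistical runs or 6
    fuzzy runs), stage 2 picks the candidate head via ``rho``, and stage 3
    runs the requested wrapper.  Returns a SelectionResult tagged
    "<criterion>_<wrapper>".
    """
    if criterion == "statistic":
        runs = score_runs_statistic(sessions, use_entropy=use_entropy)
    elif criterion == "fuzzy":
        runs = score_runs_fuzzy(sessions, rho_v=rho_v, gamma_f=gamma_f, aggregate=aggregate)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    tbl = accumulate(runs)
    K, candidates = select_candidates(tbl, rho=rho)
    cand_scores = [int(tbl.scores[f - 1]) for f in candidates]
    if wrapper == "order":
        result = order_selection(
            candidates, sessions, rho=rho, scores=cand_scores,
            rho_v=rho_v, gamma_f=gamma_f,
        )
    elif wrapper == "gmdh":
        result = gmdh_selection(
            candidates, sessions, rho=rho, scores=cand_scores,
            rho_v=rho_v, gamma_f=gamma_f,
        )
    else:
        raise ValueError(f"unknown wrapper {wrapper!r}")
    return dataclasses.replace(result, method=f"{criterion}_{wrapper}")


def unified_model(
    per_user_results: Mapping[str, Sequence[Sequence[int] | SelectionResult]],
) -> list[int]:
    """Cross-user unified feature set.

    Per user, the selected sets of that user's methods are intersected; the
    per-user intersections are united across users and returned in ascending
    order.  A user whose methods share no feature contributes nothing.
    """
    if not per_user_results:
        raise ValueError("at least one user required")
    union: set[int] = set()
    for user, results in per_user_results.items():
        sets = [
            set(r.selected) if isinstance(r, SelectionResult) else set(int(f) for f in r)
            for r in results
        ]
        if len(sets) < 2:
            raise ValueError(f"user {user!r} needs at least 2 method results")
        common = set.intersection(*sets)
        union |= common
    return sorted(union)
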