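"""Supervised fuzzy-rule classifier with learn / prune / vote protocol.

Each rule is a conjunction of per-feature trapezoidal fuzzy sets: membership
is 1 on the core interval [lo_j, hi_j] and decays linearly to 0 over a width
``gamma_f`` (in normalized feature units) outside it.  A rule fires with the
minimum of its per-feature memberships; prediction picks the rule with the
highest activation.

This is a deliberately static stand-in for dynamic fuzzy-ART-family models:
learning is a deterministic one-pass procedure in which a sample either
expands the core of the best-matching same-class rule (when the match reaches
the vigilance ``rho_v``) or seeds a new point-core rule.  Vigilance matching
uses the mean per-feature membership (an ART-style normalized match), while
prediction uses the min-conjunction.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np

from .session import FeatureSession

__all__ = [
    "FuzzyRule",
    "Normalization",
    "Model",
    "IntermediateModel",
    "fit",
    "prune",
    "build_models",
    "predict_sample",
    "predict_batch",
    "vote_predict",
    "vote_counts",
    "intermediate_model",
    "save_model",
    "load_model",
]

_MATCH_TOL = 1e-12


@dataclasses.dataclass
class FuzzyRule:
    """Per-feature trapezoid cores plus a class label and audit counters."""

    core_lo: np.ndarray
    core_hi: np.ndarray
    class_label: int
    success_count: int = 0
    error_count: int = 0

    def __post_init__(self) -> None:
        self.core_lo = np.asarray(self.core_lo, dtype=float)
        self.core_hi = np.asarray(self.core_hi, dtype=float)
        if self.core_lo.shape != self.core_hi.shape:
            raise ValueError("core_lo / core_hi shape mismatch")
        if np.any(self.core_lo > self.core_hi):
            raise ValueError("core_lo must be <= core_hi")


@dataclasses.dataclass
class Normalization:
    """Per-feature affine map of the learning session onto [0, 1] (clipped)."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_features(cls, features: np.ndarray) -> "Normalization":
        return cls(lo=features.min(axis=0), hi=features.max(axis=0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((np.asarray(x, dtype=float) - self.lo) / span, 0.0, 1.0)


@dataclasses.dataclass
class Model:
    """Ordered rule set from one (learn, prune) session pair."""

    rules: list[FuzzyRule]
    rho_v: float
    gamma_f: float
    normalization: Normalization
    learn_session_id: str = ""
    prune_session_id: str = ""

    @property
    def n_features(self) -> int:
        return self.rules[0].core_lo.size

    @property
    def class_labels(self) -> tuple[int, ...]:
        return tuple(sorted({r.class_label for r in self.rules}))

    def _stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo = np.stack([r.core_lo for r in self.rules])
        hi = np.stack([r.core_hi for r in self.rules])
        cls = np.array([r.class_label for r in self.rules])
        return lo, hi, cls


@dataclasses.dataclass
class IntermediateModel:
    """Exactly one prototype rule per class, feature-wise mean of rule cores."""

    class_labels: tuple[int, ...]
    core_lo: np.ndarray  # [C, n_features]
    core_hi: np.ndarray  # [C, n_features]
    gamma_f: float

    def __post_init__(self) -> None:
        if self.core_lo.shape != self.core_hi.shape:
            raise ValueError("core shape mismatch")
        if self.core_lo.shape[0] != len(self.class_labels):
            raise ValueError("one prototype per class required")


def _memberships(
    lo: np.ndarray, hi: np.ndarray, gamma: float, x: np.ndarray
) -> np.ndarray:
    """Trapezoid memberships, broadcasting x against stacked cores."""
    residual = np.maximum(np.maximum(lo - x, x - hi), 0.0)
    if gamma > 0:
        return np.clip(1.0 - residual / gamma, 0.0, 1.0)
    return (residual <= 0.0).astype(float)


def fit(
    session: FeatureSession,
    rho_v: float = 0.75,
    gamma_f: float = 0.1,
    seed: int | None = None,
) -> Model:
    """One-pass sequential rule learning on a labeled session.

    Samples are presented in session order; each either expands the core of
    the best-matching rule of its own class (match >= rho_v) or creates a new
    rule with a point core.  Deterministic given (session order, rho_v,
    gamma_f); ``seed`` is accepted for interface uniformity but unused.
    """
    if not 0.0 <= rho_v <= 1.0:
        raise ValueError("rho_v must lie in [0, 1]")
    labels, counts = np.unique(session.labels, return_counts=True)
    if np.any(counts == 0) or labels.size == 0:
        raise ValueError("every class needs at least one sample")

    norm = Normalization.from_features(session.features)
    X = norm.transform(session.features)
    n, d = X.shape

    # growable stacked storage; python-level loop is unavoidable (sequential)
    cap = 64
    lo = np.empty((cap, d))
    hi = np.empty((cap, d))
    by_class: dict[int, list[int]] = {int(c): [] for c in labels}
    n_rules = 0

    for i in range(n):
        x = X[i]
        c = int(session.labels[i])
        own = by_class[c]
        placed = False
        if own:
            idx = np.array(own)
            mu = _memberships(lo[idx], hi[idx], gamma_f, x)
            match = mu.mean(axis=1)
            best = int(np.argmax(match))
            if match[best] >= rho_v - _MATCH_TOL:
                r = idx[best]
                np.minimum(lo[r], x, out=lo[r])
                np.maximum(hi[r], x, out=hi[r])
                placed = True
        if not placed:
            if n_rules == cap:
                cap *= 2
                lo = np.concatenate([lo, np.empty((cap - n_rules, d))])
                hi = np.concatenate([hi, np.empty((cap - n_rules, d))])
            lo[n_rules] = x
            hi[n_rules] = x
            by_class[c].append(n_rules)
            n_rules += 1

    cls_of = np.empty(n_rules, dtype=int)
    for c, idxs in by_class.items():
        cls_of[idxs] = c
    rules = [
        FuzzyRule(core_lo=lo[r].copy(), core_hi=hi[r].copy(), class_label=int(cls_of[r]))
        for r in range(n_rules)  # creation order
    ]
    return Model(
        rules=rules,
        rho_v=rho_v,
        gamma_f=gamma_f,
        normalization=norm,
        learn_session_id=session.session_id,
    )


def _activations(model: Model, X: np.ndarray) -> np.ndarray:
    """Min-conjunction activation of every rule on every (raw) sample.

    Returns [n_samples, n_rules]; inputs are normalized (and clipped) with the
    model's learn-session transform.  Work is chunked to bound the size of the
    broadcast [chunk, n_rules, n_features] intermediate.
    """
    lo, hi, _ = model._stacked()
    Xn = model.normalization.transform(X)
    n = Xn.shape[0]
    n_rules, d = lo.shape
    chunk = max(1, int(4e6 // (n_rules * d)))
    out = np.empty((n, n_rules))
    for s in range(0, n, chunk):
        mu = _memberships(lo, hi, model.gamma_f, Xn[s : s + chunk, None, :])
        out[s : s + chunk] = mu.min(axis=2)
    return out


def predict_batch(model: Model, X: np.ndarray) -> np.ndarray:
    """Winner-class per row; ties broken by lowest rule index (argmax order)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature arity {X.shape[1]} != model arity {model.n_features}"
        )
    act = _activations(model, X)
    winners = act.argmax(axis=1)  # first max -> lowest rule index
    _, _, cls = model._stacked()
    return cls[winners]


def predict_sample(model: Model, x: np.ndarray) -> int:
    """Class of the rule with maximal min-conjunction activation on ``x``."""
    return int(predict_batch(model, np.asarray(x, dtype=float)[None, :])[0])


def prune(model: Model, session: FeatureSession) -> Model:
    """Winner-take-all audit then removal of rules with more errors than wins.

    Every sample is classified by its winning rule, whose success or error
    counter increments; afterwards rules with error_count > success_count are
    dropped.  If that would empty a class, the best rule of the class (highest
    success - error, then success, then lowest index) is retained.
    """
    if session.n_windows == 0:
        return model
    if session.n_features != model.n_features:
        raise ValueError("session arity does not match model")
    act = _activations(model, session.features)
    winners = act.argmax(axis=1)
    rules = [
        dataclasses.replace(
            r, core_lo=r.core_lo.copy(), core_hi=r.core_hi.copy()
        )
        for r in model.rules
    ]
    for w, y in zip(winners, session.labels):
        if rules[w].class_label == int(y):
            rules[w].success_count += 1
        else:
            rules[w].error_count += 1

    keep = [r.error_count <= r.success_count for r in rules]
    for c in model.class_labels:
        of_class = [i for i, r in enumerate(rules) if r.class_label == c]
        if not any(keep[i] for i in of_class):
            best = max(
                of_class,
                key=lambda i: (
                    rules[i].success_count - rules[i].error_count,
                    rules[i].success_count,
                    -i,
                ),
            )
            keep[best] = True
    return Model(
        rules=[r for i, r in enumerate(rules) if keep[i]],
        rho_v=model.rho_v,
        gamma_f=model.gamma_f,
        normalization=model.normalization,
        learn_session_id=model.learn_session_id,
        prune_session_id=session.session_id,
    )


def build_models(
    sessions: Sequence[FeatureSession],
    rho_v: float = 0.75,
    gamma_f: float = 0.1,
) -> list[Model]:
    """One model per ordered (learn, prune) pair of 3 distinct sessions -> 6."""
    if len(sessions) != 3:
        raise ValueError(f"exactly 3 sessions required, got {len(sessions)}")
    ids = [s.session_id for s in sessions]
    if len(set(ids)) != 3:
        raise ValueError(f"duplicate session ids: {ids}")
    models = []
    for i, learn in enumerate(sessions):
        fitted = fit(learn, rho_v=rho_v, gamma_f=gamma_f)
        for j, adj in enumerate(sessions):
            if i == j:
                continue
            models.append(prune(fitted, adj))
    return models


def vote_counts(models: Sequence[Model], window: np.ndarray) -> Counter:
    """Counter over the 6 x 8 = 48 sample-level predictions of one window."""
    window = np.asarray(window, dtype=float)
    votes: Counter = Counter()
    for model in models:
        preds = predict_batch(model, window)
        votes.update(int(p) for p in preds)
    return votes


def vote_predict(
    models: Sequence[Model],
    window: np.ndarray,
    previous: int | None = None,
    window_len: int = 8,
) -> int:
    """Majority vote over all per-model per-vector predictions of one window.

    Ties resolve to the previous decision when available, else to the lowest
    class label.  The outcome depends only on the multiset of votes.
    """
    window = np.asarray(window, dtype=float)
    if len(models) != 6:
        raise ValueError(f"exactly 6 models required, got {len(models)}")
    if window.shape[0] != window_len:
        raise ValueError(
            f"decision window must have {window_len} vectors, got {window.shape[0]}"
        )
    votes = vote_counts(models, window)
    top = max(votes.values())
    tied = sorted(c for c, n in votes.items() if n == top)
    if len(tied) > 1 and previous is not None and previous in tied:
        return previous
    return tied[0]


def save_model(model: Model, path: str | Path) -> None:
    """Serialize a model (rules, normalization, provenance) to JSON."""
    doc = {
        "rho_v": model.rho_v,
        "gamma_f": model.gamma_f,
        "normalization": {
            "lo": model.normalization.lo.tolist(),
            "hi": model.normalization.hi.tolist(),
        },
        "learn_session_id": model.learn_session_id,
        "prune_session_id": model.prune_session_id,
        "rules": [
            {
                "core_lo": r.core_lo.tolist(),
                "core_hi": r.core_hi.tolist(),
                "class_label": r.class_label,
                "success_count": r.success_count,
                "error_count": r.error_count,
            }
            for r in model.rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_model(path: str | Path) -> Model:
    with open(path) as fh:
        doc = json.load(fh)
    return Model(
        rules=[
            FuzzyRule(
                core_lo=np.array(r["core_lo"]),
                core_hi=np.array(r["core_hi"]),
                class_label=int(r["class_label"]),
                success_count=int(r["success_count"]),
                error_count=int(r["error_count"]),
            )
            for r in doc["rules"]
        ],
        rho_v=doc["rho_v"],
        gamma_f=doc["gamma_f"],
        normalization=Normalization(
            lo=np.array(doc["normalization"]["lo"]),
            hi=np.array(doc["normalization"]["hi"]),
        ),
        learn_session_id=doc["learn_session_id"],
        prune_session_id=doc["prune_session_id"],
    )


def intermediate_model(model: Model) -> IntermediateModel:
    """Per-class prototype rules: feature-wise mean of the class's rule cores."""
    classes = model.class_labels
    if not classes:
        raise ValueError("model has no rules")
    lo_rows, hi_rows = [], []
    for c in classes:
        of_class = [r for r in model.rules if r.class_label == c]
        if not of_class:
            raise ValueError(f"class {c} has no rules")
        lo_rows.append(np.mean([r.core_lo for r in of_class], axis=0))
        hi_rows.append(np.mean([r.core_hi for r in of_class], axis=0))
    return IntermediateModel(
        class_labels=classes,
        core_lo=np.stack(lo_rows),
        core_hi=np.stack(hi_rows),
        gamma_f=model.gamma_f,
    )
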