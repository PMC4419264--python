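"""Synthetic feature-session generator with known discriminant structure.

Sessions emulate the structure of the precomputed competition files: three
task classes presented in 15 s blocks at 16 feature vectors per second, 96
strictly positive PSD-like features.  Noise is lognormal (heavy-tailed, like
band powers) and temporally correlated across consecutive vectors (the real
preprocessing hops a 1 s window by 32 samples, so neighbouring vectors share
93.75% of their samples); a designated subset of "informative" features
receives class-specific multiplicative mean shifts, i.e. additive shifts of
the log-scale mean expressed in within-class log-SD units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .session import FeatureSession

__all__ = ["SyntheticSpec", "generate_sessions", "known_answer"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the generator; feature indices are 1-based."""

    n_classes: int = 3
    n_features: int = 96
    informative: tuple[int, ...] = ()
    effect_size: float = 2.0
    block_seconds: int = 15
    vectors_per_second: int = 16
    session_minutes: float = 4.0
    log_sigma: float = 0.4
    offset_mode: str = "one_vs_rest"
    ar_coeff: float = 0.9
    labels: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_features < 1:
            raise ValueError("need at least 1 feature")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")
        if min(self.block_seconds, self.vectors_per_second) <= 0:
            raise ValueError("block_seconds and vectors_per_second must be positive")
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")
        bad = [f for f in self.informative if not 1 <= f <= self.n_features]
        if bad:
            raise ValueError(f"informative features out of range: {bad}")
        if self.offset_mode not in ("pairwise", "one_vs_rest", "linear"):
            raise ValueError("offset_mode must be 'pairwise', 'one_vs_rest' or 'linear'")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.labels is None:
            # competition-style codes for 3 classes, else consecutive
            self.labels = (2, 3, 7) if self.n_classes == 3 else tuple(
                range(1, self.n_classes + 1)
            )
        if len(self.labels) != self.n_classes:
            raise ValueError("label list must match n_classes")

    @property
    def vectors_per_block(self) -> int:
        return self.block_seconds * self.vectors_per_second

    @property
    def n_vectors(self) -> int:
        return int(round(self.session_minutes * 60 * self.vectors_per_second))


def _offset_matrix(spec: SyntheticSpec) -> np.ndarray:
    """[n_informative, n_classes] log-mean offsets, unit = one effect size.

    The effect size of a feature is its largest between-class log-mean gap in
    within-class SD units.  Modes:

    ``linear``: centered unit-spaced offsets scaled so the extreme classes
    are one effect apart; a single feature orders all classes.
    ``one_vs_rest`` (default): feature t shifts only class ``t mod C`` by the
    full effect (ERD/ERS-like single-task power modulation); classes are only
    jointly separable, the regime a forward wrapper search is meant to
    exercise.
    ``pairwise``: feature t contrasts classes ``t mod C`` (up half an effect)
    and ``(t+1) mod C`` (down half an effect), so each feature fully
    separates exactly one class pair.
    """
    k = len(spec.informative)
    C = spec.n_classes
    if spec.offset_mode == "linear":
        base = np.arange(C) - (C - 1) / 2.0
        return np.tile(base / (C - 1), (k, 1))
    out = np.zeros((k, C))
    if spec.offset_mode == "one_vs_rest":
        for t in range(k):
            out[t, t % C] = 1.0
    else:  # pairwise
        for t in range(k):
            out[t, t % C] = 0.5
            out[t, (t + 1) % C] = -0.5
    return out


def generate_sessions(spec: SyntheticSpec, n_sessions: int = 4) -> list[FeatureSession]:
    """Deterministic list of labeled sessions for a generator spec.

    Each session is a sequence of class blocks; the cyclic class order is
    re-randomized per session from ``spec.seed``.  Non-informative features
    are i.i.d. lognormal and identical in law across classes; informative
    features receive class-dependent multiplicative mean shifts of
    ``effect_size`` within-class SDs on the log scale, with the per-class
    pattern set by ``offset_mode`` (see :func:`_offset_matrix`).
    """
    root = np.random.SeedSequence(spec.seed)
    sessions = []
    offsets = _offset_matrix(spec)  # [k, C]
    informative = np.asarray(sorted(spec.informative), dtype=int) - 1
    for s, child in enumerate(root.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        n = spec.n_vectors
        # cyclic class order, randomized once per session
        cycle = rng.permutation(spec.n_classes)
        n_blocks = -(-n // spec.vectors_per_block)  # ceil
        block_classes = np.tile(cycle, -(-n_blocks // spec.n_classes))[:n_blocks]
        class_idx = np.repeat(block_classes, spec.vectors_per_block)[:n]

        z = rng.standard_normal((n, spec.n_features))
        if spec.ar_coeff > 0.0:
            # stationary AR(1) across consecutive vectors: successive analysis
            # windows overlap by 93.75% in the emulated preprocessing, so
            # neighbouring feature vectors are strongly correlated
            phi = spec.ar_coeff
            z[0] /= np.sqrt(1.0 - phi**2)
            z = signal.lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi], z, axis=0)
        log_feats = spec.log_sigma * z
        if informative.size:
            # [n, k]: per-sample shift of each informative feature
            shift = spec.effect_size * spec.log_sigma * offsets[:, class_idx].T
            log_feats[:, informative] += shift
        features = np.exp(log_feats)
        labels = np.asarray(spec.labels)[class_idx]
        sessions.append(
            FeatureSession(
                features=features,
                labels=labels,
                vectors_per_second=spec.vectors_per_second,
                session_id=f"synthetic-{spec.seed}-{s + 1}",
            )
        )
    return sessions


def known_answer(spec: SyntheticSpec) -> set[int]:
    """Ground-truth informative feature subset (1-based) for recovery tests."""
    return set(spec.informative)
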