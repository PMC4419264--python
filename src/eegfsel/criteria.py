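"""Stage-1 discriminant-character criteria.

Statistical route: the class-prior-weighted normalized within-class variance
of each feature and two scalar separability criteria derived from it (an
entropy form and a product form).  Fuzzy route: pairwise overlap of the
per-class prototype fuzzy sets of an intermediate classifier model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classifier import IntermediateModel
from .session import FeatureSession

__all__ = [
    "NormalizedVarianceTable",
    "CriterionVector",
    "normalized_variance",
    "entropy_criterion",
    "product_criterion",
    "fuzzy_pair_similarity",
    "fuzzy_feature_scores",
]


@dataclasses.dataclass
class NormalizedVarianceTable:
    """Per-(class, feature) normalized variances gamma_tilde = P_i*var_ij/lambda_j.

    Variances are population (divide-by-n) estimates, which makes the
    law-of-total-variance bound sum_i gamma_tilde_ij <= 1 exact.  Features
    with zero total variance are flagged in ``constant_mask`` and must be
    excluded from ranking.
    """

    gamma_tilde: np.ndarray  # [C, M]
    priors: np.ndarray  # [C]
    class_variances: np.ndarray  # [C, M]
    total_variances: np.ndarray  # [M]
    class_labels: tuple[int, ...]
    constant_mask: np.ndarray  # [M] bool, True where lambda_j == 0

    @property
    def n_classes(self) -> int:
        return self.gamma_tilde.shape[0]

    @property
    def n_features(self) -> int:
        return self.gamma_tilde.shape[1]


@dataclasses.dataclass
class CriterionVector:
    """Per-feature criterion values plus the direction of discriminance.

    ``low_is_discriminant`` states whether small values flag useful features.
    ``rankable`` marks features eligible for scoring (non-constant ones).
    """

    values: np.ndarray
    low_is_discriminant: bool
    method: str
    rankable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rankable is None:
            self.rankable = np.ones(self.values.shape, dtype=bool)


def normalized_variance(session: FeatureSession) -> NormalizedVarianceTable:
    """Normalized within-class variance table of a labeled session."""
    if session.n_windows < 2:
        raise ValueError("need at least 2 samples")
    X = session.features
    y = session.labels
    classes = session.label_set
    priors = np.array([np.mean(y == c) for c in classes])
    class_var = np.stack([X[y == c].var(axis=0) for c in classes])  # population
    total_var = X.var(axis=0)
    constant = total_var == 0.0
    lam = np.where(constant, 1.0, total_var)
    gamma_tilde = priors[:, None] * class_var / lam
    gamma_tilde[:, constant] = np.nan
    return NormalizedVarianceTable(
        gamma_tilde=gamma_tilde,
        priors=priors,
        class_variances=class_var,
        total_variances=total_var,
        class_labels=classes,
        constant_mask=constant,
    )


def _table_values(tbl: NormalizedVarianceTable) -> np.ndarray:
    g = np.array(tbl.gamma_tilde, dtype=float)
    g[:, tbl.constant_mask] = 0.0
    return g


def entropy_criterion(tbl: NormalizedVarianceTable) -> CriterionVector:
    """J(x_j) = sum_i gt_ij * ln(gt_ij), with 0*log 0 = 0.

    All terms are <= 0; values near 0 indicate small normalized within-class
    variances, i.e. a discriminant feature, so high values are discriminant.
    """
    g = _table_values(tbl)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(g > 0, g * np.log(np.where(g > 0, g, 1.0)), 0.0)
    values = terms.sum(axis=0)
    values[tbl.constant_mask] = np.nan
    return CriterionVector(
        values=values,
        low_is_discriminant=False,
        method="entropy",
        rankable=~tbl.constant_mask,
    )


def product_criterion(tbl: NormalizedVarianceTable) -> CriterionVector:
    """J(x_j) = prod_i gt_ij; bounded by (1/C)^C, attained only by features
    whose normalized variances are all equal with full mass (non-discriminant),
    so low values are discriminant."""
    g = _table_values(tbl)
    values = g.prod(axis=0)
    values[tbl.constant_mask] = np.nan
    return CriterionVector(
        values=values,
        low_is_discriminant=True,
        method="product",
        rankable=~tbl.constant_mask,
    )


def _trapezoid_mu(grid: np.ndarray, lo: float, hi: float, gamma: float) -> np.ndarray:
    residual = np.maximum(np.maximum(lo - grid, grid - hi), 0.0)
    if gamma > 0:
        return np.clip(1.0 - residual / gamma, 0.0, 1.0)
    return (residual <= 0.0).astype(float)


def fuzzy_pair_similarity(
    a: tuple[float, float],
    b: tuple[float, float],
    gamma: float,
    grid_n: int = 1001,
    domain: tuple[float, float] | None = None,
) -> float:
    """Overlap ratio of two trapezoidal sets: integral(min) / integral(max).

    ``a`` and ``b`` are (core_lo, core_hi) pairs sharing the fuzziness width
    ``gamma``; integrals use the trapezoid rule on ``grid_n`` uniform points
    over a domain covering both supports.  1 for identical sets, 0 for
    disjoint supports; an empty/empty pair is defined as 1.
    """
    if domain is None:
        lo = min(a[0], b[0]) - gamma
        hi = max(a[1], b[1]) + gamma
        if hi <= lo:
            return 1.0
        domain = (lo, hi)
    grid = np.linspace(domain[0], domain[1], grid_n)
    mu_a = _trapezoid_mu(grid, a[0], a[1], gamma)
    mu_b = _trapezoid_mu(grid, b[0], b[1], gamma)
    num = np.trapezoid(np.minimum(mu_a, mu_b), grid)
    den = np.trapezoid(np.maximum(mu_a, mu_b), grid)
    if den == 0.0:
        return 1.0
    return float(num / den)


def fuzzy_feature_scores(
    im: IntermediateModel,
    aggregate: str = "min",
    grid_n: int = 1001,
) -> CriterionVector:
    """Per-feature fuzzy discriminance from the per-class prototype sets.

    For every feature the pairwise overlap F is computed for all C(C-1)/2
    class pairs and aggregated (min by default: a feature separating any pair
    counts as discriminant).  F near 0 is discriminant, F near 1 is not.
    """
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    C, M = im.core_lo.shape
    pair_values = []
    for i in range(C):
        for k in range(i + 1, C):
            row = np.empty(M)
            for j in range(M):
                row[j] = fuzzy_pair_similarity(
                    (im.core_lo[i, j], im.core_hi[i, j]),
                    (im.core_lo[k, j], im.core_hi[k, j]),
                    gamma=im.gamma_f,
                    grid_n=grid_n,
                )
            pair_values.append(row)
    stacked = np.stack(pair_values)
    values = stacked.min(axis=0) if aggregate == "min" else stacked.mean(axis=0)
    return CriterionVector(values=values, low_is_discriminant=True, method="fuzzy")
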