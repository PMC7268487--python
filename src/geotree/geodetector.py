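"""Factor-detector q-statistic for stratified heterogeneity.

For a numeric response partitioned into L strata with sizes N_h, the
q-statistic is

    q = 1 - (sum_h N_h * sigma_h^2) / (N * sigma^2) = 1 - SSW / SST,

where sigma^2 and sigma_h^2 are population variances (denominator N, so any
common variance convention cancels exactly). q in [0, 1] measures how much of
the response variance the stratification explains: q = 0 when strata means are
identical, q = 1 when the response is constant within every stratum.

Significance is assessed by a permutation test on the stratum labels (the
published tables report p-values without naming a test; permutation is
assumption-free and exactly reproducible under a seed). Weight allocation
normalizes q-values of competing factors to proportions summing to one, which
is how the two development-stage indicators are combined downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class QResult:
    """q-statistic with its sum-of-squares decomposition and optional p-value."""

    q: float
    n_total: int
    ssw: float
    sst: float
    stratum_sizes: dict
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.q <= 1 + 1e-12):
            raise ValueError(f"q out of [0, 1]: {self.q}")
        if self.ssw > self.sst * (1 + 1e-12):
            raise ValueError("SSW exceeds SST")
        if abs(self.q - (1.0 - self.ssw / self.sst)) > 1e-12:
            raise ValueError("q inconsistent with 1 - SSW/SST")


@dataclasses.dataclass(frozen=True)
class WeightAllocation:
    """Non-negative factor weights summing to one."""

    weights: dict

    def __post_init__(self) -> None:
        vals = list(self.weights.values())
        if any(w < 0 for w in vals):
            raise ValueError("negative weight")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __getitem__(self, key: str) -> float:
        return self.weights[key]


def _prepare(values, strata, dropna: bool = True):
    y = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(strata, dtype=object).ravel()
    if y.shape[0] != labels.shape[0]:
        raise ValueError("values and strata must have equal length")
    if dropna:
        keep = ~np.isnan(y)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("q_statistic: dropped %d rows with missing response", n_drop)
        y, labels = y[keep], labels[keep]
    if y.shape[0] == 0:
        raise ValueError("no complete observations after missing-value filtering")
    if y.shape[0] < 2:
        raise ValueError("q-statistic requires at least 2 observations")
    return y, labels


def _ssw(y: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    sums = np.bincount(codes, weights=y, minlength=counts.size)
    sumsq = np.bincount(codes, weights=y * y, minlength=counts.size)
    return float(np.sum(sumsq - sums * sums / counts))


def q_statistic(values, strata) -> QResult:
    """Compute the factor-detector q of ``strata`` on ``values``.

    Missing responses are dropped pairwise (with a logged count). Raises
    ``ValueError`` for a constant response (zero total variance) or an empty
    overlap after filtering.
    """
    y, labels = _prepare(values, strata)
    levels, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise ValueError("constant response: total variance is zero")
    ssw = _ssw(y, codes, counts)
    ssw = min(max(ssw, 0.0), sst)
    return QResult(
        q=1.0 - ssw / sst,
        n_total=int(y.size),
        ssw=ssw,
        sst=sst,
        stratum_sizes={lev: int(c) for lev, c in zip(levels, counts)},
    )


def q_significance(values, strata, n_permutations: int = 999, seed: int | None = 0) -> QResult:
    """q-statistic with a permutation p-value on the stratum labels.

    p = (1 + #{permuted q >= observed q}) / (1 + n_permutations), a valid
    (conservative) Monte-Carlo p-value; reproducible under a fixed seed.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    base = q_statistic(values, strata)
    y, labels = _prepare(values, strata)
    _, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        q_perm = 1.0 - _ssw(perm, codes, counts) / base.sst
        if q_perm >= base.q - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return dataclasses.replace(
        base, p_value=p, n_permutations=n_permutations, seed=seed
    )


def allocate_weights(q_by_factor: Mapping[str, float]) -> WeightAllocation:
    """Normalize factor q-values to proportional weights (w_f = q_f / sum q).

    Weights are kept at full precision; rounding (e.g. the printed two-decimal
    0.55/0.45) happens only at display time.
    """
    if not q_by_factor:
        raise ValueError("no factors supplied")
    if any(q < 0 for q in q_by_factor.values()):
        raise ValueError("q-values must be non-negative")
    total = float(sum(q_by_factor.values()))
    if total <= 0.0:
        raise ValueError("no explanatory power: all q-values are zero")
    return WeightAllocation({k: float(q) / total for k, q in q_by_factor.items()})
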