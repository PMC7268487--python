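"""Fisher-Jenks optimal natural breaks (1-D classification).

Dynamic programming over the sorted unique values (weighted by multiplicity)
finds the partition into k contiguous classes minimizing the within-class sum
of squared deviations — the exact optimum, not the iterative-reassignment
heuristic. Working on unique values guarantees that tied observations always
share a class, so the classification is a function of the value alone and can
be re-applied to new data through the stored break points.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass(frozen=True)
class BreaksResult:
    """Optimal k-class 1-D classification.

    ``breaks`` are the k-1 internal cut points (the maximum value of each
    class but the last); a value v belongs to class ``1 + #{breaks < v}``.
    ``gvf`` is the goodness of variance fit, 1 - SSW/SST.
    """

    breaks: tuple[float, ...]
    class_of: np.ndarray
    gvf: float
    k: int

    def assign(self, values) -> np.ndarray:
        """Classify (possibly new) values with the stored break points."""
        return assign_classes(values, self.breaks)


def assign_classes(values, breaks) -> np.ndarray:
    """Class labels 1..k for ``values`` given ascending internal cut points."""
    v = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(breaks, dtype=float), v, side="left") + 1


def natural_breaks(values, k: int) -> BreaksResult:
    """Optimal Fisher-Jenks classification of ``values`` into ``k`` classes.

    Requires at least ``k`` distinct values. Deterministic: ties in the DP are
    broken toward the earliest split.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty value vector")
    if np.isnan(v).any():
        raise ValueError("missing values not allowed in natural_breaks")
    if k < 1:
        raise ValueError("k must be >= 1")
    u, counts = np.unique(v, return_counts=True)
    m = u.size
    if k > m:
        raise ValueError(f"k={k} exceeds number of distinct values ({m})")

    w = counts.astype(float)
    # prefix sums over unique values: weight, weighted value, weighted square
    W = np.concatenate(([0.0], np.cumsum(w)))
    S1 = np.concatenate(([0.0], np.cumsum(w * u)))
    S2 = np.concatenate(([0.0], np.cumsum(w * u * u)))

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SS of unique-value segment [i, j] (inclusive, 0-based)
        ww = W[j + 1] - W[i]
        s1 = S1[j + 1] - S1[i]
        s2 = S2[j + 1] - S2[i]
        return s2 - s1 * s1 / ww

    # D[c, j]: minimal SSW of classifying u[0..j] into c+1 classes
    D = np.empty((k, m))
    idx = np.arange(m)
    D[0, :] = S2[1:] - S1[1:] * S1[1:] / W[1:]
    back = np.zeros((k, m), dtype=int)
    for c in range(1, k):
        D[c, :c] = np.inf
        for j in range(c, m):
            starts = idx[c : j + 1]  # first index of the last class
            cand = D[c - 1, starts - 1] + seg_cost(starts, j)
            best = int(np.argmin(cand))
            D[c, j] = cand[best]
            back[c, j] = starts[best]

    # backtrack class boundaries on unique values
    bounds = []  # index of last unique value of each class except the final
    j = m - 1
    for c in range(k - 1, 0, -1):
        start = back[c, j]
        bounds.append(start - 1)
        j = start - 1
    bounds.reverse()
    cut_points = tuple(float(u[b]) for b in bounds)

    class_of = assign_classes(v, cut_points)
    sst = seg_cost(np.array([0]), m - 1)[0]
    ssw = float(D[k - 1, m - 1])
    gvf = 0.0 if sst <= 0 else 1.0 - ssw / sst
    gvf = min(max(gvf, 0.0), 1.0)
    return BreaksResult(breaks=cut_points, class_of=class_of, gvf=gvf, k=k)
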