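"""Full-precision reference metrics and the filter-then-refine driver.

The bit engine gives a coarse similarity (shared extreme features). Cosine
similarity and Euclidean distance on the original continuous data are the
sensitive metrics it stands in front of:

    euclidean(a, b) = sqrt(sum_k (a_k - b_k)^2)
    cosine(a, b)    = sum_k a_k b_k / (sqrt(sum_k a_k^2) sqrt(sum_k b_k^2))

``filter_then_refine`` runs the cheap binary comparison first and evaluates
the full-precision metric only on pairs whose combined up+down shared count
reaches ``min_shared``, pruning the (typically overwhelming) majority of
unproductive pairs. Refined values are identical to computing the metric
directly on the surviving pairs.

On 0/1 vectors the bit counts and the full metrics coincide exactly:
cosine == AND / sqrt(pop_i * pop_j) and euclidean == sqrt(XOR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binarize import DenseMatrix, ThresholdSpec, threshold_binarize
from .engine import compare

__all__ = ["cosine", "euclidean", "RefinedPairs", "filter_then_refine"]

# default minimum combined shared up+down count for a pair to be refined;
# scores below ~20 are typical of unrelated expression signatures
DEFAULT_MIN_SHARED = 20


def _as_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    return v


def cosine(a, b) -> float:
    """Cosine similarity in [-1, 1]; zero-norm vectors are rejected."""
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na = float(np.sqrt(np.dot(a, a)))
    nb = float(np.sqrt(np.dot(b, b)))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for zero-norm vectors")
    return float(np.dot(a, b)) / (na * nb)


def euclidean(a, b) -> float:
    """Euclidean distance, >= 0."""
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    d = a - b
    return float(np.sqrt(np.dot(d, d)))


_METRICS = {"cosine": cosine, "euclidean": euclidean}


@dataclass
class RefinedPairs:
    """Pairs surviving the binary filter, with their full-precision values."""

    pairs: list  # (query index, library index, filter_count, refined_value)
    metric: str
    min_shared: int
    query_ids: list = field(default_factory=list)
    library_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def filter_then_refine(
    query: DenseMatrix,
    library: DenseMatrix,
    spec: ThresholdSpec = ThresholdSpec(),
    operator: str = "AND",
    min_shared: int = DEFAULT_MIN_SHARED,
    metric: str = "cosine",
) -> RefinedPairs:
    """Binary pre-filter, then the full-precision metric on survivors.

    Both matrices are binarized with ``spec``; the filter statistic for a
    pair is low-shared + high-shared (the merged up/down count). Pairs with
    statistic >= ``min_shared`` get the exact ``metric`` evaluated on the
    original continuous columns.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    if query.feature_ids != library.feature_ids:
        raise ValueError("query and library must share the same feature universe")
    K = len(query.feature_ids)
    if min_shared > 2 * K:
        raise ValueError(
            f"min_shared={min_shared} can never be reached with K={K} features"
        )
    q_low, q_high = threshold_binarize(query, spec)
    l_low, l_high = threshold_binarize(library, spec)
    shared = (
        compare(q_low, l_low, operator).counts.astype(np.int64)
        + compare(q_high, l_high, operator).counts.astype(np.int64)
    )
    fn = _METRICS[metric]
    pairs = []
    for i, j in np.argwhere(shared >= min_shared):
        value = fn(query.values[:, i], library.values[:, j])
        pairs.append((int(i), int(j), int(shared[i, j]), value))
    return RefinedPairs(
        pairs=pairs,
        metric=metric,
        min_shared=min_shared,
        query_ids=query.sample_ids,
        library_ids=library.sample_ids,
    )
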