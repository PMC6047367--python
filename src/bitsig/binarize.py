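"""Binarization of continuous feature matrices into paired low/high signatures.

Gene-expression style data arrives as a continuous K-features x N-samples
matrix (e.g. log ratios against a reference). Two binary matrices are
derived by thresholding the tails of the distribution: the *low* (down)
matrix marks values strictly below the low cut, the *high* (up) matrix marks
values strictly above the high cut. With data ~ N(0, 0.5 sd) and cuts at
-0.6 / +0.6, each tail captures Phi(-1.2) ~ 11.5% of entries.

Signatures may also arrive as explicit per-sample up/down gene lists (the
output of a differential-expression caller); ``from_updown_calls`` turns
those into the same paired matrices over a fixed feature universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bitpack import SignatureMatrix, pack

__all__ = ["DenseMatrix", "ThresholdSpec", "threshold_binarize", "from_updown_calls"]


@dataclass
class DenseMatrix:
    """K x N continuous values with ordered feature and sample ids."""

    values: np.ndarray
    feature_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        K, N = self.values.shape
        if K < 1 or N < 1:
            raise ValueError("matrix must have at least one feature and one sample")
        if len(self.feature_ids) != K or len(self.sample_ids) != N:
            raise ValueError("id lengths do not match the value matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DenseMatrix":
        return cls(
            values=frame.to_numpy(dtype=np.float64),
            feature_ids=list(frame.index),
            sample_ids=list(frame.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class ThresholdSpec:
    """Strict two-sided cuts: low bit iff value < low_cut, high iff > high_cut."""

    low_cut: float = -0.6
    high_cut: float = 0.6

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise ValueError(
                f"low_cut ({self.low_cut}) must be below high_cut ({self.high_cut})"
            )


def threshold_binarize(
    data: DenseMatrix,
    spec: ThresholdSpec = ThresholdSpec(),
    missing: str = "zero",
) -> tuple[SignatureMatrix, SignatureMatrix]:
    """Split a continuous matrix into (low, high) signature matrices.

    Inequalities are strict: a value exactly at a cut sets neither bit, and
    no value can ever set both. Non-finite entries are governed by
    ``missing``: ``"zero"`` (default) leaves both bits unset, ``"error"``
    rejects the input.
    """
    if missing not in ("zero", "error"):
        raise ValueError(f"missing policy must be 'zero' or 'error', got {missing!r}")
    vals = data.values
    finite = np.isfinite(vals)
    if missing == "error" and not finite.all():
        k, j = (int(x) for x in np.argwhere(~finite)[0])
        raise ValueError(
            f"non-finite value at (feature {data.feature_ids[k]!r}, "
            f"sample {data.sample_ids[j]!r})"
        )
    low = finite & (vals < spec.low_cut)
    high = finite & (vals > spec.high_cut)
    low_sig = pack(low, data.feature_ids, data.sample_ids)
    high_sig = pack(high, data.feature_ids, data.sample_ids)
    return low_sig, high_sig


def from_updown_calls(
    up_sets: Mapping[object, Sequence],
    down_sets: Mapping[object, Sequence],
    universe: Sequence,
) -> tuple[SignatureMatrix, SignatureMatrix]:
    """Build (down, up) signature matrices from per-sample feature lists.

    ``up_sets`` and ``down_sets`` map sample id -> iterable of feature ids;
    the sample universe is the union of both keys (missing direction = empty
    set). Features must belong to ``universe`` and the two directions must be
    disjoint within each sample.
    """
    universe = list(universe)
    pos = {f: k for k, f in enumerate(universe)}
    if len(pos) != len(universe):
        raise ValueError("universe contains duplicate feature ids")
    samples = sorted(set(up_sets) | set(down_sets), key=str)
    if not samples:
        raise ValueError("no samples in up/down calls")
    K, N = len(universe), len(samples)
    up = np.zeros((K, N), dtype=np.uint8)
    down = np.zeros((K, N), dtype=np.uint8)
    for j, s in enumerate(samples):
        u = set(up_sets.get(s, ()))
        d = set(down_sets.get(s, ()))
        overlap = u & d
        if overlap:
            raise ValueError(
                f"sample {s!r}: features {sorted(map(str, overlap))} are listed "
                "as both up and down"
            )
        for direction, mat in ((u, up), (d, down)):
            for f in direction:
                if f not in pos:
                    raise ValueError(f"sample {s!r}: feature {f!r} not in universe")
                mat[pos[f], j] = 1
    return (
        pack(down, universe, samples),
        pack(up, universe, samples),
    )
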