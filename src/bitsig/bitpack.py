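"""Bit-packed binary signature matrices.

A *signature* is a binary vector over an ordered feature universe: bit ``k``
of a signature says whether feature ``k`` belongs to the signature (a
differentially expressed gene, an ortholog present in a genome, a gene-set
member). Signatures are stored column-wise, each column packed into
``W = ceil(K / 64)`` unsigned 64-bit words so that pairwise set operations
(intersection, symmetric difference, union) reduce to one bitwise machine
instruction per word pair followed by a population count.

Bit order convention
--------------------
Feature ``k`` lives in word ``k // 64`` at bit position ``k % 64``,
least-significant bit first. The convention is fixed so that serialized word
arrays are portable and bit-exact across platforms. All padding positions
(bit indices >= K in the last word) are forced to zero at pack time and
re-validated on load; because AND/OR/XOR map zero pads to zero pads, every
downstream count is automatically correct without masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SignatureMatrix", "pack", "unpack", "popcount_words"]

WORD_BITS = 64


def _pad_mask(K: int) -> np.uint64:
    """Mask of the valid (non-padding) bits in the last word of a column."""
    rem = K % WORD_BITS
    if rem == 0:
        return np.uint64(0xFFFFFFFFFFFFFFFF)
    return np.uint64((1 << rem) - 1)


@dataclass
class SignatureMatrix:
    """K features x N signatures, packed column-wise into 64-bit words.

    Attributes
    ----------
    words : ndarray, shape (W, N), dtype uint64
        ``W = ceil(K/64)`` words per signature; column ``j`` holds signature j.
    feature_ids : list
        Ordered feature identifiers, length K.
    signature_ids : list
        Ordered signature identifiers, length N.
    K : int
        Number of features (signature length).
    """

    words: np.ndarray
    feature_ids: list = field(repr=False)
    signature_ids: list = field(repr=False)
    K: int

    def __post_init__(self) -> None:
        self.words = np.ascontiguousarray(self.words, dtype=np.uint64)
        self.feature_ids = list(self.feature_ids)
        self.signature_ids = list(self.signature_ids)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("signature length K must be >= 1")
        if self.N < 1:
            raise ValueError("signature count N must be >= 1")
        if self.words.ndim != 2:
            raise ValueError("words must be a 2-D (W, N) array")
        W = -(-self.K // WORD_BITS)
        if self.words.shape != (W, self.N):
            raise ValueError(
                f"words shape {self.words.shape} != expected ({W}, {self.N}) "
                f"for K={self.K}"
            )
        if len(self.feature_ids) != self.K:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for K={self.K} features"
            )
        bad = np.nonzero(self.words[-1] & ~_pad_mask(self.K))[0]
        if bad.size:
            raise ValueError(
                f"nonzero padding bits in signature column {int(bad[0])}; "
                "the container is corrupted"
            )

    # -- convenience --------------------------------------------------------

    @property
    def N(self) -> int:
        return self.words.shape[1] if self.words.ndim == 2 else len(self.signature_ids)

    @property
    def W(self) -> int:
        return self.words.shape[0]

    def popcounts(self) -> np.ndarray:
        """Per-signature set-bit counts (column sums of the unpacked matrix)."""
        return np.bitwise_count(self.words).sum(axis=0, dtype=np.int64)

    def column(self, j: int) -> np.ndarray:
        """The packed words of signature ``j``."""
        return self.words[:, j]

    def select(self, idx: Sequence[int]) -> "SignatureMatrix":
        """Sub-matrix with the signatures at positions ``idx``, in order."""
        idx = list(idx)
        return SignatureMatrix(
            words=self.words[:, idx],
            feature_ids=self.feature_ids,
            signature_ids=[self.signature_ids[i] for i in idx],
            K=self.K,
        )


def pack(
    dense01: np.ndarray,
    feature_ids: Sequence | None = None,
    signature_ids: Sequence | None = None,
) -> SignatureMatrix:
    """Pack a K x N 0/1 matrix into a :class:`SignatureMatrix`.

    Bit ``k`` of column ``j`` is set iff ``dense01[k, j] == 1``. Entries other
    than 0 and 1 are rejected, naming the first offending coordinate.
    """
    dense01 = np.asarray(dense01)
    if dense01.ndim != 2 or dense01.size == 0:
        raise ValueError("input must be a non-empty 2-D matrix")
    if dense01.dtype != bool:
        bad = (dense01 != 0) & (dense01 != 1)
        if bad.any():
            k, j = (int(x) for x in np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary entry {dense01[k, j]!r} at (feature {k}, signature {j})"
            )
    K, N = dense01.shape
    if feature_ids is None:
        feature_ids = [f"f{k}" for k in range(K)]
    if signature_ids is None:
        signature_ids = [f"s{j}" for j in range(N)]
    W = -(-K // WORD_BITS)
    bits = np.zeros((W * WORD_BITS, N), dtype=np.uint8)
    bits[:K] = dense01 != 0
    # little-endian bit order within each byte, bytes little-endian in the word
    packed = np.packbits(bits.reshape(W, WORD_BITS, N), axis=1, bitorder="little")
    words = packed.reshape(W, 8, N).transpose(0, 2, 1).copy().view(np.uint64)[:, :, 0]
    return SignatureMatrix(
        words=words, feature_ids=feature_ids, signature_ids=signature_ids, K=K
    )


def unpack(sig: SignatureMatrix) -> np.ndarray:
    """Exact inverse of :func:`pack`: the K x N 0/1 matrix, dtype uint8.

    Padding bits never leak into the output; a container with nonzero padding
    is rejected by validation.
    """
    sig.validate()
    W, N = sig.words.shape
    as_bytes = sig.words[:, :, None].view(np.uint8).reshape(W, N, 8)
    bits = np.unpackbits(as_bytes, axis=2, bitorder="little")  # (W, N, 64)
    dense = bits.transpose(0, 2, 1).reshape(W * WORD_BITS, N)
    return np.ascontiguousarray(dense[: sig.K])


def popcount_words(words: np.ndarray) -> int:
    """Total number of set bits across an array of 64-bit words."""
    words = np.asarray(words, dtype=np.uint64)
    return int(np.bitwise_count(words).sum(dtype=np.int64))
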