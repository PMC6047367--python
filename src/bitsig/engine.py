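"""All-vs-all signature comparison via bitwise operators and popcount.

Given two packed signature matrices (a *query* of N signatures and a
*library* of M signatures over the same K-feature universe), the engine
produces an N x M table of counts: cell (i, j) is the popcount of
``query_column_i OP library_column_j``. With OP = AND the count is the size
of the set intersection (shared features), XOR the symmetric difference,
OR the union.

Self-comparison stores each unordered pair once, as a strictly upper
triangular matrix with a zero diagonal. For outputs too large for memory the
engine tiles the result into rectangular chunks under a byte budget and
streams the blocks to a sink; chunked and unchunked results are cellwise
identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .bitpack import SignatureMatrix

__all__ = [
    "OPERATORS",
    "ComparisonResult",
    "ChunkPlan",
    "compare",
    "compare_self",
    "plan_chunks",
    "compare_chunked",
    "pair_count",
]

OPERATORS = {
    "AND": np.bitwise_and,
    "XOR": np.bitwise_xor,
    "OR": np.bitwise_or,
}

BYTES_PER_CELL = 4  # counts are uint32: K < 2^32 in every intended use

# cap on the transient (W, n_block, m_block) word tensor used per block;
# small enough to stay cache-resident, which beats larger batches
_WORK_BYTES = 2 << 20


def _check_operator(operator: str) -> str:
    op = str(operator).upper()
    if op not in OPERATORS:
        raise ValueError(
            f"unknown operator {operator!r}; expected one of {sorted(OPERATORS)}"
        )
    return op


@dataclass
class ComparisonResult:
    """N x M table of pairwise popcounts ``a_ij``, tagged with the operator.

    For self-comparisons (``is_self=True``) the table is square, strictly
    upper triangular with a zero diagonal: each unordered pair appears once.
    """

    query_ids: list
    library_ids: list
    counts: np.ndarray
    operator: str
    K: int
    is_self: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.query_ids = list(self.query_ids)
        self.library_ids = list(self.library_ids)
        if self.counts.shape != (len(self.query_ids), len(self.library_ids)):
            raise ValueError("counts shape does not match id lists")
        self.operator = _check_operator(self.operator)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def symmetric_counts(self) -> np.ndarray:
        """Full symmetric matrix for a self-comparison (diagonal stays zero)."""
        if not self.is_self:
            raise ValueError("symmetric_counts is defined for self-comparisons")
        return self.counts + self.counts.T

    def iter_pairs(self) -> Iterator[tuple[int, int, int]]:
        """Yield (i, j, count); for self-comparisons only pairs with i < j."""
        n, m = self.counts.shape
        if self.is_self:
            iu = np.triu_indices(n, k=1)
            for i, j in zip(*iu):
                yield int(i), int(j), int(self.counts[i, j])
        else:
            for i in range(n):
                for j in range(m):
                    yield i, j, int(self.counts[i, j])


def _block_counts(
    qwords: np.ndarray, lwords: np.ndarray, ufunc: np.ufunc
) -> np.ndarray:
    """Counts for a (W, n) x (W, m) block of packed columns, dtype uint32."""
    W, n = qwords.shape
    m = lwords.shape[1]
    out = np.empty((n, m), dtype=np.uint32)
    # batch query columns so the (W, step, m) word tensor stays in cache
    step = max(1, _WORK_BYTES // max(1, W * m * 8))
    for s in range(0, n, step):
        e = min(n, s + step)
        ops = ufunc(qwords[:, s:e, None], lwords[:, None, :])
        out[s:e] = np.bitwise_count(ops).sum(axis=0, dtype=np.uint32)
    return out


def compare(
    query: SignatureMatrix, library: SignatureMatrix, operator: str = "AND"
) -> ComparisonResult:
    """All query signatures against all library signatures.

    counts[i, j] = popcount(query column i OP library column j). Deterministic
    and independent of any chunking.
    """
    op = _check_operator(operator)
    if query.K != library.K:
        raise ValueError(
            f"signature length mismatch: query K={query.K}, library K={library.K}"
        )
    counts = _block_counts(query.words, library.words, OPERATORS[op])
    return ComparisonResult(
        query_ids=query.signature_ids,
        library_ids=library.signature_ids,
        counts=counts,
        operator=op,
        K=query.K,
    )


def compare_self(matrix: SignatureMatrix, operator: str = "AND") -> ComparisonResult:
    """All unordered pairs within one matrix.

    Returns an M x M strictly upper triangular table with zero diagonal;
    cell (i, j), i < j, equals ``compare(matrix, matrix).counts[i, j]``.
    """
    op = _check_operator(operator)
    M = matrix.N
    if M < 2:
        raise ValueError(f"self-comparison needs at least 2 signatures, got {M}")
    ufunc = OPERATORS[op]
    counts = np.zeros((M, M), dtype=np.uint32)
    W = matrix.W
    step = max(1, _WORK_BYTES // max(1, W * M * 8))
    for s in range(0, M - 1, step):
        e = min(M - 1, s + step)
        block = _block_counts(matrix.words[:, s:e], matrix.words[:, s:], ufunc)
        # keep only j > i within the block's column offset
        rows = np.arange(s, e)
        mask = np.arange(s, M)[None, :] > rows[:, None]
        counts[s:e, s:] = np.where(mask, block, 0)
    return ComparisonResult(
        query_ids=matrix.signature_ids,
        library_ids=matrix.signature_ids,
        counts=counts,
        operator=op,
        K=matrix.K,
        is_self=True,
    )


@dataclass
class ChunkPlan:
    """A tiling of an N x M output into blocks under a byte budget."""

    blocks: list[tuple[int, int, int, int]]  # (row_start, row_end, col_start, col_end)
    N: int
    M: int
    bytes_per_cell: int
    memory_budget_bytes: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cover = np.zeros((self.N, self.M), dtype=np.uint8) if self.N * self.M <= 10**7 else None
        for r0, r1, c0, c1 in self.blocks:
            if not (0 <= r0 < r1 <= self.N and 0 <= c0 < c1 <= self.M):
                raise ValueError(f"block {(r0, r1, c0, c1)} out of bounds")
            if (r1 - r0) * (c1 - c0) * self.bytes_per_cell > self.memory_budget_bytes:
                raise ValueError(f"block {(r0, r1, c0, c1)} exceeds the byte budget")
            if cover is not None:
                cover[r0:r1, c0:c1] += 1
        if cover is not None and not (cover == 1).all():
            raise ValueError("blocks do not tile the output exactly once")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def plan_chunks(
    N: int,
    M: int,
    bytes_per_cell: int = BYTES_PER_CELL,
    memory_budget_bytes: int = 1 << 30,
) -> ChunkPlan:
    """Tile an N x M count matrix into blocks of at most the budget.

    Rows are split first; only when a single row does not fit are columns
    split as well. A single block covers everything when the whole output
    fits in the budget.
    """
    if min(N, M, bytes_per_cell, memory_budget_bytes) <= 0:
        raise ValueError("all plan_chunks arguments must be positive")
    if memory_budget_bytes < bytes_per_cell:
        raise ValueError(
            f"budget {memory_budget_bytes} B cannot hold even one "
            f"{bytes_per_cell}-byte cell"
        )
    cells_per_chunk = memory_budget_bytes // bytes_per_cell
    blocks: list[tuple[int, int, int, int]] = []
    rows_per_chunk = cells_per_chunk // M
    if rows_per_chunk >= 1:
        for r0 in range(0, N, rows_per_chunk):
            blocks.append((r0, min(N, r0 + rows_per_chunk), 0, M))
    else:
        cols = cells_per_chunk  # one row at a time, columns split
        for r0 in range(N):
            for c0 in range(0, M, cols):
                blocks.append((r0, r0 + 1, c0, min(M, c0 + cols)))
    return ChunkPlan(
        blocks=blocks,
        N=N,
        M=M,
        bytes_per_cell=bytes_per_cell,
        memory_budget_bytes=memory_budget_bytes,
    )


def compare_chunked(
    query: SignatureMatrix,
    library: SignatureMatrix,
    operator: str,
    plan: ChunkPlan,
    sink: Callable[[tuple[int, int, int, int], np.ndarray], None],
    self_mode: bool = False,
) -> None:
    """Stream the comparison blockwise to ``sink(block_coords, counts)``.

    The concatenation of the emitted blocks is cellwise identical to the
    unchunked :func:`compare` (or :func:`compare_self` when ``self_mode``,
    in which case blocks straddling the diagonal zero their lower parts).
    """
    op = _check_operator(operator)
    if query.K != library.K:
        raise ValueError(
            f"signature length mismatch: query K={query.K}, library K={library.K}"
        )
    if (plan.N, plan.M) != (query.N, library.N):
        raise ValueError(
            f"plan tiles {(plan.N, plan.M)} but inputs are {(query.N, library.N)}"
        )
    ufunc = OPERATORS[op]
    for block in plan.blocks:
        r0, r1, c0, c1 = block
        counts = _block_counts(
            query.words[:, r0:r1], library.words[:, c0:c1], ufunc
        )
        if self_mode:
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            counts = np.where(cols > rows, counts, 0)
        try:
            sink(block, counts)
        except Exception as exc:
            raise RuntimeError(f"sink failed on block {block}: {exc}") from exc


def pair_count(N: int) -> int:
    """Number of unordered pairs among N signatures: N(N-1)/2, exact."""
    N = int(N)
    if N < 0:
        raise ValueError("N must be non-negative")
    return N * (N - 1) // 2
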