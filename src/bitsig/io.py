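"""Readers and writers for the package's on-disk formats.

Text formats: dense feature-by-sample TSV/CSV (first column feature ids,
header row sample ids), two-column up/down call TSV (sample id, feature id),
GMT gene-set collections, edge-list TSV and GraphML, taxonomy TSV, and count
tables. Floats are written with 9 significant digits so TSV round-trips are
value-exact at that precision.

Binary container (``.bsig`` / ``.bcnt``): a little-endian layout of
``magic(4s) version(u32) K(u64) N(u64) W(u64)``, then the column-major
packed words (``'<u8'``), then a length-prefixed UTF-8 JSON id table. The
loader re-validates the padding invariant, so a corrupted container is
rejected rather than producing silently wrong counts.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .binarize import DenseMatrix
from .bitpack import SignatureMatrix, pack
from .engine import ComparisonResult
from .genomesim import TaxonomyLabels
from .netsig import EdgeTable
from .refmetrics import RefinedPairs

__all__ = [
    "read_dense", "write_dense",
    "read_updown_calls",
    "read_gmt",
    "read_signatures", "write_signatures",
    "read_counts_tsv", "write_counts_tsv",
    "read_edge_table", "write_edge_table", "write_graphml",
    "read_taxonomy", "write_taxonomy",
    "write_refined_pairs",
    "write_manifest", "read_manifest",
]

FLOAT_FMT = "%.9g"
_MAGIC = b"BSG1"
_VERSION = 1
_HEADER = struct.Struct("<4sIQQQ")


# ---------------------------------------------------------------- dense text

def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"

def read_dense(path) -> DenseMatrix:
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return DenseMatrix.from_frame(frame)

def write_dense(data: DenseMatrix, path) -> None:
    data.to_frame().to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def read_updown_calls(path) -> dict:
    """Two-column TSV (sample id, feature id) -> {sample: [features]}."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "feature"], dtype=str
    )
    out: dict = {}
    for s, f in frame.itertuples(index=False):
        out.setdefault(s, []).append(f)
    return out


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> tuple[list, SignatureMatrix]:
    """Gene-set collection -> (set names, membership signature matrix).

    One set per line: name, description, then tab-separated members. The
    feature universe is the sorted union of all members; bit (k, j) is set
    iff feature k belongs to set j. Duplicate set names are rejected; an
    empty set yields an all-zero column.
    """
    names: list[str] = []
    members: list[set] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno} lacks a description field")
        name = fields[0]
        if name in names:
            raise ValueError(f"{path}: duplicate gene-set name {name!r}")
        names.append(name)
        members.append({f for f in fields[2:] if f})
    if not names:
        raise ValueError(f"{path}: no gene sets found")
    universe = sorted(set().union(*members))
    if not universe:
        raise ValueError(f"{path}: every gene set is empty")
    pos = {f: k for k, f in enumerate(universe)}
    dense = np.zeros((len(universe), len(names)), dtype=np.uint8)
    for j, mset in enumerate(members):
        for f in mset:
            dense[pos[f], j] = 1
    return names, pack(dense, universe, names)


# ----------------------------------------------------------- binary container

def write_signatures(sig: SignatureMatrix, path) -> None:
    sig.validate()
    ids = json.dumps(
        {"feature_ids": sig.feature_ids, "signature_ids": sig.signature_ids}
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, sig.K, sig.N, sig.W))
        fh.write(np.ascontiguousarray(sig.words.T, dtype="<u8").tobytes())
        fh.write(struct.pack("<Q", len(ids)))
        fh.write(ids)

def read_signatures(path) -> SignatureMatrix:
    with open(path, "rb") as fh:
        magic, version, K, N, W = _HEADER.unpack(fh.read(_HEADER.size))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a signature container (bad magic)")
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported container version {version}")
        words = np.frombuffer(fh.read(8 * W * N), dtype="<u8").reshape(N, W).T
        (id_len,) = struct.unpack("<Q", fh.read(8))
        ids = json.loads(fh.read(id_len).decode())
    return SignatureMatrix(  # __post_init__ re-checks the padding invariant
        words=words.astype(np.uint64),
        feature_ids=ids["feature_ids"],
        signature_ids=ids["signature_ids"],
        K=int(K),
    )


# --------------------------------------------------------------- count tables

def write_counts_tsv(result: ComparisonResult, path, sparse: bool = True) -> None:
    """(query_id, library_id, count) rows; self-comparisons keep only i < j."""
    with open(path, "w") as fh:
        fh.write(f"# operator={result.operator}\tK={result.K}"
                 f"\tself={int(result.is_self)}\n")
        fh.write("query_id\tlibrary_id\tcount\n")
        for i, j, c in result.iter_pairs():
            if sparse and c == 0:
                continue
            fh.write(f"{result.query_ids[i]}\t{result.library_ids[j]}\t{c}\n")

def read_counts_tsv(path, query_ids=None, library_ids=None) -> ComparisonResult:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").strip().split("\t"))
        frame = pd.read_csv(fh, sep="\t", dtype={"count": np.uint32})
    frame["query_id"] = frame["query_id"].astype(str)
    frame["library_id"] = frame["library_id"].astype(str)
    qids = list(query_ids) if query_ids is not None else sorted(
        set(frame["query_id"]) | set(frame["library_id"])
    )
    lids = list(library_ids) if library_ids is not None else qids
    qpos = {q: i for i, q in enumerate(qids)}
    lpos = {l: j for j, l in enumerate(lids)}
    counts = np.zeros((len(qids), len(lids)), dtype=np.uint32)
    for q, l, c in frame.itertuples(index=False):
        counts[qpos[q], lpos[l]] = c
    is_self = bool(int(meta.get("self", 0)))
    if is_self:
        # each unordered pair is stored once; re-normalize to the strictly
        # upper triangle under this reader's id ordering
        counts = np.triu(counts + counts.T, k=1).astype(np.uint32)
    return ComparisonResult(
        query_ids=qids, library_ids=lids, counts=counts,
        operator=meta["operator"], K=int(meta["K"]),
        is_self=is_self,
    )


# ---------------------------------------------------------------- edge tables

def write_edge_table(table: EdgeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in table.edges:
            fh.write(f"{i}\t{j}\t{w}\n")

def read_edge_table(path) -> EdgeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"node_i": str, "node_j": str})
    edges = [(i, j, int(w)) for i, j, w in frame.itertuples(index=False)]
    return EdgeTable(edges=edges)

def write_graphml(table: EdgeTable, path) -> None:
    nx.write_graphml(table.to_networkx(), path)


# ------------------------------------------------------------------- taxonomy

def read_taxonomy(path) -> TaxonomyLabels:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyLabels(frame)

def write_taxonomy(labels: TaxonomyLabels, path) -> None:
    labels.table.rename_axis("genome").to_csv(path, sep="\t")


# -------------------------------------------------------------- refined pairs

def write_refined_pairs(refined: RefinedPairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tlibrary_id\tfilter_count\tmetric\tvalue\n")
        for i, j, c, v in refined.pairs:
            qid = refined.query_ids[i] if refined.query_ids else i
            lid = refined.library_ids[j] if refined.library_ids else j
            fh.write(f"{qid}\t{lid}\t{c}\t{refined.metric}\t{FLOAT_FMT % v}\n")


# ------------------------------------------------------------------- manifest

def write_manifest(path, **entries) -> None:
    """JSON run manifest (command, parameters, outputs) for provenance."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")

def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
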