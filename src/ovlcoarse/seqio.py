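"""Readers and writers for reads, overlap tables, and hierarchy levels.

Sequence input goes through Biopython's SeqIO; all other formats are small
flat TSV files designed for bit-exact round trips.  Read identifiers are
internal integers 0..n_reads-1 assigned in file order; they correspond
one-to-one with the node labels of the level-0 overlap graph.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

_VALID = set("ACGTN")


@dataclass
class ReadSet:
    """A set of reads with integer ids and optional ground-truth labels.

    ``sequences[i]`` is the uppercase sequence of internal read id ``i``;
    ``ids[i]`` is the external name; ``labels[i]``, when present, is the
    source-genome identifier used for evaluation.
    """

    sequences: list[str]
    ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if self.labels is not None and len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences must have equal length")
        for i, s in enumerate(self.sequences):
            if not s:
                raise ValueError(f"read {i} is empty")

    @property
    def n_reads(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=np.int64)


@dataclass(frozen=True)
class OverlapRecord:
    query_id: int
    ref_id: int
    alignment_length: int
    identity: float  # percent in [0, 100]


@dataclass
class OverlapTable:
    """Accepted pairwise overlaps; each unordered pair appears at most once."""

    records: list[OverlapRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for r in self.records:
            if r.query_id == r.ref_id:
                raise ValueError(f"self-overlap for read {r.query_id}")
            if r.alignment_length < 1:
                raise ValueError("alignment_length must be >= 1")
            key = (min(r.query_id, r.ref_id), max(r.query_id, r.ref_id))
            if key in seen:
                raise ValueError(f"duplicate overlap pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _clean(seq: str) -> str:
    s = seq.upper()
    if set(s) - _VALID:
        # ambiguity codes other than N are collapsed to N
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_sequences(path: str | os.PathLike, format: str = "fasta") -> ReadSet:
    """Load reads from FASTA/FASTQ; ids are assigned 0,1,2,... in file order.

    Malformed records raise ``ValueError`` naming the record index; an empty
    file yields an empty ReadSet.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    sequences: list[str] = []
    names: list[str] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            seq = _clean(str(rec.seq))
            if not seq:
                raise ValueError(f"record {i} ({rec.id}) has an empty sequence")
            sequences.append(seq)
            names.append(rec.id)
    except ValueError as e:
        raise ValueError(f"parse error in {path} at record {len(sequences)}: {e}") from e
    if not sequences:
        return ReadSet(sequences=[], ids=[])
    return ReadSet(sequences=sequences, ids=names)


def write_sequences(reads: ReadSet, path: str | os.PathLike) -> None:
    """Write reads as plain FASTA (deterministic byte layout, one line per seq)."""
    with open(path, "w") as fh:
        for name, seq in zip(reads.ids, reads.sequences):
            fh.write(f">{name}\n{seq}\n")


def trim_low_quality_ends(read: str, qualities: Sequence[int], min_quality: int) -> str:
    """Trim both ends so the terminal bases have quality >= ``min_quality``.

    Interior bases are never touched; the result may be empty.  Qualities are
    Phred scores (FASTQ input is interpreted as Phred+33 upstream).
    """
    if len(qualities) != len(read):
        raise ValueError("qualities and read must have equal length")
    lo = 0
    hi = len(read)
    while lo < hi and qualities[lo] < min_quality:
        lo += 1
    while hi > lo and qualities[hi - 1] < min_quality:
        hi -= 1
    return read[lo:hi]


_OVL_HEADER = "#query_id\tref_id\talignment_length\tidentity"


def write_overlaps(table: OverlapTable, path: str | os.PathLike) -> None:
    """Write a 4-column TSV; identity serialized with 2 decimal places."""
    with open(path, "w") as fh:
        fh.write(_OVL_HEADER + "\n")
        for r in table.records:
            fh.write(f"{r.query_id}\t{r.ref_id}\t{r.alignment_length}\t{r.identity:.2f}\n")


def read_overlaps(path: str | os.PathLike) -> OverlapTable:
    records: list[OverlapRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                q, r = int(parts[0]), int(parts[1])
                length = int(parts[2])
                ident = float(parts[3])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed row: {e}") from e
            if q == r:
                raise ValueError(f"{path}:{ln}: query_id == ref_id ({q})")
            records.append(OverlapRecord(q, r, length, ident))
    return OverlapTable(records=records)


def write_truth(reads: ReadSet, path: str | os.PathLike) -> None:
    """Write the per-read ground-truth genome labels as a 2-column TSV."""
    if reads.labels is None:
        raise ValueError("ReadSet carries no truth labels")
    with open(path, "w") as fh:
        fh.write("#read_id\tgenome_id\n")
        for i, lab in enumerate(reads.labels):
            fh.write(f"{i}\t{lab}\n")


def read_truth(path: str | os.PathLike) -> list[str]:
    pairs: list[tuple[int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            pairs.append((int(parts[0]), parts[1]))
    pairs.sort()
    if [i for i, _ in pairs] != list(range(len(pairs))):
        raise ValueError(f"{path}: read ids are not a contiguous 0-based range")
    return [lab for _, lab in pairs]


# ---------------------------------------------------------------------------
# Hierarchy level persistence: one directory per level, flat TSV arrays.
# ---------------------------------------------------------------------------

def _level_dir(base: str | os.PathLike, i: int) -> str:
    return os.path.join(str(base), f"level_{i}")


def _write_int_array(path: str, arr: np.ndarray) -> None:
    np.savetxt(path, np.asarray(arr, dtype=np.int64), fmt="%d")


def _read_int_array(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing level file: {path}")
    arr = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return arr.reshape(-1)


def write_level(level, base_dir: str | os.PathLike, i: int) -> None:
    """Persist one coarsening level as a ``level_<i>/`` file group.

    The group holds the edge list (one row per unordered pair, weight and —
    at level 0 — identity), node_weights, edge_weights, and whichever of
    node_map / node_map_inverse the level carries.
    """
    d = _level_dir(base_dir, i)
    os.makedirs(d, exist_ok=True)
    g = level.graph
    with open(os.path.join(d, "edges.tsv"), "w") as fh:
        if g.identity is not None:
            fh.write("#src\tdst\tweight\tidentity\n")
        else:
            fh.write("#src\tdst\tweight\n")
        for u, v, w, ident in g.iter_edges(with_identity=True):
            if g.identity is not None:
                fh.write(f"{u}\t{v}\t{w}\t{ident:.2f}\n")
            else:
                fh.write(f"{u}\t{v}\t{w}\n")
    _write_int_array(os.path.join(d, "node_weights.tsv"), level.node_weights)
    _write_int_array(os.path.join(d, "edge_weights.tsv"), level.edge_weights)
    if level.node_map is not None:
        _write_int_array(os.path.join(d, "node_map.tsv"), level.node_map)
    if level.node_map_inverse is not None:
        _write_int_array(os.path.join(d, "node_map_inverse.tsv"), level.node_map_inverse)


def read_level(base_dir: str | os.PathLike, i: int):
    """Load one coarsening level written by :func:`write_level`."""
    from .coarsen import CoarseningLevel
    from .graph import OverlapGraph, build_graph_from_edges

    d = _level_dir(base_dir, i)
    edge_path = os.path.join(d, "edges.tsv")
    if not os.path.exists(edge_path):
        raise FileNotFoundError(f"missing level file: {edge_path}")
    nw = _read_int_array(os.path.join(d, "node_weights.tsv"))
    ew = _read_int_array(os.path.join(d, "edge_weights.tsv"))
    n = nw.size
    src, dst, w, ident = [], [], [], []
    has_ident = False
    with open(edge_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                has_ident = "identity" in line
                continue
            parts = line.split("\t")
            src.append(int(parts[0]))
            dst.append(int(parts[1]))
            w.append(int(parts[2]))
            if has_ident:
                ident.append(float(parts[3]))
    graph = build_graph_from_edges(
        n, src, dst, w, identity=ident if has_ident else None
    )
    node_map = None
    nm_path = os.path.join(d, "node_map.tsv")
    if os.path.exists(nm_path):
        node_map = _read_int_array(nm_path)
    nmi = None
    nmi_path = os.path.join(d, "node_map_inverse.tsv")
    if os.path.exists(nmi_path):
        nmi = _read_int_array(nmi_path)
        if nmi.size != 2 * n:
            raise ValueError(
                f"{nmi_path}: node_map_inverse has length {nmi.size}, expected {2 * n}"
            )
    return CoarseningLevel(
        graph=graph,
        node_weights=nw,
        edge_weights=ew,
        node_map=node_map,
        node_map_inverse=nmi,
    )
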