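from __future__ import annotations

import numpy as np
import pytest

from ovlcoarse.coarsen import CoarsenParams, coarsen
from ovlcoarse.graph import build_graph_from_edges
from ovlcoarse.seqio import ReadSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_reads(rng, n=10, min_len=40, max_len=120) -> ReadSet:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = []
    for _ in range(n):
        l = int(rng.integers(min_len, max_len + 1))
        seqs.append(rng.choice(bases, size=l).tobytes().decode())
    return ReadSet(sequences=seqs, ids=[f"r{i}" for i in range(n)])


def random_weighted_graph(rng, n_max=200, p=None, w_max=120):
    """Seeded Erdos-Renyi graph with random integer weights."""
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.02, 0.2))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < p
    src, dst = iu[0][mask], iu[1][mask]
    w = rng.integers(1, w_max + 1, size=src.size)
    return build_graph_from_edges(n, src, dst, w)


def random_hierarchy(rng, n_max=60, **params_kw):
    G = random_weighted_graph(rng, n_max=n_max)
    params = CoarsenParams(seed=int(rng.integers(0, 2**31 - 1)), **params_kw)
    return coarsen(G, params), params


def tiled_reads(rng, genome_length=2000, n_reads=50, read_length=100) -> ReadSet:
    """Error-free reads tiled evenly across a random genome."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = rng.choice(bases, size=genome_length).tobytes().decode()
    starts = np.linspace(0, genome_length - read_length, n_reads).round().astype(int)
    seqs = [genome[s : s + read_length] for s in starts]
    return ReadSet(sequences=seqs, ids=[f"t{i}" for i in range(n_reads)])
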