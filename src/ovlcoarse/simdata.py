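"""Synthetic metagenome generator with per-read ground truth.

Emulates a mixed bacterial community sequenced at a target fold-coverage:
several random reference genomes, optionally sharing homologous segments,
sampled either with fixed-length Illumina-like reads (100 bp) or
variable-length 454-like reads (Gaussian, ~400-470 bp mean), with i.i.d.
substitution errors.  Every read carries its source-genome label so that
downstream clustering can be scored by majority vote.

The error model is substitution-only; quality-profile effects and
homopolymer indels are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seqio import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G


@dataclass
class ReadLengthModel:
    """Fixed length (sd=0) or truncated-Gaussian length distribution."""

    mean: float = 100.0
    sd: float = 0.0
    min_length: int = 30

    @property
    def fixed(self) -> bool:
        return self.sd == 0.0


def illumina_lengths() -> ReadLengthModel:
    return ReadLengthModel(mean=100.0, sd=0.0)


def roche454_lengths(mean: float = 440.0, sd: float = 60.0) -> ReadLengthModel:
    return ReadLengthModel(mean=mean, sd=sd, min_length=50)


@dataclass
class MetagenomeSpec:
    """Design of one simulated metagenome.

    Defaults describe the standard study conditions used throughout the
    test-bed: four non-homologous 50 kb genomes sequenced with 100 bp reads
    at 15-fold coverage and a 0.5% substitution rate.
    """

    n_genomes: int = 4
    genome_length: Union[int, Sequence[int]] = 50_000
    homology_pairs: Sequence[tuple[int, int]] = ()
    shared_fraction: float = 0.1
    homology_divergence: float = 0.05
    coverage: float = 15.0
    read_length_model: ReadLengthModel = field(default_factory=illumina_lengths)
    substitution_rate: float = 0.005
    both_strands: bool = False
    seed: int = 0

    def lengths(self) -> list[int]:
        if isinstance(self.genome_length, int):
            return [self.genome_length] * self.n_genomes
        L = list(self.genome_length)
        if len(L) != self.n_genomes:
            raise ValueError("genome_length list must have n_genomes entries")
        return L

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        for a, b in self.homology_pairs:
            if not (0 <= a < self.n_genomes and 0 <= b < self.n_genomes) or a == b:
                raise ValueError(f"bad homology pair ({a}, {b})")
        if min(self.lengths()) < self.read_length_model.mean:
            raise ValueError("genome shorter than mean read length")


def apply_substitutions(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Replace each base independently with a different base at ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0 or not sequence:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        acgt = np.isin(arr[idx], _BASES)
        idx = idx[acgt]  # N and other codes are left untouched
        code = np.searchsorted(np.sort(_BASES), arr[idx])
        # map ACGT sort order back to 0..3 (sorted _BASES is already ACGT)
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode("ascii")


def _random_genome(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_genomes(spec: MetagenomeSpec) -> list[str]:
    """Generate the community's reference genomes, deterministic given seed.

    Genomes are i.i.d. uniform over A/C/G/T.  For each homology pair (i, j)
    a contiguous segment of length shared_fraction x genome_length is copied
    from genome i into genome j at the same coordinates, then the copy is
    mutated at ``homology_divergence`` — shared_fraction=1 with divergence 0
    yields identical genomes.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = spec.lengths()
    genomes = [_random_genome(L, rng) for L in lengths]
    for a, b in spec.homology_pairs:
        L = min(lengths[a], lengths[b])
        seg_len = int(round(spec.shared_fraction * L))
        if seg_len == 0:
            continue
        if seg_len > lengths[a] or seg_len > lengths[b]:
            raise ValueError("shared segment longer than genome")
        start = int(rng.integers(0, L - seg_len + 1))
        segment = genomes[a][start : start + seg_len]
        segment = apply_substitutions(segment, spec.homology_divergence, rng)
        genomes[b] = genomes[b][:start] + segment + genomes[b][start + seg_len :]
    return genomes


def _revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty_like(arr)
    for k, v in _COMP.items():
        out[arr == k] = v
    out[~np.isin(arr, list(_COMP))] = ord("N")
    return out[::-1].tobytes().decode("ascii")


def simulate_reads(genomes: Sequence[str], spec: MetagenomeSpec) -> ReadSet:
    """Sample labeled reads from each genome at the spec's fold-coverage.

    Per genome i the read count is n_i = floor(coverage * L_i / mean_length);
    start positions are uniform, lengths fixed or truncated-Gaussian, and
    substitution errors i.i.d. at ``substitution_rate``.  Deterministic given
    the spec seed.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    rng = np.random.default_rng(spec.seed + 1)
    model = spec.read_length_model
    sequences: list[str] = []
    names: list[str] = []
    labels: list[str] = []
    for gi, genome in enumerate(genomes):
        L = len(genome)
        n_i = int(np.floor(spec.coverage * L / model.mean))
        if model.fixed:
            read_lens = np.full(n_i, int(model.mean), dtype=np.int64)
        else:
            raw = rng.normal(model.mean, model.sd, size=n_i)
            read_lens = np.maximum(np.round(raw).astype(np.int64), model.min_length)
            read_lens = np.minimum(read_lens, L)
        if n_i and read_lens.max() > L:
            raise ValueError(f"read longer than genome {gi}")
        starts = rng.integers(0, L - read_lens + 1)
        if spec.both_strands:
            flip = rng.random(n_i) < 0.5
        else:
            flip = np.zeros(n_i, dtype=bool)
        for ri in range(n_i):
            s = int(starts[ri])
            seq = genome[s : s + int(read_lens[ri])]
            if flip[ri]:
                seq = _revcomp(seq)
            seq = apply_substitutions(seq, spec.substitution_rate, rng)
            sequences.append(seq)
            names.append(f"g{gi}_r{ri}")
            labels.append(f"genome_{gi}")
    return ReadSet(sequences=sequences, ids=names, labels=labels)


def simulate_metagenome(spec: MetagenomeSpec) -> ReadSet:
    """Convenience: genomes + reads in one call."""
    return simulate_reads(generate_genomes(spec), spec)
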