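"""Block partitioning and per-block Shannon entropy.

A genome of length ``L`` is subdivided into ``N = floor(L / B)`` consecutive,
non-overlapping blocks of exactly ``B`` nucleotides; the trailing remainder
(< B bases) is discarded and recorded. Each block's entropy is the plug-in
Shannon entropy (base 2) of its single-nucleotide composition,

    H(X_i) = - sum_b  (n_b / B) * log2(n_b / B),   b in {A, C, G, T},

which ranges from 0 bits (homopolymer block) to 2 bits (all four bases
equally frequent). Per-block GC fraction is computed alongside as a
diagnostic: under Chargaff's second parity rule (A≈T, C≈G within a strand)
block composition collapses to one degree of freedom and block entropy is a
deterministic function of GC, namely ``1 + h(gc)`` with ``h`` the binary
entropy function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sequence import GenomeSequence

#: Fixed alphabet order used for all count vectors.
ALPHABET = ("A", "C", "G", "T")

_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE_LUT[ord(_b)] = _i


class BlockingError(ValueError):
    """Raised when a genome cannot be partitioned as requested."""


@dataclass(frozen=True)
class BlockComposition:
    """Nucleotide counts of one block."""

    counts: Mapping[str, int]
    block_index: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_block(cls, block: str, block_index: int = 0) -> "BlockComposition":
        return cls(
            counts={b: block.count(b) for b in ALPHABET},
            block_index=block_index,
        )

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(b, 0) for b in ALPHABET], dtype=np.int64)


@dataclass(frozen=True)
class BlockEntropyProfile:
    """Ordered per-block entropies of one genome at block size B.

    ``entropies[i]`` is the Shannon entropy (bits) of block ``i``, which
    covers cleaned-sequence positions ``[i*B, (i+1)*B)`` (0-based,
    half-open). ``gc_fractions`` carries the matching per-block GC diagnostic.
    """

    genome_label: str
    block_size: int
    entropies: np.ndarray
    gc_fractions: np.ndarray
    discarded_tail: int
    n_blocks: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_blocks", len(self.entropies))
        if len(self.gc_fractions) != self.n_blocks:
            raise ValueError("entropies and gc_fractions length mismatch")

    def to_frame(self) -> pd.DataFrame:
        """One row per block: genome, block_index, start, end, entropy_bits, gc_fraction."""
        idx = np.arange(self.n_blocks)
        return pd.DataFrame(
            {
                "genome": self.genome_label,
                "block_index": idx,
                "start": idx * self.block_size,
                "end": (idx + 1) * self.block_size,
                "entropy_bits": self.entropies,
                "gc_fraction": self.gc_fractions,
            }
        )


class Partition(NamedTuple):
    blocks: list[str]
    discarded_tail: int


def block_partition(genome: GenomeSequence | str, block_size: int) -> Partition:
    """Split a genome into consecutive non-overlapping blocks of ``block_size`` bases.

    Returns the blocks in genome order together with the length of the
    discarded trailing remainder. Raises :class:`BlockingError` when the
    genome is shorter than one block or ``block_size < 2``.
    """
    seq = genome.residues if isinstance(genome, GenomeSequence) else genome
    if block_size < 2:
        raise BlockingError(f"block size must be >= 2, got {block_size}")
    n = len(seq) // block_size
    if n < 1:
        raise BlockingError(
            f"genome of length {len(seq)} is shorter than one block of {block_size}"
        )
    blocks = [seq[i * block_size : (i + 1) * block_size] for i in range(n)]
    return Partition(blocks=blocks, discarded_tail=len(seq) - n * block_size)


def _entropy_from_count_rows(counts: np.ndarray) -> np.ndarray:
    """Plug-in Shannon entropy (bits) for each row of a (n, 4) count array."""
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    logs = np.log2(p, out=np.zeros_like(p), where=p > 0)
    return -(p * logs).sum(axis=1) + 0.0  # +0.0 normalizes -0.0


def block_entropy(comp: BlockComposition | Mapping[str, int] | str) -> float:
    """Shannon entropy (bits) of one block's composition; 0 log 0 := 0.

    Accepts a :class:`BlockComposition`, a counts mapping, or the block
    string itself. 0 bits iff one base takes the whole block; 2 bits iff all
    four counts are equal.
    """
    if isinstance(comp, str):
        comp = BlockComposition.from_block(comp)
    elif isinstance(comp, Mapping):
        comp = BlockComposition(counts=dict(comp))
    vec = comp.count_vector()
    if vec.sum() == 0:
        raise ValueError("all-zero composition has no entropy")
    return float(_entropy_from_count_rows(vec[None, :])[0])


def block_gc(comp: BlockComposition | Mapping[str, int] | str) -> float:
    """GC fraction (C+G)/B of one block."""
    if isinstance(comp, str):
        comp = BlockComposition.from_block(comp)
    elif isinstance(comp, Mapping):
        comp = BlockComposition(counts=dict(comp))
    vec = comp.count_vector()
    total = vec.sum()
    if total == 0:
        raise ValueError("all-zero composition has no GC fraction")
    return float((vec[1] + vec[2]) / total)


def _encode(seq: str) -> np.ndarray:
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0][:5]})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return codes


def block_count_matrix(seq: str, block_size: int) -> np.ndarray:
    """(N, 4) matrix of per-block base counts in ALPHABET order (vectorized)."""
    codes = _encode(seq)
    n = len(codes) // block_size
    if n < 1:
        raise BlockingError(
            f"sequence of length {len(codes)} is shorter than one block of {block_size}"
        )
    tiles = codes[: n * block_size].reshape(n, block_size)
    counts = np.empty((n, 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = (tiles == k).sum(axis=1)
    return counts


def entropy_profile(genome: GenomeSequence, block_size: int) -> BlockEntropyProfile:
    """Compute the ordered per-block entropy (and GC) profile of a genome."""
    if block_size < 2:
        raise BlockingError(f"block size must be >= 2, got {block_size}")
    counts = block_count_matrix(genome.residues, block_size)
    n = counts.shape[0]
    return BlockEntropyProfile(
        genome_label=genome.label,
        block_size=block_size,
        entropies=_entropy_from_count_rows(counts),
        gc_fractions=(counts[:, 1] + counts[:, 2]) / block_size,
        discarded_tail=len(genome.residues) - n * block_size,
    )


def profiles_frame(profiles: Sequence[BlockEntropyProfile]) -> pd.DataFrame:
    """Concatenate several profiles into one long-form table."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
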