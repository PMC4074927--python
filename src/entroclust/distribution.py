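"""Block-entropy histograms and superinformation.

The block entropies of one genome are collected into ``M`` equally spaced
bins and normalized into a probability vector

    p_j = H_j / N,    j = 1..M,

where ``H_j`` counts blocks whose entropy falls in bin ``j`` and ``N`` is the
number of blocks. The Shannon entropy of that vector,

    H_s = - sum_j p_j log2 p_j,

is the *superinformation* — the entropy of the entropy histogram — and
measures how variable local entropy is along the genome. H_s depends on both
the block size ``B`` (the resolution of the local entropies) and the bin
count ``M``, so it is always reported together with ``(B, M)``.

The default binning spans the full possible range of four-letter block
entropy, [0, 2] bits, for every genome; a shared, fixed support is what makes
histograms of different genomes directly comparable by the Jensen-Shannon
machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import BlockEntropyProfile, entropy_profile
from .sequence import GenomeSequence


class BinningError(ValueError):
    """Raised for invalid bin schemes or out-of-range values."""


@dataclass(frozen=True)
class BinningScheme:
    """``n_bins`` equally spaced bins over [lower, upper] bits.

    Bins are left-closed right-open except the last, which is closed on both
    sides so the maximal value (2.0 bits by default) is counted.
    """

    n_bins: int
    lower: float = 0.0
    upper: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise BinningError(f"need at least 2 bins, got {self.n_bins}")
        if not self.lower < self.upper:
            raise BinningError(f"degenerate bin range [{self.lower}, {self.upper}]")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_bins + 1)

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_bins


def make_binning(n_bins: int, lower: float = 0.0, upper: float = 2.0) -> BinningScheme:
    """Construct an equally spaced binning scheme (default support [0, 2] bits)."""
    return BinningScheme(n_bins=n_bins, lower=lower, upper=upper)


@dataclass(frozen=True)
class EntropyDistribution:
    """Normalized histogram of one genome's block entropies on a fixed binning."""

    genome_label: str
    scheme: BinningScheme
    counts: np.ndarray
    n_blocks: int
    block_size: int

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.n_blocks

    def same_scheme(self, other: "EntropyDistribution") -> bool:
        s, o = self.scheme, other.scheme
        return s.n_bins == o.n_bins and s.lower == o.lower and s.upper == o.upper

    def to_frame(self) -> pd.DataFrame:
        """Long-form export: one row per bin with count, probability and density."""
        edges = self.scheme.edges
        p = self.probs
        return pd.DataFrame(
            {
                "genome": self.genome_label,
                "B": self.block_size,
                "M": self.scheme.n_bins,
                "bin_lower": edges[:-1],
                "bin_upper": edges[1:],
                "count": self.counts,
                "probability": p,
                "density": p / self.scheme.bin_width,
            }
        )


def histogram_entropies(
    profile: BlockEntropyProfile, scheme: BinningScheme
) -> EntropyDistribution:
    """Bin a block-entropy profile into a normalized distribution.

    Every entropy must lie within the scheme's range; values outside signal a
    user-supplied range narrower than [0, 2] and raise :class:`BinningError`
    rather than being silently dropped.
    """
    h = np.asarray(profile.entropies, dtype=float)
    if h.size == 0:
        raise BinningError("empty entropy profile")
    if h.min() < scheme.lower or h.max() > scheme.upper:
        raise BinningError(
            f"entropies span [{h.min():.6f}, {h.max():.6f}] outside binning range "
            f"[{scheme.lower}, {scheme.upper}]"
        )
    counts, _ = np.histogram(h, bins=scheme.edges)
    return EntropyDistribution(
        genome_label=profile.genome_label,
        scheme=scheme,
        counts=counts.astype(np.int64),
        n_blocks=profile.n_blocks,
        block_size=profile.block_size,
    )


def superinformation(dist: EntropyDistribution | np.ndarray, atol: float = 1e-9) -> float:
    """Entropy of the entropy histogram, H_s = -sum_j p_j log2 p_j (bits).

    Accepts an :class:`EntropyDistribution` or a bare probability vector.
    Bounded by ``log2 M``; zero iff exactly one bin is occupied.
    """
    p = dist.probs if isinstance(dist, EntropyDistribution) else np.asarray(dist, dtype=float)
    if p.ndim != 1 or (p < 0).any():
        raise ValueError("probability vector must be 1-D and non-negative")
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"probabilities sum to {total!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)


@dataclass(frozen=True)
class SweepRow:
    """One block size of a sensitivity sweep."""

    block_size: int
    distribution: EntropyDistribution
    superinfo: float


def sensitivity_sweep(
    genome: GenomeSequence,
    block_sizes: Sequence[int],
    scheme: BinningScheme,
) -> list[SweepRow]:
    """Recompute the distribution and H_s of one genome at several block sizes.

    Each block size is processed independently on the same cleaned genome;
    use :func:`sweep_frame` for the tabular view including the stability
    diagnostic |H_s(B_k) - H_s(B_{k+1})| between consecutive block sizes.
    """
    if not block_sizes:
        raise ValueError("block_sizes must be non-empty")
    rows = []
    for b in block_sizes:
        dist = histogram_entropies(entropy_profile(genome, b), scheme)
        rows.append(SweepRow(block_size=b, distribution=dist, superinfo=superinformation(dist)))
    return rows


def sweep_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Tabulate a sweep: B, N, H_s, and |ΔH_s| to the next block size."""
    hs = [r.superinfo for r in rows]
    deltas = [abs(hs[i + 1] - hs[i]) for i in range(len(hs) - 1)] + [np.nan]
    return pd.DataFrame(
        {
            "B": [r.block_size for r in rows],
            "M": [r.distribution.scheme.n_bins for r in rows],
            "n_blocks": [r.distribution.n_blocks for r in rows],
            "H_s_bits": hs,
            "abs_delta_H_s_next": deltas,
        }
    )


def superinfo_frame(dists: Sequence[EntropyDistribution]) -> pd.DataFrame:
    """Superinformation report: one row per genome with its (B, M) context."""
    return pd.DataFrame(
        {
            "genome": [d.genome_label for d in dists],
            "B": [d.block_size for d in dists],
            "M": [d.scheme.n_bins for d in dists],
            "n_blocks": [d.n_blocks for d in dists],
            "H_s_bits": [superinformation(d) for d in dists],
        }
    )
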