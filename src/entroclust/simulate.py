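"""Synthetic genomes with controlled along-sequence composition variability.

The comparison method only sees single-nucleotide block composition, so the
generator emulates exactly that degree of freedom: a genome is a chain of
segments, each segment drawing a fresh GC fraction from a configurable regime
and then emitting bases i.i.d. Segments with a fixed GC value produce narrow,
unimodal block-entropy histograms (virus-like); regimes that spread GC widely
(a beta distribution, or a two-point mixture of distinct GC levels) produce
broad or multimodal histograms (plant-like), because block entropy is a
deterministic function of composition.

All randomness is explicit: every genome carries a mandatory integer seed,
and cohorts derive per-genome seeds from (master seed, group index, genome
index) via numpy's SeedSequence so any single genome is regenerable in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence import GenomeSequence, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Raised for invalid regime or spec parameters."""


@dataclass(frozen=True)
class CompositionRegime:
    """How the per-segment GC fraction is drawn.

    kind:
        ``fixed`` — constant ``gc``;
        ``beta`` — gc ~ Beta(alpha, beta), a wide-spread "organism-like" regime;
        ``two_point`` — gc1 with probability ``weight``, else gc2 (isochore-like
        alternation between two composition levels).
    at_skew / cg_skew:
        Within-pair imbalance in [-1, 1]: p(A) = (1-gc)/2 * (1+at_skew),
        p(T) = (1-gc)/2 * (1-at_skew), and likewise C vs G with cg_skew.
        Zero skews give exact Chargaff parity.
    """

    name: str
    kind: str
    gc: float = 0.5
    alpha: float = 2.0
    beta: float = 2.0
    gc1: float = 0.35
    gc2: float = 0.65
    weight: float = 0.5
    at_skew: float = 0.0
    cg_skew: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta", "two_point"):
            raise SimulationError(f"unknown regime kind {self.kind!r}")
        for s in (self.at_skew, self.cg_skew):
            if not -1.0 <= s <= 1.0:
                raise SimulationError(f"skew {s} outside [-1, 1]")
        for g in self._gc_support():
            if not 0.0 <= g <= 1.0:
                raise SimulationError(f"gc value {g} outside [0, 1]")
        if not 0.0 <= self.weight <= 1.0:
            raise SimulationError(f"mixture weight {self.weight} outside [0, 1]")

    def _gc_support(self) -> tuple[float, ...]:
        if self.kind == "fixed":
            return (self.gc,)
        if self.kind == "two_point":
            return (self.gc1, self.gc2)
        return ()

    def mean_gc(self) -> float:
        """Expected GC fraction under the regime."""
        if self.kind == "fixed":
            return self.gc
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta)
        return self.weight * self.gc1 + (1 - self.weight) * self.gc2

    def draw_gc(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.gc)
        if self.kind == "beta":
            return rng.beta(self.alpha, self.beta, size=n)
        pick = rng.random(n) < self.weight
        return np.where(pick, self.gc1, self.gc2)

    def describe(self) -> str:
        if self.kind == "fixed":
            core = f"fixed:gc={self.gc}"
        elif self.kind == "beta":
            core = f"beta:alpha={self.alpha},beta={self.beta}"
        else:
            core = f"two_point:gc1={self.gc1},gc2={self.gc2},weight={self.weight}"
        if self.at_skew or self.cg_skew:
            core += f",at_skew={self.at_skew},cg_skew={self.cg_skew}"
        return core


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for one synthetic genome; ``seed`` is mandatory."""

    label: str
    length: int
    regime: CompositionRegime
    seed: int
    segment_length: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.segment_length <= self.length:
            raise SimulationError(
                f"need length >= segment_length >= 1, got {self.length}, {self.segment_length}"
            )


def _base_probs(gc: np.ndarray, regime: CompositionRegime) -> np.ndarray:
    """(n_segments, 4) base probabilities in A,C,G,T order for each segment."""
    half_gc = gc / 2.0
    half_at = (1.0 - gc) / 2.0
    probs = np.column_stack(
        [
            half_at * (1 + regime.at_skew),
            half_gc * (1 + regime.cg_skew),
            half_gc * (1 - regime.cg_skew),
            half_at * (1 - regime.at_skew),
        ]
    )
    if (probs < 0).any() or (probs > 1).any():
        raise SimulationError("skew/gc combination yields invalid base probabilities")
    return probs


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeSequence:
    """Generate one genome; identical spec (incl. seed) gives identical bases."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_seg = -(-spec.length // spec.segment_length)  # ceil
    gc = spec.regime.draw_gc(rng, n_seg)
    probs = _base_probs(gc, spec.regime)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0  # guard float round-off at the top edge
    seg_of_pos = np.arange(spec.length) // spec.segment_length
    u = rng.random(spec.length)
    codes = (u[:, None] > cum[seg_of_pos]).sum(axis=1)
    residues = _BASES[codes].tobytes().decode("ascii")
    return GenomeSequence(
        label=spec.label,
        residues=residues,
        source_length=spec.length,
        removed_count=0,
    )


def derive_seed(master_seed: int, group_index: int, genome_index: int) -> int:
    """Per-genome seed: first 32-bit state word of SeedSequence(master, (g, i)).

    Documented so any single cohort genome can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index, genome_index))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: n_genomes drawn from a shared regime."""

    name: str
    regime: CompositionRegime
    n_genomes: int
    length: int
    segment_length: int = 1000


def generate_cohort(
    groups: Sequence[GroupSpec | tuple], seed: int
) -> list[tuple[GenomeSequence, str]]:
    """Generate a labeled multi-group cohort of synthetic genomes.

    Returns (genome, group_name) pairs. Per-genome seeds come from
    :func:`derive_seed`, so the cohort is reproducible as a whole and each
    member individually.
    """
    specs = [g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in groups]
    if len(specs) < 2:
        raise SimulationError("a cohort needs at least 2 groups")
    if any(g.n_genomes < 2 for g in specs):
        raise SimulationError("each group needs at least 2 genomes")
    out: list[tuple[GenomeSequence, str]] = []
    for gi, grp in enumerate(specs):
        for gj in range(grp.n_genomes):
            gspec = SyntheticGenomeSpec(
                label=f"{grp.name}_{gj:02d}",
                length=grp.length,
                regime=grp.regime,
                seed=derive_seed(seed, gi, gj),
                segment_length=grp.segment_length,
            )
            out.append((generate_genome(gspec), grp.name))
    labels = [g.label for g, _ in out]
    if len(set(labels)) != len(labels):
        raise SimulationError("duplicate genome labels across groups; use distinct group names")
    return out


def write_cohort(
    cohort: Sequence[tuple[GenomeSequence, str]],
    out_dir: str | Path,
    groups: Sequence[GroupSpec] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write one FASTA per genome plus a manifest TSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_name = {g.name: g for g in groups} if groups else {}
    rows = []
    for gi_genome, group_name in cohort:
        write_fasta(gi_genome, out_dir / f"{gi_genome.label}.fasta")
        grp = by_name.get(group_name)
        rows.append(
            {
                "label": gi_genome.label,
                "group": group_name,
                "length": len(gi_genome),
                "regime": grp.regime.describe() if grp else "",
                "master_seed": seed if seed is not None else "",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def parse_regime(text: str, name: str = "") -> CompositionRegime:
    """Parse a compact regime string, e.g. ``fixed:0.5``, ``beta:2,2``,
    ``two_point:0.35,0.65,0.5``."""
    kind, _, rest = text.partition(":")
    vals = [float(x) for x in rest.split(",")] if rest else []
    name = name or text
    if kind == "fixed":
        return CompositionRegime(name=name, kind="fixed", gc=vals[0] if vals else 0.5)
    if kind == "beta":
        a, b = (vals + [2.0, 2.0])[:2]
        return CompositionRegime(name=name, kind="beta", alpha=a, beta=b)
    if kind == "two_point":
        g1, g2, w = (vals + [0.35, 0.65, 0.5])[:3]
        return CompositionRegime(name=name, kind="two_point", gc1=g1, gc2=g2, weight=w)
    raise SimulationError(f"cannot parse regime {text!r}")
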