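"""Reading, validating and cleaning DNA sequences.

A genome enters the pipeline as a :class:`GenomeSequence`: a labeled string
over the strict four-letter alphabet ``{A, C, G, T}``. Everything else
(ambiguity codes, gaps, whitespace) is stripped before blocking so that every
block later contains exactly ``B`` informative bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

# uppercase a/c/g/t, pass ACGT through; everything else maps to None (deleted)
_CLEAN_TABLE = {ord(c): ord(c.upper()) for c in "acgt"}
_CLEAN_TABLE.update({ord(c): ord(c) for c in "ACGT"})


class SequenceError(ValueError):
    """Raised for unusable sequence input (empty, unparseable, no valid bases)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A cleaned DNA sequence: the unit of comparison.

    Attributes
    ----------
    label:
        Non-empty identifier, unique within one analysis run.
    residues:
        Sequence string containing only A, C, G, T.
    source_length:
        Number of characters read before cleaning.
    removed_count:
        Number of characters deleted by cleaning; always
        ``len(residues) + removed_count == source_length``.
    """

    label: str
    residues: str
    source_length: int
    removed_count: int

    def __post_init__(self) -> None:
        if not self.label:
            raise SequenceError("genome label must be non-empty")
        if len(self.residues) + self.removed_count != self.source_length:
            raise SequenceError("inconsistent length bookkeeping")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gc_fraction(self) -> float:
        """Overall G+C fraction of the cleaned sequence."""
        gc = self.residues.count("G") + self.residues.count("C")
        return gc / len(self.residues)


def clean_sequence(raw: str, label: str = "seq") -> GenomeSequence:
    """Uppercase a/c/g/t and delete every character outside {A,C,G,T}.

    Deleted characters (N runs, IUPAC ambiguity codes, gaps, whitespace) are
    counted in ``removed_count``. Raises :class:`SequenceError` if nothing
    survives cleaning.
    """
    if not raw:
        raise SequenceError("empty input sequence")
    cleaned = raw.translate(_CLEAN_TABLE)
    # translate() uppercased but did not delete; filter in one pass
    kept = "".join(c for c in cleaned if c in VALID_BASES)
    if not kept:
        raise SequenceError(f"no valid A/C/G/T bases in input for {label!r}")
    return GenomeSequence(
        label=label,
        residues=kept,
        source_length=len(raw),
        removed_count=len(raw) - len(kept),
    )


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, combine: bool = True) -> list[GenomeSequence]:
    """Read one FASTA file into :class:`GenomeSequence` records.

    With ``combine=True`` (default) all records in the file are concatenated
    in file order into a single genome labeled by the file stem — the natural
    treatment for multi-chromosome assemblies analyzed as one entity. With
    ``combine=False`` each record becomes its own genome labeled by the first
    word of its header. Cleaning is applied after concatenation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_maybe_gzip(path) as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    records = [(rid, seq) for rid, seq in records if seq]
    if not records:
        raise SequenceError(f"no parseable FASTA records with sequence in {path}")
    if combine:
        stem = path.name
        for ext in (".gz", ".fasta", ".fa", ".fna"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
        raw = "".join(seq for _, seq in records)
        return [clean_sequence(raw, label=stem)]
    out = []
    for rid, seq in records:
        out.append(clean_sequence(seq, label=rid))
    labels = [g.label for g in out]
    if len(set(labels)) != len(labels):
        raise SequenceError(f"duplicate record labels in {path}")
    return out


def read_many(paths: Sequence[str | Path], combine: bool = True) -> list[GenomeSequence]:
    """Read several FASTA files, enforcing label uniqueness across the run."""
    genomes: list[GenomeSequence] = []
    for p in paths:
        genomes.extend(read_fasta(p, combine=combine))
    labels = [g.label for g in genomes]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SequenceError(f"duplicate genome labels across inputs: {dupes}")
    return genomes


def write_fasta(genomes: GenomeSequence | Sequence[GenomeSequence], path: str | Path, width: int = 70) -> None:
    """Write genomes to a FASTA file with fixed line width."""
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    path = Path(path)
    with open(path, "wt") as fh:
        for g in genomes:
            fh.write(f">{g.label}\n")
            for i in range(0, len(g.residues), width):
                fh.write(g.residues[i : i + width] + "\n")


def iter_fasta_labels(path: str | Path) -> Iterator[str]:
    """Yield record ids of a FASTA file without loading sequences."""
    with _open_maybe_gzip(Path(path)) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id
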