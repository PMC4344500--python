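"""Circular mitochondrial reference model and shared coordinate conventions.

The human mitochondrial genome is a 16,569 bp circular molecule; all
coordinates in this package are 1-based, fully closed intervals in the rCRS
convention.  Features that wrap the replication origin (the D-loop control
region) are stored as two intervals sharing one feature name.

The module also carries the phred-quality arithmetic shared by the read
filters: a phred score ``Q`` corresponds to a per-base error probability of
``10**(-Q/10)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "GeneFeature",
    "GeneMap",
    "ReferenceFormatError",
    "CoordinateError",
    "load_reference",
    "load_gene_map",
    "load_bundled_reference",
    "load_bundled_gene_map",
    "annotate_position",
    "phred_to_error",
    "revcomp",
]

_VALID_BASES = frozenset("ACGT")
FEATURE_CLASSES = ("protein", "tRNA", "rRNA", "D-loop")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceFormatError(ValueError):
    """Raised for FASTA input that cannot serve as an mtDNA reference."""


class CoordinateError(ValueError):
    """Raised for positions outside the 1-based reference coordinate range."""


def revcomp(sequence: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """A single circular (or linear) reference sequence over {A,C,G,T}."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceFormatError("empty reference sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceFormatError(
                f"non-ACGT characters in reference {self.name!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise CoordinateError(
                f"position {pos} outside [1, {self.length}] on {self.name!r}"
            )

    def base(self, pos: int) -> str:
        """Base at a 1-based position."""
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def fetch(self, start: int, length: int) -> str:
        """Fetch ``length`` bases starting at 1-based ``start``.

        On a circular reference the fetch may wrap the origin; ``length``
        must not exceed the genome length.
        """
        self._check_pos(start)
        if length < 0 or length > self.length:
            raise CoordinateError(f"fetch length {length} outside [0, {self.length}]")
        if start - 1 + length <= self.length:
            return self.sequence[start - 1 : start - 1 + length]
        if not self.circular:
            raise CoordinateError("fetch runs past the end of a linear reference")
        return (self.sequence + self.sequence)[start - 1 : start - 1 + length]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated interval: 1-based closed [start, end] on a strand."""

    name: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"feature {self.name!r} has invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name!r} strand must be '+' or '-'")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.name!r} class {self.feature_class!r} not one of {FEATURE_CLASSES}"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class GeneMap:
    """Gene annotation for one reference.

    Overlapping entries are permitted (ATP8/ATP6 overlap on the heavy
    strand); origin-wrapping features appear as two entries with the same
    name.
    """

    entries: tuple[GeneFeature, ...]
    reference_length: int

    def __post_init__(self) -> None:
        for f in self.entries:
            if f.end > self.reference_length:
                raise CoordinateError(
                    f"feature {f.name!r} end {f.end} exceeds reference length "
                    f"{self.reference_length}"
                )

    def annotate_position(self, pos: int) -> list[str]:
        """Names of every feature whose interval contains ``pos`` (1-based).

        Duplicate names (origin-wrapping features stored as two intervals)
        are reported once; order follows the map.
        """
        if not 1 <= pos <= self.reference_length:
            raise CoordinateError(
                f"position {pos} outside [1, {self.reference_length}]"
            )
        seen: list[str] = []
        for f in self.entries:
            if f.contains(pos) and f.name not in seen:
                seen.append(f.name)
        return seen


def annotate_position(pos: int, gene_map: GeneMap) -> list[str]:
    """Functional form of :meth:`GeneMap.annotate_position`."""
    return gene_map.annotate_position(pos)


def load_reference(path: str | Path, circular: bool = True) -> ReferenceGenome:
    """Load a single-record A/C/G/T FASTA as a (circular) reference.

    Raises :class:`ReferenceFormatError` for empty files, multi-record
    files, or sequences containing ambiguity codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceFormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ReferenceFormatError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_reference(ref: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    """Write a reference as single-record FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, width):
            fh.write(ref.sequence[i : i + width] + "\n")


def load_gene_map(path: str | Path, reference_length: int) -> GeneMap:
    """Read a gene map from a tab-separated file.

    Columns: gene, start, end, strand, class; '#' lines are comments.
    """
    entries: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end, strand, cls = line.split("\t")
            entries.append(GeneFeature(name, int(start), int(end), strand, cls))
    return GeneMap(entries=tuple(entries), reference_length=reference_length)


_DATA = resources.files("heteroseek.data")


def load_bundled_reference() -> ReferenceGenome:
    """The bundled synthetic 16,569 bp circular reference.

    A stand-in with the rCRS length and coordinate system but a randomly
    generated sequence; it carries no real human variation.
    """
    with resources.as_file(_DATA / "synthetic_rcrs_like.fa") as p:
        return load_reference(p, circular=True)


def load_bundled_gene_map(reference_length: int = 16569) -> GeneMap:
    """The bundled rCRS-style gene map (13 protein genes, 22 tRNA, 2 rRNA,
    D-loop).

    Coordinates follow the standard rCRS annotation; the map is versioned
    configuration, not ground truth.
    """
    with resources.as_file(_DATA / "mt_gene_map.tsv") as p:
        return load_gene_map(p, reference_length=reference_length)


def phred_to_error(q: float) -> float:
    """Error probability ``10**(-Q/10)`` for a phred score Q >= 0."""
    if q < 0:
        raise ValueError(f"phred score must be >= 0, got {q}")
    return float(10.0 ** (-q / 10.0))
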