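"""Front half of the analysis: quality filtering, mapping to the circular
reference, clonal collapse, coverage and nuclear-contamination estimation.

The filter conventions:

* a read is eliminated if it carries a run of more than 10 consecutive
  bases with Q < 20;
* identical reads are clonal library duplicates and are counted once,
  irrespective of copy number;
* nuclear contamination is estimated from reads recognized as LINE/SINE-like
  repeat sequence, which occurs only in nDNA: the repeat-read share of all
  mapped reads divided by the repeat fraction of the nuclear genome.

The mapper here is deliberately simple plumbing — exact k-mer seeding
against the doubled circular reference, extension by mismatch counting —
standing in for a production short-read aligner.  It natively reports
alignments that wrap the origin as a single record.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

import numpy as np

from .refmodel import ReferenceGenome, revcomp

__all__ = [
    "Read",
    "Alignment",
    "CoverageProfile",
    "RepeatCatalog",
    "ReadMapper",
    "UndefinedEstimatorError",
    "quality_filter",
    "map_reads",
    "collapse_clonal",
    "estimate_ndna_fraction",
    "mean_coverage",
]

logger = logging.getLogger(__name__)


class UndefinedEstimatorError(ValueError):
    """Raised when the nDNA estimator is requested with repeat_fraction == 0."""


@dataclass
class Read:
    """A sequencing read: id, bases and per-base phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class Alignment:
    """Placement of a read.

    ``ref_start`` is 1-based in the coordinates of the genome named by
    ``maps_to`` (mtDNA alignments may wrap the circular origin); it is None
    for unmapped and repeat-labeled reads.  ``mismatches`` holds read
    offsets in reference orientation.
    """

    read_id: str
    maps_to: str  # 'mtDNA' | 'nuclear-repeat' | 'nuclear-other' | 'unmapped'
    ref_start: int | None = None
    strand: str | None = None
    matched_length: int = 0
    mismatches: tuple[int, ...] = ()


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position depth over the circular reference."""

    depth: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.depth.mean())


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def quality_filter(
    reads: Sequence[Read], min_quality: int = 20, max_run: int = 10
) -> tuple[list[Read], int]:
    """Drop reads with a run of more than ``max_run`` bases below ``min_quality``.

    The boundary is strict: a run of exactly ``max_run`` low-quality bases is
    kept. Order is preserved; the filter is idempotent.
    """
    kept: list[Read] = []
    removed = 0
    for r in reads:
        if _longest_run(np.asarray(r.qualities) < min_quality) > max_run:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


class RepeatCatalog:
    """Recognizer for nuclear repeat-family reads plus an optional nuclear
    genome for placing the remaining nDNA reads.

    A read is labeled as repeat-derived when at least half of it is an exact
    match to a family motif (detected as a run of consecutive matching
    ``kmer``-mers).  The half-read rule makes the repeat-read probability of
    a uniformly drawn nuclear read equal to the genomic repeat fraction,
    which keeps the contamination estimator unbiased at tract boundaries.
    """

    def __init__(
        self,
        motifs: dict[str, str] | None = None,
        nuclear_sequence: str | None = None,
        kmer: int = 25,
    ) -> None:
        if motifs is None:
            from .synthetic_data import REPEAT_MOTIFS

            motifs = REPEAT_MOTIFS
        self.kmer = kmer
        self._family_kmers: dict[str, set[str]] = {}
        for family, motif in motifs.items():
            tiled = motif + motif  # cover the tiling junction
            kmers = {tiled[i : i + kmer] for i in range(len(tiled) - kmer + 1)}
            rc = revcomp(tiled)
            kmers |= {rc[i : i + kmer] for i in range(len(rc) - kmer + 1)}
            self._family_kmers[family] = kmers
        self.nuclear_sequence = nuclear_sequence

    @classmethod
    def from_background(cls, background, kmer: int = 25) -> "RepeatCatalog":
        """Catalog using the package's fixed family motifs and the background
        sequence for nuclear-other placement."""
        return cls(nuclear_sequence=background.sequence, kmer=kmer)

    def repeat_family(self, sequence: str) -> str | None:
        """Family name if >= half the read exactly matches a family motif."""
        n = len(sequence)
        k = self.kmer
        if n < k:
            return None
        probes = [sequence[p : p + k] for p in (n // 4, n // 2, min(3 * n // 4, n - k))]
        for family, kmers in self._family_kmers.items():
            if not any(p in kmers for p in probes):
                continue
            hits = np.fromiter(
                (sequence[i : i + k] in kmers for i in range(n - k + 1)),
                dtype=bool,
                count=n - k + 1,
            )
            # a run of s consecutive matching k-mers is an exact stretch of s+k-1 nt
            if _longest_run(hits) + k - 1 >= ceil(n / 2):
                return family
        return None


def _build_kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i : i + k]].append(i)
    return dict(index)


class ReadMapper:
    """Seed-and-extend mapper against the doubled circular mtDNA reference.

    Exact ``k``-mer seeds (default k=15) are looked up at stride ``k`` along
    the read on both strands; every candidate locus is scored by Hamming
    mismatches and the fewest-mismatch hit wins.  A hit is acceptable below
    a mismatch ceiling of ``max_mismatch_per_100`` per 100 nt (default 5,
    comfortably above the expectation for Q30 bases).  Ties across distinct
    loci — e.g. inside a zero-divergence Numt copy — are resolved in favor
    of the smallest mtDNA coordinate and counted in ``ambiguous_count``:
    the working premise is that nDNA depletion, not mapping, removes Numts,
    so ambiguity is reported rather than dropped.
    """

    def __init__(
        self,
        ref: ReferenceGenome,
        catalog: RepeatCatalog | None = None,
        k: int = 15,
        max_mismatch_per_100: float = 5.0,
    ) -> None:
        self.ref = ref
        self.catalog = catalog
        self.k = k
        self.max_mismatch_per_100 = max_mismatch_per_100
        L = ref.length
        doubled = ref.sequence + ref.sequence
        self._arr = np.frombuffer(doubled.encode(), dtype=np.uint8)
        # index k-mers starting in [0, L): every circular start exactly once
        self._index = _build_kmer_index(doubled[: L + k - 1], k)
        self._nuc_arr: np.ndarray | None = None
        self._nuc_index: dict[str, list[int]] | None = None
        if catalog is not None and catalog.nuclear_sequence is not None:
            self._nuc_arr = np.frombuffer(catalog.nuclear_sequence.encode(), dtype=np.uint8)
            self._nuc_index = _build_kmer_index(catalog.nuclear_sequence, k)
        self.ambiguous_count = 0

    def _candidates(
        self, seq: str, index: dict[str, list[int]], modulus: int | None
    ) -> set[int]:
        k = self.k
        cands: set[int] = set()
        for off in range(0, len(seq) - k + 1, k):
            for hit in index.get(seq[off : off + k], ()):
                start = hit - off
                if modulus is not None:
                    start %= modulus
                cands.add(start)
        return cands

    def _best_hit(
        self, oriented: np.ndarray, cands: Iterable[int], arr: np.ndarray, limit: int
    ) -> tuple[int | None, int, int]:
        """(best start, mismatch count, n tied loci) among candidate starts."""
        n = len(oriented)
        best_start: int | None = None
        best_mm = limit + 1
        ties = 1
        for c in sorted(cands):
            if c < 0 or c + n > len(arr):
                continue
            mm = int(np.count_nonzero(arr[c : c + n] != oriented))
            if mm < best_mm:
                best_start, best_mm, ties = c, mm, 1
            elif mm == best_mm and best_start is not None:
                ties += 1
        return best_start, best_mm, ties

    def map_read(self, read: Read) -> Alignment:
        seq = read.sequence
        n = len(seq)
        if self.catalog is not None:
            family = self.catalog.repeat_family(seq)
            if family is not None:
                return Alignment(read_id=read.id, maps_to="nuclear-repeat")
        limit = int(ceil(self.max_mismatch_per_100 * n / 100.0))
        L = self.ref.length
        best: tuple[int, str, int, np.ndarray] | None = None  # start, strand, mm, oriented
        best_ties = 1
        for strand, oriented_seq in (("+", seq), ("-", revcomp(seq))):
            cands = self._candidates(oriented_seq, self._index, L)
            if not cands:
                continue
            oriented = np.frombuffer(oriented_seq.encode(), dtype=np.uint8)
            start, mm, ties = self._best_hit(oriented, cands, self._arr, limit)
            if start is not None and mm <= limit and (best is None or mm < best[2]):
                best, best_ties = (start, strand, mm, oriented), ties
        if best is not None:
            start, strand, mm, oriented = best
            if best_ties > 1:
                self.ambiguous_count += 1
            mism = tuple(
                int(i) for i in np.flatnonzero(self._arr[start : start + n] != oriented)
            )
            return Alignment(
                read_id=read.id,
                maps_to="mtDNA",
                ref_start=start + 1,
                strand=strand,
                matched_length=n,
                mismatches=mism,
            )
        if self._nuc_index is not None:
            for strand, oriented_seq in (("+", seq), ("-", revcomp(seq))):
                cands = self._candidates(oriented_seq, self._nuc_index, None)
                if not cands:
                    continue
                oriented = np.frombuffer(oriented_seq.encode(), dtype=np.uint8)
                start, mm, _ = self._best_hit(oriented, cands, self._nuc_arr, limit)
                if start is not None and mm <= limit:
                    return Alignment(
                        read_id=read.id,
                        maps_to="nuclear-other",
                        ref_start=start + 1,
                        strand=strand,
                        matched_length=n,
                    )
        return Alignment(read_id=read.id, maps_to="unmapped")

    def map_reads(self, reads: Sequence[Read]) -> list[Alignment]:
        out = [self.map_read(r) for r in reads]
        if self.ambiguous_count:
            logger.info("mapping: %d reads had tied best loci (assigned to mtDNA)",
                        self.ambiguous_count)
        return out


def map_reads(
    reads: Sequence[Read],
    ref: ReferenceGenome,
    catalog: RepeatCatalog | None = None,
    k: int = 15,
    max_mismatch_per_100: float = 5.0,
) -> list[Alignment]:
    """Convenience wrapper around :class:`ReadMapper`."""
    return ReadMapper(ref, catalog, k=k, max_mismatch_per_100=max_mismatch_per_100).map_reads(reads)


def collapse_clonal(
    alignments: Sequence[Alignment], reads: Sequence[Read]
) -> tuple[list[Alignment], int]:
    """Keep one representative per identical read sequence.

    Clonality is identical full sequence (not identical start coordinate):
    reverse-complement pairs are independent strand observations and are NOT
    collapsed.  The representative is the lexicographically smallest read id
    in each group, making the result invariant to input order; the output is
    sorted by read id.
    """
    seq_of = {r.id: r.sequence for r in reads}
    chosen: dict[str, str] = {}  # sequence -> read id
    for a in alignments:
        s = seq_of[a.read_id]
        if s not in chosen or a.read_id < chosen[s]:
            chosen[s] = a.read_id
    keep = set(chosen.values())
    kept = sorted((a for a in alignments if a.read_id in keep), key=lambda a: a.read_id)
    return kept, len(alignments) - len(kept)


def estimate_ndna_fraction(
    alignments: Sequence[Alignment], repeat_fraction: float
) -> float:
    """Nuclear contamination estimate from repeat-labeled reads.

    estimate = (repeat-labeled reads / total mapped reads) / repeat_fraction,
    clipped to [0, 1].  ``repeat_fraction`` is the fraction of the nuclear
    genome covered by LINE/SINE-like repeats.
    """
    if repeat_fraction <= 0:
        raise UndefinedEstimatorError(
            "nDNA estimator undefined for repeat_fraction <= 0"
        )
    mapped = [a for a in alignments if a.maps_to != "unmapped"]
    if not mapped:
        raise UndefinedEstimatorError("no mapped reads")
    n_repeat = sum(a.maps_to == "nuclear-repeat" for a in mapped)
    return float(np.clip((n_repeat / len(mapped)) / repeat_fraction, 0.0, 1.0))


def mean_coverage(alignments: Sequence[Alignment], length: int) -> CoverageProfile:
    """Per-position depth of mtDNA alignments over a circular reference.

    Each aligned base counts once; origin-wrapping alignments contribute to
    both ends.  Conservation holds: ``depth.sum()`` equals the total number
    of aligned bases.
    """
    mt = [a for a in alignments if a.maps_to == "mtDNA"]
    diff = np.zeros(length + 1, dtype=np.int64)
    if mt:
        starts = np.array([a.ref_start - 1 for a in mt], dtype=np.int64)
        lens = np.array([a.matched_length for a in mt], dtype=np.int64)
        if (lens > length).any():
            raise ValueError("alignment longer than the reference")
        first = np.minimum(lens, length - starts)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + first, -1)
        wrap = lens - first
        w = wrap > 0
        if w.any():
            diff[0] += int(w.sum())
            np.add.at(diff, wrap[w], -1)
    return CoverageProfile(depth=np.cumsum(diff[:length]))
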