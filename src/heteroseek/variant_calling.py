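"""Pileup construction and heteroplasmic variant calling.

The caller applies a strict filter set designed for non-clonal (duplicate-
collapsed) read support:

1. at least ``min_support`` non-clonal reads carry the variant through a
   base at least ``end_distance`` nt away from both read ends;
2. non-clonal coverage at the site is at least ``min_coverage``;
3. variants whose supporting reads sit predominantly on one strand
   (strictly more than ``max_strand_fraction``, default 80%) are excluded
   as likely artifacts;
4. the variant frequency must reach the ``detection_floor``.

The reported variant frequency is (all non-clonal alt-supporting reads) /
(non-clonal depth); the end-distance rule governs *eligibility* — whether
enough trustworthy mid-read support exists — while the frequency estimate
uses every non-clonal observation so that it stays unbiased.

With a per-base error rate e, requiring k independent non-clonal reads to
show the same alternative allele suppresses the residual per-site error to
the binomial tail P(X >= k) at per-allele rate e/3, computed exactly by
:func:`residual_error_bound`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .refmodel import GeneMap, ReferenceGenome, revcomp
from .read_processing import Alignment, Read

__all__ = [
    "CallerConfig",
    "PileupColumn",
    "Pileup",
    "VariantCall",
    "SpectrumSummary",
    "build_pileup",
    "call_variants",
    "classify_substitution",
    "mutation_spectrum",
    "residual_error_bound",
]

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the variant caller (defaults follow the filter set
    described in the module docstring)."""

    min_support: int = 3
    min_coverage: int = 10
    end_distance: int = 10
    max_strand_fraction: float = 0.80
    detection_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.min_support < 1 or self.min_coverage < 1 or self.end_distance < 0:
            raise ValueError("caller thresholds must be positive")
        if not 0.5 < self.max_strand_fraction <= 1.0:
            raise ValueError("max_strand_fraction must be in (0.5, 1]")
        if not 0.0 <= self.detection_floor < 1.0:
            raise ValueError("detection_floor must be in [0, 1)")


@dataclass(frozen=True)
class PileupColumn:
    """One reference position: per-allele non-clonal counts split by strand,
    plus end-proximal tallies (support within ``end_distance`` of a read
    end)."""

    pos: int
    ref_allele: str
    counts: dict[str, tuple[int, int]]  # allele -> (plus, minus)
    end_proximal: dict[str, int]
    depth: int


class Pileup:
    """Dense pileup over the whole circular reference.

    ``counts_all[pos0, allele, strand]`` tallies every non-clonal base;
    ``counts_interior`` tallies only bases at least ``end_distance`` nt from
    both ends of their read.
    """

    def __init__(
        self,
        ref: ReferenceGenome,
        counts_all: np.ndarray,
        counts_interior: np.ndarray,
        end_distance: int,
    ) -> None:
        self.ref = ref
        self.counts_all = counts_all
        self.counts_interior = counts_interior
        self.end_distance = end_distance

    @property
    def depth(self) -> np.ndarray:
        return self.counts_all.sum(axis=(1, 2))

    def column(self, pos: int) -> PileupColumn:
        """1-based single-column view (for inspection and tests)."""
        i = pos - 1
        counts = {
            _BASES[a]: (int(self.counts_all[i, a, 0]), int(self.counts_all[i, a, 1]))
            for a in range(4)
        }
        endprox = {
            _BASES[a]: int(
                self.counts_all[i, a].sum() - self.counts_interior[i, a].sum()
            )
            for a in range(4)
        }
        return PileupColumn(
            pos=pos,
            ref_allele=self.ref.base(pos),
            counts=counts,
            end_proximal=endprox,
            depth=int(self.counts_all[i].sum()),
        )


@dataclass(frozen=True)
class VariantCall:
    """A called substitution with its non-clonal support."""

    pos: int
    ref: str
    alt: str
    frequency: float
    support_forward: int
    support_reverse: int
    depth: int
    genes: tuple[str, ...] = ()
    substitution_class: str = ""

    @property
    def support(self) -> int:
        return self.support_forward + self.support_reverse

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def build_pileup(
    alignments: Sequence[Alignment],
    reads: Sequence[Read],
    ref: ReferenceGenome,
    end_distance: int = 10,
) -> Pileup:
    """Tally non-clonal bases per position, allele and strand.

    Expects clonal-collapsed mtDNA alignments (other labels are ignored).
    A base is *end-proximal* when it lies within ``end_distance`` nt of
    either end of its read; such bases count toward depth but not toward
    the interior support used for call eligibility.
    """
    L = ref.length
    counts_all = np.zeros((L, 4, 2), dtype=np.int64)
    counts_interior = np.zeros((L, 4, 2), dtype=np.int64)
    seq_of = {r.id: r.sequence for r in reads}
    for a in alignments:
        if a.maps_to != "mtDNA":
            continue
        seq = seq_of[a.read_id]
        if a.strand == "-":
            seq = revcomp(seq)
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        n = len(codes)
        pos0 = (a.ref_start - 1 + np.arange(n)) % L
        strand_idx = 0 if a.strand == "+" else 1
        np.add.at(counts_all, (pos0, codes, strand_idx), 1)
        if n > 2 * end_distance:
            inner = slice(end_distance, n - end_distance)
            np.add.at(counts_interior, (pos0[inner], codes[inner], strand_idx), 1)
    return Pileup(ref, counts_all, counts_interior, end_distance)


def call_variants(
    pileup: Pileup,
    cfg: CallerConfig = CallerConfig(),
    gene_map: GeneMap | None = None,
) -> list[VariantCall]:
    """Emit every substitution passing all four filters.

    Multi-allelic sites emit one call per passing alternative allele.
    Frequencies lie in (0, 1]; a homoplasmic variant observed without error
    yields exactly 1.0.
    """
    L = pileup.ref.length
    depth = pileup.depth
    interior = pileup.counts_interior.sum(axis=2)  # (L, 4)
    total = pileup.counts_all.sum(axis=2)  # (L, 4)
    ref_codes = _CODE[np.frombuffer(pileup.ref.sequence.encode(), dtype=np.uint8)]

    candidate = (interior >= cfg.min_support) & (depth[:, None] >= cfg.min_coverage)
    candidate[np.arange(L), ref_codes] = False
    calls: list[VariantCall] = []
    for i, a in zip(*np.nonzero(candidate)):
        plus = int(pileup.counts_all[i, a, 0])
        minus = int(pileup.counts_all[i, a, 1])
        support = plus + minus
        if max(plus, minus) / support > cfg.max_strand_fraction:
            continue
        freq = support / int(depth[i])
        if freq < cfg.detection_floor:
            continue
        pos = int(i) + 1
        ref_base = _BASES[ref_codes[i]]
        alt = _BASES[a]
        calls.append(
            VariantCall(
                pos=pos,
                ref=ref_base,
                alt=alt,
                frequency=freq,
                support_forward=plus,
                support_reverse=minus,
                depth=int(depth[i]),
                genes=tuple(gene_map.annotate_position(pos)) if gene_map else (),
                substitution_class=classify_substitution(ref_base, alt),
            )
        )
    return calls


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else
    'transversion'."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"alleles must be in {{A,C,G,T}}, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical ({ref!r})")
    pair = {ref, alt}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class SpectrumSummary:
    """Substitution-class tallies over a call set."""

    n_transitions: int
    n_transversions: int
    empty: bool

    @property
    def transition_fraction(self) -> float:
        total = self.n_transitions + self.n_transversions
        return self.n_transitions / total if total else float("nan")


def mutation_spectrum(calls: Sequence[VariantCall]) -> SpectrumSummary:
    """Transition/transversion tallies; flagged empty for zero calls."""
    if not calls:
        return SpectrumSummary(0, 0, empty=True)
    ts = sum(classify_substitution(c.ref, c.alt) == "transition" for c in calls)
    return SpectrumSummary(ts, len(calls) - ts, empty=False)


def residual_error_bound(
    per_base_error: float, depth: int, min_support: int = 3
) -> float:
    """Probability that ``min_support`` or more independent sequencing errors
    produce the same alternative allele at one site of non-clonal depth
    ``depth``.

    Assumes a uniform miscall spectrum, so the per-allele error rate is
    ``per_base_error / 3``; returns the exact binomial upper tail
    P(X >= min_support).
    """
    if not 0.0 <= per_base_error < 1.0:
        raise ValueError("per_base_error must be in [0, 1)")
    if min_support < 1 or depth < min_support:
        raise ValueError("need depth >= min_support >= 1")
    if per_base_error == 0.0:
        return 0.0
    q = per_base_error / 3.0
    return float(stats.binom.sf(min_support - 1, depth, q))
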