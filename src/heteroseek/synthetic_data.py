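"""Ground-truth heteroplasmic populations and MiSeq-like read simulation.

This module produces everything the downstream pipeline needs without any
external data: a random circular reference, pools of mtDNA haplotypes at
chosen population frequencies, a nuclear background carrying Numt copies of
the reference and LINE/SINE-like repeat tracts, and single-end FASTQ-style
reads with per-base errors, clonal (library-amplification) duplicates and a
tunable mtDNA purity.

Every generator is driven by a `numpy` Generator seeded from an explicit
integer, so all outputs are bit-reproducible.

Simulation model, in brief:

* Fragments are drawn uniformly from the circular mtDNA (reads may wrap the
  origin) with probability ``purity``, otherwise uniformly from the linear
  nuclear background.
* Fragment lengths are uniform in ``read_length +/- length_jitter``,
  emulating the spread of sonication fragment sizes; the whole fragment is
  read out as one single-end read.
* Substitution errors are planted at ``per_base_error`` per base; indels are
  not simulated (the downstream variant analysis is substitution-only).
* Clonal duplicates are exact copies of a fragment's read (same sequence,
  same strand), emitted ``Poisson(clonal_rate)`` times per fragment.
* Base qualities are a two-level fixture: constant Q35, with an optional
  fraction of reads carrying an 11-base Q15 run to exercise the low-quality
  read filter deterministically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .refmodel import ReferenceGenome, revcomp
from .read_processing import Read

__all__ = [
    "Haplotype",
    "HaplotypePool",
    "NuclearBackground",
    "ReadSimConfig",
    "REPEAT_MOTIFS",
    "make_reference",
    "make_haplotype_pool",
    "make_frequency_ladder_pool",
    "make_nuclear_background",
    "simulate_reads",
]

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: default transition:transversion odds of the variant generator; polymerase-
#: gamma replication errors are strongly transition biased.
DEFAULT_TS_TV_ODDS = 4.0


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASE_BYTES[codes]).decode()


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, length).astype(np.uint8))


def _random_motif(length: int, seed: int) -> str:
    return _random_sequence(length, np.random.default_rng(seed))


#: Fixed family motifs used to fill repeat tracts. Real LINE/SINE elements
#: are diverged families; here a single exact motif per family is enough to
#: make repeat-derived reads unambiguously recognizable.
REPEAT_MOTIFS: dict[str, str] = {
    "LINE": _random_motif(1500, seed=9101),
    "SINE": _random_motif(300, seed=9102),
}


@dataclass(frozen=True)
class Haplotype:
    """One mtDNA haplotype: a set of substitutions and its population frequency."""

    id: str
    variants: tuple[tuple[int, str, str], ...]  # (pos, ref, alt), 1-based
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"haplotype {self.id!r} frequency {self.frequency} not in [0,1]")
        positions = [p for p, _, _ in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError(f"haplotype {self.id!r} has duplicate variant positions")


@dataclass(frozen=True)
class HaplotypePool:
    """A reference plus haplotypes whose frequencies sum to one."""

    reference: ReferenceGenome
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("a pool needs at least one haplotype")
        total = sum(h.frequency for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
        for h in self.haplotypes:
            for pos, ref, _ in h.variants:
                if self.reference.base(pos) != ref:
                    raise ValueError(
                        f"haplotype {h.id!r} variant at {pos} claims ref {ref!r} "
                        f"but reference has {self.reference.base(pos)!r}"
                    )

    def sequence_of(self, haplotype: Haplotype) -> str:
        """Full sequence of one haplotype (reference with substitutions applied)."""
        seq = list(self.reference.sequence)
        for pos, _, alt in haplotype.variants:
            seq[pos - 1] = alt
        return "".join(seq)

    def truth_variants(self) -> dict[tuple[int, str, str], float]:
        """Population frequency of every planted variant (summed over carriers)."""
        out: dict[tuple[int, str, str], float] = {}
        for h in self.haplotypes:
            for key in h.variants:
                out[key] = out.get(key, 0.0) + h.frequency
        return out


@dataclass(frozen=True)
class NuclearBackground:
    """Linear nuclear contaminant sequence with Numt and repeat tracts.

    Intervals are 1-based closed coordinates on the nuclear sequence; Numt
    and repeat intervals are mutually disjoint. ``repeat_fraction`` is the
    realized fraction of the sequence covered by repeat tracts.
    """

    sequence: str
    numt_intervals: tuple[tuple[int, int, int, float], ...]  # (start, end, mt_source_start, divergence)
    repeat_intervals: tuple[tuple[int, int, str], ...]  # (start, end, family)
    repeat_fraction: float

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for s, e, *_ in itertools.chain(self.numt_intervals, self.repeat_intervals):
            if not 1 <= s <= e <= n:
                raise ValueError(f"interval [{s},{e}] outside nuclear sequence of length {n}")
        covered = sum(e - s + 1 for s, e, _ in self.repeat_intervals)
        if abs(self.repeat_fraction - covered / n) > 1e-9:
            raise ValueError("repeat_fraction inconsistent with repeat intervals")


@dataclass(frozen=True)
class ReadSimConfig:
    """Knobs of the read simulator.

    ``depth`` is the target mean non-duplicate mtDNA coverage; the total
    fragment count is scaled by ``1/purity`` so that the mtDNA share hits
    the target.  ``length_jitter`` draws fragment lengths uniformly from
    ``read_length +/- length_jitter``.
    """

    read_length: int = 100
    depth: float = 50.0
    per_base_error: float = 1e-3
    purity: float = 1.0
    clonal_rate: float = 0.0
    length_jitter: int = 10
    low_q_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name in ("per_base_error", "purity", "low_q_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.clonal_rate < 0:
            raise ValueError("clonal_rate must be >= 0")
        if not 0 <= self.length_jitter <= self.read_length - 25:
            raise ValueError("length_jitter must leave reads >= 25 nt")


def make_reference(length: int, seed: int, name: str = "synthetic_mt") -> ReferenceGenome:
    """A uniform-random circular reference of at least 1000 bp."""
    if length < 1000:
        raise ValueError(f"reference length must be >= 1000, got {length}")
    rng = np.random.default_rng(seed)
    return ReferenceGenome(name=name, sequence=_random_sequence(length, rng), circular=True)


def _draw_alt(ref_base: str, rng: np.random.Generator, ts_tv_odds: float) -> str:
    if rng.random() < ts_tv_odds / (ts_tv_odds + 1.0):
        return _TRANSITION[ref_base]
    tv = [b for b in _BASES if b != ref_base and b != _TRANSITION[ref_base]]
    return tv[int(rng.integers(2))]


def make_haplotype_pool(
    ref: ReferenceGenome,
    composition: Sequence[tuple[int, float]],
    seed: int,
    ts_tv_odds: float = DEFAULT_TS_TV_ODDS,
) -> HaplotypePool:
    """Build a pool from ``(n_variants, frequency)`` pairs.

    Variant positions are drawn without replacement across the whole pool so
    haplotypes never collide at a site; alternative alleles are transition
    biased at ``ts_tv_odds`` (default 4:1, giving an expected transition
    fraction of 0.8).
    """
    freqs = [f for _, f in composition]
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {sum(freqs)}, expected 1")
    if any(n < 0 for n, _ in composition):
        raise ValueError("variant counts must be >= 0")
    rng = np.random.default_rng(seed)
    total = sum(n for n, _ in composition)
    positions = rng.choice(ref.length, size=total, replace=False) + 1
    cursor = 0
    haplotypes = []
    for i, (n, f) in enumerate(composition):
        variants = []
        for pos in sorted(int(p) for p in positions[cursor : cursor + n]):
            ref_base = ref.base(pos)
            variants.append((pos, ref_base, _draw_alt(ref_base, rng, ts_tv_odds)))
        cursor += n
        haplotypes.append(Haplotype(id=f"h{i}", variants=tuple(variants), frequency=f))
    return HaplotypePool(reference=ref, haplotypes=tuple(haplotypes))


def make_frequency_ladder_pool(
    ref: ReferenceGenome,
    frequencies: Sequence[float],
    seed: int,
    ts_tv_odds: float = DEFAULT_TS_TV_ODDS,
) -> HaplotypePool:
    """A pool in which variant ``i`` segregates at population frequency
    ``frequencies[i]``.

    Arbitrary per-variant frequencies (e.g. the 0.1-0.9 ladder seen in
    heteroplasmic samples) cannot be realized with disjoint haplotypes, so
    the pool is built from nested haplotypes: sorting frequencies in
    descending order f(1) >= ... >= f(k), haplotype j carries variants
    1..j and has frequency f(j) - f(j+1) (with f(0)=1, f(k+1)=0).
    """
    if not frequencies:
        raise ValueError("need at least one variant frequency")
    if any(not 0.0 < f <= 1.0 for f in frequencies):
        raise ValueError("variant frequencies must be in (0,1]")
    rng = np.random.default_rng(seed)
    order = np.argsort(-np.asarray(frequencies, dtype=float), kind="stable")
    sorted_f = [float(frequencies[i]) for i in order]
    positions = rng.choice(ref.length, size=len(frequencies), replace=False) + 1
    variants = []
    for pos in positions:
        pos = int(pos)
        ref_base = ref.base(pos)
        variants.append((pos, ref_base, _draw_alt(ref_base, rng, ts_tv_odds)))
    k = len(sorted_f)
    bounds = [1.0] + sorted_f + [0.0]
    haplotypes = []
    for j in range(k + 1):
        w = bounds[j] - bounds[j + 1]
        if w < -1e-12:
            raise ValueError("frequencies must be realizable (each in (0,1])")
        if w <= 0:
            continue
        haplotypes.append(Haplotype(id=f"h{j}", variants=tuple(variants[:j]), frequency=w))
    return HaplotypePool(reference=ref, haplotypes=tuple(haplotypes))


def make_nuclear_background(
    ref: ReferenceGenome,
    n_numts: int = 5,
    numt_length: tuple[int, int] = (500, 2000),
    divergence: float = 0.02,
    repeat_fraction: float = 0.4,
    total_length: int = 100_000,
    seed: int = 0,
    repeat_block: int = 2000,
) -> NuclearBackground:
    """A linear nuclear contaminant with Numts and repeat tracts.

    Numt intervals copy a circular segment of the mtDNA reference and apply
    per-base substitutions at ``divergence``; repeat intervals are filled by
    tiling the fixed family motifs (alternating LINE/SINE blocks of
    ``repeat_block`` bp).  Numt and repeat tracts are placed disjointly with
    random gaps of plain random sequence.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0,1)")
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ValueError("repeat_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    lo, hi = numt_length
    if not 0 < lo <= hi <= ref.length:
        raise ValueError("numt_length range must satisfy 0 < lo <= hi <= reference length")

    items: list[tuple[str, int, object]] = []
    for _ in range(n_numts):
        nlen = int(rng.integers(lo, hi + 1))
        src = int(rng.integers(1, ref.length + 1))
        items.append(("numt", nlen, src))
    repeat_total = int(round(repeat_fraction * total_length))
    families = itertools.cycle(("LINE", "SINE"))
    remaining = repeat_total
    while remaining > 0:
        blen = min(repeat_block, remaining)
        # avoid trailing slivers too short to recognize
        if 0 < remaining - blen < 100:
            blen = remaining
        items.append(("repeat", blen, next(families)))
        remaining -= blen

    occupied = sum(length for _, length, _ in items)
    free = total_length - occupied
    if free < 0:
        raise ValueError(
            f"cannot pack {occupied} bp of Numt/repeat tracts into {total_length} bp"
        )
    items = [items[i] for i in rng.permutation(len(items))]
    gaps = rng.multinomial(free, np.full(len(items) + 1, 1.0 / (len(items) + 1)))

    seq = np.frombuffer(_random_sequence(total_length, rng).encode(), dtype=np.uint8).copy()
    numt_intervals: list[tuple[int, int, int, float]] = []
    repeat_intervals: list[tuple[int, int, str]] = []
    cursor = int(gaps[0])
    for (kind, length, info), gap_after in zip(items, gaps[1:]):
        start0 = cursor
        if kind == "numt":
            src = int(info)  # type: ignore[arg-type]
            segment = _encode(ref.fetch(src, length)).copy()
            if divergence > 0:
                mask = rng.random(length) < divergence
                shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
                segment[mask] = (segment[mask] + shift) % 4
            seq[start0 : start0 + length] = _BASE_BYTES[segment]
            numt_intervals.append((start0 + 1, start0 + length, src, divergence))
        else:
            family = str(info)
            motif = REPEAT_MOTIFS[family]
            tiled = (motif * (length // len(motif) + 1))[:length]
            seq[start0 : start0 + length] = np.frombuffer(tiled.encode(), dtype=np.uint8)
            repeat_intervals.append((start0 + 1, start0 + length, family))
        cursor += length + int(gap_after)

    realized = sum(e - s + 1 for s, e, _ in repeat_intervals) / total_length
    return NuclearBackground(
        sequence=bytes(seq).decode(),
        numt_intervals=tuple(numt_intervals),
        repeat_intervals=tuple(repeat_intervals),
        repeat_fraction=realized,
    )


def simulate_reads(
    pool: HaplotypePool,
    background: NuclearBackground | None,
    cfg: ReadSimConfig,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate single-end reads from a haplotype pool plus nuclear background.

    Returns the reads and a truth table with one row per emitted read:
    ``read_id, source, start, strand, length, is_duplicate`` where ``source``
    is a haplotype id or ``"nuclear"`` and ``start`` is the 1-based fragment
    start in the source coordinate system.
    """
    if cfg.purity < 1.0 and background is None:
        raise ValueError("purity < 1 requires a nuclear background")
    if cfg.purity <= 0.0:
        raise ValueError("purity must be > 0 to target an mtDNA depth")
    rng = np.random.default_rng(cfg.seed)
    L = pool.reference.length
    n_mt_target = int(round(cfg.depth * L / cfg.read_length))
    n_frag = int(round(n_mt_target / cfg.purity))

    hap_freqs = np.array([h.frequency for h in pool.haplotypes])
    hap_arrays = []
    for h in pool.haplotypes:
        s = pool.sequence_of(h)
        hap_arrays.append(_encode(s + s))  # doubled for circular slicing
    nuc_arr = _encode(background.sequence) if background is not None else None

    is_mt = rng.random(n_frag) < cfg.purity
    hap_idx = rng.choice(len(pool.haplotypes), size=n_frag, p=hap_freqs)
    lengths = rng.integers(
        cfg.read_length - cfg.length_jitter, cfg.read_length + cfg.length_jitter + 1,
        size=n_frag,
    )
    strands = rng.integers(0, 2, size=n_frag)  # 0:'+', 1:'-'
    n_errors = (
        rng.binomial(lengths, cfg.per_base_error) if cfg.per_base_error > 0
        else np.zeros(n_frag, dtype=np.int64)
    )
    low_q = (
        rng.random(n_frag) < cfg.low_q_read_fraction
        if cfg.low_q_read_fraction > 0
        else np.zeros(n_frag, dtype=bool)
    )
    n_dups = (
        rng.poisson(cfg.clonal_rate, size=n_frag) if cfg.clonal_rate > 0
        else np.zeros(n_frag, dtype=np.int64)
    )

    reads: list[Read] = []
    rows: list[tuple] = []
    for i in range(n_frag):
        length = int(lengths[i])
        if is_mt[i]:
            start = int(rng.integers(1, L + 1))
            codes = hap_arrays[hap_idx[i]][start - 1 : start - 1 + length]
            source = pool.haplotypes[hap_idx[i]].id
        else:
            start = int(rng.integers(1, len(background.sequence) - length + 2))
            codes = nuc_arr[start - 1 : start - 1 + length]
            source = "nuclear"
        codes = codes.copy()
        if strands[i]:
            codes = 3 - codes[::-1]
        if n_errors[i]:
            where = rng.choice(length, size=int(n_errors[i]), replace=False)
            shift = rng.integers(1, 4, size=len(where)).astype(np.uint8)
            codes[where] = (codes[where] + shift) % 4
        quals = np.full(length, 35, dtype=np.int16)
        if low_q[i]:
            off = int(rng.integers(0, length - 11 + 1))
            quals[off : off + 11] = 15
        seq = _decode(codes)
        strand = "-" if strands[i] else "+"
        rid = f"r{i:07d}"
        reads.append(Read(id=rid, sequence=seq, qualities=quals))
        rows.append((rid, source, start, strand, length, False))
        for d in range(int(n_dups[i])):
            did = f"{rid}d{d}"
            reads.append(Read(id=did, sequence=seq, qualities=quals.copy()))
            rows.append((did, source, start, strand, length, True))

    truth = pd.DataFrame(
        rows, columns=["read_id", "source", "start", "strand", "length", "is_duplicate"]
    )
    return reads, truth
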