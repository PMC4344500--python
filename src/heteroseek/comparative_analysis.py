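"""Colony-stability comparison and co-culture mtDNA transfer detection.

Two samples are compared through their variant profiles (exact
(pos, ref, alt) keys mapped to frequencies).  A detection floor (default
2%, where variant persistence becomes unreliable) separates shared variants
from ones private to either sample; shared variants are summarized by the
largest frequency difference and the Pearson correlation — stable
heteroplasmy puts points on the diagonal of a frequency-frequency plot.

Transfer detection takes three profiles: the donor line, the recipient line
before co-culture (required — a donor-only comparison cannot distinguish
transfer from pre-existing variation), and the recipient after co-culture
and re-sorting.  For every donor-private variant the *transfer index* is
f_after / f_donor; indices near the co-culture mixing proportion indicate
mtDNA moving between the lines, and per-variant heterogeneity (indices
legitimately spanning 0 to 1 in one experiment) is preserved in the report
rather than averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_calling import VariantCall

__all__ = [
    "VariantProfile",
    "ProfileComparison",
    "TransferRecord",
    "TransferReport",
    "ComparisonError",
    "compare_profiles",
    "private_variants",
    "detect_transfer",
]

Key = tuple[int, str, str]

DEFAULT_FLOOR = 0.02


class ComparisonError(ValueError):
    """Raised when profiles cannot be compared (mismatched references)."""


@dataclass(frozen=True)
class VariantProfile:
    """One sample's called variants: (pos, ref, alt) -> frequency (+ depth)."""

    sample_id: str
    reference_name: str
    frequencies: dict[Key, float]
    depths: dict[Key, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, f in self.frequencies.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{self.sample_id}: frequency {f} at {key} not in (0,1]")

    @classmethod
    def from_calls(
        cls, sample_id: str, reference_name: str, calls: Sequence[VariantCall]
    ) -> "VariantProfile":
        return cls(
            sample_id=sample_id,
            reference_name=reference_name,
            frequencies={c.key: c.frequency for c in calls},
            depths={c.key: c.depth for c in calls},
        )

    def get(self, key: Key) -> float:
        return self.frequencies.get(key, 0.0)


@dataclass(frozen=True)
class ProfileComparison:
    """Shared and private variants of two profiles at a detection floor.

    ``shared`` maps each common key to its (fA, fB) pair; ``private_a`` /
    ``private_b`` hold variants at or above the floor in only one sample
    (i.e. lost or gained relative to the other).  Keys below the floor in
    both samples are outside the comparison.
    """

    sample_a: str
    sample_b: str
    floor: float
    shared: dict[Key, tuple[float, float]]
    private_a: dict[Key, float]
    private_b: dict[Key, float]

    @property
    def max_abs_delta(self) -> float:
        if not self.shared:
            return float("nan")
        return max(abs(fa - fb) for fa, fb in self.shared.values())

    @property
    def pearson_r(self) -> float:
        if len(self.shared) < 2:
            return float("nan")
        fa, fb = (np.array(v) for v in zip(*self.shared.values()))
        if fa.std() == 0 or fb.std() == 0:
            return float("nan")
        return float(np.corrcoef(fa, fb)[0, 1])

    @property
    def n_lost_below_floor(self) -> int:
        return len(self.private_a) + len(self.private_b)


def _check_same_reference(a: VariantProfile, b: VariantProfile) -> None:
    if a.reference_name != b.reference_name:
        raise ComparisonError(
            f"profiles on different references: {a.reference_name!r} vs "
            f"{b.reference_name!r}"
        )


def compare_profiles(
    a: VariantProfile, b: VariantProfile, floor: float = DEFAULT_FLOOR
) -> ProfileComparison:
    """Match variant keys exactly and partition them into shared / private
    sets at the detection floor."""
    _check_same_reference(a, b)
    shared: dict[Key, tuple[float, float]] = {}
    private_a: dict[Key, float] = {}
    private_b: dict[Key, float] = {}
    for key in sorted(set(a.frequencies) | set(b.frequencies)):
        fa, fb = a.get(key), b.get(key)
        if fa >= floor and fb >= floor:
            shared[key] = (fa, fb)
        elif fa >= floor:
            private_a[key] = fa
        elif fb >= floor:
            private_b[key] = fb
    return ProfileComparison(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        floor=floor,
        shared=shared,
        private_a=private_a,
        private_b=private_b,
    )


def private_variants(
    a: VariantProfile, b: VariantProfile, floor: float = DEFAULT_FLOOR
) -> tuple[dict[Key, float], dict[Key, float]]:
    """Variants at/above the floor in exactly one of the two profiles."""
    cmp = compare_profiles(a, b, floor)
    return cmp.private_a, cmp.private_b


@dataclass(frozen=True)
class TransferRecord:
    """One donor-private variant tracked through a co-culture."""

    key: Key
    f_donor: float
    f_baseline: float
    f_after: float

    @property
    def transfer_index(self) -> float:
        return self.f_after / self.f_donor

    def verdict(self, floor: float = DEFAULT_FLOOR) -> str:
        return "transfer" if self.f_after >= floor else "no transfer"


@dataclass(frozen=True)
class TransferReport:
    """Per-variant transfer indices plus a per-pair verdict."""

    donor: str
    recipient: str
    floor: float
    records: tuple[TransferRecord, ...]
    verdict: str  # 'transfer' | 'partial' | 'no transfer' | 'indeterminate'

    @property
    def transfer_indices(self) -> np.ndarray:
        return np.array([r.transfer_index for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pos": r.key[0],
                    "ref": r.key[1],
                    "alt": r.key[2],
                    "f_donor": r.f_donor,
                    "f_baseline": r.f_baseline,
                    "f_after": r.f_after,
                    "transfer_index": r.transfer_index,
                    "transferred": r.f_after >= self.floor,
                }
                for r in self.records
            ]
        )


def detect_transfer(
    donor: VariantProfile,
    recipient_baseline: VariantProfile,
    recipient_after: VariantProfile,
    floor: float = DEFAULT_FLOOR,
    transfer_call_fraction: float = 0.5,
) -> TransferReport:
    """Report donor-private variants appearing in the recipient after
    co-culture.

    A variant counts as transferred when its post-co-culture frequency
    reaches the floor.  The pair verdict is 'transfer' when at least
    ``transfer_call_fraction`` of donor-private variants transferred,
    'no transfer' when none did, and 'partial' in between; with no
    donor-private variants the verdict is 'indeterminate'.
    """
    _check_same_reference(donor, recipient_baseline)
    _check_same_reference(donor, recipient_after)
    donor_private, _ = private_variants(donor, recipient_baseline, floor)
    records = tuple(
        TransferRecord(
            key=key,
            f_donor=f_donor,
            f_baseline=recipient_baseline.get(key),
            f_after=recipient_after.get(key),
        )
        for key, f_donor in sorted(donor_private.items())
    )
    if not records:
        verdict = "indeterminate"
    else:
        transferred = sum(r.f_after >= floor for r in records)
        if transferred == 0:
            verdict = "no transfer"
        elif transferred >= transfer_call_fraction * len(records):
            verdict = "transfer"
        else:
            verdict = "partial"
    return TransferReport(
        donor=donor.sample_id,
        recipient=recipient_after.sample_id,
        floor=floor,
        records=records,
        verdict=verdict,
    )
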