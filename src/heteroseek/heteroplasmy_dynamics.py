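"""Stochastic model of mtDNA segregation drift and intercellular exchange.

Model of one cell division: a cell holding N mtDNA copies (k of them the
focal haplotype) assorts its copies randomly between two daughters — the
tracked daughter receives a hypergeometric draw of N/2 physical copies —
and each received copy replicates once, restoring the tissue-specific
quorum N.  Homoplasmy (k = 0 or k = N) is absorbing under pure drift.

Under this split-then-double scheme the inter-lineage frequency variance
after g divisions has the closed form

    Var_g = P (1 - P) [1 - (1 - 1/(N-1))^g],

which :func:`drift_variance_oracle` returns exactly; the mean frequency is
a martingale.  Drift is slower (variance smaller) for larger N and for P
closer to 0 or 1.

Intercellular exchange is modeled per generation: each cell replaces a
Binomial(N, m) number of its copies with copies drawn from the population's
pooled haplotype frequency.  Exchange pulls every cell toward the
population average and thereby counteracts drift; m = 0 is the identity.

Two model variants are available for sensitivity analysis, since the
assortment/replication details are not observable: binomial assortment
(sampling with replacement) and stochastic Polya-urn replication.  The
variance oracle applies only to the default hypergeometric/deterministic
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DriftParams",
    "FrequencySnapshot",
    "divide_cell",
    "divide_population",
    "apply_exchange",
    "simulate_population",
    "drift_variance_oracle",
    "homoplasmy_fraction",
    "fixation_generation",
]

DEFAULT_SNAPSHOTS = (1, 6, 11, 16, 21, 26)


@dataclass(frozen=True)
class DriftParams:
    """Parameters of a drift/exchange simulation.

    N: mtDNA copies per cell at quorum (even); P: initial focal-haplotype
    frequency; generations: number of divisions; n_cells: independent
    lineages tracked; exchange_rate m in [0,1]: per-generation fraction of
    copies replaced from the population pool.
    """

    N: int = 250
    P: float = 0.3
    generations: int = 26
    n_cells: int = 10_000
    exchange_rate: float = 0.0
    seed: int = 0
    snapshot_generations: tuple[int, ...] = DEFAULT_SNAPSHOTS
    assortment: str = "hypergeometric"  # or 'binomial'
    replication: str = "deterministic"  # or 'stochastic'

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be even and >= 2")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must be in [0,1]")
        if not 0.0 <= self.exchange_rate <= 1.0:
            raise ValueError("exchange_rate must be in [0,1]")
        if self.generations < 0 or self.n_cells < 1:
            raise ValueError("generations must be >= 0 and n_cells >= 1")
        if self.assortment not in ("hypergeometric", "binomial"):
            raise ValueError("assortment must be 'hypergeometric' or 'binomial'")
        if self.replication not in ("deterministic", "stochastic"):
            raise ValueError("replication must be 'deterministic' or 'stochastic'")


@dataclass(frozen=True)
class FrequencySnapshot:
    """Per-cell focal-haplotype frequencies at one generation."""

    generation: int
    frequencies: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.frequencies.mean())

    @property
    def variance(self) -> float:
        return float(self.frequencies.var())

    @property
    def homoplasmic_fraction(self) -> float:
        f = self.frequencies
        return float(((f == 0.0) | (f == 1.0)).mean())


def divide_population(
    ks: np.ndarray,
    N: int,
    rng: np.random.Generator,
    assortment: str = "hypergeometric",
    replication: str = "deterministic",
) -> np.ndarray:
    """One division for every cell; returns the tracked daughters' focal counts.

    The daughter receives N/2 copies (hypergeometric without replacement by
    default) and replication restores quorum N (deterministic doubling by
    default, or a Polya-urn scheme when ``replication='stochastic'``).
    """
    if N % 2:
        raise ValueError("N must be even")
    ks = np.asarray(ks, dtype=np.int64)
    half = N // 2
    if assortment == "hypergeometric":
        received = rng.hypergeometric(ks, N - ks, half)
    elif assortment == "binomial":
        received = rng.binomial(half, ks / N)
    else:
        raise ValueError(f"unknown assortment {assortment!r}")
    if replication == "deterministic":
        return 2 * received
    if replication != "stochastic":
        raise ValueError(f"unknown replication {replication!r}")
    # Polya urn: each of the half new copies is templated proportionally to
    # the current composition; focal additions are Beta-Binomial.
    added = np.where(received == 0, 0, np.where(received == half, half, 0)).astype(np.int64)
    interior = (received > 0) & (received < half)
    if interior.any():
        p = rng.beta(received[interior], half - received[interior])
        added[interior] = rng.binomial(half, p)
    return received + added


def divide_cell(
    k: int,
    N: int,
    rng: np.random.Generator,
    assortment: str = "hypergeometric",
    replication: str = "deterministic",
) -> int:
    """Scalar convenience wrapper around :func:`divide_population`."""
    if not 0 <= k <= N:
        raise ValueError(f"focal count {k} outside [0, {N}]")
    return int(
        divide_population(np.array([k]), N, rng, assortment, replication)[0]
    )


def apply_exchange(
    ks: np.ndarray, N: int, m: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace a Binomial(N, m) number of each cell's copies with copies drawn
    from the population's pooled frequency.

    m = 0 is the identity; m = 1 re-draws every cell from the pool, so every
    cell's frequency approaches the population mean for large N.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("exchange rate must be in [0,1]")
    ks = np.asarray(ks, dtype=np.int64)
    if m == 0.0:
        return ks.copy()
    pool_freq = float(ks.mean()) / N
    r = rng.binomial(N, m, size=ks.shape)
    removed_focal = rng.hypergeometric(ks, N - ks, r)
    incoming = rng.binomial(r, pool_freq)
    return ks - removed_focal + incoming


def simulate_population(params: DriftParams) -> list[FrequencySnapshot]:
    """Track ``n_cells`` independent lineages (one daughter kept per
    division), applying exchange each generation when m > 0; snapshots at
    the configured generations."""
    rng = np.random.default_rng(params.seed)
    ks = np.full(params.n_cells, int(round(params.P * params.N)), dtype=np.int64)
    wanted = {g for g in params.snapshot_generations if 0 <= g <= params.generations}
    snapshots: list[FrequencySnapshot] = []
    if 0 in wanted:
        snapshots.append(FrequencySnapshot(0, ks / params.N))
    for g in range(1, params.generations + 1):
        ks = divide_population(ks, params.N, rng, params.assortment, params.replication)
        if params.exchange_rate > 0:
            ks = apply_exchange(ks, params.N, params.exchange_rate, rng)
        if g in wanted:
            snapshots.append(FrequencySnapshot(g, ks / params.N))
    return snapshots


def drift_variance_oracle(N: int, P: float, g: int) -> float:
    """Exact inter-lineage variance P(1-P)[1 - (1 - 1/(N-1))^g] for the
    default hypergeometric-assortment, deterministic-doubling model."""
    if N < 2 or N % 2:
        raise ValueError("N must be even and >= 2")
    if g < 0:
        raise ValueError("g must be >= 0")
    return P * (1.0 - P) * (1.0 - (1.0 - 1.0 / (N - 1)) ** g)


def homoplasmy_fraction(snapshots: Sequence[FrequencySnapshot]) -> dict[int, float]:
    """Fraction of cells at frequency 0 or 1, per snapshot generation.

    Monotone non-decreasing in generation under pure drift (homoplasmy is
    absorbing when m = 0)."""
    return {s.generation: s.homoplasmic_fraction for s in snapshots}


def fixation_generation(
    snapshots: Sequence[FrequencySnapshot], threshold: float = 0.5
) -> int | None:
    """First snapshot generation at which the homoplasmic fraction reaches
    ``threshold`` — an exploratory summary of the drift time scale, not a
    calibrated estimate."""
    for s in sorted(snapshots, key=lambda s: s.generation):
        if s.homoplasmic_fraction >= threshold:
            return s.generation
    return None
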