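"""Trial design: in-patient randomization and paired-t power analysis.

Each patient carries both arms — one liver lobe is treated intra-arterially,
the contralateral lobe serves as its control — so randomization assigns the
*lobe* (left or right hepatic artery), and the power analysis is that of a
one-sample t-test on within-patient differences with effect size Cohen's
d_z = mean(d) / sd(d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RandomizationList",
    "PowerSpec",
    "generate_randomization",
    "power_paired_t",
    "min_n_paired_t",
]

ARMS = ("left", "right")


@dataclass(frozen=True)
class RandomizationList:
    """Permuted-block assignment sequence of treated lobes."""

    assignments: tuple[str, ...]
    block_structure: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if sum(self.block_structure) != len(self.assignments):
            raise ValueError("block sizes must sum to the number of assignments")
        pos = 0
        for size in self.block_structure:
            block = self.assignments[pos:pos + size]
            if size == 2 and set(block) != {"left", "right"}:
                raise ValueError(f"unbalanced size-2 block at position {pos}: {block}")
            pos += size
        if any(a not in ARMS for a in self.assignments):
            raise ValueError("assignments must be 'left' or 'right'")


def generate_randomization(n_patients: int, seed: int) -> RandomizationList:
    """Permuted-block sequence with block sizes 1 and 2.

    Block sizes are drawn uniformly from {1, 2}; a size-2 block contains one
    left and one right in random order, a size-1 block is a fair coin.  The
    trailing block is truncated to fit ``n_patients`` exactly.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    assignments: list[str] = []
    blocks: list[int] = []
    while len(assignments) < n_patients:
        size = int(rng.integers(1, 3))
        if size == 2:
            block = list(rng.permutation(ARMS))
        else:
            block = [ARMS[int(rng.integers(0, 2))]]
        remaining = n_patients - len(assignments)
        if size > remaining:
            block = block[:remaining]
            size = remaining
        assignments.extend(block)
        blocks.append(size)
    return RandomizationList(tuple(assignments), tuple(blocks), seed)


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of the paired-t power computation."""

    effect_size_dz: float
    alpha: float = 0.05
    power: float = 0.9
    sidedness: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size_dz < 0:
            raise ValueError("effect size d_z must be non-negative")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


def power_paired_t(spec: PowerSpec, n: int) -> float:
    """Exact noncentral-t power of the paired t-test at sample size ``n``.

    The test statistic has df = n - 1 and noncentrality d_z * sqrt(n) under
    the alternative.
    """
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    df = n - 1
    nc = spec.effect_size_dz * np.sqrt(n)
    if spec.sidedness == "two":
        tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
        lower = stats.nct.cdf(-tcrit, df, nc)
        if not np.isfinite(lower):  # far-tail underflow in scipy's nct
            lower = 0.0
        power = stats.nct.sf(tcrit, df, nc) + lower
    else:
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
    return float(min(power, 1.0))


def min_n_paired_t(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n whose exact paired-t power reaches ``spec.power``."""
    if spec.effect_size_dz == 0:
        raise ValueError("power cannot exceed alpha at d_z = 0: target unreachable")
    for n in range(2, n_max + 1):
        if power_paired_t(spec, n) >= spec.power:
            return n
    raise ValueError(f"target power {spec.power} not reached by n = {n_max}")
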