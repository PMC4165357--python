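"""How often do two independent templates receive the same tag by chance?

A random L-mer tag drawn uniformly has 4^L possible values; when n tags are
drawn independently, per-sequence usage counts are well approximated as
Poisson with rate lambda = n / 4^L.  That gives closed forms for the expected
number of distinct tags seen and for the upper tail of usage counts — the
yardstick against which biased tag synthesis shows up as excess reuse.  A
seeded resampling estimator measures the chance-collision fraction within a
target at a given read depth, for the uniform model or for any empirical tag
frequency distribution (including a truncation to the first 8 bases, which
demonstrates that 8-mer tags lack the complexity for ~1,000X depth).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CollisionModel:
    """Poisson model of uniform tag usage: n_draws tags from a 4^L universe."""

    L: int
    n_draws: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("tag length must be >= 1")
        if self.n_draws < 0:
            raise ValueError("n_draws must be >= 0")

    @property
    def K(self) -> int:
        return 4**self.L

    @property
    def lam(self) -> float:
        return self.n_draws / self.K


def expected_distinct(model: CollisionModel) -> float:
    """Expected number of distinct tag sequences observed: K(1 - e^-lambda)."""
    return -model.K * np.expm1(-model.lam)


def expected_count_at_least(model: CollisionModel, k: int) -> float:
    """Expected number of tag sequences observed at least k times.

    K * P(Pois(lambda) >= k), computed through the survival function so the
    extreme tail does not lose precision to 1 - CDF cancellation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if model.n_draws == 0:
        return 0.0
    return float(model.K * stats.poisson.sf(k - 1, model.lam))


def expected_sequence_count_distribution(
    model: CollisionModel, k_max: int
) -> pd.DataFrame:
    """Expected number of tag sequences seen exactly k times, for k = 1..k_max."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k = np.arange(1, k_max + 1)
    expected = model.K * stats.poisson.pmf(k, model.lam)
    return pd.DataFrame({"k": k, "expected_sequences": expected})


class UniformSmtDistribution:
    """Uniform tag usage over all 4^L sequences of length L."""

    def __init__(self, L: int):
        if L < 1:
            raise ValueError("tag length must be >= 1")
        self.L = L
        self.K = 4**L

    def sample_codes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.integers(0, self.K, size=size)


class SmtFrequencyDistribution:
    """Empirical tag usage: one count per tag per target per sample.

    Counts weight the resampling estimator, so tags favoured by synthesis
    bias are drawn proportionally more often than the uniform model would.
    """

    def __init__(self, counts: Mapping[str, int]):
        if not counts:
            raise ValueError("empty tag frequency distribution")
        lengths = {len(s) for s in counts}
        if len(lengths) != 1:
            raise ValueError(f"mixed tag lengths: {sorted(lengths)}")
        if any(c < 1 for c in counts.values()):
            raise ValueError("all counts must be >= 1")
        (self.L,) = lengths
        self.counts = dict(counts)
        self._tags = np.arange(len(self.counts))
        weights = np.array(list(self.counts.values()), dtype=float)
        self._cum = np.cumsum(weights)
        self.n_draws = int(weights.sum())

    @classmethod
    def from_tags(cls, tags: list[str]) -> "SmtFrequencyDistribution":
        return cls(Counter(tags))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SmtFrequencyDistribution":
        df = pd.read_csv(path, sep="\t", dtype={"smt": str, "count": int})
        return cls(dict(zip(df["smt"], df["count"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["smt", "count"]
        ).to_csv(path, sep="\t", index=False)

    def sample_codes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        # inverse-CDF sampling over tag indices, weighted by observed counts
        u = rng.random(size) * self._cum[-1]
        return np.searchsorted(self._cum, u, side="right")


def truncate_to_prefix(
    dist: SmtFrequencyDistribution, new_L: int
) -> SmtFrequencyDistribution:
    """Aggregate an empirical distribution over the first ``new_L`` bases.

    Total count is preserved; distinct tags that share a prefix merge, which
    is how restricting a 12-mer data set to its first 8 bases is modelled.
    """
    if new_L <= 0:
        raise ValueError("new_L must be positive")
    if new_L >= dist.L:
        raise ValueError(f"new_L must be < current tag length {dist.L}")
    agg: Counter[str] = Counter()
    for tag, count in dist.counts.items():
        agg[tag[:new_L]] += count
    return SmtFrequencyDistribution(agg)


def collision_fraction_by_resampling(
    dist: UniformSmtDistribution | SmtFrequencyDistribution,
    depth: int,
    n_targets: int,
    seed: int,
) -> float:
    """Fraction of reads that repeat an already-drawn tag within their target.

    For each of ``n_targets`` targets, ``depth`` tags are drawn i.i.d. from
    ``dist``; every draw whose tag already occurred in the same target is a
    chance collision (it would be miscalled a PCR duplicate).  Returns total
    collisions / total draws.  Per-target random streams are spawned from one
    root seed, so results are reproducible and independent of evaluation
    order.
    """
    if depth < 1 or n_targets < 1:
        raise ValueError("depth and n_targets must be >= 1")
    root = np.random.SeedSequence(seed)
    collisions = 0
    for child in root.spawn(n_targets):
        rng = np.random.default_rng(child)
        codes = dist.sample_codes(rng, depth)
        collisions += depth - len(np.unique(codes))
    return collisions / (depth * n_targets)


def uniform_collision_fraction(L: int, depth: int) -> float:
    """Closed-form occupancy value of the uniform chance-collision fraction.

    E[collisions]/depth = 1 - K(1 - (1 - 1/K)^depth)/depth with K = 4^L:
    the expected number of occupied tag values subtracted from the number of
    draws gives the expected repeats.
    """
    K = 4**L
    expected_distinct_tags = -K * np.expm1(depth * np.log1p(-1.0 / K))
    return 1.0 - expected_distinct_tags / depth
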