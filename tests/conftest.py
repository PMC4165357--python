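import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smtdedup import SimulationConfig, SnpAnnotation, TargetDesign, generate_design

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming Levenshtein distance (unbounded, unoptimised)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def fisher_2x2_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over the hypergeometric
    support with the observed margins (minimum-likelihood definition)."""
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return 1.0
    obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        # small relative slack against float round-off in the implementation
        if w <= obs:
            total += w
    return total / denom


def fisher_2x3_enumeration(ref, alt) -> float:
    """Two-sided 2x3 Fisher p by exact integer enumeration of all tables
    with the observed margins."""
    from math import comb

    cols = [r + a for r, a in zip(ref, alt)]
    A = sum(alt)
    N = sum(cols)
    denom = comb(N, A)
    obs = comb(cols[0], alt[0]) * comb(cols[1], alt[1]) * comb(cols[2], alt[2])
    total = 0
    for a1 in range(min(cols[0], A) + 1):
        for a2 in range(min(cols[1], A - a1) + 1):
            a3 = A - a1 - a2
            if a3 > cols[2]:
                continue
            w = comb(cols[0], a1) * comb(cols[1], a2) * comb(cols[2], a3)
            if w <= obs:
                total += w
    return total / denom


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small panel: 12 targets, all het, modest depth."""
    return SimulationConfig(
        seed=42, n_targets=12, mean_depth=200, het_fraction=1.0, duplicate_rate=0.2
    )


@pytest.fixture(scope="session")
def small_designs(small_config) -> list[TargetDesign]:
    return generate_design(small_config)


@pytest.fixture
def two_designs() -> list[TargetDesign]:
    """Two hand-built designs with well-separated primers."""
    return [
        TargetDesign(
            target_id="T1",
            upstream_primer="A" * 11 + "C" * 11,
            downstream_primer="G" * 11 + "T" * 11,
            insert_seq="ACGT" * 25,
            snps=(SnpAnnotation(position=50, ref_allele="G", alt_allele="A"),),
        ),
        TargetDesign(
            target_id="T2",
            upstream_primer="GA" * 11,
            downstream_primer="CT" * 11,
            insert_seq="TTGG" * 25,
        ),
    ]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140807)
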