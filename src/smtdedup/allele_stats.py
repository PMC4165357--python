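"""Allele extraction, het-SNP calling, cluster concordance and Fisher testing.

Because amplicon reads have a fixed start, the base at an annotated SNP is
read off directly by position within the trimmed read — no alignment or
genotype-likelihood machinery.  Counts are per read pair (Read 1 only), so
no paired-read double-counting correction is needed.  On top of the counts
sit the comparisons: two-sided Fisher exact tests of allele frequency
between paired samples (whose false positive rate at heterozygous SNPs is
the study's key readout), a 2xk exact test with Benjamini-Hochberg control
for somatic-site identification, and concordance summaries showing that
reads sharing a tag carry the same allele.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .formats_io import SnpAnnotation
from .smt_dedup import DedupAnnotation

REF = "REF"
ALT = "ALT"
OTHER = "OTHER"

COUNT_COLUMNS = ["sample_id", "target_id", "position", "n_ref", "n_alt", "n_other"]


def extract_allele(seq: str, snp: SnpAnnotation, insert_offset: int = 0) -> str | None:
    """Classify the base a trimmed read shows at an annotated SNP.

    ``insert_offset`` is the insert position of the read's first base (0 for
    a trimmed Read 2; ``len(insert) - len(read)`` for a trimmed, re-oriented
    Read 1, which covers the insert's 3' end).  Returns None when the read
    does not cover the position; N and any third allele classify as OTHER.
    """
    i = snp.position - insert_offset
    if i < 0 or i >= len(seq):
        return None
    base = seq[i]
    if base == snp.ref_allele:
        return REF
    if base == snp.alt_allele:
        return ALT
    return OTHER


def count_alleles(
    calls: Iterable[tuple[str, str, int, str]],
) -> pd.DataFrame:
    """Aggregate per-read calls into an allele count table.

    ``calls`` yields ``(sample_id, target_id, position, call)`` with call in
    {REF, ALT, OTHER}.  One row per (sample, target, position) with columns
    n_ref, n_alt, n_other.
    """
    counts: dict[tuple[str, str, int], Counter] = defaultdict(Counter)
    for sample_id, target_id, position, call in calls:
        counts[(sample_id, target_id, position)][call] += 1
    rows = [
        {
            "sample_id": s,
            "target_id": t,
            "position": p,
            "n_ref": c.get(REF, 0),
            "n_alt": c.get(ALT, 0),
            "n_other": c.get(OTHER, 0),
        }
        for (s, t, p), c in counts.items()
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def snp_qc_filter(counts: pd.DataFrame, max_other_frac: float = 0.10) -> pd.DataFrame:
    """Drop sites reporting a non-ref, non-alt allele too often.

    A site where more than ``max_other_frac`` (default 10%) of covering reads
    show a third allele is unreliable (mispriming, tracking error) and is
    excluded.  Sites with zero coverage are dropped as unevaluable.
    """
    total = counts["n_ref"] + counts["n_alt"] + counts["n_other"]
    with np.errstate(invalid="ignore"):
        other_frac = counts["n_other"] / total
    keep = (total > 0) & (other_frac <= max_other_frac)
    return counts.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class HetSnpCall:
    sample_id: str
    target_id: str
    position: int
    depth: int
    alt_frequency: float
    is_het: bool


def call_het_snps(
    counts: pd.DataFrame,
    min_depth: int = 50,
    band: tuple[float, float] = (0.2, 0.8),
    max_other_frac: float = 0.10,
) -> list[HetSnpCall]:
    """Call heterozygous SNPs from unique-read allele counts.

    A simple depth-and-frequency genotyper: after the third-allele QC filter,
    a site is heterozygous when its ref+alt depth reaches ``min_depth`` and
    the alternate allele frequency n_alt/(n_ref+n_alt) falls inside ``band``.
    Thresholds are deliberately conservative for ~1,000X amplicon data.
    """
    filtered = snp_qc_filter(counts, max_other_frac)
    calls = []
    for row in filtered.itertuples(index=False):
        depth = row.n_ref + row.n_alt
        alt_freq = row.n_alt / depth if depth > 0 else float("nan")
        is_het = depth >= min_depth and band[0] <= alt_freq <= band[1]
        calls.append(
            HetSnpCall(
                sample_id=row.sample_id,
                target_id=row.target_id,
                position=row.position,
                depth=depth,
                alt_frequency=alt_freq,
                is_het=is_het,
            )
        )
    return calls


def cluster_concordance(
    annotations: Iterable[DedupAnnotation],
    calls: Mapping[str, str | None],
) -> pd.DataFrame:
    """Allele-call agreement within duplicate clusters, by cluster size.

    ``calls`` maps read_id -> allele call at the target's SNP of interest
    (None when the read does not cover it); sites should already have passed
    :func:`snp_qc_filter`.  Clusters are (target, SMT) groups restricted to
    their called members; only clusters with >= 2 called reads are evaluable.
    A cluster is concordant when every member shows the same allele.  Returns
    one row per cluster size with n_clusters, n_concordant and
    percent_agreement.
    """
    clusters: dict[tuple[str, str], list[str]] = defaultdict(list)
    for ann in annotations:
        call = calls.get(ann.read_id)
        if call is not None:
            clusters[(ann.target_id, ann.smt)].append(call)
    by_size: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for members in clusters.values():
        size = len(members)
        if size < 2:
            continue
        by_size[size][0] += 1
        if len(set(members)) == 1:
            by_size[size][1] += 1
    rows = [
        {
            "cluster_size": size,
            "n_clusters": n,
            "n_concordant": conc,
            "percent_agreement": 100.0 * conc / n,
        }
        for size, (n, conc) in sorted(by_size.items())
    ]
    return pd.DataFrame(
        rows, columns=["cluster_size", "n_clusters", "n_concordant", "percent_agreement"]
    )


def paired_read_concordance(
    call_pairs: Iterable[tuple[str, str]],
) -> float:
    """Fraction of read pairs whose two mates call the same allele at a SNP.

    Near-perfect agreement here shows that within-cluster discordance is not
    sequencing error.  Returns NaN when no pair covers the site with both
    mates.
    """
    n = agree = 0
    for c1, c2 in call_pairs:
        n += 1
        agree += c1 == c2
    return agree / n if n else float("nan")


def fisher_2x2(a_ref: int, a_alt: int, b_ref: int, b_alt: int) -> float:
    """Two-sided Fisher exact p for a 2x2 allele count table.

    Minimum-likelihood two-sided definition (sum of tables no more probable
    than the observed one), the convention of R's fisher.test.  Degenerate
    margins give p = 1.
    """
    for v in (a_ref, a_alt, b_ref, b_alt):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return float(
        stats.fisher_exact([[a_ref, a_alt], [b_ref, b_alt]], alternative="two-sided")[1]
    )


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # 'exact' or 'monte_carlo'
    mc_se: float = 0.0


# relative slack when comparing table log-probabilities to the observed one,
# mirroring fisher.test's 1 + 1e-7 tolerance against round-off
_LOG_P_TOL = 1e-7


def _log_ncr(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def fisher_exact_2xk(
    ref_counts: Sequence[int],
    alt_counts: Sequence[int],
    max_exact_total: int = 5000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact test on a 2xk table of (ref, alt) x samples.

    Conditional on all margins, the alt-count allocation across samples is
    multivariate hypergeometric; the two-sided p sums the probability of
    every allocation no more probable than the observed one.  For k <= 3 and
    total count <= ``max_exact_total`` the allocation space is enumerated
    exactly (O(A^2) tables for k=3, vectorised); larger problems fall back
    to seeded Monte Carlo sampling from the null, with the standard error of
    the p estimate reported.
    """
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    if ref.shape != alt.shape or ref.ndim != 1 or len(ref) < 2:
        raise ValueError("need (ref, alt) counts for at least two samples")
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("counts must be non-negative")
    cols = ref + alt
    A = int(alt.sum())
    N = int(cols.sum())
    if A == 0 or A == N or (cols == 0).all():
        return FisherResult(1.0, "exact")
    if len(ref) == 2:
        return FisherResult(fisher_2x2(ref[0], alt[0], ref[1], alt[1]), "exact")

    log_denom = _log_ncr(N, A)
    log_p_obs = float(_log_ncr(cols, alt).sum() - log_denom)

    if len(ref) == 3 and N <= max_exact_total:
        a1 = np.arange(0, min(cols[0], A) + 1)
        a2 = np.arange(0, min(cols[1], A) + 1)
        g1, g2 = np.meshgrid(a1, a2, indexing="ij")
        g3 = A - g1 - g2
        valid = (g3 >= 0) & (g3 <= cols[2])
        logp = (
            _log_ncr(cols[0], g1) + _log_ncr(cols[1], g2) + _log_ncr(cols[2], g3)
            - log_denom
        )
        mask = valid & (logp <= log_p_obs + _LOG_P_TOL)
        return FisherResult(float(np.exp(logp[mask]).sum()), "exact")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, A, size=n_mc)
    logp = _log_ncr(cols[None, :], draws).sum(axis=1) - log_denom
    hits = logp <= log_p_obs + _LOG_P_TOL
    p_hat = float(hits.mean())
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_mc))
    return FisherResult(p_hat, "monte_carlo", se)


def fisher_2x3(
    germ_ref: int,
    germ_alt: int,
    t1_ref: int,
    t1_alt: int,
    t2_ref: int,
    t2_alt: int,
    **kwargs,
) -> float:
    """Two-sided Fisher exact p for a 2x3 table (germline and two tumors)."""
    return fisher_exact_2xk(
        [germ_ref, t1_ref, t2_ref], [germ_alt, t1_alt, t2_alt], **kwargs
    ).p_value


@dataclass(frozen=True)
class FprResult:
    """Observed false positive rate of a batch of null comparisons."""

    p_values: tuple[float, ...]
    alpha: float
    n_sites: int
    fpr: float


def compute_fpr(p_values: Sequence[float], alpha: float = 0.05) -> FprResult:
    """Fraction of p-values below alpha across a set of null-site tests."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    fpr = float((p < alpha).mean())
    return FprResult(tuple(p.tolist()), alpha, int(p.size), fpr)


def benjamini_hochberg(p_values: Sequence[float], fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask at the given FDR.

    Rejects hypotheses 1..k* in p-value order, where k* is the largest k
    with p_(k) <= k/m * fdr.
    """
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = fdr * (np.arange(1, m + 1) / m)
    passing = np.nonzero(p[order] <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def identify_somatic(
    counts: pd.DataFrame,
    germline_sample: str,
    min_cov: int = 50,
    germ_alt_max: float = 0.10,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Identify somatic sites from germline + tumor allele counts.

    ``counts`` is an allele count table (see :func:`count_alleles`) holding
    the germline sample and at least one tumor sample.  Per site (target,
    position) covered to ``min_cov`` ref+alt depth in every sample, a 2xk
    Fisher exact test compares allele frequencies across samples; p-values
    are Benjamini-Hochberg adjusted across sites, and a site is somatic when
    it is significant at ``fdr`` and the germline alternate frequency is
    below ``germ_alt_max``.
    """
    samples = list(dict.fromkeys(counts["sample_id"]))
    if germline_sample not in samples:
        raise ValueError(f"germline sample {germline_sample!r} not in counts")
    if len(samples) < 2:
        raise ValueError("need a germline and at least one tumor sample")
    tumor_samples = [s for s in samples if s != germline_sample]

    wide = counts.set_index(["target_id", "position", "sample_id"])[["n_ref", "n_alt"]]
    rows = []
    for (target_id, position), grp in wide.groupby(level=[0, 1]):
        per_sample = grp.droplevel([0, 1])
        if not all(s in per_sample.index for s in samples):
            continue
        ref = [int(per_sample.loc[s, "n_ref"]) for s in [germline_sample] + tumor_samples]
        alt = [int(per_sample.loc[s, "n_alt"]) for s in [germline_sample] + tumor_samples]
        depths = [r + a for r, a in zip(ref, alt)]
        if min(depths) < min_cov:
            continue
        germ_alt_freq = alt[0] / depths[0]
        p = fisher_exact_2xk(ref, alt, seed=seed).p_value
        rows.append(
            {
                "target_id": target_id,
                "position": position,
                "germ_alt_freq": germ_alt_freq,
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["target_id", "position", "germ_alt_freq", "p_value"]
    )
    if result.empty:
        result["significant"] = pd.Series(dtype=bool)
        result["somatic"] = pd.Series(dtype=bool)
        return result
    result["significant"] = benjamini_hochberg(result["p_value"].to_numpy(), fdr)
    result["somatic"] = result["significant"] & (result["germ_alt_freq"] < germ_alt_max)
    return result
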