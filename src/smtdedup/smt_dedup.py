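"""Mark PCR duplicates by single molecule tag and summarise tag usage.

Within one target of one sample, the first read carrying a given SMT is the
unique (template-defining) read; every later read with that tag is a
duplicate.  Duplicates are strictly per-target: the same tag on two targets
marks two independent templates.  Tags containing N cannot establish
molecular identity and are excluded up front with a QC tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._dna import gc_fraction
from .formats_io import TargetDesign

UNIQUE = "UNIQUE"
DUPLICATE = "DUPLICATE"


@dataclass(frozen=True)
class DedupAnnotation:
    read_id: str
    target_id: str
    smt: str
    label: str
    cluster_rank: int  # 1 = first occurrence of this (target, SMT)


def mark_duplicates(
    records: Iterable[tuple[str, str, str]],
    qc_counts: dict[str, int] | None = None,
) -> Iterator[DedupAnnotation]:
    """Label a stream of ``(read_id, target_id, smt)`` records in input order.

    Single pass, deterministic: the first occurrence of each (target, SMT)
    pair is UNIQUE with cluster_rank 1; later occurrences are DUPLICATE with
    consecutive ranks.  Reads whose tag contains N are skipped and counted in
    ``qc_counts['smt_with_N']`` when a counter dict is supplied.
    """
    seen: dict[tuple[str, str], int] = {}
    for read_id, target_id, smt in records:
        if "N" in smt:
            if qc_counts is not None:
                qc_counts["smt_with_N"] = qc_counts.get("smt_with_N", 0) + 1
            continue
        key = (target_id, smt)
        rank = seen.get(key, 0) + 1
        seen[key] = rank
        yield DedupAnnotation(
            read_id=read_id,
            target_id=target_id,
            smt=smt,
            label=UNIQUE if rank == 1 else DUPLICATE,
            cluster_rank=rank,
        )


def cluster_size_histogram(annotations: Iterable[DedupAnnotation]) -> dict[int, int]:
    """Map cluster size -> number of (target, SMT) clusters of that size.

    Invariants: sum(size * count) equals the number of annotated reads and
    sum(count) the number of distinct (target, SMT) pairs.
    """
    max_rank: dict[tuple[str, str], int] = {}
    for ann in annotations:
        key = (ann.target_id, ann.smt)
        if ann.cluster_rank > max_rank.get(key, 0):
            max_rank[key] = ann.cluster_rank
    return dict(Counter(max_rank.values()))


def duplicate_rate_report(
    annotations: Iterable[DedupAnnotation],
    by: str = "sample",
    designs: Sequence[TargetDesign] | None = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Duplicate counts and rates, per sample or per target.

    ``by='target'`` adds per-target covariate columns — coverage (n_total)
    and the GC fractions of the insert and of each locus-specific primer —
    so a user can regress duplicate rate on them with any standard linear
    model; the regression itself is out of scope here.
    """
    if by not in ("sample", "target"):
        raise ValueError("by must be 'sample' or 'target'")
    totals: Counter[str] = Counter()
    dups: Counter[str] = Counter()
    for ann in annotations:
        key = sample_id if by == "sample" else ann.target_id
        totals[key] += 1
        if ann.label == DUPLICATE:
            dups[key] += 1
    rows = []
    design_map = {d.target_id: d for d in designs} if designs else {}
    for key in totals:
        n_total = totals[key]
        n_dup = dups[key]
        row = {
            ("sample_id" if by == "sample" else "target_id"): key,
            "n_total": n_total,
            "n_unique": n_total - n_dup,
            "n_duplicate": n_dup,
            "rate": n_dup / n_total,
        }
        if by == "target" and key in design_map:
            d = design_map[key]
            row["coverage"] = n_total
            row["insert_gc"] = gc_fraction(d.insert_seq)
            row["upstream_primer_gc"] = gc_fraction(d.upstream_primer)
            row["downstream_primer_gc"] = gc_fraction(d.downstream_primer)
        rows.append(row)
    return pd.DataFrame(rows)


def _smt_matrix(smts: Sequence[str]) -> np.ndarray:
    arr = np.asarray(smts, dtype="U")
    if arr.size == 0:
        raise ValueError("empty SMT list")
    lengths = {len(s) for s in smts}
    if len(lengths) != 1:
        raise ValueError(f"mixed SMT lengths: {sorted(lengths)}")
    (length,) = lengths
    return arr.view(np.uint32).reshape(arr.size, -1)[:, :length]


def smt_diversity(
    smts: Sequence[str],
    max_pairs: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean pairwise Hamming distance, fraction of pairs at distance 1).

    All unordered pairs are evaluated unless there are more than
    ``max_pairs``, in which case pairs are subsampled reproducibly with
    ``seed``.  High mean distance and a vanishing distance-1 fraction
    indicate that observed tag reuse is not a product of sequencing error.
    """
    mat = _smt_matrix(smts)
    n = mat.shape[0]
    n_pairs = n * (n - 1) // 2
    if n_pairs == 0:
        return (0.0, 0.0)
    if n_pairs <= max_pairs:
        idx = np.array(list(combinations(range(n), 2)))
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=2 * max_pairs)
        j = rng.integers(0, n, size=2 * max_pairs)
        keep = i < j
        idx = np.column_stack([i[keep], j[keep]])[:max_pairs]
    dists = (mat[idx[:, 0]] != mat[idx[:, 1]]).sum(axis=1)
    return float(dists.mean()), float((dists == 1).mean())


def smt_positional_base_frequencies(smts: Sequence[str]) -> pd.DataFrame:
    """Per-position A/C/G/T frequency table (rows = positions, columns sum to 1).

    A tabular stand-in for a sequence-logo view of tag composition; biased
    tag synthesis (e.g. poly-T enrichment) shows up as positions where one
    base exceeds the uniform 0.25.
    """
    mat = _smt_matrix(smts)
    out = {}
    for base in "ACGT":
        out[base] = (mat == ord(base)).mean(axis=0)
    df = pd.DataFrame(out)
    df.index.name = "position"
    return df


def annotations_to_frame(annotations: Iterable[DedupAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.read_id, a.target_id, a.smt, a.label, a.cluster_rank) for a in annotations],
        columns=["read_id", "target_id", "smt", "label", "cluster_rank"],
    )
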