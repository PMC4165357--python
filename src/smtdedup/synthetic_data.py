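"""Synthetic SMT-tagged amplicon data with known truth, plus the
sample-splitting / duplicate-injection experiments.

The generator emulates a targeted amplicon panel: ~150 bp inserts flanked by
locus-specific primers, per-target depths with negative-binomial spread,
random 8- or 12-mer tags (optionally poly-T biased), heterozygous SNPs at
50% allele frequency, configurable PCR duplicate rates, and per-base
sequencing error.  Duplicates are created occupancy-style — resampling with
replacement from the unique templates — matching how duplicate injection is
defined, not via a PCR branching process.

Two layers exist: a fast records level (arrays of target / tag / allele /
template identity) that all statistics run on, and a FASTQ rendering level
that emits real read triplets to exercise the assignment and trimming
pipeline end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._dna import BASES, decode_tag, revcomp
from .allele_stats import call_het_snps, compute_fpr, count_alleles, fisher_2x2
from .formats_io import SnpAnnotation, TaggedReadPair, TargetDesign
from .target_assignment import PREFIX_LEN, bounded_levenshtein


@dataclass(frozen=True)
class PolyTBias:
    """Tag synthesis bias: with probability ``weight`` a run of ``run_length``
    T's is planted at a random offset of an otherwise-uniform tag."""

    weight: float = 0.2
    run_length: int = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic panel/sample.

    Defaults mirror a deep targeted amplicon experiment: a 1,225-target panel
    of 150 bp inserts sequenced to ~1,000X with a 12-base tag, ~10% PCR
    duplicates, heterozygous SNPs on a sixth of targets, and 0.5% per-base
    sequencing error.  ``seed`` is mandatory: every stochastic operation is a
    pure function of (inputs, seed).
    """

    seed: int
    n_targets: int = 1225
    insert_length: int = 150
    smt_length: int = 12
    read_length: int = 151
    primer_length: int = 24
    mean_depth: float = 1000.0
    depth_dispersion: float = 10.0  # negative-binomial size; None = fixed depth
    duplicate_rate: float = 0.1
    het_fraction: float = 0.16
    error_rate: float = 0.005
    smt_error_rate: float = 0.0
    smt_bias: PolyTBias | None = None
    gc_range: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        if self.smt_length not in (8, 12):
            raise ValueError("smt_length must be 8 or 12")
        for name in ("duplicate_rate", "het_fraction", "error_rate", "smt_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= (0.9 if name == "duplicate_rate" else 1.0):
                raise ValueError(f"{name}={v} out of range")


@dataclass
class ReadRecords:
    """Truth-level view of a read set: one entry per read, no sequences.

    ``template`` identifies the original molecule, so truth duplicate status
    is "not the first occurrence of my template in emitted order".
    """

    target: np.ndarray  # int32 index into the design list
    smt: np.ndarray  # int64 packed tag codes
    allele: np.ndarray  # int8: -1 no SNP, 0 ref, 1 alt
    template: np.ndarray  # int64 molecule identity

    @property
    def n(self) -> int:
        return len(self.target)

    def subset(self, idx: np.ndarray) -> "ReadRecords":
        return ReadRecords(
            self.target[idx], self.smt[idx], self.allele[idx], self.template[idx]
        )

    def truth_duplicate(self) -> np.ndarray:
        """Boolean truth labels: True where the template was seen before."""
        _, first = np.unique(self.template, return_index=True)
        is_dup = np.ones(self.n, dtype=bool)
        is_dup[first] = False
        return is_dup

    def to_dataframe(self, designs: Sequence[TargetDesign] | None = None,
                     smt_length: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "target": self.target,
                "smt_code": self.smt,
                "allele": self.allele,
                "template": self.template,
                "is_duplicate": self.truth_duplicate(),
            }
        )
        if designs is not None:
            df["target_id"] = [designs[i].target_id for i in self.target]
        if smt_length is not None:
            df["smt"] = [decode_tag(c, smt_length) for c in self.smt]
        return df


def concat_records(parts: Sequence[ReadRecords]) -> ReadRecords:
    return ReadRecords(
        np.concatenate([p.target for p in parts]),
        np.concatenate([p.smt for p in parts]),
        np.concatenate([p.allele for p in parts]),
        np.concatenate([p.template for p in parts]),
    )


def _random_insert(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=probs))


def generate_design(config: SimulationConfig, max_retries: int = 200) -> list[TargetDesign]:
    """Generate an amplicon panel whose primer windows are unambiguous.

    Insert GC is drawn uniformly from ``gc_range`` per target.  Each new
    design's 22-base comparison windows (both read orientations) must be
    Levenshtein distance > 4 from every accepted window, guaranteeing that
    assignment at the default max_dist of 2 can never tie; designs failing
    after ``max_retries`` draws raise.  Targets carry one mid-insert
    heterozygous SNP with probability ``het_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD5]))
    designs: list[TargetDesign] = []
    windows: list[str] = []
    for t in range(config.n_targets):
        for attempt in range(max_retries):
            gc = rng.uniform(*config.gc_range)
            upstream = _random_insert(rng, config.primer_length, 0.5)
            downstream = _random_insert(rng, config.primer_length, 0.5)
            w2 = upstream[:PREFIX_LEN]
            w1 = revcomp(downstream)[:PREFIX_LEN]
            if any(
                bounded_levenshtein(w, existing, 4) >= 0
                for w in (w1, w2)
                for existing in windows
            ) or bounded_levenshtein(w1, w2, 4) >= 0:
                continue
            insert = _random_insert(rng, config.insert_length, gc)
            snps: tuple[SnpAnnotation, ...] = ()
            if rng.random() < config.het_fraction:
                pos = config.insert_length // 2
                ref = insert[pos]
                alt = rng.choice([b for b in BASES if b != ref])
                snps = (SnpAnnotation(position=pos, ref_allele=ref, alt_allele=alt),)
            designs.append(
                TargetDesign(
                    target_id=f"T{t:05d}",
                    upstream_primer=upstream,
                    downstream_primer=downstream,
                    insert_seq=insert,
                    snps=snps,
                )
            )
            windows.extend([w1, w2])
            break
        else:
            raise RuntimeError(
                f"could not place separable primers for target {t} "
                f"after {max_retries} retries"
            )
    return designs


def draw_smt_codes(
    rng: np.random.Generator,
    n: int,
    smt_length: int,
    bias: PolyTBias | None = None,
) -> np.ndarray:
    """Draw ``n`` packed tag codes, uniform or poly-T biased."""
    base_mat = rng.integers(0, 4, size=(n, smt_length), dtype=np.int64)
    if bias is not None and bias.weight > 0:
        biased = rng.random(n) < bias.weight
        run = min(bias.run_length, smt_length)
        offsets = rng.integers(0, smt_length - run + 1, size=n)
        for i in np.nonzero(biased)[0]:
            base_mat[i, offsets[i] : offsets[i] + run] = 3  # T
    weights = (4 ** np.arange(smt_length - 1, -1, -1)).astype(np.int64)
    return base_mat @ weights


def _target_depths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.depth_dispersion is None:
        return np.full(n, int(round(config.mean_depth)), dtype=np.int64)
    size = config.depth_dispersion
    p = size / (size + config.mean_depth)
    return np.maximum(1, rng.negative_binomial(size, p, size=n))


def generate_sample_records(
    designs: Sequence[TargetDesign],
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> ReadRecords:
    """Generate one sample at the records level.

    Per target: depth d ~ NegBin(mean_depth, dispersion); m = round(d * (1 -
    duplicate_rate)) unique templates each receive a tag and, on het targets,
    a Bernoulli(0.5) allele; the remaining d - m reads are duplicates drawn
    with replacement from the templates, inheriting tag and allele.  Reads
    are shuffled within each target so "first occurrence" is not structured.
    """
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 0x5A])
    rng = np.random.default_rng(seed)
    het = np.array([len(d.snps) > 0 for d in designs])
    depths = _target_depths(rng, config, len(designs))
    parts: list[ReadRecords] = []
    template_base = 0
    for t, d in enumerate(depths):
        d = int(d)
        m = int(round(d * (1 - config.duplicate_rate)))
        if m == 0:
            warnings.warn(
                f"target {t}: no unique templates at depth {d} and duplicate "
                f"rate {config.duplicate_rate}; skipped"
            )
            continue
        smts = draw_smt_codes(rng, m, config.smt_length, config.smt_bias)
        alleles = (
            rng.integers(0, 2, size=m).astype(np.int8)
            if het[t]
            else np.full(m, -1, dtype=np.int8)
        )
        templates = template_base + np.arange(m, dtype=np.int64)
        template_base += m
        src = np.concatenate([np.arange(m), rng.integers(0, m, size=d - m)])
        src = rng.permutation(src)
        parts.append(
            ReadRecords(
                target=np.full(d, t, dtype=np.int32),
                smt=smts[src],
                allele=alleles[src],
                template=templates[src],
            )
        )
    if not parts:
        raise RuntimeError("no targets produced any reads")
    return concat_records(parts)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        chars[pos] = BASES[(("ACGT".index(chars[pos]) if chars[pos] in BASES else 0)
                            + rng.integers(1, 4)) % 4]
    return "".join(chars)


def render_reads(
    records: ReadRecords,
    designs: Sequence[TargetDesign],
    config: SimulationConfig,
    sample_id: str = "S1",
    seed: int | np.random.SeedSequence | None = None,
) -> Iterator[TaggedReadPair]:
    """Render records as sequenced read pairs with per-base error.

    Read 2 runs forward from the upstream primer; Read 1 is the reverse
    complement end, starting with the reverse complement of the downstream
    primer.  Qualities are constant Q30 (the pipeline never consumes them).
    """
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 0xF0])
    rng = np.random.default_rng(seed)
    qual = "?" * config.read_length
    for i in range(records.n):
        d = designs[records.target[i]]
        insert = d.insert_seq
        if records.allele[i] == 1 and d.snps:
            snp = d.snps[0]
            insert = insert[: snp.position] + snp.alt_allele + insert[snp.position + 1 :]
        amplicon = d.upstream_primer + insert + d.downstream_primer
        seq2 = amplicon[: config.read_length]
        seq1 = revcomp(amplicon)[: config.read_length]
        seq1 = _apply_errors(rng, seq1, config.error_rate)
        seq2 = _apply_errors(rng, seq2, config.error_rate)
        smt = decode_tag(int(records.smt[i]), config.smt_length)
        smt = _apply_errors(rng, smt, config.smt_error_rate)
        yield TaggedReadPair(
            read_id=f"sim:{sample_id}:{i}",
            seq1=seq1,
            qual1=qual[: len(seq1)],
            seq2=seq2,
            qual2=qual[: len(seq2)],
            smt=smt,
            sample_id=sample_id,
        )


def generate_sample(
    designs: Sequence[TargetDesign],
    config: SimulationConfig,
    sample_id: str = "S1",
) -> tuple[list[TaggedReadPair], pd.DataFrame]:
    """Generate one full synthetic sample: read pairs plus a truth table."""
    records = generate_sample_records(designs, config)
    pairs = list(render_reads(records, designs, config, sample_id=sample_id))
    truth = records.to_dataframe(designs, smt_length=config.smt_length)
    truth.insert(0, "read_id", [p.read_id for p in pairs])
    return pairs, truth


def split_sample(
    records: ReadRecords, seed: int | np.random.SeedSequence
) -> tuple[ReadRecords, ReadRecords]:
    """Randomly split reads into two disjoint pseudo-samples of near-equal size."""
    if records.n < 2:
        raise ValueError("need at least 2 reads to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(records.n)
    half = records.n // 2
    return records.subset(perm[:half]), records.subset(perm[half:])


def inject_duplicates(
    records: ReadRecords,
    rate: float,
    seed: int | np.random.SeedSequence,
    constant_depth: bool = True,
) -> ReadRecords:
    """Inject a defined duplicate proportion into a unique read set.

    With ``constant_depth`` (the default), m = round(n(1-rate)) reads are
    kept (sampled without replacement) and n - m duplicates are drawn with
    replacement from the kept set, so total depth stays n and the duplicate
    fraction is exactly (n - m)/n.  Duplicates inherit their source read's
    tag and allele by construction.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return records.subset(np.arange(records.n))
    rng = np.random.default_rng(seed)
    n = records.n
    if constant_depth:
        m = int(round(n * (1 - rate)))
        if m == 0:
            raise ValueError(f"rate {rate} leaves no unique reads at n={n}")
        kept = rng.choice(n, size=m, replace=False)
        dup_src = kept[rng.integers(0, m, size=n - m)]
        idx = rng.permutation(np.concatenate([kept, dup_src]))
    else:
        n_dup = int(round(n * rate / (1 - rate)))
        dup_src = rng.integers(0, n, size=n_dup)
        idx = rng.permutation(np.concatenate([np.arange(n), dup_src]))
    return records.subset(idx)


def allocate_experimental_duplicates(
    half_a: ReadRecords,
    half_b: ReadRecords,
    duplicates: ReadRecords,
) -> tuple[ReadRecords, ReadRecords, int]:
    """Attach observed duplicate reads to the half holding their unique read.

    Each duplicate follows the (target, SMT) of its unique read; duplicates
    whose tag is absent from both halves are dropped and counted.  Returns
    (augmented A, augmented B, n_dropped).
    """
    def keys(r: ReadRecords) -> set[tuple[int, int]]:
        return set(zip(r.target.tolist(), r.smt.tolist()))

    in_a, in_b = keys(half_a), keys(half_b)
    to_a, to_b = [], []
    dropped = 0
    for i in range(duplicates.n):
        key = (int(duplicates.target[i]), int(duplicates.smt[i]))
        if key in in_a:
            to_a.append(i)
        elif key in in_b:
            to_b.append(i)
        else:
            dropped += 1
    aug_a = concat_records([half_a, duplicates.subset(np.array(to_a, dtype=int))])
    aug_b = concat_records([half_b, duplicates.subset(np.array(to_b, dtype=int))])
    return aug_a, aug_b, dropped


def _het_site_counts(
    records: ReadRecords, het_targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(ref, alt) count vectors over ``het_targets`` for one read set."""
    covered = np.isin(records.target, het_targets) & (records.allele >= 0)
    t = records.target[covered]
    a = records.allele[covered]
    size = het_targets.max() + 1 if het_targets.size else 0
    ref = np.bincount(t[a == 0], minlength=size)[het_targets]
    alt = np.bincount(t[a == 1], minlength=size)[het_targets]
    return ref, alt


def _records_allele_counts(
    records: ReadRecords, designs: Sequence[TargetDesign], sample_id: str
) -> pd.DataFrame:
    """Allele count table over all SNP-bearing targets of one read set."""
    rows = []
    het_targets = np.array([i for i, d in enumerate(designs) if d.snps], dtype=int)
    if het_targets.size == 0:
        return count_alleles([])
    ref, alt = _het_site_counts(records, het_targets)
    for i, t in enumerate(het_targets):
        rows.append(
            {
                "sample_id": sample_id,
                "target_id": designs[t].target_id,
                "position": designs[t].snps[0].position,
                "n_ref": int(ref[i]),
                "n_alt": int(alt[i]),
                "n_other": 0,
            }
        )
    return pd.DataFrame(rows)


def fpr_experiment(
    config: SimulationConfig,
    rates: Sequence[float],
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    min_depth: int = 50,
    designs: Sequence[TargetDesign] | None = None,
) -> pd.DataFrame:
    """The duplicate-injection false-positive-rate experiment.

    Per replicate: generate one sample's unique reads, call heterozygous
    SNPs from them, split the uniques into two pseudo-samples, then for each
    requested duplicate rate inject duplicates into each half independently
    (total depth preserved) and Fisher-test ref/alt counts at every callable
    het SNP between the halves.  Since both halves are drawn from one urn,
    every significant test is a false positive.  Returns a tidy table with
    columns (rate, replicate, n_sites, fpr), fully determined by ``seed``.
    """
    if designs is None:
        designs = generate_design(config)
    het_targets = np.array([i for i, d in enumerate(designs) if d.snps], dtype=int)
    if het_targets.size == 0:
        raise ValueError("design set contains no heterozygous SNP targets")
    cfg_unique = replace(config, duplicate_rate=0.0)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(root.spawn(n_replicates)):
        streams = rep_ss.spawn(2 + 2 * len(rates))
        uniques = generate_sample_records(designs, cfg_unique, seed=streams[0])
        counts = _records_allele_counts(uniques, designs, "parent")
        het_ids = {
            c.target_id for c in call_het_snps(counts, min_depth=min_depth) if c.is_het
        }
        if not het_ids:
            raise ValueError("no heterozygous SNPs callable from unique reads")
        tested = np.array(
            [i for i in het_targets if designs[i].target_id in het_ids], dtype=int
        )
        half_a, half_b = split_sample(uniques, streams[1])
        for j, rate in enumerate(rates):
            aug_a = inject_duplicates(half_a, rate, streams[2 + 2 * j])
            aug_b = inject_duplicates(half_b, rate, streams[3 + 2 * j])
            ref_a, alt_a = _het_site_counts(aug_a, tested)
            ref_b, alt_b = _het_site_counts(aug_b, tested)
            p_values = [
                fisher_2x2(ra, aa, rb, ab)
                for ra, aa, rb, ab in zip(ref_a, alt_a, ref_b, alt_b)
            ]
            result = compute_fpr(p_values, alpha=alpha)
            rows.append(
                {
                    "rate": rate,
                    "replicate": rep,
                    "n_sites": result.n_sites,
                    "fpr": result.fpr,
                }
            )
    return pd.DataFrame(rows, columns=["rate", "replicate", "n_sites", "fpr"])


def allele_frequency_variance_experiment(
    config: SimulationConfig,
    rates: Sequence[float],
    n_injections: int,
    seed: int,
    designs: Sequence[TargetDesign] | None = None,
) -> pd.DataFrame:
    """Variance of the alt-allele frequency estimate under duplicate injection.

    One parent sample's unique reads are generated once; for each duplicate
    rate, ``n_injections`` independent injections are performed at constant
    total depth and the alt frequency at every het SNP is recorded.  Returned
    per rate: the mean (across sites) of the variance (across injections) of
    the frequency estimate.  Duplicates add no information, so this variance
    grows with the duplicate rate even though depth is fixed.
    """
    if designs is None:
        designs = generate_design(config)
    het_targets = np.array([i for i, d in enumerate(designs) if d.snps], dtype=int)
    if het_targets.size == 0:
        raise ValueError("design set contains no heterozygous SNP targets")
    root = np.random.SeedSequence(seed)
    ss_gen, ss_inj = root.spawn(2)
    uniques = generate_sample_records(
        designs, replace(config, duplicate_rate=0.0), seed=ss_gen
    )
    inj_streams = iter(ss_inj.spawn(len(rates) * n_injections))
    rows = []
    for rate in rates:
        freqs = np.empty((n_injections, het_targets.size))
        for k in range(n_injections):
            injected = inject_duplicates(uniques, rate, next(inj_streams))
            ref, alt = _het_site_counts(injected, het_targets)
            with np.errstate(invalid="ignore"):
                freqs[k] = alt / (ref + alt)
        rows.append(
            {
                "rate": rate,
                "n_injections": n_injections,
                "mean_alt_freq_variance": float(
                    np.nanvar(freqs, axis=0, ddof=1).mean()
                ),
            }
        )
    return pd.DataFrame(rows, columns=["rate", "n_injections", "mean_alt_freq_variance"])
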