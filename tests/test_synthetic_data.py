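"""Generator truth, splitting, duplicate injection, and the FPR experiments."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from smtdedup import (
    SimulationConfig,
    allele_frequency_variance_experiment,
    allocate_experimental_duplicates,
    fpr_experiment,
    generate_design,
    generate_sample,
    generate_sample_records,
    inject_duplicates,
    mark_duplicates,
    split_sample,
)
from smtdedup.synthetic_data import ReadRecords
from smtdedup._dna import decode_tag

from conftest import dp_levenshtein


def _dedup_rate(records) -> float:
    smts = [decode_tag(int(c), 12) for c in records.smt]
    anns = list(
        mark_duplicates(
            (str(i), str(t), s) for i, (t, s) in enumerate(zip(records.target, smts))
        )
    )
    return sum(a.label == "DUPLICATE" for a in anns) / len(anns)


class TestGenerateDesign:
    def test_windows_pairwise_separated(self):
        """All 22-base comparison windows are Levenshtein distance >= 5 apart
        (full-DP check), so assignment can never tie at max_dist 2."""
        cfg = SimulationConfig(seed=3, n_targets=10)
        designs = generate_design(cfg)
        from smtdedup._dna import revcomp

        windows = [d.upstream_primer[:22] for d in designs] + [
            revcomp(d.downstream_primer)[:22] for d in designs
        ]
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                assert dp_levenshtein(windows[i], windows[j]) >= 5

    def test_het_fraction_one_places_snp_everywhere(self):
        cfg = SimulationConfig(seed=3, n_targets=10, het_fraction=1.0)
        designs = generate_design(cfg)
        assert all(len(d.snps) == 1 for d in designs)
        for d in designs:
            snp = d.snps[0]
            assert d.insert_seq[snp.position] == snp.ref_allele

    def test_same_seed_identical_design(self):
        cfg = SimulationConfig(seed=9, n_targets=6)
        assert generate_design(cfg) == generate_design(cfg)

    def test_gc_spans_configured_range(self):
        from smtdedup._dna import gc_fraction

        cfg = SimulationConfig(seed=4, n_targets=40, gc_range=(0.25, 0.75))
        gcs = [gc_fraction(d.insert_seq) for d in generate_design(cfg)]
        assert min(gcs) < 0.4 and max(gcs) > 0.6


class TestGenerateSample:
    def test_zero_duplicate_rate_all_unique(self):
        cfg = SimulationConfig(seed=5, n_targets=10, mean_depth=200, duplicate_rate=0.0)
        recs = generate_sample_records(generate_design(cfg), cfg)
        assert not recs.truth_duplicate().any()
        assert _dedup_rate(recs) < 1e-3  # only chance collisions possible

    def test_configured_rate_recovered_and_alleles_balanced(self):
        cfg = SimulationConfig(
            seed=6, n_targets=20, mean_depth=1000, duplicate_rate=0.5,
            het_fraction=1.0, error_rate=0.0,
        )
        designs = generate_design(cfg)
        recs = generate_sample_records(designs, cfg)
        assert _dedup_rate(recs) == pytest.approx(0.5, abs=0.03)
        # truth label matches configured rate
        assert recs.truth_duplicate().mean() == pytest.approx(0.5, abs=0.03)
        # unique reads at het sites are ~50% alt
        uniq = recs.subset(~recs.truth_duplicate())
        covered = uniq.allele >= 0
        assert uniq.allele[covered].mean() == pytest.approx(0.5, abs=0.02)

    def test_duplicates_inherit_template_tag_and_allele(self):
        cfg = SimulationConfig(
            seed=7, n_targets=5, mean_depth=300, duplicate_rate=0.4, het_fraction=1.0
        )
        recs = generate_sample_records(generate_design(cfg), cfg)
        df = pd.DataFrame(
            {"template": recs.template, "smt": recs.smt, "allele": recs.allele}
        )
        per_template = df.groupby("template").nunique()
        assert (per_template["smt"] == 1).all()
        assert (per_template["allele"] == 1).all()

    def test_full_sample_truth_is_consistent_with_fastq(self):
        cfg = SimulationConfig(
            seed=8, n_targets=6, mean_depth=40, error_rate=0.0, het_fraction=0.5
        )
        designs = generate_design(cfg)
        pairs, truth = generate_sample(designs, cfg)
        assert len(pairs) == len(truth)
        assert [p.smt for p in pairs] == list(truth["smt"])
        # dedup of the emitted triplet matches the truth duplicate count
        anns = list(
            mark_duplicates(zip(truth["read_id"], truth["target_id"], truth["smt"]))
        )
        assert sum(a.label == "DUPLICATE" for a in anns) == int(
            truth["is_duplicate"].sum()
        )

    def test_determinism(self):
        cfg = SimulationConfig(seed=11, n_targets=5, mean_depth=50)
        designs = generate_design(cfg)
        a = generate_sample_records(designs, cfg)
        b = generate_sample_records(designs, cfg)
        assert (a.smt == b.smt).all() and (a.target == b.target).all()


class TestSplitSample:
    def _records(self, n):
        return ReadRecords(
            target=np.zeros(n, dtype=np.int32),
            smt=np.arange(n, dtype=np.int64),
            allele=np.full(n, -1, dtype=np.int8),
            template=np.arange(n, dtype=np.int64),
        )

    def test_disjoint_halves_cover_input(self):
        a, b = split_sample(self._records(10), seed=1)
        assert a.n == 5 and b.n == 5
        assert sorted(np.concatenate([a.smt, b.smt]).tolist()) == list(range(10))

    def test_odd_split(self):
        a, b = split_sample(self._records(11), seed=1)
        assert {a.n, b.n} == {5, 6}

    def test_seeded(self):
        a1, _ = split_sample(self._records(10), seed=2)
        a2, _ = split_sample(self._records(10), seed=2)
        assert (a1.smt == a2.smt).all()

    def test_too_few_reads(self):
        with pytest.raises(ValueError):
            split_sample(self._records(1), seed=0)

    def test_split_halves_are_an_frequency_null(self):
        """Both halves draw from one urn: 2x2 Fisher FPR across het sites
        stays at or below alpha (within binomial noise)."""
        from smtdedup.allele_stats import fisher_2x2
        from smtdedup.synthetic_data import _het_site_counts

        cfg = SimulationConfig(
            seed=13, n_targets=100, mean_depth=600, duplicate_rate=0.0, het_fraction=1.0
        )
        recs = generate_sample_records(generate_design(cfg), cfg)
        a, b = split_sample(recs, seed=3)
        het = np.arange(100)
        (ra, aa), (rb, ab) = _het_site_counts(a, het), _het_site_counts(b, het)
        p = [fisher_2x2(*t) for t in zip(ra, aa, rb, ab)]
        fpr = np.mean(np.array(p) < 0.05)
        assert fpr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)


class TestInjectDuplicates:
    def _uniques(self, n=100):
        return ReadRecords(
            target=np.zeros(n, dtype=np.int32),
            smt=np.arange(n, dtype=np.int64),
            allele=np.tile([0, 1], n // 2).astype(np.int8),
            template=np.arange(n, dtype=np.int64),
        )

    def test_rate_zero_is_identity(self):
        u = self._uniques()
        out = inject_duplicates(u, 0.0, seed=1)
        assert (np.sort(out.smt) == np.sort(u.smt)).all() and out.n == u.n

    def test_constant_depth_exact_composition(self):
        """n=100 at rate 0.3: 70 kept uniques + 30 duplicates whose tags all
        come from the kept set; measured duplicate rate is exactly 0.3."""
        u = self._uniques(100)
        out = inject_duplicates(u, 0.3, seed=2)
        assert out.n == 100
        kept = set(out.template.tolist())
        assert len(kept) == 70
        assert out.truth_duplicate().sum() == 30
        # every duplicate's tag is present among the kept uniques
        assert set(out.smt.tolist()) <= set(u.smt.tolist())

    def test_growing_mode_preserves_all_uniques(self):
        u = self._uniques(100)
        out = inject_duplicates(u, 0.3, seed=2, constant_depth=False)
        assert set(u.template.tolist()) <= set(out.template.tolist())
        assert out.truth_duplicate().mean() == pytest.approx(0.3, abs=0.01)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            inject_duplicates(self._uniques(), 1.0, seed=0)
        with pytest.raises(ValueError):
            inject_duplicates(self._uniques(), -0.1, seed=0)


class TestAllocateExperimentalDuplicates:
    def test_duplicates_follow_their_unique_read(self):
        half_a = ReadRecords(
            np.array([0], dtype=np.int32), np.array([7], dtype=np.int64),
            np.array([0], dtype=np.int8), np.array([0], dtype=np.int64),
        )
        half_b = ReadRecords(
            np.array([0], dtype=np.int32), np.array([9], dtype=np.int64),
            np.array([1], dtype=np.int8), np.array([1], dtype=np.int64),
        )
        dups = ReadRecords(
            np.array([0, 0, 0], dtype=np.int32),
            np.array([7, 7, 5], dtype=np.int64),  # 5 matches neither half
            np.array([0, 0, 0], dtype=np.int8),
            np.array([0, 0, 9], dtype=np.int64),
        )
        aug_a, aug_b, dropped = allocate_experimental_duplicates(half_a, half_b, dups)
        assert aug_a.n == 3 and aug_b.n == 1 and dropped == 1
        assert aug_a.n + aug_b.n == half_a.n + half_b.n + dups.n - dropped


class TestFprExperiment:
    CFG = SimulationConfig(seed=21, n_targets=60, mean_depth=400, het_fraction=1.0)

    def test_table_shape_and_determinism(self):
        t1 = fpr_experiment(self.CFG, [0.0, 0.5], 2, seed=5)
        t2 = fpr_experiment(self.CFG, [0.0, 0.5], 2, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1.columns) == {"rate", "replicate", "n_sites", "fpr"}
        assert len(t1) == 4

    def test_dedup_only_fpr_near_alpha(self):
        table = fpr_experiment(self.CFG, [0.0], 6, seed=7)
        mean_fpr = table["fpr"].mean()
        n_tests = table["n_sites"].sum()
        assert mean_fpr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)

    def test_duplicates_inflate_fpr(self):
        table = fpr_experiment(self.CFG, [0.0, 0.75], 4, seed=9)
        means = table.groupby("rate")["fpr"].mean()
        assert means[0.75] > means[0.0]

    def test_no_het_targets_is_error(self):
        cfg = replace(self.CFG, het_fraction=0.0, n_targets=5)
        with pytest.raises(ValueError, match="het"):
            fpr_experiment(cfg, [0.0], 1, seed=1)


class TestAlleleFrequencyVariance:
    def test_variance_grows_with_duplicate_rate(self):
        cfg = SimulationConfig(seed=23, n_targets=20, mean_depth=500, het_fraction=1.0)
        table = allele_frequency_variance_experiment(
            cfg, [0.0, 0.25, 0.5, 0.75], n_injections=40, seed=3
        )
        v = table["mean_alt_freq_variance"].to_numpy()
        assert v[0] == pytest.approx(0.0, abs=1e-20)  # rate 0 is deterministic
        assert (np.diff(v) > 0).all()


class TestCollisionContamination:
    def test_12mer_vs_8mer_truth_disagreement(self):
        """Chance tag collisions mislabel truth-unique reads as duplicates:
        negligible with 12-mers at ~1,000X, but >0.3% with 8-mers."""
        base = dict(n_targets=30, mean_depth=1074, depth_dispersion=None,
                    duplicate_rate=0.0, het_fraction=0.0)
        for L, bound, comparator in ((12, 1e-4, "lt"), (8, 3e-3, "gt")):
            cfg = SimulationConfig(seed=29, smt_length=L, **base)
            recs = generate_sample_records(generate_design(cfg), cfg)
            smts = [decode_tag(int(c), L) for c in recs.smt]
            anns = list(
                mark_duplicates(
                    (str(i), str(t), s)
                    for i, (t, s) in enumerate(zip(recs.target, smts))
                )
            )
            # all reads are truth-unique, so every DUPLICATE is a collision
            frac = sum(a.label == "DUPLICATE" for a in anns) / len(anns)
            assert frac < bound if comparator == "lt" else frac > bound
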