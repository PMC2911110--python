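"""Pileup construction, genotype-likelihood scoring, filters, concordance."""

import itertools
import math

import numpy as np
import pytest

from capture_eval.coverage import depth_profile
from capture_eval.intervals import GenomicInterval, consolidate
from capture_eval.reads import ReadSet, encode_seq
from capture_eval.simulate import TruthSet, TruthVariant
from capture_eval.variants import (
    PileupColumn,
    VariantCall,
    apply_profile,
    build_pileup,
    call_variants,
    evaluate_calls,
    filter_illumina,
    filter_solid,
    read_calls_vcf,
    score_site,
    write_calls_vcf,
)


def column(ref="A", alt="C", n_ref=0, n_alt=0, alt_fwd=None, baseq=20.0, depth=None):
    """Build a pileup column with the given ref/alt counts (ref always split
    evenly across strands; alt split per alt_fwd or evenly)."""
    cf = np.zeros(4, dtype=np.int64)
    cr = np.zeros(4, dtype=np.int64)
    ri, ai = "ACGT".index(ref), "ACGT".index(alt)
    cf[ri] = n_ref // 2
    cr[ri] = n_ref - n_ref // 2
    if alt_fwd is None:
        alt_fwd = n_alt // 2
    cf[ai] = alt_fwd
    cr[ai] = n_alt - alt_fwd
    return PileupColumn(
        chrom="chr1", pos=100, ref=ref, depth=depth or (n_ref + n_alt),
        counts_fwd=cf, counts_rev=cr, mean_baseq=baseq,
    )


def brute_force_lod(n_ref, n_alt, eps):
    """Independent likelihood computation for the three-genotype model."""
    def ll(f):
        p_alt = f * (1 - eps) + (1 - f) * eps / 3
        p_ref = (1 - f) * (1 - eps) + f * eps / 3
        return n_ref * math.log10(p_ref) + n_alt * math.log10(p_alt)

    return max(ll(0.5), ll(1.0)) - ll(0.0)


def simple_reads(entries, genome, rl=10):
    """entries: list of (start, strand_rev, seq)"""
    starts = np.array([e[0] for e in entries])
    rs = ReadSet(
        "chr1", starts, starts + rl,
        np.array([e[1] for e in entries], bool),
        seq=np.stack([encode_seq(e[2]) for e in entries]),
        base_quality=20,
    )
    order = np.argsort(rs.start, kind="stable")
    return rs.subset(order)


GENOME = encode_seq("ACGTACGTAC" * 30)
TARGETS = consolidate([GenomicInterval("chr1", 0, 100)])


class TestBuildPileup:
    def test_all_alt_column(self):
        ref10 = "ACGTACGTAC"
        alt = "C" + ref10[1:]
        rs = simple_reads([(0, i % 2 == 0, alt) for i in range(10)], GENOME)
        cols = build_pileup(rs, TARGETS, GENOME)
        c0 = cols[0]
        assert c0.pos == 0 and c0.ref == "A"
        assert c0.counts["ACGT".index("C")] == 10
        assert c0.depth == 10

    def test_duplicates_excluded(self):
        rs = simple_reads([(0, False, "ACGTACGTAC")] * 3, GENOME)
        rs.is_duplicate = np.array([False, True, True])
        cols = build_pileup(rs, TARGETS, GENOME)
        assert all(c.depth == 1 for c in cols)
        rs.is_duplicate = np.ones(3, bool)
        assert build_pileup(rs, TARGETS, GENOME) == []

    def test_columns_only_for_covered_bases(self):
        rs = simple_reads([(20, False, "ACGTACGTAC")], GENOME)
        cols = build_pileup(rs, TARGETS, GENOME)
        assert [c.pos for c in cols] == list(range(20, 30))

    def test_low_quality_bases_tracked_in_raw_depth_only(self):
        rs = simple_reads([(0, False, "ACGTACGTAC")], GENOME)
        cols = build_pileup(rs, TARGETS, GENOME, min_baseq=30)
        assert cols and all(c.depth == 1 and c.used_depth == 0 for c in cols)

    def test_region_outside_reference_rejected(self):
        rs = simple_reads([(0, False, "ACGTACGTAC")], GENOME)
        far = consolidate([GenomicInterval("chr1", 0, 10_000)])
        with pytest.raises(ValueError):
            build_pileup(rs, far, GENOME)

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_per_read_tally(self, seed):
        rng = np.random.default_rng(seed)
        entries = []
        for _ in range(60):
            start = int(rng.integers(0, 90))
            seq = "".join(rng.choice(list("ACGT"), 10))
            entries.append((start, bool(rng.integers(2)), seq))
        rs = simple_reads(entries, GENOME)
        cols = {c.pos: c for c in build_pileup(rs, TARGETS, GENOME)}
        for pos in range(100):
            tally = np.zeros((4, 2), dtype=int)
            for start, rev, seq in entries:
                if start <= pos < start + 10:
                    tally["ACGT".index(seq[pos - start]), int(rev)] += 1
            if tally.sum() == 0:
                assert pos not in cols
            else:
                np.testing.assert_array_equal(cols[pos].counts_fwd, tally[:, 0])
                np.testing.assert_array_equal(cols[pos].counts_rev, tally[:, 1])


class TestScoreSite:
    def test_all_ref_scores_zero(self):
        score, lod, gt = score_site(column(n_ref=10))
        assert score == 0.0 and lod <= 0 and gt == "hom-ref"

    def test_balanced_het_matches_independent_likelihood(self):
        score, lod, gt = score_site(column(n_ref=5, n_alt=5), eps=0.01)
        assert lod == pytest.approx(brute_force_lod(5, 5, 0.01), abs=1e-6)
        assert gt == "het"

    def test_all_alt_called_homozygous(self):
        score, lod, gt = score_site(column(n_ref=0, n_alt=10), eps=0.01)
        assert gt == "hom"
        assert score == pytest.approx(10 * brute_force_lod(0, 10, 0.01))

    def test_exhaustive_grid_matches_oracle(self):
        # every (n_ref, n_alt) column with depth <= 12
        for n_ref, n_alt in itertools.product(range(13), repeat=2):
            if not 1 <= n_ref + n_alt <= 12 or n_alt == 0:
                continue
            _, lod, _ = score_site(column(n_ref=n_ref, n_alt=n_alt), eps=0.01)
            assert lod == pytest.approx(brute_force_lod(n_ref, n_alt, 0.01), abs=1e-9)

    def test_eps_defaults_to_mean_base_quality(self):
        _, lod_q20, _ = score_site(column(n_ref=4, n_alt=4, baseq=20.0))
        assert lod_q20 == pytest.approx(brute_force_lod(4, 4, 0.01), abs=1e-9)


class TestCallVariants:
    def test_alt_tie_broken_alphabetically(self):
        cf = np.array([0, 2, 2, 0])
        cr = np.array([6, 0, 0, 0])
        col = PileupColumn("chr1", 5, "A", 10, cf, cr, 20.0)
        calls = call_variants([col])
        assert calls and calls[0].alt == "C"

    def test_vaf_denominator_choice(self):
        col = column(n_ref=5, n_alt=5, depth=20)  # 10 extra low-quality reads
        filt = call_variants([col], vaf_denominator="filtered")[0]
        raw = call_variants([col], vaf_denominator="raw")[0]
        assert filt.vaf == pytest.approx(0.5)
        assert raw.vaf == pytest.approx(0.25)

    def test_no_call_without_alt_evidence(self):
        assert call_variants([column(n_ref=10)]) == []


class TestFilterTruthTable:
    @pytest.mark.parametrize("score", [29, 30, 35, 40, 45])
    @pytest.mark.parametrize("strands", [1, 2])
    @pytest.mark.parametrize("vaf", [0.10, 0.15, 0.20])
    def test_solid_rule_combinations(self, score, strands, vaf):
        call = VariantCall(
            chrom="chr1", pos=1, ref="A", alt="C", variant_score=float(score),
            lod=score / 10, vaf=vaf, strands_seen=strands, genotype="het", depth=30,
        )
        expected = (score >= 40 or (score >= 30 and strands == 2)) and vaf >= 0.15
        ok, reasons = filter_solid(call)
        assert ok is expected
        if not ok:
            assert reasons

    @pytest.mark.parametrize(
        "score,strands,vaf,expected",
        [
            (45, 1, 0.16, True),   # high score carries a one-strand call
            (35, 2, 0.20, True),   # 30 <= score < 40 rescued by both strands
            (35, 1, 0.20, False),  # one strand, score below 40
            (50, 1, 0.10, False),  # allele fraction below 15%
        ],
    )
    def test_solid_examples(self, score, strands, vaf, expected):
        call = VariantCall(
            chrom="chr1", pos=1, ref="A", alt="C", variant_score=float(score),
            lod=score / 10, vaf=vaf, strands_seen=strands, genotype="het", depth=30,
        )
        assert filter_solid(call)[0] is expected


def het_call(pos, lod=6.0, vaf=0.5, genotype="het"):
    return VariantCall(
        chrom="chr1", pos=pos, ref="A", alt="C", variant_score=max(0.0, 10 * lod),
        lod=lod, vaf=vaf, strands_seen=2, genotype=genotype, depth=30,
    )


class TestFilterIllumina:
    def test_passing_het(self):
        assert filter_illumina([het_call(100)])[0][0]

    def test_allele_balance_bounds(self):
        ok, reasons = filter_illumina([het_call(100, vaf=0.20)])[0]
        assert not ok and "allele_balance" in reasons
        # homozygous calls are exempt from the balance window
        assert filter_illumina([het_call(100, vaf=0.95, genotype="hom")])[0][0]

    def test_lod_threshold(self):
        ok, reasons = filter_illumina([het_call(100, lod=4.9)])[0]
        assert not ok and "low_lod" in reasons

    def test_clustered_calls_fail(self):
        calls = [het_call(100), het_call(104), het_call(108)]
        verdicts = filter_illumina(calls)
        assert all(not ok and "clustered_snps" in r for ok, r in verdicts)

    def test_sparse_calls_not_clustered(self):
        calls = [het_call(100), het_call(104), het_call(200)]
        verdicts = filter_illumina(calls)
        assert sum(ok for ok, _ in verdicts) == 3

    def test_failing_call_does_not_seed_cluster(self):
        calls = [het_call(100), het_call(104, lod=1.0), het_call(108)]
        verdicts = filter_illumina(calls)
        assert verdicts[0][0] and verdicts[2][0] and not verdicts[1][0]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            filter_illumina([het_call(200), het_call(100)])

    def test_raising_lod_never_increases_passes(self):
        rng = np.random.default_rng(4)
        calls = [
            het_call(int(p), lod=float(rng.uniform(0, 12)),
                     vaf=float(rng.uniform(0.1, 0.9)))
            for p in np.sort(rng.choice(10_000, 200, replace=False))
        ]
        n5 = sum(ok for ok, _ in filter_illumina(calls, lod_min=5))
        n8 = sum(ok for ok, _ in filter_illumina(calls, lod_min=8))
        assert n8 <= n5

    def test_apply_profile_strict_subset(self):
        rng = np.random.default_rng(5)
        calls = [
            het_call(int(p), lod=float(rng.uniform(0, 12)))
            for p in np.sort(rng.choice(10_000, 100, replace=False))
        ]
        std = {c.pos for c in apply_profile([het_call(c.pos, c.lod) for c in calls], "illumina") if c.passed}
        strict = {c.pos for c in apply_profile([het_call(c.pos, c.lod) for c in calls], "illumina-strict") if c.passed}
        assert strict <= std


class TestEvaluateCalls:
    def make_world(self):
        truth = TruthSet(tuple(
            TruthVariant("chr1", p, "A", "C", "het", known)
            for p, known in [(10, True), (30, True), (50, False), (70, True)]
        ))
        # depth: reads covering positions 0..59 only
        rs = ReadSet("chr1", np.array([0, 0, 0]), np.array([60, 60, 60]),
                     np.zeros(3, bool))
        tgt = consolidate([GenomicInterval("chr1", 0, 100)])
        depths = depth_profile(rs, tgt)
        return truth, depths

    def pass_call(self, pos, alt="C"):
        c = het_call(pos)
        c.alt = alt
        c.filter_status = "PASS"
        return c

    def test_overall_and_restricted_concordance(self):
        truth, depths = self.make_world()
        calls = [self.pass_call(p) for p in (10, 30, 50)]
        rep = evaluate_calls(calls, truth, depths, cov_threshold=2)
        assert rep.concordance_pct == 75.0
        # position 70 has zero depth: missed overall, excluded from stratum
        assert rep.truth_sites_above_threshold == 3
        assert rep.concordance_above_threshold_pct == 100.0

    def test_alt_allele_must_match(self):
        truth, depths = self.make_world()
        calls = [self.pass_call(10, alt="G")]
        rep = evaluate_calls(calls, truth, depths)
        assert rep.recovered == 0

    def test_known_fraction(self):
        truth, depths = self.make_world()
        calls = [self.pass_call(p) for p in (10, 50)]  # one known, one novel
        rep = evaluate_calls(calls, truth, depths)
        assert rep.known_pct == 50.0
        calls = [self.pass_call(10), self.pass_call(30)]
        assert evaluate_calls(calls, truth, depths).known_pct == 100.0

    def test_failed_calls_ignored(self):
        truth, depths = self.make_world()
        c = het_call(10)
        c.filter_status = "FAIL"
        rep = evaluate_calls([c], truth, depths)
        assert rep.total_calls == 0 and rep.recovered == 0

    def test_depth_bin_table_mass(self):
        truth, depths = self.make_world()
        rep = evaluate_calls([], truth, depths, bins=(0, 2, 4))
        assert rep.by_depth_bin.truth_sites.sum() == len(truth)


class TestVcfRoundtrip:
    def test_calls_roundtrip(self, tmp_path):
        calls = apply_profile(
            [het_call(10), het_call(20, lod=2.0), het_call(40, vaf=0.1)], "illumina"
        )
        path = tmp_path / "calls.vcf"
        write_calls_vcf(calls, path, {"chr1": 1000})
        back = read_calls_vcf(path)
        assert [(c.pos, c.passed) for c in back] == [(c.pos, c.passed) for c in calls]
        assert back[0].lod == pytest.approx(calls[0].lod, abs=1e-3)
        assert back[0].genotype == "het"
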