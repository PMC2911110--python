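"""Naive pileup SNV caller with strand/allele-fraction filter profiles, and
concordance evaluation against a planted truth set.

The caller scores each covered target base with genotype likelihoods under
a symmetric per-base error model: given error rate eps (from the column's
mean base quality), a read base matches an allele present at fraction f in
the genotype with probability f(1-eps) + (1-f)(eps/3). Three genotypes are
considered — homozygous reference, heterozygous (f = 1/2), homozygous
alternate — and

    LOD  = log10( max(L_het, L_hom_alt) / L_hom_ref )
    variant score = 10 * LOD, clamped at 0.

Two filter profiles mirror the two short-read pipelines of the era:

* ``solid``  — score >= 40, or score >= 30 with the variant seen on both
  strands; and the alternate allele in at least 15% of reads;
* ``illumina`` — LOD >= 5 (``illumina-strict``: 8), heterozygote allele
  balance within [0.25, 0.75], and no cluster of >= 3 passing calls
  within 10 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthProfile
from .intervals import TargetSet
from .reads import BASES, ReadSet
from .simulate import TruthSet

__all__ = [
    "PileupColumn",
    "VariantCall",
    "ConcordanceReport",
    "build_pileup",
    "score_site",
    "call_variants",
    "filter_solid",
    "filter_illumina",
    "apply_profile",
    "evaluate_calls",
    "write_calls_vcf",
    "read_calls_vcf",
]

_BASE_STR = "ACGT"


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 0-based
    ref: str
    depth: int  # non-duplicate reads covering the site (raw)
    counts_fwd: np.ndarray  # quality-passing base counts, length 4 (ACGT)
    counts_rev: np.ndarray
    mean_baseq: float

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def used_depth(self) -> int:
        return int(self.counts.sum())


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    variant_score: float  # Phred-scaled, >= 0
    lod: float  # log10 likelihood ratio vs hom-ref
    vaf: float
    strands_seen: int  # 1 or 2
    genotype: str  # 'het' | 'hom'
    depth: int
    filter_status: str = "unfiltered"  # 'PASS' | 'FAIL' | 'unfiltered'
    filter_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")
        if self.strands_seen not in (1, 2):
            raise ValueError("strands_seen must be 1 or 2")
        if self.variant_score < 0:
            raise ValueError("variant_score must be >= 0")

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"


def build_pileup(
    reads: ReadSet,
    targets: TargetSet,
    reference: np.ndarray,
    min_mapq: int = 0,
    min_baseq: int = 0,
) -> list[PileupColumn]:
    """Pileup over target bases from non-duplicate reads.

    Bases below ``min_baseq`` are excluded from allele counts but still
    contribute to the raw ``depth``; columns are emitted for every target
    base covered by at least one read. Reads in a ReadSet share one base
    quality, so the quality cut is all-or-nothing per library.
    """
    for t in targets:
        if t.end > len(reference):
            raise ValueError(f"target {t} outside the reference")
    rs = reads.non_duplicates()
    if rs.mapq < min_mapq:
        rs = rs.subset(np.zeros(len(rs), dtype=bool))
    if rs.seq is None:
        raise ValueError("pileup requires read sequences")
    qual_ok = rs.base_quality >= min_baseq
    rl = rs.read_length
    columns: list[PileupColumn] = []
    starts = rs.start
    order_t = list(targets)
    # reads sorted by start: locate overlappers per target by binary search
    lo_idx = np.searchsorted(starts, np.array([t.start - rl for t in order_t]))
    hi_idx = np.searchsorted(starts, np.array([t.end for t in order_t]))
    for t, lo, hi in zip(order_t, lo_idx, hi_idx):
        L = len(t)
        depth = np.zeros(L + 1, dtype=np.int64)
        cnt = np.zeros((L, 4, 2), dtype=np.int64)
        sel = slice(int(lo), int(hi))
        r_start = rs.start[sel]
        r_end = rs.end[sel]
        ov = (r_start < t.end) & (r_end > t.start)
        if ov.any():
            a = np.maximum(r_start[ov], t.start) - t.start
            b = np.minimum(r_end[ov], t.end) - t.start
            np.add.at(depth, a, 1)
            np.add.at(depth, b, -1)
            if qual_ok:
                seqs = rs.seq[sel][ov]
                rev = rs.reverse[sel][ov].astype(np.int64)
                offs = a + t.start - r_start[ov]  # read offset of target entry
                for i in range(len(a)):
                    span = b[i] - a[i]
                    pos_in_t = np.arange(a[i], b[i])
                    bases = seqs[i, offs[i] : offs[i] + span]
                    np.add.at(cnt, (pos_in_t, bases, np.full(span, rev[i])), 1)
        dprof = np.cumsum(depth[:-1])
        covered = np.flatnonzero(dprof > 0)
        for j in covered:
            columns.append(
                PileupColumn(
                    chrom=t.chrom,
                    pos=t.start + int(j),
                    ref=_BASE_STR[reference[t.start + j]],
                    depth=int(dprof[j]),
                    counts_fwd=cnt[j, :, 0].copy(),
                    counts_rev=cnt[j, :, 1].copy(),
                    mean_baseq=float(rs.base_quality),
                )
            )
    return columns


def _pick_alt(col: PileupColumn) -> Optional[int]:
    """Highest-count non-reference base; ties broken alphabetically."""
    counts = col.counts
    ref_i = _BASE_STR.index(col.ref)
    best, best_n = None, 0
    for b in range(4):
        if b == ref_i:
            continue
        if counts[b] > best_n:
            best, best_n = b, counts[b]
    return best


def score_site(
    col: PileupColumn, eps: Optional[float] = None
) -> tuple[float, float, str]:
    """Genotype-likelihood score for one pileup column.

    Returns (variant_score, lod, genotype). ``eps`` defaults to the error
    rate implied by the column's mean base quality.
    """
    if col.depth < 1:
        raise ValueError("cannot score a zero-depth column")
    if eps is None:
        eps = 10.0 ** (-col.mean_baseq / 10.0)
    eps = min(max(eps, 1e-10), 0.75)
    ref_i = _BASE_STR.index(col.ref)
    alt_i = _pick_alt(col)
    counts = col.counts
    n_ref = int(counts[ref_i])
    if alt_i is None:
        return 0.0, _all_ref_lod(n_ref, eps), "hom-ref"
    n_alt = int(counts[alt_i])

    def loglik(f_alt: float) -> float:
        # other-base observations contribute eps/3 under every genotype and
        # cancel in the ratios, so only ref/alt counts enter
        p_alt = f_alt * (1 - eps) + (1 - f_alt) * (eps / 3)
        p_ref = (1 - f_alt) * (1 - eps) + f_alt * (eps / 3)
        return n_ref * math.log(p_ref) + n_alt * math.log(p_alt)

    ll_ref, ll_het, ll_hom = loglik(0.0), loglik(0.5), loglik(1.0)
    lod = (max(ll_het, ll_hom) - ll_ref) / math.log(10)
    score = max(0.0, 10.0 * lod)
    best = max(
        [("hom-ref", ll_ref), ("het", ll_het), ("hom", ll_hom)], key=lambda kv: kv[1]
    )[0]
    return score, lod, best


def _all_ref_lod(n_ref: int, eps: float) -> float:
    # with zero alt observations the best non-ref genotype is het
    return n_ref * (math.log10(0.5 * (1 - eps) + 0.5 * eps / 3) - math.log10(1 - eps))


def call_variants(
    columns: Sequence[PileupColumn],
    eps: Optional[float] = None,
    vaf_denominator: str = "filtered",
) -> list[VariantCall]:
    """Score pileup columns and emit candidate SNV calls (LOD > 0 sites).

    ``vaf_denominator`` selects whether the allele fraction uses the
    quality-passing depth ('filtered', default) or the raw read depth
    ('raw').
    """
    if vaf_denominator not in ("filtered", "raw"):
        raise ValueError("vaf_denominator must be 'filtered' or 'raw'")
    calls: list[VariantCall] = []
    for col in columns:
        alt_i = _pick_alt(col)
        if alt_i is None:
            continue
        score, lod, genotype = score_site(col, eps)
        if lod <= 0 or genotype == "hom-ref":
            continue
        denom = col.used_depth if vaf_denominator == "filtered" else col.depth
        n_alt = int(col.counts[alt_i])
        strands = int(col.counts_fwd[alt_i] > 0) + int(col.counts_rev[alt_i] > 0)
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref=col.ref,
                alt=_BASE_STR[alt_i],
                variant_score=score,
                lod=lod,
                vaf=n_alt / denom if denom else 0.0,
                strands_seen=max(strands, 1),
                genotype=genotype,
                depth=col.depth,
            )
        )
    return calls


def filter_solid(
    call: VariantCall,
    min_score: float = 40.0,
    min_score_both_strands: float = 30.0,
    min_vaf: float = 0.15,
) -> tuple[bool, tuple[str, ...]]:
    """SOLiD-style profile: score >= 40, or >= 30 on both strands; and the
    variant present in >= 15% of reads."""
    reasons = []
    score_ok = call.variant_score >= min_score or (
        call.variant_score >= min_score_both_strands and call.strands_seen == 2
    )
    if not score_ok:
        reasons.append("low_score")
    if call.vaf < min_vaf:
        reasons.append("low_allele_fraction")
    return (not reasons), tuple(reasons)


def filter_illumina(
    calls: Sequence[VariantCall],
    lod_min: float = 5.0,
    ab_low: float = 0.25,
    ab_high: float = 0.75,
    cluster_n: int = 3,
    cluster_window: int = 10,
) -> list[tuple[bool, tuple[str, ...]]]:
    """Illumina-style profile: minimum LOD, heterozygote allele balance in
    [ab_low, ab_high], and rejection of clusters of >= cluster_n otherwise
    passing calls within cluster_window bp. Input must be position-sorted."""
    positions = [(c.chrom, c.pos) for c in calls]
    if positions != sorted(positions):
        raise ValueError("calls must be position-sorted")
    verdicts: list[list[str]] = []
    for c in calls:
        reasons = []
        if c.lod < lod_min:
            reasons.append("low_lod")
        if c.genotype == "het" and not (ab_low <= c.vaf <= ab_high):
            reasons.append("allele_balance")
        verdicts.append(reasons)
    passing = [i for i, r in enumerate(verdicts) if not r]
    clustered: set[int] = set()
    for k in range(len(passing) - cluster_n + 1):
        window = passing[k : k + cluster_n]
        first, last = calls[window[0]], calls[window[-1]]
        if first.chrom == last.chrom and last.pos - first.pos <= cluster_window:
            clustered.update(window)
    for i in clustered:
        verdicts[i].append("clustered_snps")
    return [(not r, tuple(r)) for r in verdicts]


def apply_profile(calls: Sequence[VariantCall], profile: str) -> list[VariantCall]:
    """Annotate calls with PASS/FAIL under a named profile
    ('solid', 'illumina', 'illumina-strict')."""
    if profile == "solid":
        results = [filter_solid(c) for c in calls]
    elif profile in ("illumina", "illumina-strict"):
        lod_min = 8.0 if profile == "illumina-strict" else 5.0
        results = filter_illumina(calls, lod_min=lod_min)
    else:
        raise ValueError(f"unknown profile: {profile!r}")
    for c, (ok, reasons) in zip(calls, results):
        c.filter_status = "PASS" if ok else "FAIL"
        c.filter_reasons = reasons
    return list(calls)


@dataclass(frozen=True)
class ConcordanceReport:
    total_calls: int
    known_calls: int
    known_pct: float
    truth_sites: int
    recovered: int
    concordance_pct: float
    truth_sites_above_threshold: int
    recovered_above_threshold: int
    concordance_above_threshold_pct: float
    cov_threshold: int
    by_depth_bin: pd.DataFrame

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_calls": self.total_calls,
                "known_calls_pct": self.known_pct,
                "truth_sites": self.truth_sites,
                "concordance_pct": self.concordance_pct,
                f"concordance_gt{self.cov_threshold}x_pct": self.concordance_above_threshold_pct,
            }
        )


def evaluate_calls(
    calls: Sequence[VariantCall],
    truth: TruthSet,
    depths: DepthProfile,
    cov_threshold: int = 9,
    bins: Sequence[int] = (0, 5, 10, 20, 40),
) -> ConcordanceReport:
    """Concordance of passing calls against the planted truth.

    A truth site is recovered when a passing call matches its position and
    alternate allele; truth sites with zero coverage count as missed in the
    overall figure but are excluded from the > ``cov_threshold`` stratum.
    The known-sites proportion is the fraction of passing calls that hit a
    truth record flagged known (the database-catalogue proxy).
    """
    passing = [c for c in calls if c.passed]
    call_index = {(c.chrom, c.pos): c.alt for c in passing}
    known_index = {(v.chrom, v.pos): v.alt for v in truth if v.known}
    n_known = sum(
        1 for c in passing if known_index.get((c.chrom, c.pos)) == c.alt
    )
    recovered_all = 0
    recovered_hi = 0
    truth_hi = 0
    bin_edges = list(bins) + [np.inf]
    bin_truth = np.zeros(len(bins), dtype=int)
    bin_rec = np.zeros(len(bins), dtype=int)
    for v in truth:
        hit = call_index.get((v.chrom, v.pos)) == v.alt
        d = depths.depth_at(v.chrom, v.pos) or 0
        if hit:
            recovered_all += 1
        if d > cov_threshold:
            truth_hi += 1
            if hit:
                recovered_hi += 1
        b = int(np.searchsorted(bin_edges, d, side="right")) - 1
        b = min(max(b, 0), len(bins) - 1)
        bin_truth[b] += 1
        if hit:
            bin_rec[b] += 1
    table = pd.DataFrame(
        {
            "depth_min": list(bins),
            "truth_sites": bin_truth,
            "recovered": bin_rec,
            "concordance_pct": [
                100.0 * r / t if t else float("nan")
                for r, t in zip(bin_rec, bin_truth)
            ],
        }
    )
    n_truth = len(truth)
    return ConcordanceReport(
        total_calls=len(passing),
        known_calls=n_known,
        known_pct=100.0 * n_known / len(passing) if passing else float("nan"),
        truth_sites=n_truth,
        recovered=recovered_all,
        concordance_pct=100.0 * recovered_all / n_truth if n_truth else float("nan"),
        truth_sites_above_threshold=truth_hi,
        recovered_above_threshold=recovered_hi,
        concordance_above_threshold_pct=(
            100.0 * recovered_hi / truth_hi if truth_hi else float("nan")
        ),
        cov_threshold=cov_threshold,
        by_depth_bin=table,
    )


# ---------------------------------------------------------------------------
# VCF I/O


def write_calls_vcf(
    calls: Sequence[VariantCall], path: str | Path, chrom_sizes: dict[str, int]
) -> None:
    import pysam

    header = pysam.VariantHeader()
    for c, l in chrom_sizes.items():
        header.contigs.add(c, length=int(l))
    header.info.add("SCORE", 1, "Float", "Phred-scaled variant score (10 x LOD)")
    header.info.add("LOD", 1, "Float", "log10 likelihood ratio vs homozygous reference")
    header.info.add("VAF", 1, "Float", "Alternate allele fraction")
    header.info.add("STRANDS", 1, "Integer", "Strands with alternate support")
    header.info.add("DP", 1, "Integer", "Non-duplicate read depth")
    header.formats.add("GT", 1, "String", "Genotype")
    for reason in (
        "low_score",
        "low_allele_fraction",
        "low_lod",
        "allele_balance",
        "clustered_snps",
    ):
        header.filters.add(reason, None, None, f"Failed {reason} filter")
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos, stop=c.pos + 1, alleles=(c.ref, c.alt)
            )
            rec.info["SCORE"] = round(c.variant_score, 4)
            rec.info["LOD"] = round(c.lod, 4)
            rec.info["VAF"] = round(c.vaf, 4)
            rec.info["STRANDS"] = c.strands_seen
            rec.info["DP"] = c.depth
            rec.samples["sample"]["GT"] = (0, 1) if c.genotype == "het" else (1, 1)
            if c.passed:
                rec.filter.add("PASS")
            else:
                for r in c.filter_reasons:
                    rec.filter.add(r)
            vcf.write(rec)


def read_calls_vcf(path: str | Path) -> list[VariantCall]:
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = tuple(rec.filter.keys())
            passed = filters == ("PASS",) or not filters
            gt = rec.samples[0]["GT"] if len(rec.samples) else (0, 1)
            calls.append(
                VariantCall(
                    chrom=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    variant_score=float(rec.info["SCORE"]),
                    lod=float(rec.info["LOD"]),
                    vaf=float(rec.info["VAF"]),
                    strands_seen=int(rec.info["STRANDS"]),
                    genotype="hom" if gt == (1, 1) else "het",
                    depth=int(rec.info["DP"]),
                    filter_status="PASS" if passed else "FAIL",
                    filter_reasons=() if passed else filters,
                )
            )
    return calls
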