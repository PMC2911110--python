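"""Per-target coverage, normalized coverage, and library summary statistics.

The summary block mirrors how capture experiments are reported: total
aligned yield, percent of reads on target (duplicates included), duplicate
percent, mean/median depth over target bases after duplicate removal,
percent of targets hit, and the percent of target bases covered at a set
of depth thresholds, plus the full depth histogram.

Normalized coverage divides each target's mean depth by the library's
total aligned bases, making the per-target profile comparable between
libraries of different depth; technical replicates of the same capture
should show near-perfect correlation of this profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dedup import DupReport
from .intervals import GenomicInterval, TargetSet
from .reads import ReadSet

__all__ = [
    "DepthProfile",
    "TargetCoverage",
    "CoverageSummary",
    "depth_profile",
    "reads_on_target",
    "coverage_summary",
    "normalized_target_coverage",
    "replicate_correlation",
]


@dataclass(frozen=True)
class TargetCoverage:
    target: GenomicInterval
    mean_depth: float
    normalized_depth: float  # mean depth / total aligned bases (1/bp)


class DepthProfile:
    """Per-base read depth over the target bases of one chromosome."""

    def __init__(self, targets: TargetSet, depths: list[np.ndarray]) -> None:
        if len(depths) != len(targets):
            raise ValueError("one depth array per target required")
        self.targets = targets
        self.depths = depths
        self._starts = np.array([t.start for t in targets])
        self._ends = np.array([t.end for t in targets])

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.depths) if self.depths else np.array([], dtype=np.int64)

    def per_target_mean(self) -> np.ndarray:
        return np.array([d.mean() for d in self.depths])

    def depth_at(self, chrom: str, pos: int) -> Optional[int]:
        """Depth at one position, or None if it is not a target base."""
        i = int(np.searchsorted(self._ends, pos, side="right"))
        if i < len(self.targets):
            t = self.targets.intervals[i]
            if t.chrom == chrom and t.start <= pos < t.end:
                return int(self.depths[i][pos - t.start])
        return None


def depth_profile(reads: ReadSet, targets: TargetSet, use_dedup: bool = True) -> DepthProfile:
    """Count reads overlapping each target base (duplicates excluded when
    ``use_dedup``)."""
    if len(targets) == 0:
        raise ValueError("empty target set")
    rs = reads.non_duplicates() if use_dedup else reads
    span_end = max(t.end for t in targets)
    diff = np.zeros(span_end + 1, dtype=np.int64)
    if rs.chrom in {t.chrom for t in targets}:
        mask = rs.start < span_end
        np.add.at(diff, rs.start[mask], 1)
        np.add.at(diff, np.minimum(rs.end[mask], span_end), -1)
    depth = np.cumsum(diff[:-1])
    return DepthProfile(targets, [depth[t.start : t.end].copy() for t in targets])


def reads_on_target(reads: ReadSet, targets: TargetSet) -> float:
    """Fraction of reads whose alignment overlaps any target by >= 1 bp
    (duplicates included)."""
    if len(reads) == 0:
        return 0.0
    t = [iv for iv in targets if iv.chrom == reads.chrom]
    if not t:
        return 0.0
    starts = np.array([iv.start for iv in t])
    ends = np.array([iv.end for iv in t])
    # first target whose end lies beyond the read start; overlap iff it
    # begins before the read end
    idx = np.searchsorted(ends, reads.start, side="right")
    inb = idx < len(t)
    on = np.zeros(len(reads), dtype=bool)
    on[inb] = starts[np.minimum(idx[inb], len(t) - 1)] < reads.end[inb]
    return float(on.mean())


def _median_low(values: np.ndarray) -> float:
    """Median with the lower central order statistic on even counts."""
    if len(values) == 0:
        raise ValueError("median of empty vector")
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


@dataclass(frozen=True)
class CoverageSummary:
    total_reads: int
    total_bases_aligned: int
    reads_on_target_pct: float
    duplicate_pct: float
    mean_coverage: float
    median_coverage: float
    targets_hit_pct: float
    pct_bases_at_least: dict[int, float]  # threshold -> percent of target bases
    depth_histogram: np.ndarray  # counts of target bases per depth

    def __post_init__(self) -> None:
        thr = sorted(self.pct_bases_at_least)
        pcts = [self.pct_bases_at_least[t] for t in thr]
        if any(a < b for a, b in zip(pcts, pcts[1:])):
            raise ValueError("threshold percentages must be non-increasing")

    def as_series(self) -> pd.Series:
        rows = {
            "total_reads_aligned": self.total_reads,
            "total_bases_aligned": self.total_bases_aligned,
            "reads_on_target_pct": self.reads_on_target_pct,
            "duplicate_reads_pct": self.duplicate_pct,
            "mean_coverage": self.mean_coverage,
            "median_coverage": self.median_coverage,
            "targets_hit_pct": self.targets_hit_pct,
        }
        for t, p in sorted(self.pct_bases_at_least.items()):
            rows[f"bases_ge_{t}x_pct"] = p
        return pd.Series(rows)


def coverage_summary(
    reads: ReadSet,
    targets: TargetSet,
    dup_report: Optional[DupReport] = None,
    thresholds: Sequence[int] = (1, 10, 20),
) -> CoverageSummary:
    """Compute the library-level coverage block from deduplicated depth."""
    profile = depth_profile(reads, targets, use_dedup=True)
    depth = profile.concatenated()
    dup_pct = (
        100.0 * dup_report.duplicate_rate
        if dup_report is not None
        else 100.0 * reads.is_duplicate.mean()
    )
    hist = np.bincount(depth)
    targets_hit = sum(1 for d in profile.depths if d.max(initial=0) > 0)
    return CoverageSummary(
        total_reads=len(reads),
        total_bases_aligned=int((reads.end - reads.start).sum()),
        reads_on_target_pct=100.0 * reads_on_target(reads, targets),
        duplicate_pct=float(dup_pct),
        mean_coverage=float(depth.mean()),
        median_coverage=_median_low(depth),
        targets_hit_pct=100.0 * targets_hit / len(targets),
        pct_bases_at_least={int(t): float(100.0 * (depth >= t).mean()) for t in thresholds},
        depth_histogram=hist,
    )


def normalized_target_coverage(
    mean_depths: Sequence[float], total_bases_aligned: int
) -> np.ndarray:
    """Per-target mean depth as a proportion of the total sequence generated."""
    if total_bases_aligned <= 0:
        raise ValueError("total_bases_aligned must be positive")
    return np.asarray(mean_depths, dtype=float) / float(total_bases_aligned)


def replicate_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation of two per-target coverage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance vector has no defined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def per_target_table(
    reads: ReadSet, targets: TargetSet, use_dedup: bool = True
) -> pd.DataFrame:
    """Per-target coverage table: chrom, start, end, mean depth, normalized depth."""
    profile = depth_profile(reads, targets, use_dedup=use_dedup)
    total = int((reads.end - reads.start).sum())
    means = profile.per_target_mean()
    norm = normalized_target_coverage(means, total)
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in targets],
            "start": [t.start for t in targets],
            "end": [t.end for t in targets],
            "mean_depth": means,
            "normalized_depth": norm,
        }
    )
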