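"""Capture target and probe-tiling geometry.

All coordinates are 0-based half-open (BED convention). Conversion to the
1-based conventions of SAM/VCF happens only at I/O boundaries.

The workflow mirrors how a solution-capture design is built from an exon
annotation: pad each exon to a minimum capturable length, pad small-RNA
targets by a fixed flank, consolidate the result into a non-redundant
target universe, and tile fixed-length probes across each target on the
forward strand.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "TargetSet",
    "Probe",
    "DesignStats",
    "pad_to_min_length",
    "pad_flanks",
    "consolidate",
    "tile_probes",
    "design_stats",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TargetSet:
    """A sorted, pairwise-disjoint collection of target intervals.

    Construct via :func:`consolidate`; the constructor validates the
    invariants rather than enforcing them.
    """

    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        ivs = self.intervals
        for a, b in zip(ivs, ivs[1:]):
            if (a.chrom, a.start) > (b.chrom, b.start):
                raise ValueError("TargetSet intervals must be sorted")
            if a.chrom == b.chrom and a.end >= b.start:
                # abutting intervals count as redundant too
                raise ValueError("TargetSet intervals must be disjoint")

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class Probe:
    """A capture probe; always on the genomic forward strand."""

    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand != "+":
            raise ValueError("probes are selected on the forward strand only")


@dataclass(frozen=True)
class DesignStats:
    probe_count: int
    target_bases: int
    median_probe_length: float
    median_spacing: Optional[float]  # None when < 2 probes share a target
    targets_covered_fraction: float


def pad_to_min_length(
    iv: GenomicInterval, min_len: int, chrom_len: int
) -> GenomicInterval:
    """Extend ``iv`` symmetrically so its length is at least ``min_len``.

    An odd deficit puts the extra base on the right. If an end hits a
    chromosome edge the remaining deficit is shifted to the other side.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if iv.end > chrom_len:
        raise ValueError(f"{iv!r} extends past chromosome end {chrom_len}")
    if min_len > chrom_len:
        raise ValueError(
            f"cannot pad to {min_len} bp on a {chrom_len} bp chromosome"
        )
    deficit = min_len - len(iv)
    if deficit <= 0:
        return iv
    left = deficit // 2
    right = deficit - left
    start = iv.start - left
    end = iv.end + right
    if start < 0:  # shift unmet left extension to the right
        end += -start
        start = 0
    if end > chrom_len:  # shift unmet right extension to the left
        start -= end - chrom_len
        end = chrom_len
    return GenomicInterval(iv.chrom, start, end, iv.name)


def pad_flanks(iv: GenomicInterval, flank: int, chrom_len: int) -> GenomicInterval:
    """Extend ``iv`` by ``flank`` bp on each side, clamped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicInterval(
        iv.chrom, max(0, iv.start - flank), min(chrom_len, iv.end + flank), iv.name
    )


def consolidate(ivs: Iterable[GenomicInterval]) -> TargetSet:
    """Merge overlapping and abutting intervals into a non-redundant set."""
    ordered = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, prev.name)
        else:
            merged.append(iv)
    return TargetSet(tuple(merged))


def tile_probes(ts: TargetSet, probe_len: int, step: int) -> list[Probe]:
    """Tile fixed-length probes across each target at a fixed step.

    Probes start at ``target_start + k*step``. When the last stepped probe
    would overhang the target, a final probe is right-aligned to the target
    end instead. Targets shorter than ``probe_len`` get a single probe equal
    to the target, so every target base is always covered.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if not 1 <= step <= probe_len:
        raise ValueError("step must satisfy 1 <= step <= probe_len")
    probes: list[Probe] = []
    for t in ts:
        if len(t) <= probe_len:
            probes.append(Probe(GenomicInterval(t.chrom, t.start, t.end, t.name)))
            continue
        start = t.start
        last_start = None
        while start + probe_len <= t.end:
            probes.append(
                Probe(GenomicInterval(t.chrom, start, start + probe_len, t.name))
            )
            last_start = start
            start += step
        final_start = t.end - probe_len
        if final_start != last_start:
            probes.append(
                Probe(GenomicInterval(t.chrom, final_start, t.end, t.name))
            )
    return probes


def _covered_fraction(probes: Sequence[Probe], ts: TargetSet) -> float:
    covered = 0
    merged = consolidate(p.interval for p in probes)
    # both sets sorted and disjoint: sweep per chromosome
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for t in ts:
        for p in by_chrom.get(t.chrom, ()):
            lo = max(t.start, p.start)
            hi = min(t.end, p.end)
            if lo < hi:
                covered += hi - lo
    return covered / ts.total_bases


def design_stats(probes: Sequence[Probe], ts: TargetSet) -> DesignStats:
    """Summarize a probe tiling the way a design report would (probe count,
    median probe length, median start-to-start spacing within targets,
    fraction of target bases covered)."""
    if not probes:
        raise ValueError("empty probe set")
    lengths = [len(p.interval) for p in probes]
    # spacing between consecutive probe starts within each target
    spacings: list[int] = []
    for t in ts:
        starts = sorted(p.interval.start for p in probes if t.contains(p.interval))
        spacings.extend(b - a for a, b in zip(starts, starts[1:]))
    return DesignStats(
        probe_count=len(probes),
        target_bases=ts.total_bases,
        median_probe_length=statistics.median(lengths),
        median_spacing=statistics.median(spacings) if spacings else None,
        targets_covered_fraction=_covered_fraction(probes, ts),
    )


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open) into intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
        on_bad_lines="error",
    ) if _bed_has_names(path) else pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    ).assign(name=None)
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.name if isinstance(r.name, str) else None)
        for r in df.itertuples()
    ]


def _bed_has_names(path: str | Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) >= 4
    return False


def write_bed(ivs: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file (faidx-style)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split("\t")
            sizes[fields[0]] = int(fields[1])
    return sizes
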