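"""Duplicate-read identification and the natural-duplication occupancy model.

Two duplicate definitions are supported:

* **frag** — reads sharing the same 5'-most aligned position and direction
  are duplicates of one another (the single-end definition);
* **PE** — read pairs sharing the same fragment endpoints (leftmost start,
  rightmost end) and orientation are duplicates; knowing both ends of the
  captured fragment distinguishes molecules that merely share one end.

Deep single-end data saturate the start-position space, so many coincident
reads from *different* molecules are marked as duplicates. The occupancy
model quantifies that: throwing N reads uniformly over P equally likely
keys leaves P(1-(1-1/P)^N) keys occupied in expectation, so
N - P(1-(1-1/P)^N) reads are "natural" duplicates even without any PCR
amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .reads import AlignedRead, ReadSet

__all__ = [
    "FragmentKey",
    "DupReport",
    "frag_key",
    "pe_key",
    "mark_duplicates",
    "expected_natural_dup_fraction",
    "simulate_natural_dup",
    "decompose_duplicates",
]

FragmentKey = tuple


@dataclass(frozen=True)
class DupReport:
    total: int
    duplicates: int
    mode: str
    excluded_interchromosomal: int = 0

    @property
    def duplicate_rate(self) -> float:
        return self.duplicates / self.total if self.total else 0.0


def frag_key(r: AlignedRead) -> FragmentKey:
    """Single-end duplicate key: (chrom, strand-aware 5' position, strand)."""
    if not r.mapped:
        raise ValueError(f"unmapped read has no fragment key: {r.name}")
    pos5 = r.start if r.strand == "+" else r.end
    return (r.chrom, pos5, r.strand)


def pe_key(pair: Sequence[AlignedRead]) -> FragmentKey:
    """Paired-end duplicate key: (chrom, fragment start, fragment end,
    orientation). Symmetric in mate order."""
    a, b = pair
    if not (a.mapped and b.mapped):
        raise ValueError("both mates must be mapped")
    if a.chrom != b.chrom:
        raise ValueError(f"inter-chromosomal pair {a.name}: no fragment key")
    left, right = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    if left.strand == "+" and right.strand == "-":
        orient = "FR"
    elif left.strand == "-" and right.strand == "+":
        orient = "RF"
    else:
        orient = "TT"  # tandem
    return (a.chrom, min(a.start, b.start), max(a.end, b.end), orient)


def mark_duplicates(
    reads: Union[ReadSet, Sequence[AlignedRead]], mode: str
) -> tuple[Union[ReadSet, list[AlignedRead]], DupReport]:
    """Flag duplicates under the given definition and report the rate.

    Within each key group the record with the highest base-quality sum is
    kept (ties broken by lexicographically smallest read name); all others
    are flagged. In PE mode keys are per fragment, both mates are flagged
    together, and the report counts flagged *reads*.
    """
    if mode not in ("frag", "PE"):
        raise ValueError("mode must be 'frag' or 'PE'")
    if isinstance(reads, ReadSet):
        return _mark_readset(reads, mode)
    records = [replace_dup(r, False) for r in reads]
    if mode == "frag":
        groups: dict[FragmentKey, list[AlignedRead]] = {}
        for r in records:
            groups.setdefault(frag_key(r), []).append(r)
        dup = 0
        for grp in groups.values():
            keep = min(grp, key=lambda r: (-r.qual_sum, r.name))
            for r in grp:
                if r is not keep:
                    r.is_duplicate = True
                    dup += 1
        return records, DupReport(len(records), dup, mode)
    # PE
    if any(not r.is_paired for r in records):
        raise ValueError("PE-mode duplicate marking requires paired reads only")
    pairs: dict[str, list[AlignedRead]] = {}
    for r in records:
        pairs.setdefault(r.name, []).append(r)
    if any(len(p) != 2 for p in pairs.values()):
        raise ValueError("PE mode requires both mates of every pair")
    groups = {}
    excluded = 0
    for name, pair in pairs.items():
        if pair[0].chrom != pair[1].chrom:
            excluded += 2
            continue
        groups.setdefault(pe_key(pair), []).append(pair)
    dup = 0
    for grp in groups.values():
        keep = min(
            grp, key=lambda p: (-(p[0].qual_sum + p[1].qual_sum), p[0].name)
        )
        for pair in grp:
            if pair is not keep:
                for r in pair:
                    r.is_duplicate = True
                    dup += 1
    return records, DupReport(len(records), dup, mode, excluded)


def replace_dup(r: AlignedRead, value: bool) -> AlignedRead:
    from dataclasses import replace

    return replace(r, is_duplicate=value)


def _flag_worst_per_group(
    key_cols: tuple[np.ndarray, ...], qual_sum: np.ndarray, names: np.ndarray
) -> np.ndarray:
    """True for every record that is not the best of its key group (best =
    highest quality sum, then lexicographically smallest name)."""
    n = len(names)
    names = np.asarray(names, dtype="U")
    order = np.lexsort((names, -qual_sum.astype(np.int64)) + key_cols[::-1])
    dup_sorted = np.zeros(n, dtype=bool)
    if n > 1:
        same = np.ones(n - 1, dtype=bool)
        for c in key_cols:
            cs = c[order]
            same &= cs[1:] == cs[:-1]
        dup_sorted[1:] = same  # first (best) record of each group is kept
    flags = np.empty(n, dtype=bool)
    flags[order] = dup_sorted
    return flags


def _mark_readset(reads: ReadSet, mode: str) -> tuple[ReadSet, DupReport]:
    n = len(reads)
    out = reads.subset(np.arange(n))
    if mode == "frag":
        pos5 = np.where(out.reverse, out.end, out.start)
        flags = _flag_worst_per_group(
            (pos5, out.reverse.astype(np.int64)), out.qual_sum, out.names
        )
        out.is_duplicate = flags
        return out, DupReport(n, int(flags.sum()), mode)

    if not out.is_paired.all():
        raise ValueError("PE-mode duplicate marking requires paired reads only")
    # one representative read per fragment (read1); mates share the name
    r1 = np.flatnonzero(out.is_read1)
    r2 = np.flatnonzero(~out.is_read1)
    if len(r1) != len(r2):
        raise ValueError("PE mode requires both mates of every pair")
    rl = out.end[r1] - out.start[r1]
    fstart = np.minimum(out.start[r1], out.mate_start[r1])
    fend = np.maximum(out.end[r1], out.mate_start[r1] + rl)
    # orientation under FR-style pairing (mate strand opposite): keyed by the
    # strand of the leftmost read; full FR/RF/TT handling lives in pe_key()
    left_is_rev = np.where(
        out.start[r1] <= out.mate_start[r1], out.reverse[r1], ~out.reverse[r1]
    ).astype(np.int64)
    names = np.asarray(out.names, dtype="U")
    frag_flags = _flag_worst_per_group(
        (fstart, fend, left_is_rev), 2 * out.qual_sum[r1], names[r1]
    )
    flags = np.zeros(n, dtype=bool)
    flags[r1] = frag_flags
    # propagate to mates by shared name
    dup_names = np.sort(names[r1][frag_flags])
    idx = np.searchsorted(dup_names, names[r2])
    idx = np.clip(idx, 0, max(len(dup_names) - 1, 0))
    if len(dup_names):
        flags[r2] = dup_names[idx] == names[r2]
    out.is_duplicate = flags
    return out, DupReport(n, int(flags.sum()), mode)


# ---------------------------------------------------------------------------
# Occupancy model of natural (non-PCR) duplication


def _expected_duplicates(n: float, p: float) -> float:
    """E[duplicates] when n reads land uniformly on p equiprobable keys."""
    if n <= 0 or p <= 0:
        return 0.0
    occupied = p * -np.expm1(n * np.log1p(-1.0 / p)) if p > 1 else 1.0
    return float(n - min(occupied, n))


def expected_natural_dup_fraction(
    n_reads: int, on_positions: int, off_positions: int, on_fraction: float
) -> float:
    """Expected duplicate fraction from random read placement alone.

    Reads split into an on-target stratum (``n_reads * on_fraction`` reads
    over ``on_positions`` equiprobable keys) and an off-target stratum;
    within each stratum the occupancy expectation N - P(1-(1-1/P)^N)
    counts reads beyond the first on each key. Pass key counts that already
    include strand multiplicity where the key is stranded.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= on_fraction <= 1.0:
        raise ValueError("on_fraction must be in [0, 1]")
    n_on = n_reads * on_fraction
    n_off = n_reads - n_on
    if n_on > 0 and on_positions < 1:
        raise ValueError("on_positions must be >= 1 when on_fraction > 0")
    if n_off > 0 and off_positions < 1:
        raise ValueError("off_positions must be >= 1 when on_fraction < 1")
    dups = _expected_duplicates(n_on, on_positions) + _expected_duplicates(
        n_off, off_positions
    )
    return dups / n_reads


def simulate_natural_dup(
    n_reads: int,
    strata: Sequence[tuple[int, float]],
    reps: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the natural duplicate fraction.

    ``strata`` is a sequence of ``(n_positions, read_fraction)`` pairs; each
    replicate throws the stratum's reads uniformly over its keys and counts
    reads in excess of one per occupied key. Returns (mean, standard error).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fractions = np.array([f for _, f in strata], dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("stratum read fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.round(fractions * n_reads).astype(np.int64)
    # keep the total exact after rounding
    counts[-1] = n_reads - counts[:-1].sum()
    rates = np.empty(reps)
    for r in range(reps):
        dup = 0
        for (p, _), n in zip(strata, counts):
            if n <= 0:
                continue
            keys = rng.integers(0, p, size=n)
            dup += n - len(np.unique(keys))
        rates[r] = dup / n_reads
    se = float(rates.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return float(rates.mean()), se


def decompose_duplicates(observed_rate: float, natural_rate: float) -> tuple[float, float]:
    """Split an observed duplicate rate into PCR-attributable and natural
    shares of the duplicates: ((observed-natural)/observed, natural/observed)."""
    if not 0.0 <= natural_rate <= observed_rate < 1.0:
        raise ValueError(
            "need 0 <= natural_rate <= observed_rate < 1; "
            f"got natural={natural_rate}, observed={observed_rate}"
        )
    if observed_rate == 0.0:
        return 0.0, 0.0
    pcr = (observed_rate - natural_rate) / observed_rate
    return pcr, 1.0 - pcr
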