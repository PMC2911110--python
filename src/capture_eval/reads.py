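"""Aligned-read containers and SAM I/O.

Two views of the same data:

* :class:`AlignedRead` — a per-record dataclass, convenient for small
  inputs, oracle tests and key functions.
* :class:`ReadSet` — a columnar (NumPy) container holding a whole library;
  all bulk operations (duplicate marking, depth profiles, pileups) run on
  it. All reads in a ReadSet share one read length and one base quality,
  which is what the simulator emits (quality recalibration is out of
  scope for this pipeline).

SAM files are read and written through pysam; the duplicate flag uses the
standard 0x400 bit and simulator provenance travels in ``MI`` (molecule id)
and ``PC`` (PCR-copy index, 0 = original) tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

__all__ = ["AlignedRead", "ReadSet", "read_sam", "write_sam", "BASES"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def encode_seq(s: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGT base in {s!r}")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


@dataclass
class AlignedRead:
    """One mapped read."""

    name: str
    chrom: Optional[str]
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    mapq: int = 60
    seq: Optional[str] = None
    base_quality: int = 20  # uniform Phred quality over the read
    is_paired: bool = False
    is_read1: bool = True
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None
    tlen: int = 0
    is_duplicate: bool = False
    molecule_id: int = -1
    pcr_copy: int = 0  # 0 = original molecule, >0 = PCR copy index

    def __post_init__(self) -> None:
        if self.chrom is not None and not self.start < self.end:
            raise ValueError(f"start must be < end: {self!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def mapped(self) -> bool:
        return self.chrom is not None

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def qual_sum(self) -> int:
        return self.base_quality * len(self)


class ReadSet:
    """Columnar container for a library of uniform-length reads.

    Columns are NumPy arrays indexed by read; ``seq`` is an optional
    ``(n, read_length)`` uint8 matrix of base codes. Mates of a pair share
    ``molecule_id`` and ``pcr_copy`` and are distinguished by ``is_read1``.
    """

    def __init__(
        self,
        chrom: str,
        start: np.ndarray,
        end: np.ndarray,
        reverse: np.ndarray,
        *,
        seq: Optional[np.ndarray] = None,
        base_quality: int = 20,
        mapq: int = 60,
        is_paired: Optional[np.ndarray] = None,
        is_read1: Optional[np.ndarray] = None,
        mate_start: Optional[np.ndarray] = None,
        tlen: Optional[np.ndarray] = None,
        molecule_id: Optional[np.ndarray] = None,
        pcr_copy: Optional[np.ndarray] = None,
        is_duplicate: Optional[np.ndarray] = None,
        names: Optional[np.ndarray] = None,
    ) -> None:
        n = len(start)
        self.chrom = chrom
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.reverse = np.asarray(reverse, dtype=bool)
        self.seq = seq
        self.base_quality = int(base_quality)
        self.mapq = int(mapq)
        self.is_paired = (
            np.zeros(n, dtype=bool) if is_paired is None else np.asarray(is_paired, bool)
        )
        self.is_read1 = (
            np.ones(n, dtype=bool) if is_read1 is None else np.asarray(is_read1, bool)
        )
        self.mate_start = (
            np.full(n, -1, dtype=np.int64)
            if mate_start is None
            else np.asarray(mate_start, np.int64)
        )
        self.tlen = (
            np.zeros(n, dtype=np.int64) if tlen is None else np.asarray(tlen, np.int64)
        )
        self.molecule_id = (
            np.arange(n, dtype=np.int64)
            if molecule_id is None
            else np.asarray(molecule_id, np.int64)
        )
        self.pcr_copy = (
            np.zeros(n, dtype=np.int32) if pcr_copy is None else np.asarray(pcr_copy, np.int32)
        )
        self.is_duplicate = (
            np.zeros(n, dtype=bool)
            if is_duplicate is None
            else np.asarray(is_duplicate, bool)
        )
        self._names = names  # object array, built lazily when None
        if not (np.all(self.start < self.end)):
            raise ValueError("all reads must satisfy start < end")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def read_length(self) -> int:
        return int((self.end - self.start).max(initial=0))

    @property
    def names(self) -> np.ndarray:
        if self._names is None:
            self._names = np.array(
                [f"m{m:010d}c{c:03d}" for m, c in zip(self.molecule_id, self.pcr_copy)],
                dtype=object,
            )
        return self._names

    @property
    def qual_sum(self) -> np.ndarray:
        return (self.end - self.start) * self.base_quality

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.chrom,
            self.start[mask],
            self.end[mask],
            self.reverse[mask],
            seq=None if self.seq is None else self.seq[mask],
            base_quality=self.base_quality,
            mapq=self.mapq,
            is_paired=self.is_paired[mask],
            is_read1=self.is_read1[mask],
            mate_start=self.mate_start[mask],
            tlen=self.tlen[mask],
            molecule_id=self.molecule_id[mask],
            pcr_copy=self.pcr_copy[mask],
            is_duplicate=self.is_duplicate[mask],
            names=None if self._names is None else self._names[mask],
        )

    def sort_by_coordinate(self) -> "ReadSet":
        order = np.lexsort((~self.is_read1, self.pcr_copy, self.molecule_id, self.start))
        return self.subset(order)

    def non_duplicates(self) -> "ReadSet":
        return self.subset(~self.is_duplicate)

    # -- record view --------------------------------------------------------

    def to_records(self) -> Iterator[AlignedRead]:
        names = self.names
        for i in range(len(self)):
            yield AlignedRead(
                name=str(names[i]),
                chrom=self.chrom,
                start=int(self.start[i]),
                end=int(self.end[i]),
                strand="-" if self.reverse[i] else "+",
                mapq=self.mapq,
                seq=None if self.seq is None else decode_seq(self.seq[i]),
                base_quality=self.base_quality,
                is_paired=bool(self.is_paired[i]),
                is_read1=bool(self.is_read1[i]),
                mate_chrom=self.chrom if self.is_paired[i] else None,
                mate_start=int(self.mate_start[i]) if self.is_paired[i] else None,
                tlen=int(self.tlen[i]),
                is_duplicate=bool(self.is_duplicate[i]),
                molecule_id=int(self.molecule_id[i]),
                pcr_copy=int(self.pcr_copy[i]),
            )

    @classmethod
    def from_records(cls, records: Sequence[AlignedRead]) -> "ReadSet":
        if not records:
            raise ValueError("cannot build a ReadSet from zero records")
        chroms = {r.chrom for r in records}
        if len(chroms) != 1:
            raise ValueError("ReadSet holds reads from a single chromosome")
        lengths = {len(r) for r in records}
        quals = {r.base_quality for r in records}
        seqs = None
        if all(r.seq is not None for r in records):
            if len(lengths) != 1:
                raise ValueError("uniform read length required to store sequences")
            seqs = np.stack([encode_seq(r.seq) for r in records])
        return cls(
            records[0].chrom,
            np.array([r.start for r in records]),
            np.array([r.end for r in records]),
            np.array([r.strand == "-" for r in records]),
            seq=seqs,
            base_quality=records[0].base_quality if len(quals) == 1 else 20,
            mapq=records[0].mapq,
            is_paired=np.array([r.is_paired for r in records]),
            is_read1=np.array([r.is_read1 for r in records]),
            mate_start=np.array(
                [r.mate_start if r.mate_start is not None else -1 for r in records]
            ),
            tlen=np.array([r.tlen for r in records]),
            molecule_id=np.array([r.molecule_id for r in records]),
            pcr_copy=np.array([r.pcr_copy for r in records]),
            is_duplicate=np.array([r.is_duplicate for r in records]),
            names=np.array([r.name for r in records], dtype=object),
        )


# ---------------------------------------------------------------------------
# SAM I/O


def write_sam(reads: ReadSet, path: str | Path, chrom_sizes: dict[str, int]) -> None:
    """Write a ReadSet as coordinate-sorted SAM text."""
    rs = reads.sort_by_coordinate()
    refs = list(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    tid = refs.index(rs.chrom)
    names = rs.names
    rl = rs.read_length
    qual_str = pysam.qualities_to_qualitystring([rs.base_quality] * rl)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i in range(len(rs)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = str(names[i])
            a.reference_id = tid
            a.reference_start = int(rs.start[i])
            length = int(rs.end[i] - rs.start[i])
            a.cigarstring = f"{length}M"
            a.mapping_quality = rs.mapq
            if rs.seq is not None:
                a.query_sequence = decode_seq(rs.seq[i])
                a.query_qualities = pysam.qualitystring_to_array(qual_str[:length])
            flag = 0
            if rs.reverse[i]:
                flag |= 0x10
            if rs.is_paired[i]:
                flag |= 0x1 | 0x2
                flag |= 0x40 if rs.is_read1[i] else 0x80
                # FR orientation: mate strand is the opposite of ours
                if not rs.reverse[i]:
                    flag |= 0x20
                a.next_reference_id = tid
                a.next_reference_start = int(rs.mate_start[i])
                a.template_length = int(rs.tlen[i])
            if rs.is_duplicate[i]:
                flag |= 0x400
            a.flag = flag
            a.set_tag("MI", int(rs.molecule_id[i]))
            a.set_tag("PC", int(rs.pcr_copy[i]))
            fh.write(a)


def read_sam(path: str | Path) -> tuple[ReadSet, dict[str, int]]:
    """Read mapped reads from a SAM/BAM file into a ReadSet.

    Returns the reads plus the chromosome sizes from the header. All reads
    must share one reference and one uniform base quality/read length
    (the simulator's output format).
    """
    records: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        sizes = {sq["SN"]: sq["LN"] for sq in fh.header.to_dict().get("SQ", [])}
        for a in fh:
            if a.is_unmapped:
                continue
            qual = a.query_qualities
            records.append(
                AlignedRead(
                    name=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                    mapq=a.mapping_quality,
                    seq=a.query_sequence,
                    base_quality=int(qual[0]) if qual is not None and len(qual) else 20,
                    is_paired=a.is_paired,
                    is_read1=not a.is_read2,
                    mate_chrom=a.next_reference_name if a.is_paired else None,
                    mate_start=a.next_reference_start if a.is_paired else None,
                    tlen=a.template_length,
                    is_duplicate=a.is_duplicate,
                    molecule_id=a.get_tag("MI") if a.has_tag("MI") else -1,
                    pcr_copy=a.get_tag("PC") if a.has_tag("PC") else 0,
                )
            )
    return ReadSet.from_records(records), sizes
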