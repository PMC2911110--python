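"""Synthetic capture-sequencing library generator.

Emulates the statistical structure of a solution-capture experiment without
modelling the wet lab: a random reference genome, a set of capture targets,
planted single-nucleotide variants on two haplotypes, and aligned reads
drawn so that

* a configurable fraction ``on_target_fraction`` of unique molecules comes
  from the targets (the "reads on target" regime, ~50-78% in real capture
  libraries), the rest from the non-target genome;
* each target captures molecules in proportion to a log-normal per-target
  efficiency weight (``efficiency_sigma`` is the SD of the log10 weight),
  reproducing the reproducible target-to-target variability real capture
  shows;
* each unique molecule is sequenced ``1 + Geometric(pcr_extra_copy_prob)``
  times; PCR copies share their molecule's coordinates and haplotype but
  receive independent base errors, so they carry the "same start point"
  signature duplicate marking exploits;
* bases are misread uniformly at rate ``base_error_rate``.

Reads are emitted as *aligned* records at their true simulated coordinates
(read mapping is outside this pipeline's scope); a FASTQ writer is provided
for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, TargetSet, consolidate
from .reads import BASES, ReadSet, decode_seq

__all__ = [
    "SimulationConfig",
    "TruthVariant",
    "TruthSet",
    "make_genome",
    "make_targets",
    "plant_variants",
    "simulate_library",
    "write_fasta",
    "write_truth_vcf",
    "read_truth_vcf",
    "write_fastq",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic capture library.

    Defaults emulate the ~3-Gbp short-read capture regime scaled to a
    10-Mbp toy genome: 50% of molecules on target, Q20 bases (1% error),
    50-bp reads from ~200-bp fragments, and a modest PCR amplification.
    """

    genome_length: int = 10_000_000
    gc_content: float = 0.41  # human-like background composition
    chrom_name: str = "chr1"
    n_targets: int = 2000
    target_length: int = 160
    on_target_fraction: float = 0.5
    efficiency_sigma: float = 0.5  # SD of log10 per-target capture weight
    fragment_mean: int = 200
    fragment_sd: float = 20.0
    read_length: int = 50
    mode: str = "frag"  # 'frag' or 'PE'
    n_molecules: int = 100_000
    pcr_extra_copy_prob: float = 0.1
    base_error_rate: float = 0.01
    base_quality: Optional[int] = None  # derived from base_error_rate when None
    variant_density: float = 0.001  # variants per target bp
    het_fraction: float = 0.7
    known_sites_fraction: float = 0.9
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "on_target_fraction",
            "pcr_extra_copy_prob",
            "base_error_rate",
            "het_fraction",
            "known_sites_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_extra_copy_prob >= 1.0:
            raise ValueError("pcr_extra_copy_prob must be < 1")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.mode not in ("frag", "PE"):
            raise ValueError("mode must be 'frag' or 'PE'")
        if self.base_quality is None:
            # the Phred quality consistent with the configured error rate
            eps = max(self.base_error_rate, 1e-6)
            self.base_quality = int(round(-10 * math.log10(eps)))


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # 'het' | 'hom'
    known: bool


@dataclass(frozen=True)
class TruthSet:
    """Planted-variant ground truth; the 'known' flag marks the subset that
    plays the role of a population-database (dbSNP-style) catalogue."""

    variants: tuple[TruthVariant, ...]

    def __post_init__(self) -> None:
        positions = [(v.chrom, v.pos) for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError("truth variants must be unique per position")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def make_genome(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw an i.i.d. reference genome with the configured GC content.

    Returns base codes (0..3 = ACGT) as uint8.
    """
    if cfg.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = rng or np.random.default_rng(cfg.seed)
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=cfg.genome_length, p=p).astype(np.uint8)


def make_targets(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> TargetSet:
    """Place ``n_targets`` equal-length targets roughly evenly, with random
    jitter, leaving untargeted space between them."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, L, G = cfg.n_targets, cfg.target_length, cfg.genome_length
    if n * L * 2 > G:
        raise ValueError("genome too small for the requested target set")
    pitch = G // n
    jitter = rng.integers(0, max(1, pitch - L), size=n)
    starts = np.arange(n) * pitch + jitter
    ivs = [
        GenomicInterval(cfg.chrom_name, int(s), int(s) + L, f"t{i:05d}")
        for i, s in enumerate(starts)
    ]
    ts = consolidate(ivs)
    if len(ts) != n:  # jitter should never merge targets given the size check
        raise RuntimeError("target placement produced overlapping targets")
    return ts


def plant_variants(
    genome: np.ndarray,
    targets: TargetSet,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TruthSet, tuple[np.ndarray, np.ndarray]]:
    """Plant SNVs over target bases and return the truth plus two haplotypes.

    Heterozygous variants are substituted on exactly one haplotype (chosen
    at random), homozygous ones on both.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    hap0 = genome.copy()
    hap1 = genome.copy()
    target_positions = np.concatenate(
        [np.arange(t.start, t.end) for t in targets]
    ) if len(targets) else np.array([], dtype=np.int64)
    n_var = int(round(cfg.variant_density * len(target_positions)))
    if n_var == 0:
        return TruthSet(()), (hap0, hap1)
    pos = np.sort(rng.choice(target_positions, size=n_var, replace=False))
    ref_codes = genome[pos]
    # alt drawn uniformly from the three non-reference bases
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_var)) % 4
    is_het = rng.random(n_var) < cfg.het_fraction
    het_hap = rng.integers(0, 2, size=n_var)
    known = rng.random(n_var) < cfg.known_sites_fraction
    variants = []
    for i, p in enumerate(pos):
        if is_het[i]:
            (hap0 if het_hap[i] == 0 else hap1)[p] = alt_codes[i]
        else:
            hap0[p] = alt_codes[i]
            hap1[p] = alt_codes[i]
        variants.append(
            TruthVariant(
                chrom=cfg.chrom_name,
                pos=int(p),
                ref=chr(BASES[ref_codes[i]]),
                alt=chr(BASES[alt_codes[i]]),
                genotype="het" if is_het[i] else "hom",
                known=bool(known[i]),
            )
        )
    return TruthSet(tuple(variants)), (hap0, hap1)


@dataclass
class LibraryResult:
    reads: ReadSet
    efficiencies: np.ndarray  # per-target capture weights actually used
    n_molecules: int
    config: SimulationConfig


def _sample_fragments(
    cfg: SimulationConfig,
    targets: TargetSet,
    efficiencies: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (fragment_start, fragment_length, on_target flag) per molecule."""
    G, M, rl = cfg.genome_length, cfg.n_molecules, cfg.read_length
    lengths = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, M)).astype(np.int64)
    np.clip(lengths, rl, G, out=lengths)
    on = rng.random(M) < cfg.on_target_fraction
    n_on = int(on.sum())
    starts = np.empty(M, dtype=np.int64)

    if n_on:
        if len(targets) == 0:
            raise ValueError("on_target_fraction > 0 requires a non-empty target set")
        w = efficiencies / efficiencies.sum()
        tidx = rng.choice(len(targets), size=n_on, p=w)
        t_start = np.array([t.start for t in targets])
        t_len = np.array([len(t) for t in targets])
        mid = t_start[tidx] + (rng.random(n_on) * t_len[tidx]).astype(np.int64)
        s = mid - lengths[on] // 2
        np.clip(s, 0, G - lengths[on], out=s)
        starts[on] = s

    n_off = M - n_on
    if n_off:
        # off-target molecules come from the non-target genome: rejection-sample
        # uniform placements until the fragment is target-free
        t_start = np.array([t.start for t in targets]) if len(targets) else np.array([G + 1])
        t_end = np.array([t.end for t in targets]) if len(targets) else np.array([G + 2])
        off_len = lengths[~on]
        s = rng.integers(0, G - off_len + 1)
        for _ in range(1000):
            e = s + off_len
            # a fragment [s, e) overlaps a target iff the first target with
            # end > s starts before e
            idx = np.searchsorted(t_end, s, side="right")
            bad = (idx < len(t_start)) & (t_start[np.minimum(idx, len(t_start) - 1)] < e)
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            s[bad] = rng.integers(0, G - off_len[bad] + 1)
        else:
            raise RuntimeError("could not place off-target fragments; targets too dense")
        starts[~on] = s
    return starts, lengths, on


def simulate_library(
    cfg: SimulationConfig,
    haplotypes: tuple[np.ndarray, np.ndarray],
    targets: TargetSet,
    *,
    seed: Optional[int] = None,
    efficiencies: Optional[np.ndarray] = None,
) -> LibraryResult:
    """Simulate one capture library as coordinate-sorted aligned reads.

    ``efficiencies`` lets technical replicates share one per-target capture
    weight vector (pass the previous library's vector); when None a fresh
    log-normal vector is drawn from the same stream.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if efficiencies is None:
        efficiencies = 10.0 ** rng.normal(0.0, cfg.efficiency_sigma, len(targets))
    else:
        efficiencies = np.asarray(efficiencies, dtype=float)
        if len(efficiencies) != len(targets):
            raise ValueError("one efficiency weight per target required")

    M, rl, G = cfg.n_molecules, cfg.read_length, cfg.genome_length
    fstart, flen, _on = _sample_fragments(cfg, targets, efficiencies, rng)
    fend = fstart + flen
    hap_idx = rng.integers(0, 2, size=M)
    if cfg.pcr_extra_copy_prob > 0:
        # extra copies ~ Geometric on {0,1,...}: P(k) = (1-p) p^k
        copies = rng.geometric(1.0 - cfg.pcr_extra_copy_prob, size=M)
    else:
        copies = np.ones(M, dtype=np.int64)
    if cfg.mode == "frag":
        strand_rev = rng.integers(0, 2, size=M).astype(bool)

    # expand molecules -> sequencing copies
    mol_id = np.repeat(np.arange(M, dtype=np.int64), copies)
    copy_idx = _within_group_index(copies)
    c_fstart = np.repeat(fstart, copies)
    c_fend = np.repeat(fend, copies)
    c_hap = np.repeat(hap_idx, copies)

    if cfg.mode == "frag":
        c_rev = np.repeat(strand_rev, copies)
        r_start = np.where(c_rev, c_fend - rl, c_fstart)
        reads = ReadSet(
            cfg.chrom_name,
            r_start,
            r_start + rl,
            c_rev,
            base_quality=cfg.base_quality,
            molecule_id=mol_id,
            pcr_copy=copy_idx,
        )
        r_hap = c_hap
    else:  # PE: read1 forward at the fragment start, read2 reverse at its end
        nc = len(mol_id)
        r_start = np.empty(2 * nc, dtype=np.int64)
        r_rev = np.empty(2 * nc, dtype=bool)
        is_r1 = np.empty(2 * nc, dtype=bool)
        mate = np.empty(2 * nc, dtype=np.int64)
        tl = np.empty(2 * nc, dtype=np.int64)
        r_start[0::2] = c_fstart
        r_start[1::2] = c_fend - rl
        r_rev[0::2] = False
        r_rev[1::2] = True
        is_r1[0::2] = True
        is_r1[1::2] = False
        mate[0::2] = c_fend - rl
        mate[1::2] = c_fstart
        tl[0::2] = c_fend - c_fstart
        tl[1::2] = -(c_fend - c_fstart)
        reads = ReadSet(
            cfg.chrom_name,
            r_start,
            r_start + rl,
            r_rev,
            base_quality=cfg.base_quality,
            is_paired=np.ones(2 * nc, dtype=bool),
            is_read1=is_r1,
            mate_start=mate,
            tlen=tl,
            molecule_id=np.repeat(mol_id, 2),
            pcr_copy=np.repeat(copy_idx, 2),
        )
        r_hap = np.repeat(c_hap, 2)

    reads.seq = _draw_sequences(reads, haplotypes, r_hap, cfg, rng)
    result = reads.sort_by_coordinate()
    # sequences follow the reads through subset(); haplotype array no longer needed
    return LibraryResult(result, efficiencies, M, cfg)


def _within_group_index(counts: np.ndarray) -> np.ndarray:
    """[3,1,2] -> [0,1,2, 0, 0,1] (copy index within each molecule)."""
    total = int(counts.sum())
    out = np.arange(total, dtype=np.int64)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    return (out - offsets).astype(np.int32)


def _draw_sequences(
    reads: ReadSet,
    haplotypes: tuple[np.ndarray, np.ndarray],
    hap_idx: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chunk: int = 200_000,
) -> np.ndarray:
    """Gather read sequences from their haplotype, then apply uniform errors.

    Reverse-strand reads keep reference orientation here: alignments store
    the forward-strand sequence, which is what pileups consume.
    """
    n, rl = len(reads), reads.read_length
    seq = np.empty((n, rl), dtype=np.uint8)
    offs = np.arange(rl, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        idx = reads.start[lo:hi, None] + offs[None, :]
        block = np.empty((hi - lo, rl), dtype=np.uint8)
        for h in (0, 1):
            m = hap_idx[lo:hi] == h
            if m.any():
                block[m] = haplotypes[h][idx[m]]
        if cfg.base_error_rate > 0:
            err = rng.random((hi - lo, rl)) < cfg.base_error_rate
            n_err = int(err.sum())
            if n_err:
                block[err] = (block[err] + rng.integers(1, 4, size=n_err)) % 4
        seq[lo:hi] = block
    return seq


# ---------------------------------------------------------------------------
# I/O


def write_fasta(genome: np.ndarray, chrom_name: str, path: str | Path) -> None:
    rec = SeqRecord(Seq(decode_seq(genome)), id=chrom_name, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in sizes.items():
            fh.write(f"{c}\t{l}\n")


def write_truth_vcf(
    truth: TruthSet, path: str | Path, chrom_sizes: dict[str, int]
) -> None:
    """Write planted variants as VCF with genotype and a KNOWN info flag."""
    import pysam

    header = pysam.VariantHeader()
    for c, l in chrom_sizes.items():
        header.contigs.add(c, length=int(l))
    header.info.add("KNOWN", 0, "Flag", "Site present in the known-sites catalogue")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("truth")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(truth, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos,
                stop=v.pos + 1,
                alleles=(v.ref, v.alt),
            )
            rec.samples["truth"]["GT"] = (0, 1) if v.genotype == "het" else (1, 1)
            rec.samples["truth"].phased = False
            if v.known:
                rec.info["KNOWN"] = True
            vcf.write(rec)


def read_truth_vcf(path: str | Path) -> TruthSet:
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), None)
        for rec in vcf:
            gt = rec.samples[sample]["GT"] if sample else (0, 1)
            variants.append(
                TruthVariant(
                    chrom=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype="hom" if gt == (1, 1) else "het",
                    known=bool(rec.info.get("KNOWN", False)),
                )
            )
    return TruthSet(tuple(variants))


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """FASTQ export (unused by the pipeline, which consumes aligned reads).

    Reverse-strand reads are written as sequenced, i.e. reverse-complemented
    relative to the reference-orientation sequence stored in the ReadSet.
    """
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    qual_char = chr(reads.base_quality + 33)
    names = reads.names
    with open(path, "w") as fh:
        for i in range(len(reads)):
            codes = reads.seq[i]
            if reads.reverse[i]:
                codes = comp[codes[::-1]]
            suffix = "" if not reads.is_paired[i] else ("/1" if reads.is_read1[i] else "/2")
            fh.write(
                f"@{names[i]}{suffix}\n{decode_seq(codes)}\n+\n{qual_char * len(codes)}\n"
            )
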