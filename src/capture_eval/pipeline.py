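"""End-to-end orchestration: simulate -> dedup -> coverage -> call -> evaluate.

One :class:`RunConfig` drives a fully deterministic run that writes every
intermediate artifact (FASTA reference, BED targets, truth VCF, SAM reads,
duplicate report, coverage tables, calls VCF, concordance tables) plus a
manifest with SHA-256 checksums. Each stage is also callable standalone
through the modules it wraps; a state file records completed stages so a
partially failed run can resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import dedup as dd
from . import simulate as sim
from . import variants as var
from .intervals import TargetSet, write_bed
from .reads import ReadSet, read_sam, write_sam

logger = logging.getLogger("capture_eval")

__all__ = ["RunConfig", "run_pipeline", "compare_libraries"]


@dataclass
class RunConfig:
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    dedup_mode: Optional[str] = None  # default: follow sim.mode
    coverage_thresholds: tuple[int, ...] = (1, 10, 20)
    caller_profile: str = "solid"
    cov_threshold: int = 9
    outdir: str = "run"
    seed: Optional[int] = None  # overrides sim.seed when set
    write_sam_output: bool = True

    def __post_init__(self) -> None:
        if self.dedup_mode is None:
            self.dedup_mode = "PE" if self.sim.mode == "PE" else "frag"
        if self.seed is not None:
            self.sim.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = sim.SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim_cfg, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state_path = out / "state.json"
    state = {}
    if resume and state_path.exists():
        state = json.loads(state_path.read_text())

    def done(stage: str) -> None:
        state[stage] = "done"
        state_path.write_text(json.dumps(state, indent=1))

    scfg = cfg.sim
    chrom_sizes = {scfg.chrom_name: scfg.genome_length}

    # -- simulate ------------------------------------------------------------
    rng = np.random.default_rng(scfg.seed)
    genome = sim.make_genome(scfg, rng)
    targets = sim.make_targets(scfg, rng)
    truth, haplotypes = sim.plant_variants(genome, targets, scfg, rng)
    lib = sim.simulate_library(scfg, haplotypes, targets, seed=scfg.seed + 10)
    reads = lib.reads
    logger.info("simulate: %d molecules -> %d reads, %d truth variants",
                lib.n_molecules, len(reads), len(truth))
    sim.write_fasta(genome, scfg.chrom_name, out / "reference.fa")
    sim.write_chrom_sizes(chrom_sizes, out / "reference.sizes")
    write_bed(targets, out / "targets.bed")
    sim.write_truth_vcf(truth, out / "truth.vcf", chrom_sizes)
    done("simulate")

    # -- dedup ---------------------------------------------------------------
    marked, dup_report = dd.mark_duplicates(reads, cfg.dedup_mode)
    logger.info("dedup(%s): %d/%d duplicates (%.2f%%)", cfg.dedup_mode,
                dup_report.duplicates, dup_report.total,
                100 * dup_report.duplicate_rate)
    if cfg.write_sam_output:
        write_sam(marked, out / "marked.sam", chrom_sizes)
    pd.Series(
        {
            "mode": dup_report.mode,
            "total_reads": dup_report.total,
            "duplicate_reads": dup_report.duplicates,
            "duplicate_pct": 100 * dup_report.duplicate_rate,
        }
    ).to_csv(out / "dup_report.tsv", sep="\t", header=False)
    done("dedup")

    # -- coverage ------------------------------------------------------------
    summary = cov.coverage_summary(
        marked, targets, dup_report, thresholds=cfg.coverage_thresholds
    )
    summary.as_series().to_csv(out / "summary.tsv", sep="\t", header=False)
    per_target = cov.per_target_table(marked, targets)
    per_target.to_csv(out / "per_target.tsv", sep="\t", index=False)
    hist = summary.depth_histogram
    pd.DataFrame({"depth": np.arange(len(hist)), "target_bases": hist}).to_csv(
        out / "depth_histogram.tsv", sep="\t", index=False
    )
    done("coverage")

    # -- call ----------------------------------------------------------------
    columns = var.build_pileup(marked, targets, genome)
    calls = var.apply_profile(var.call_variants(columns), cfg.caller_profile)
    var.write_calls_vcf(calls, out / "calls.vcf", chrom_sizes)
    logger.info("call(%s): %d candidates, %d pass", cfg.caller_profile,
                len(calls), sum(c.passed for c in calls))
    done("call")

    # -- evaluate ------------------------------------------------------------
    depths = cov.depth_profile(marked, targets, use_dedup=True)
    report = None
    if len(truth):
        report = var.evaluate_calls(calls, truth, depths, cfg.cov_threshold)
        report.as_series().to_csv(out / "concordance.tsv", sep="\t", header=False)
        report.by_depth_bin.to_csv(out / "concordance_by_depth.tsv", sep="\t", index=False)
    else:
        pd.Series({"total_calls": sum(c.passed for c in calls)}).to_csv(
            out / "concordance.tsv", sep="\t", header=False
        )
    done("evaluate")

    manifest = {
        "seed": scfg.seed,
        "config": {
            "sim": dataclasses.asdict(scfg),
            "dedup_mode": cfg.dedup_mode,
            "coverage_thresholds": list(cfg.coverage_thresholds),
            "caller_profile": cfg.caller_profile,
            "cov_threshold": cfg.cov_threshold,
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "state.json")
        },
        "summary": {
            "duplicate_pct": 100 * dup_report.duplicate_rate,
            "reads_on_target_pct": summary.reads_on_target_pct,
            "mean_coverage": summary.mean_coverage,
            "total_passing_calls": sum(c.passed for c in calls),
            "concordance_pct": report.concordance_pct if report else None,
            f"concordance_gt{cfg.cov_threshold}x_pct": (
                report.concordance_above_threshold_pct if report else None
            ),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def compare_libraries(
    tables: Sequence[pd.DataFrame], names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-target normalized coverage.

    ``tables`` are per-target tables (from :func:`coverage.per_target_table`)
    over the same target set.
    """
    if len(tables) < 2:
        raise ValueError("need at least two libraries to compare")
    ref = tables[0][["chrom", "start", "end"]]
    for t in tables[1:]:
        if not ref.reset_index(drop=True).equals(
            t[["chrom", "start", "end"]].reset_index(drop=True)
        ):
            raise ValueError("libraries were computed over different target sets")
    names = list(names) if names else [f"lib{i+1}" for i in range(len(tables))]
    mat = np.ones((len(tables), len(tables)))
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            r = cov.replicate_correlation(
                tables[i]["normalized_depth"], tables[j]["normalized_depth"]
            )
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)
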