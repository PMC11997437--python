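"""End-to-end chip-design pipeline with config validation and a
checksummed output manifest.

Stages: (optional) simulate genome + population -> per-site QC ->
probe GC/specificity evaluation -> uniform panel selection -> panel
metrics.  Every output file, its sha256, the config snapshot and the
package version are recorded in ``manifest.json``; a rerun with the
same seed and config produces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io_core import read_fasta, read_vcf, write_fasta, write_panel, write_vcf
from .panel_select import panel_metrics, select_uniform
from .probe_design import evaluate_probes, probe_report_frame
from .synth_data import GenomeConfig, PopulationConfig, simulate_genome, simulate_population
from .variant_qc import qc_filter, sites_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    out_dir: str = "panelsmith_run"
    seed: int = 0
    vcf: str | None = None
    fasta: str | None = None
    # simulation (used when vcf/fasta are not given)
    sim_chrom_lengths: tuple[int, ...] = (200_000, 150_000)
    sim_gc: float = 0.45
    sim_n_snps: int = 800
    sim_n_pops: int = 2
    sim_samples_per_pop: int = 30
    sim_divergence_F: float = 0.05
    # thresholds
    max_missing: float = 0.1
    min_maf: float = 0.35
    max_hobs: float = 0.5
    flank_len: int = 110
    gc_low: float = 0.3
    gc_high: float = 0.7
    max_hits: int = 5
    window: int = 100_000
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("max_missing", "min_maf", "max_hobs", "gc_low", "gc_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gc_low > self.gc_high:
            raise ValueError("gc_low must be <= gc_high")
        if self.flank_len < 70:
            raise ValueError("flank_len must be >= 70 (smallest homology window)")
        if self.window < 1 or self.max_hits < 1:
            raise ValueError("window and max_hits must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim_chrom_lengths" in data:
            data["sim_chrom_lengths"] = tuple(data["sim_chrom_lengths"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the design pipeline; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.vcf and config.fasta:
            genome = read_fasta(config.fasta)
            g = read_vcf(config.vcf)
        else:
            stage = "simulate"
            gcfg = GenomeConfig(
                n_chroms=len(config.sim_chrom_lengths),
                lengths=tuple(config.sim_chrom_lengths),
                gc=config.sim_gc,
            )
            genome, _ = simulate_genome(gcfg, seed=config.seed)
            pcfg = PopulationConfig(
                n_pops=config.sim_n_pops,
                samples_per_pop=config.sim_samples_per_pop,
                n_snps=config.sim_n_snps,
                divergence_F=config.sim_divergence_F,
                maf_floor=0.05,
            )
            g, pops, _ = simulate_population(pcfg, genome, seed=config.seed + 1)
            write_fasta(genome, out / "genome.fa")
            write_vcf(g, out / "variants.vcf", contig_lengths=genome.lengths)

        stage = "qc"
        stats = sites_stats(g)
        mask = qc_filter(
            stats,
            max_missing=config.max_missing,
            min_maf=config.min_maf,
            max_hobs=config.max_hobs,
        )
        stats.assign(qc_pass=mask).to_csv(out / "site_stats.tsv", sep="\t", index=False)
        qc_sites = [s for s, m in zip(g.sites, mask) if m]
        qc_stats = stats[mask].reset_index(drop=True)

        stage = "probes"
        reports = evaluate_probes(
            qc_sites,
            genome,
            flank_len=config.flank_len,
            gc_band=(config.gc_low, config.gc_high),
            max_hits=config.max_hits,
        )
        probe_report_frame(reports).to_csv(out / "probe_report.tsv", sep="\t", index=False)
        passing = [i for i, r in enumerate(reports) if r.overall_pass]

        stage = "select"
        panel = select_uniform(
            [qc_sites[i] for i in passing],
            qc_stats.iloc[passing].reset_index(drop=True),
            window=config.window,
        )
        files = [out / "site_stats.tsv", out / "probe_report.tsv"]
        if len(panel):
            bed, tsv = write_panel(panel, out / "panel")
            files += [bed, tsv]
            stage = "metrics"
            metrics = panel_metrics(panel, genome.lengths)
            with open(out / "panel_metrics.json", "w") as fh:
                json.dump(metrics.to_dict(), fh, indent=2)
            files.append(out / "panel_metrics.json")
        if (out / "genome.fa").exists():
            files += [out / "genome.fa", out / "variants.vcf"]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "files": {str(f.name): _sha256(f) for f in files if f.exists()},
        "n_input_sites": g.n_sites,
        "n_qc_pass": int(mask.sum()),
        "n_probe_pass": len(passing),
        "n_panel": len(panel),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
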