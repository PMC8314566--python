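"""Configuration, run reports and the end-to-end synthetic pipeline.

``run_pipeline`` chains the four stages on synthetic data — simulate a
fibroin gene and reads, curate the gene back from the reads by seed
extension, segment the protein into motif regions, and compute the
mechanics statistics — writing every intermediate file and a JSON run
report.  Two runs with the same configuration produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .architecture import (
    SegConfig,
    motif_length_stats,
    protein_crystalline_fraction,
    segment_repetitive_domain,
    segmentation_to_table,
    split_repeat_units,
)
from .curation import AlignParams, CurationConfig, extend_seed, find_terminal_seeds, identity_to_template
from .errors import InputError, ParameterError
from .seqio import write_fasta, write_fastq
from .simulate import (
    ArchitectureParams,
    MechSimSpec,
    ReadSimParams,
    generate_fibroin_gene,
    generate_mech_dataset,
    simulate_reads,
    truth_table,
)
from .stats import crystallinity_trend, tensile_summary

logger = logging.getLogger("fibroin_arch")


@dataclass
class PipelineConfig:
    """All stage configurations plus global seed and output location.

    Sub-stage seeds are derived from ``rng_seed`` (gene: +0, reads: +1,
    mechanics: +2) so a single integer pins the whole run.
    """

    architecture: ArchitectureParams = field(default_factory=ArchitectureParams)
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    curation: CurationConfig = field(default_factory=CurationConfig)
    segmentation: SegConfig = field(default_factory=SegConfig)
    mech: MechSimSpec = field(default_factory=MechSimSpec)
    rng_seed: int = 0
    codon_policy: str = "first_codon"
    outdir: str = "fibroin_arch_out"
    log_level: str = "INFO"
    include_timestamp: bool = False

    def validate(self) -> None:
        self.architecture.validate()
        self.reads.validate()
        self.curation.validate()
        self.segmentation.validate()
        self.mech.validate()


@dataclass
class RunReport:
    version: str
    timestamp: str | None
    config: dict[str, Any]
    metrics: dict[str, dict[str, Any]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _build_dataclass(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(
            f"unknown {cls.__name__} field(s): {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data)
    sub = {
        "architecture": ArchitectureParams,
        "reads": ReadSimParams,
        "curation": CurationConfig,
        "segmentation": SegConfig,
        "mech": MechSimSpec,
    }
    kwargs: dict[str, Any] = {}
    for key, cls in sub.items():
        if key in data:
            kwargs[key] = _build_dataclass(cls, data.pop(key))
    kwargs.update(data)
    return _build_dataclass(PipelineConfig, kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="[%(name)s] %(levelname)s %(message)s",
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """simulate -> curate -> annotate -> stats, end to end on synthetic data."""
    config.validate()
    _setup_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict[str, dict[str, Any]] = {}

    # --- simulate -----------------------------------------------------
    try:
        gene = generate_fibroin_gene(
            config.architecture, config.rng_seed, config.codon_policy
        )
        read_params = dataclasses.replace(
            config.reads, rng_seed=config.rng_seed + 1
        )
        reads = simulate_reads(gene.cds, read_params)
        write_fasta([(gene.gene_id, gene.cds)], outdir / "gene.fasta")
        write_fasta([(gene.gene_id, gene.protein)], outdir / "protein.fasta")
        write_fastq(reads, outdir / "reads.fastq")
        truth_table(gene).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {
            "rng_seed": config.rng_seed,
            "architecture": dataclasses.asdict(config.architecture),
            "reads": dataclasses.asdict(read_params),
            "codon_policy": config.codon_policy,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        metrics["simulate"] = {
            "rng_seed": config.rng_seed,
            "protein_length": len(gene.protein),
            "cds_length": len(gene.cds),
            "n_reads": len(reads),
            "n_units": len(gene.unit_spans),
        }
        logger.info(
            "simulate: %d aa protein, %d reads", len(gene.protein), len(reads)
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # --- curate -------------------------------------------------------
    try:
        n_term_nt = 3 * config.architecture.n_term_len
        if n_term_nt < config.curation.k:
            raise InputError(
                "n_term_len too short to seed curation at the configured k"
            )
        contig = gene.cds[:n_term_nt]
        seeds = find_terminal_seeds(
            [("n_term_contig", contig)],
            [("n_term_reference", contig)],
            AlignParams(min_score=60.0),
        )
        result = extend_seed(seeds[0], reads, config.curation)
        write_fasta(
            [(f"{gene.gene_id}_curated", result.sequence)],
            outdir / "curated.fasta",
        )
        with open(outdir / "support.tsv", "w") as fh:
            fh.write("position\tbase\tdepth\tdominant_frac\n")
            for i, (depth, frac) in enumerate(result.support):
                pos = result.seed_length + i
                fh.write(f"{pos}\t{result.sequence[pos]}\t{depth}\t{frac:.4f}\n")
        identity = identity_to_template(result.sequence, gene.cds)
        metrics["curate"] = {
            "seeds_found": len(seeds),
            "seed_rng": config.rng_seed,
            "bases_extended": result.appended,
            "rounds": result.rounds,
            "termination": result.termination.value,
            "identity_to_truth": identity,
        }
        logger.info(
            "curate: +%d bases, %s, identity %.4f",
            result.appended,
            result.termination.value,
            identity,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'curate' failed: {exc}") from exc

    # --- annotate -----------------------------------------------------
    try:
        seg = segment_repetitive_domain(
            gene.protein, config.segmentation, gene.gene_id
        )
        segmentation_to_table(seg).to_csv(
            outdir / "segmentation.tsv", sep="\t", index=False
        )
        units = split_repeat_units(seg)
        with open(outdir / "units.tsv", "w") as fh:
            fh.write("unit_index\tstart\tend\n")
            for u in units:
                fh.write(f"{u.unit_index}\t{u.unit_span[0]}\t{u.unit_span[1]}\n")
        stats = motif_length_stats({"synthetic": [seg]})
        stats.summary.to_csv(outdir / "motif_stats.tsv", sep="\t", index=False)
        truth_flat = gene.flat_truth()
        seg_match = seg.typed_regions() == truth_flat
        cf = protein_crystalline_fraction(units)
        metrics["annotate"] = {
            "units_segmented": len(units),
            "regions_typed": len(seg.typed_regions()),
            "matches_truth": bool(seg_match),
            "crystalline_fraction": cf,
        }
        logger.info(
            "annotate: %d units, truth match %s, crystalline %.3f",
            len(units),
            seg_match,
            cf,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc

    # --- stats --------------------------------------------------------
    try:
        mech, cryst = generate_mech_dataset(config.mech, config.rng_seed + 2)
        mech.to_csv(outdir / "mech.tsv", sep="\t", index=False)
        cryst.to_csv(outdir / "cryst.tsv", sep="\t", index=False)
        summary = tensile_summary(mech)
        summary.to_csv(outdir / "tensile_summary.tsv", sep="\t", index=False)
        trend = crystallinity_trend(mech, cryst, "tensile_strength")
        (outdir / "trend.json").write_text(
            json.dumps(dataclasses.asdict(trend), indent=2, sort_keys=True)
        )
        metrics["stats"] = {
            "mech_rng": config.rng_seed + 2,
            "stats_emitted": len(summary),
            "trend_r": trend.r,
            "trend_slope": trend.slope,
            "monotone_decreasing": trend.monotone_decreasing,
        }
        logger.info("stats: trend r=%.3f slope=%.1f", trend.r, trend.slope)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    report = RunReport(
        version=__version__,
        timestamp=(
            datetime.now(timezone.utc).isoformat()
            if config.include_timestamp
            else None
        ),
        config=dataclasses.asdict(config),
        metrics=metrics,
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
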