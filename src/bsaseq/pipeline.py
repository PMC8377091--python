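"""Pipeline orchestration: simulate -> process -> call -> fit -> contrast.

Every stage reads and writes plain text (FASTQ/TSV/JSON, optional SAM) so
any one of them can be swapped against an external tool for
cross-validation; no external tool is ever invoked here. A single global
seed drives named per-stage substreams, and a run manifest records the
config echo and per-stage read accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    MethylationMatrix,
    SiteCounts,
    apply_depth_thresholds,
    depth_histogram_report,
    pileup_cpg_counts,
)
from .model import MCMCSettings, build_design, contrast_table, fit_model
from .reads import (
    AlignedRead,
    align_to_converted_reference,
    demultiplex_by_primer,
    merge_pairs,
    quality_trim,
    read_fastq,
    write_fastq,
)
from .reference import (
    ReferenceLocus,
    converted_strands,
    load_primer_table,
    load_reference_fasta,
    write_primer_table,
    write_reference_fasta,
)
from .simulate import (
    IndividualMeta,
    SimulationConfig,
    read_sample_sheet,
    simulate_cohort,
    simulate_reads,
    write_sample_sheet,
    write_truth,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs"]

log = logging.getLogger("bsaseq")

DEFAULT_DEPTH_THRESHOLDS = {"ACTB": 10000, "BDNF": 20000, "CRF": 100, "NR3C1": 500}


@dataclass
class PipelineConfig:
    """Every tunable of the five pipeline stages, with study defaults.

    Paths are only needed when processing externally produced inputs; the
    synthetic route fills them in itself.
    """

    reference_fasta: str | None = None
    tss_table: str | None = None
    primer_table: str | None = None
    sample_sheet: str | None = None
    output_dir: str = "bsaseq_out"
    depth_thresholds: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_THRESHOLDS)
    )
    per_site_thresholds: bool = False
    end_q: int = 20
    window: int = 5
    window_mean_q: float = 30.0
    primer_max_error_rate: float = 0.2
    min_overlap: int = 10
    max_mismatch_density: float = 0.25
    min_score_fraction: float = 0.8
    salvage_loci: list[str] = field(default_factory=lambda: ["NR3C1"])
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    hdi_mass: float = 0.95
    focal_population: str | None = None
    write_sam: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for locus, thr in self.depth_thresholds.items():
            if thr < 0:
                raise ValueError(f"negative depth threshold for {locus!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunManifest:
    version: str
    seed: int
    started: str
    finished: str = ""
    config: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Input validation


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Check parseability and schema of all configured inputs; never mutates.

    Returns a list of violation messages (empty when everything is valid).
    """
    problems: list[str] = []
    if config.reference_fasta:
        try:
            loci = load_reference_fasta(config.reference_fasta, config.tss_table)
            if not loci:
                problems.append(f"{config.reference_fasta}: no FASTA records")
        except Exception as exc:
            problems.append(f"{config.reference_fasta}: {exc}")
    if config.primer_table:
        try:
            primers = load_primer_table(config.primer_table)
            for locus, pair in primers.items():
                for which, seq in (("forward", pair.forward), ("reverse", pair.reverse)):
                    if not seq or any(b not in "ACGT" for b in seq):
                        problems.append(
                            f"{config.primer_table}: {which} primer for {locus} not plain ACGT"
                        )
        except Exception as exc:
            problems.append(f"{config.primer_table}: {exc}")
    if config.sample_sheet:
        try:
            individuals, fastqs = read_sample_sheet(config.sample_sheet)
        except Exception as exc:
            problems.append(f"{config.sample_sheet}: {exc}")
        else:
            seen = set()
            for line_no, ind in enumerate(individuals, start=2):
                if ind.id in seen:
                    problems.append(f"{config.sample_sheet}:{line_no}: duplicate id {ind.id!r}")
                seen.add(ind.id)
            for ind_id, (f1, f2) in fastqs.items():
                for path in (f1, f2):
                    if not path:
                        continue
                    try:
                        for read in read_fastq(path):
                            pass  # SequenceRead validates length/quality agreement
                    except Exception as exc:
                        problems.append(f"{path} (individual {ind_id}): {exc}")
    return problems


# ---------------------------------------------------------------------------
# Per-individual processing


@dataclass
class StageCounts:
    pairs_total: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    trimmed_empty: int = 0
    merged: int = 0
    unmerged: int = 0
    salvaged: int = 0
    aligned: int = 0
    unaligned: int = 0

    def add(self, other: "StageCounts") -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, getattr(self, f.name) + getattr(other, f.name))


def process_read_pairs(
    pairs,
    loci: list[ReferenceLocus],
    primers,
    config: PipelineConfig,
) -> tuple[dict[str, list[AlignedRead]], StageCounts]:
    """Demultiplex, trim, merge (or salvage) and align an iterable of pairs."""
    by_locus = {l.name: l for l in loci}
    strands = {l.name: converted_strands(l) for l in loci}
    fwd = {name: p.forward for name, p in primers.items()}
    rev = {name: p.reverse for name, p in primers.items()}
    alignments: dict[str, list[AlignedRead]] = {l.name: [] for l in loci}
    counts = StageCounts()
    salvage = set(config.salvage_loci)
    for r1, r2 in pairs:
        counts.pairs_total += 1
        d1 = demultiplex_by_primer(r1, fwd, config.primer_max_error_rate)
        if d1.locus is None:
            if d1.ambiguous:
                counts.ambiguous += 1
            else:
                counts.unassigned += 1
            continue
        counts.assigned += 1
        locus = d1.locus
        d2 = demultiplex_by_primer(r2, {locus: rev[locus]}, config.primer_max_error_rate)
        r2_trimmed = d2.trimmed if d2.locus is not None else r2
        t1 = quality_trim(d1.trimmed, config.end_q, config.window, config.window_mean_q)
        t2 = quality_trim(r2_trimmed, config.end_q, config.window, config.window_mean_q)
        if len(t1) == 0:
            counts.trimmed_empty += 1
            continue
        merged = merge_pairs(t1, t2, config.min_overlap, config.max_mismatch_density) if len(t2) else None
        if merged is not None:
            counts.merged += 1
            query = merged
        elif locus in salvage:
            counts.salvaged += 1
            query = t1  # unpaired forward read pressed into service
        else:
            counts.unmerged += 1
            continue
        aln = align_to_converted_reference(
            query, strands[locus], by_locus[locus], config.min_score_fraction
        )
        if aln is None:
            counts.unaligned += 1
        else:
            counts.aligned += 1
            alignments[locus].append(aln)
    return alignments, counts


def _write_sam(alignments: dict[str, list[AlignedRead]], loci: list[ReferenceLocus], path: Path) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": l.name, "LN": len(l.sequence)} for l in loci],
    }
    names = {l.name: i for i, l in enumerate(loci)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for locus, alns in alignments.items():
            for k, aln in enumerate(alns):
                a = pysam.AlignedSegment()
                a.query_name = f"{locus}.{k}"
                a.reference_id = names[locus]
                a.reference_start = aln.ref_start
                a.mapping_quality = 60
                n = int((aln.read_to_ref >= 0).sum())
                a.cigartuples = [(0, n)] if n else None
                a.flag = 0 if aln.strand == "OT" else 16
                a.set_tag("XB", aln.strand)  # bisulfite strand
                out.write(a)


# ---------------------------------------------------------------------------
# Full run


def matrix_from_alignments(
    per_individual: dict[str, dict[str, list[AlignedRead]]],
    loci: list[ReferenceLocus],
) -> MethylationMatrix:
    all_counts: list[SiteCounts] = []
    locus_depth_rows = {}
    for ind_id, by_locus in per_individual.items():
        locus_depth_rows[ind_id] = {l.name: len(by_locus.get(l.name, [])) for l in loci}
        for locus in loci:
            all_counts.extend(pileup_cpg_counts(by_locus.get(locus.name, []), locus, ind_id))
    locus_depth = pd.DataFrame.from_dict(locus_depth_rows, orient="index")[
        [l.name for l in loci]
    ]
    site_order = [lab for l in loci for lab in l.site_labels]
    return MethylationMatrix.from_counts(all_counts, locus_depth, site_order)


def run_pipeline(
    config: PipelineConfig,
    sim_config: SimulationConfig | None = None,
) -> tuple[RunManifest, pd.DataFrame]:
    """Execute all stages; returns the manifest and the contrast table.

    With ``sim_config`` given, inputs are simulated into the output
    directory first; otherwise the configured reference/primer/sample-sheet
    paths are loaded. Any stage failure raises with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config=dataclasses.asdict(config),
    )

    stage = "simulate"
    try:
        if sim_config is not None:
            loci = sim_config.loci
            primers = sim_config.primers
            individuals, truth = simulate_cohort(sim_config)
            write_reference_fasta(loci, out / "reference.fasta")
            write_primer_table(primers, out / "primers.tsv")
            write_truth(truth, out / "truth.tsv")
            fastq_paths = {}
            read_pairs_by_ind = {}
            for ind in individuals:
                pairs = []
                for locus in loci:
                    pairs.extend(simulate_reads(ind, locus, truth, sim_config))
                f1 = out / f"{ind.id}_R1.fastq.gz"
                f2 = out / f"{ind.id}_R2.fastq.gz"
                write_fastq((p[0] for p in pairs), f1)
                write_fastq((p[1] for p in pairs), f2)
                fastq_paths[ind.id] = (str(f1), str(f2))
                read_pairs_by_ind[ind.id] = pairs
            write_sample_sheet(individuals, out / "sample_sheet.tsv", fastq_paths)
            manifest.stage_counts["simulate"] = {
                "individuals": len(individuals),
                "read_pairs": sum(len(p) for p in read_pairs_by_ind.values()),
            }
        else:
            if not (config.reference_fasta and config.primer_table and config.sample_sheet):
                raise ValueError("reference_fasta, primer_table and sample_sheet are required")
            loci = load_reference_fasta(config.reference_fasta, config.tss_table)
            primers = load_primer_table(config.primer_table)
            individuals, fastq_paths = read_sample_sheet(config.sample_sheet)
            read_pairs_by_ind = None

        stage = "process"
        per_individual = {}
        totals = StageCounts()
        for ind in individuals:
            if read_pairs_by_ind is not None:
                pairs = read_pairs_by_ind[ind.id]
            else:
                f1, f2 = fastq_paths[ind.id]
                pairs = zip(read_fastq(f1), read_fastq(f2))
            alignments, counts = process_read_pairs(pairs, loci, primers, config)
            per_individual[ind.id] = alignments
            totals.add(counts)
            log.info("processed %s: %s", ind.id, counts)
            if config.write_sam:
                _write_sam(alignments, loci, out / f"{ind.id}.sam")
        manifest.stage_counts["process"] = dataclasses.asdict(totals)

        stage = "call"
        matrix = matrix_from_alignments(per_individual, loci)
        matrix.to_tsv(out / "methylation_matrix_raw.tsv", out / "site_depth.tsv")
        matrix.locus_depth.to_csv(out / "locus_depth.tsv", sep="\t", index_label="individual")
        depth_histogram_report(matrix.locus_depth).to_csv(
            out / "depth_histograms.tsv", sep="\t", index=False
        )
        thresholds = {k: v for k, v in config.depth_thresholds.items() if k in matrix.locus_depth.columns}
        filtered = apply_depth_thresholds(matrix, thresholds, config.per_site_thresholds)
        filtered.to_tsv(out / "methylation_matrix.tsv")
        manifest.stage_counts["call"] = {
            "cells_total": int(matrix.values.size),
            "cells_missing_raw": int(matrix.values.isna().sum().sum()),
            "cells_missing_after_threshold": int(filtered.values.isna().sum().sum()),
        }

        stage = "fit"
        spec = build_design(
            filtered,
            individuals,
            mcmc=MCMCSettings(
                chains=config.chains, warmup=config.warmup, draws=config.draws, seed=config.seed
            ),
            focal_population=config.focal_population,
        )
        draws = fit_model(spec)
        manifest.stage_counts["fit"] = {
            "n_obs": spec.n_obs,
            "converged": bool(draws.converged),
        }

        stage = "contrast"
        table = contrast_table(draws, config.hdi_mass)
        table.to_csv(out / "contrast_summary.tsv", sep="\t", index=False)
        wide = pd.DataFrame(
            {c: draws.contrast_draws(c).ravel() for c in spec.site_labels}
        )
        wide.to_csv(out / "contrast_draws.tsv", sep="\t", index_label="draw")
        draws.diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    config.to_yaml(out / "config_echo.yaml")
    return manifest, table
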