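"""Pipeline orchestration: simulate -> demux -> refbuild -> call ->
parent-based genotyping -> SNP filtering -> linkage mapping.

Every stage is also runnable standalone on the prior stage's artifacts (see
:mod:`sbg.cli`); this module wires them together with a single global seed
fanned out per stage (each stage derives its child seed from the CRC of
``"<stage>|<seed>"``, so stages are independently reproducible), logs every
threshold actually applied, and writes a run report whose per-stage counts
chain: each stage's input count equals the previous stage's output count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import aligncall, demux, linkmap, parentgeno, refbuild, simgen, snpfilter

log = logging.getLogger("sbg")

TAG_LENGTH = 5


def child_seed(seed: int, stage: str) -> int:
    return zlib.crc32(f"{stage}|{seed}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Every stage's parameters plus the global seed; JSON round-trippable."""

    out_dir: str = "sbg_run"
    seed: int = 1
    population: str = "bc1"  # "bc1" | "ril"
    n_offspring: int = 220
    generations: int = 8
    # founder fixture
    n_chrom: int = 5
    chrom_bp: int = 1_000_000
    chrom_cm: float = 125.0
    snp_density: float = 10.0
    gc: float = 0.5
    # digestion & sequencing
    scheme: str = "ecori-msei"
    read_length: int = 76
    paired: bool = False
    mean_depth: float = 20.0
    depth_dist: str = "poisson"
    error_rate: float = 0.001
    # demux QC
    max_homopolymer: int = 10
    max_n: int = 0
    min_mean_q: float = 20.0
    # reference thresholds (lower None -> number of samples)
    lower: Optional[int] = None
    upper: int = refbuild.UPPER_DEFAULT
    # caller thresholds
    min_dp: int = 7
    min_gq: float = 20.0
    min_snpq: float = 30.0
    max_mm: int = 3
    # filtering & mapping
    filter_preset: Optional[str] = None  # default: population
    n_orders: int = 150
    group_max_rf: float = 0.4
    group_min_lod: float = 4.0
    two_step: bool = False
    # artifact switches
    keep_sample_fastq: bool = False
    write_vcf: bool = True

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls(**json.load(f))


@dataclass
class RunResult:
    config: RunConfig
    report: dict
    paths: dict
    fixture: simgen.GenomeFixture
    individuals: list
    sheet: demux.SampleSheet
    sim: simgen.SimOutput
    demux_report: demux.DemuxReport
    refs: refbuild.ReferenceSet
    sites: list
    abh: parentgeno.ABHMatrix
    abh_filtered: parentgeno.ABHMatrix
    verdicts: object
    map_result: linkmap.MapResult


def run_all(config: RunConfig) -> RunResult:
    """Execute the full workflow; any stage failure aborts with its name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    report: dict = {"stages": {}}
    stage = "config"

    def _tick(name: str):
        nonlocal stage
        stage = name
        log.info("stage %s starting", name)
        return time.perf_counter()

    def _tock(t0: float, **counts):
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2), **counts}
        log.info("stage %s done: %s", stage, counts)

    try:
        # --- simulate ------------------------------------------------------
        t0 = _tick("simulate")
        if config.population not in ("bc1", "ril"):
            raise ValueError(f"population must be 'bc1' or 'ril', got {config.population!r}")
        scheme = simgen.SCHEMES[config.scheme]
        fixture = simgen.make_founders(
            n_chrom=config.n_chrom,
            chrom_bp=config.chrom_bp,
            chrom_cM=config.chrom_cm,
            snp_density=config.snp_density,
            gc=config.gc,
            seed=child_seed(config.seed, "founders"),
        )
        model = simgen.PopulationModel(
            kind="BC1" if config.population == "bc1" else "RIL_selfed",
            n_offspring=config.n_offspring,
            generations=config.generations,
            include_parents=True,
        )
        individuals = simgen.simulate_cross(fixture, model, child_seed(config.seed, "cross"))
        names = [ind.name for ind in individuals]
        sheet = demux.design_tags(
            len(names), length=TAG_LENGTH, min_dist=2,
            seed=child_seed(config.seed, "tags"), sample_ids=names,
        )
        sheet.to_tsv(out / "sample_sheet.tsv")
        read_cfg = simgen.ReadConfig(
            read_length=config.read_length,
            paired=config.paired,
            mean_depth=config.mean_depth,
            depth_dist=config.depth_dist,
            error_rate=config.error_rate,
            seed=child_seed(config.seed, "reads"),
        )
        sim = simgen.make_reads(individuals, fixture, scheme, sheet, read_cfg, out)
        _tock(t0, n_samples=len(names), n_fragments=len(sim.fragments),
              n_snps_simulated=len(fixture.snp_table), n_reads=sim.n_reads)

        # --- demux ---------------------------------------------------------
        t0 = _tick("demux")
        qc = demux.QCConfig(
            remnants=(scheme.rare.remnant,),
            max_homopolymer=config.max_homopolymer,
            max_n=config.max_n,
            min_mean_q=config.min_mean_q,
        )
        qc2 = demux.QCConfig(
            remnants=(scheme.frequent.remnant,),
            max_homopolymer=config.max_homopolymer,
            max_n=config.max_n,
            min_mean_q=config.min_mean_q,
        )
        log.info("demux thresholds: remnants=%s max_homopolymer=%d max_n=%d min_mean_q=%g",
                 qc.remnants, qc.max_homopolymer, qc.max_n, qc.min_mean_q)
        dreport, counters = demux.run_demux(
            sim.fastq[0], sheet, qc,
            out_dir=out, write_fastq=config.keep_sample_fastq,
            fastq_in2=sim.fastq[1] if config.paired else None,
            qc2=qc2 if config.paired else None,
        )
        _tock(t0, n_input_reads=dreport.total, n_assigned=dreport.n_assigned,
              fraction_assigned=round(dreport.fraction_assigned, 4))

        # --- refbuild ------------------------------------------------------
        t0 = _tick("refbuild")
        lower = config.lower if config.lower is not None else len(names)
        log.info("reference thresholds: lower=%d (default: number of samples) upper=%d",
                 lower, config.upper)
        expected = config.read_length - sheet.tag_length
        counts = refbuild.count_unique(counters, expected)
        refs = refbuild.build_reference(counts, lower, config.upper)
        refs.write_fasta(out / "reference.fasta")
        refs.write_summary(out / "reference_summary.json")
        sides = [(refs, counters)]
        if config.paired:
            counts2 = refbuild.count_unique(dreport.mate_counters, config.read_length)
            refs2 = refbuild.build_reference(counts2, lower, config.upper)
            refs2 = refbuild.ReferenceSet(
                [refbuild.Contig(c.id.replace("SBG_", "SBG2_"), c.sequence, c.count)
                 for c in refs2.contigs],
                refs2.lower, refs2.upper, refs2.source,
            )
            refs2.write_fasta(out / "reference_read2.fasta")
            sides.append((refs2, dreport.mate_counters))
        _tock(t0, n_full_length=counts.full_length_reads, n_unique=counts.n_unique,
              n_contigs=sum(len(r) for r, _ in sides))

        # --- aligncall -----------------------------------------------------
        t0 = _tick("call")
        th = aligncall.CallerThresholds(
            min_dp=config.min_dp, min_gq=config.min_gq,
            min_snpq=config.min_snpq, max_mm=config.max_mm,
        )
        log.info("caller thresholds: min_dp=%d min_gq=%g min_snpq=%g max_mm=%d",
                 th.min_dp, th.min_gq, th.min_snpq, th.max_mm)
        sites = []
        n_assigned_reads = 0
        for side_refs, side_counters in sides:
            assignments = aligncall.assign_counts(side_counters, side_refs, th.max_mm)
            n_assigned_reads += assignments.n_assigned
            sites.extend(aligncall.call_variants(assignments, side_refs, names, th))
        if config.paired:
            seqs1 = {c.sequence for c in sides[0][0].contigs}
            from ._seq import revcomp
            overlap = sum(
                1 for c in sides[1][0].contigs
                if c.sequence in seqs1 or revcomp(c.sequence) in seqs1
            )
            log.info("read-1/read-2 pooled without deduplication; %d contig overlaps", overlap)
            report["stages"].setdefault("call_extra", {})["contig_overlap"] = overlap
        aligncall.write_sites_tsv(sites, names, out / "sites.tsv")
        if config.write_vcf:
            all_refs = refbuild.ReferenceSet(
                [c for r, _ in sides for c in r.contigs], lower, config.upper
            )
            aligncall.write_vcf(sites, all_refs, names, out / "sites.vcf")
        _tock(t0, n_assigned_reads=n_assigned_reads, n_sites=len(sites))

        # --- parentgeno ----------------------------------------------------
        t0 = _tick("parentgeno")
        informative = parentgeno.informative_sites(sites, "P1", "P2")
        abh = parentgeno.to_abh(informative, "P1", "P2", names, poptype=config.population)
        abh.to_tsv(out / "abh.tsv")
        abh.write_summary(out / "abh_summary.json")
        _tock(t0, n_sites_in=len(sites), n_informative=len(informative),
              **{k: v for k, v in abh.summary().items() if k.startswith(("n_", "freq_"))})

        # --- snpfilter -----------------------------------------------------
        t0 = _tick("filter")
        preset = snpfilter.PRESETS[config.filter_preset or config.population]
        log.info("filter preset %s: max_missing=%g bounds=%s",
                 preset.name, preset.max_missing, preset.freq_bounds)
        abh_f, verdicts, fsummary = snpfilter.filter_matrix(abh, preset)
        abh_f.to_tsv(out / "abh_filtered.tsv")
        snpfilter.write_verdicts(verdicts, out / "filter_verdicts.tsv")
        with open(out / "filter_summary.json", "w") as f:
            json.dump(fsummary, f, indent=2)
        _tock(t0, n_input_snps=len(abh.df), n_retained_snps=len(abh_f.df))

        # --- linkmap -------------------------------------------------------
        t0 = _tick("map")
        mcfg = linkmap.MapConfig(
            group_max_rf=config.group_max_rf,
            group_min_lod=config.group_min_lod,
            n_orders=config.n_orders,
            two_step=config.two_step,
            seed=child_seed(config.seed, "map"),
        )
        map_result = linkmap.build_map(abh_f, mcfg)
        map_result.to_tsv(out / "map.tsv")
        _tock(t0, n_markers_in=len(abh_f.df), n_groups=map_result.n_groups,
              n_mapped=sum(len(g) for g in map_result.groups),
              n_ungrouped=len(map_result.ungrouped),
              lengths_cm=[round(g.length_cm, 1) for g in map_result.groups])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_report.json", "w") as f:
        json.dump(report, f, indent=2)

    paths = {p.name: str(p) for p in out.iterdir()}
    return RunResult(
        config=config, report=report, paths=paths, fixture=fixture,
        individuals=individuals, sheet=sheet, sim=sim, demux_report=dreport,
        refs=refs, sites=sites, abh=abh, abh_filtered=abh_f,
        verdicts=verdicts, map_result=map_result,
    )
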