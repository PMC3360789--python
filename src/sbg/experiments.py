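"""Canned simulation experiments exercising the whole toolkit.

These functions define the standard study conditions used by the test suite
and by ``scripts/acceptance.py``: a noise-free BC1 sequencing run through the
full pipeline, truth-level BC1/RIL genotype matrices for filter and
segregation checks, and a large-population unlinked-marker experiment.  All
randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import numpy as np

from . import linkmap, parentgeno, snpfilter
from .demux import design_tags, hamming
from .pipeline import RunConfig, child_seed, run_all
from .simgen import GenomeFixture, PopulationModel, make_founders, simulate_cross


def noise_free_bc1(seed: int, n_offspring: int = 220, out_dir: Optional[str] = None) -> dict:
    """Full pipeline on a noise-free BC1 sequencing run.

    Default fixture (5 chromosomes x 1 Mb x 125 cM, 10 SNPs/kb), zero
    sequencing error at exact 20x fragment coverage, 220 offspring plus both
    parents.  Returns the parent-based A/B/H class frequencies (in percent,
    over non-missing offspring calls, before frequency filtering) and the
    number of linkage groups found on the filtered matrix.
    """
    with tempfile.TemporaryDirectory() as tmp:
        cfg = RunConfig(
            out_dir=out_dir or tmp,
            seed=seed,
            population="bc1",
            n_offspring=n_offspring,
            error_rate=0.0,
            mean_depth=20.0,
            depth_dist="fixed",
        )
        res = run_all(cfg)
        s = res.abh.summary()
        purity = _group_purity(res)
        return {
            "n_informative_snps": s["n_snps"],
            "freq_A_pct": 100.0 * s["freq_A"],
            "freq_B_pct": 100.0 * s["freq_B"],
            "freq_H_pct": 100.0 * s["freq_H"],
            "genotypes_per_snp": s["genotypes_per_snp"],
            "n_groups": res.map_result.n_groups,
            "group_sizes": [len(g) for g in res.map_result.groups],
            "group_lengths_cm": [g.length_cm for g in res.map_result.groups],
            "group_purity": purity,
            "fraction_assigned": res.demux_report.fraction_assigned,
        }


def _group_purity(res) -> float:
    """Fraction of mapped markers whose linkage group's dominant true
    chromosome matches their own (truth read back from contig provenance)."""
    # marker id -> true chromosome via the fragment each contig came from
    contig_chrom = {}
    frag_by_seq = {}
    fixture = res.fixture
    for frag in res.sim.fragments:
        frag_by_seq[(frag.chrom, frag.start, frag.end)] = frag.chrom
    # locate each contig on the founder genome by exact substring search
    for contig in res.refs.contigs:
        chrom = None
        for c, seq in enumerate(fixture.chromosomes):
            if contig.sequence[:40] in seq:
                chrom = c
                break
        if chrom is None:
            from ._seq import revcomp
            for c, seq in enumerate(fixture.chromosomes):
                if revcomp(contig.sequence)[:40] in seq:
                    chrom = c
                    break
        contig_chrom[contig.id] = chrom
    total = 0
    pure = 0
    for group in res.map_result.groups:
        chroms = [contig_chrom.get(m.split(":")[0]) for m in group.marker_ids]
        chroms = [c for c in chroms if c is not None]
        if not chroms:
            continue
        dominant = max(set(chroms), key=chroms.count)
        pure += sum(1 for c in chroms if c == dominant)
        total += len(chroms)
    return pure / total if total else 0.0


def truth_abh_bc1(seed: int, n_offspring: int = 220, n_snps: int = 1000) -> parentgeno.ABHMatrix:
    """Truth-level BC1 A/B/H matrix (no sequencing), ~``n_snps`` markers."""
    fixture = make_founders(
        n_chrom=5, chrom_bp=100_000, chrom_cM=125.0,
        snp_density=n_snps / 5 / 100.0, seed=child_seed(seed, "founders"),
    )
    model = PopulationModel("BC1", n_offspring=n_offspring, include_parents=True)
    inds = simulate_cross(fixture, model, child_seed(seed, "cross"))
    geno = np.stack([ind.genotype for ind in inds], axis=1)
    return parentgeno.abh_from_truth(
        geno, [ind.name for ind in inds], poptype="bc1", parents=("P1", "P2")
    )


def bc1_filter_accuracy(
    seed: int,
    n_offspring: int = 220,
    n_snps: int = 1000,
    error_rate: float = 0.05,
) -> dict:
    """Inject random genotype-call errors into a truth BC1 matrix, apply the
    BC1 filter preset, and measure the worst per-SNP accuracy under the
    A-as-error proxy: min over retained SNPs of 100 * (1 - freq(A))."""
    abh = truth_abh_bc1(seed, n_offspring, n_snps)
    rng = np.random.default_rng(child_seed(seed, "inject"))
    off = abh.offspring
    vals = abh.df[off].to_numpy().copy()
    flip = rng.random(vals.shape) < error_rate
    codes = np.array(["A", "B", "H"])
    for i, j in zip(*np.nonzero(flip)):
        others = codes[codes != vals[i, j]]
        vals[i, j] = others[rng.integers(len(others))]
    abh.df.loc[:, off] = vals
    retained, verdicts, _ = snpfilter.filter_matrix(abh, snpfilter.BC1_PRESET)
    ovals = retained.offspring_frame().to_numpy()
    called = (ovals != parentgeno.MISSING).sum(axis=1)
    freq_a = (ovals == "A").sum(axis=1) / np.maximum(called, 1)
    min_acc = 100.0 * (1.0 - freq_a.max()) if len(ovals) else float("nan")
    return {
        "n_input_snps": len(abh.df),
        "n_retained_snps": len(retained.df),
        "min_accuracy_pct": float(min_acc),
        "mean_accuracy_pct": float(100.0 * (1.0 - freq_a.mean())) if len(ovals) else float("nan"),
    }


def unlinked_rf(seed: int, n_offspring: int = 10_000) -> dict:
    """BC1 recombination fraction between markers on different chromosomes."""
    fixture = make_founders(
        n_chrom=2, chrom_bp=50_000, chrom_cM=100.0, snp_density=0.1,
        seed=child_seed(seed, "founders"),
    )
    model = PopulationModel("BC1", n_offspring=n_offspring, include_parents=False)
    inds = simulate_cross(fixture, model, child_seed(seed, "cross"))
    geno = np.stack([ind.genotype for ind in inds], axis=1)
    m1 = int(fixture.snp_indices(0)[0])
    m2 = int(fixture.snp_indices(1)[0])
    est = linkmap.pair_rf(geno[m1], geno[m2], poptype="bc1")
    return {"rf": est.rf, "lod": est.lod, "n_informative": est.n_informative}


def ril_class_frequencies(
    seed: int, n_offspring: int = 2000, n_snps: int = 500, generations: int = 8
) -> dict:
    """Genotype-class frequencies of a selfed RIL truth matrix, in percent."""
    fixture = make_founders(
        n_chrom=5, chrom_bp=100_000, chrom_cM=125.0,
        snp_density=n_snps / 5 / 100.0, seed=child_seed(seed, "founders"),
    )
    model = PopulationModel(
        "RIL_selfed", n_offspring=n_offspring, generations=generations,
        include_parents=False,
    )
    inds = simulate_cross(fixture, model, child_seed(seed, "cross"))
    geno = np.stack([ind.genotype for ind in inds], axis=1)
    abh = parentgeno.abh_from_truth(geno, [ind.name for ind in inds], poptype="ril")
    counts = abh.class_counts()
    called = counts["A"] + counts["B"] + counts["H"]
    return {
        "freq_A_pct": 100.0 * counts["A"] / called,
        "freq_B_pct": 100.0 * counts["B"] / called,
        "freq_H_pct": 100.0 * counts["H"] / called,
        "hom_mean_pct": 100.0 * (counts["A"] + counts["B"]) / (2 * called),
        "n_genotypes": called,
    }


def tag_design_metrics(seed: int, n: int = 96, length: int = 5, min_dist: int = 2) -> dict:
    """Design a tag set and report its size and minimum pairwise distance."""
    sheet = design_tags(n, length=length, min_dist=min_dist, seed=seed)
    tags = list(sheet.tags.values())
    dmin = min(
        hamming(a, b) for i, a in enumerate(tags) for b in tags[i + 1:]
    )
    return {"n_tags": len(tags), "min_pairwise_hamming": dmin}
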