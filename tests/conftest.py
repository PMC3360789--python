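"""Shared fixtures: a tiny founder pair and a small end-to-end run.

Everything is generated programmatically at test time; the small pipeline
run (24 offspring, two 200-kb chromosomes, exact 10x coverage, zero
sequencing error) is session-scoped because several modules assert
properties of its artifacts.
"""

import numpy as np
import pytest

from sbg import simgen
from sbg.pipeline import RunConfig, run_all

SEED = 1


@pytest.fixture(scope="session")
def tiny_fixture():
    return simgen.make_founders(
        n_chrom=2, chrom_bp=150_000, chrom_cM=100.0, snp_density=5.0, seed=11
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    cfg = RunConfig(
        out_dir=str(tmp_path_factory.mktemp("small_run")),
        seed=SEED,
        population="bc1",
        n_offspring=24,
        n_chrom=2,
        chrom_bp=200_000,
        chrom_cm=100.0,
        mean_depth=10.0,
        depth_dist="fixed",
        error_rate=0.0,
        n_orders=30,
        keep_sample_fastq=True,
    )
    return run_all(cfg)
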