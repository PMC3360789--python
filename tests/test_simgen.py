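"""Simulator: founder construction, meiosis, digestion and read emission."""

import re
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbg import simgen
from sbg._seq import revcomp
from sbg.demux import design_tags
from sbg.simgen import (
    ECORI,
    ECORI_MSEI,
    MSEI,
    PSTI_TAQI_MSEI,
    EnzymeScheme,
    PopulationModel,
    ReadConfig,
    digest_select,
    make_founders,
    make_reads,
    simulate_cross,
)

# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def test_make_founders_is_deterministic_and_well_formed():
    a = make_founders(n_chrom=2, chrom_bp=50_000, snp_density=2.0, seed=5)
    b = make_founders(n_chrom=2, chrom_bp=50_000, snp_density=2.0, seed=5)
    assert a.chromosomes == b.chromosomes
    assert a.snp_table == b.snp_table
    for c in range(a.n_chrom):
        pos = a.snp_positions(c)
        assert np.all(np.diff(pos) > 0)
    for _, _, ref, alt in a.snp_table:
        assert ref != alt and len(ref) == len(alt) == 1


def test_founders_differ_only_at_snp_positions(tiny_fixture):
    fx = tiny_fixture
    for c in range(fx.n_chrom):
        f1 = fx.founder_sequence(0, c)
        f2 = fx.founder_sequence(1, c)
        diffs = {i for i, (x, y) in enumerate(zip(f1, f2)) if x != y}
        assert diffs == set(fx.snp_positions(c).tolist())


def test_zero_snp_density_rejected():
    with pytest.raises(ValueError):
        make_founders(n_chrom=1, chrom_bp=10_000, snp_density=0.0, seed=0)


def test_both_founders_digest_identically(tiny_fixture):
    """SNP placement is motif-neutral, so the two founders share one digest."""
    fx = tiny_fixture
    for c in range(fx.n_chrom):
        f1 = digest_select(fx.founder_sequence(0, c), ECORI_MSEI)
        f2 = digest_select(fx.founder_sequence(1, c), ECORI_MSEI)
        assert [(f.start, f.end, f.rare_left) for f in f1] == [
            (f.start, f.end, f.rare_left) for f in f2
        ]


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------


def test_bc1_offspring_never_homozygous_for_donor(tiny_fixture):
    model = PopulationModel("BC1", n_offspring=100, include_parents=False)
    inds = simulate_cross(tiny_fixture, model, seed=7)
    for ind in inds:
        assert not np.any(ind.genotype == 0)
        assert set(np.unique(ind.genotype)) <= {1, 2}


def test_ril_residual_heterozygosity_matches_mendelian_expectation(tiny_fixture):
    """F8 selfed RILs retain 0.5^7 heterozygosity per locus (~0.78%)."""
    model = PopulationModel("RIL_selfed", n_offspring=2000, generations=8,
                            include_parents=False)
    inds = simulate_cross(tiny_fixture, model, seed=13)
    per_ind = np.array([np.mean(ind.genotype == 1) for ind in inds])
    expect = 0.5**7
    se = per_ind.std(ddof=1) / np.sqrt(len(per_ind))
    assert abs(per_ind.mean() - expect) <= 3 * se + 1e-9


def test_same_seed_reproduces_cross(tiny_fixture):
    model = PopulationModel("BC1", n_offspring=10)
    a = simulate_cross(tiny_fixture, model, seed=3)
    b = simulate_cross(tiny_fixture, model, seed=3)
    for x, y in zip(a, b):
        assert np.array_equal(x.genotype, y.genotype)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def _oracle_digest(seq, scheme):
    """Independent brute-force digest: regex site scan, all adjacent cut
    pairs, then direct application of the selection rules."""
    occ = []
    for enz in scheme.enzymes:
        occ.extend((m.start(), enz) for m in re.finditer(f"(?={enz.site})", seq))
    occ.sort(key=lambda t: t[0])
    frags = []
    for i in range(len(occ) - 1):
        (s1, e1), (s2, e2) = occ[i], occ[i + 1]
        names = {e1.name, e2.name}
        if names != {scheme.rare.name, scheme.frequent.name}:
            continue
        start = s1 + len(e1.site) - len(e1.remnant)
        end = s2 + len(e2.remnant)
        if end <= start:
            continue
        if not scheme.min_fragment_len <= end - start <= scheme.max_fragment_len:
            continue
        frags.append((start, end, e1.name == scheme.rare.name))
    return frags


@pytest.mark.parametrize("scheme", [ECORI_MSEI, PSTI_TAQI_MSEI])
def test_digest_matches_bruteforce_on_random_sequence(scheme):
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=50_000))
    got = [(f.start, f.end, f.rare_left) for f in digest_select(seq, scheme)]
    assert got == _oracle_digest(seq, scheme)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=1200))
def test_digest_property_matches_oracle(seq):
    scheme = EnzymeScheme(ECORI, MSEI, min_fragment_len=5, max_fragment_len=500)
    got = [(f.start, f.end, f.rare_left) for f in digest_select(seq, scheme)]
    assert got == _oracle_digest(seq, scheme)


def test_digest_keeps_both_rare_frequent_orientations():
    """R..F..R yields the R-F fragment and the following F-R fragment."""
    scheme = EnzymeScheme(ECORI, MSEI, min_fragment_len=0, max_fragment_len=10_000)
    seq = "C" * 30 + "GAATTC" + "C" * 40 + "TTAA" + "C" * 50 + "GAATTC" + "C" * 30
    frags = digest_select(seq, scheme)
    assert len(frags) == 2
    assert frags[0].rare_left and not frags[1].rare_left


def test_excluder_site_removes_fragment():
    base = "C" * 30 + "CTGCAG" + "C" * 200 + "TCGA" + "C" * 30
    clean = digest_select(base, PSTI_TAQI_MSEI)
    assert len(clean) == 1
    poisoned = base.replace("C" * 200, "C" * 98 + "TTAA" + "C" * 98)
    assert digest_select(poisoned, PSTI_TAQI_MSEI) == []


def test_short_fragment_removed_by_size_selection():
    seq = "C" * 30 + "GAATTC" + "C" * 145 + "TTAA" + "C" * 30  # 150-bp fragment
    frags = digest_select(seq, ECORI_MSEI)  # min 200
    assert frags == []
    relaxed = EnzymeScheme(ECORI, MSEI, min_fragment_len=100, max_fragment_len=1000)
    assert len(digest_select(seq, relaxed)) == 1


def test_empty_sequence_digests_to_empty_set():
    assert digest_select("", ECORI_MSEI) == []


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def read_sim(tmp_path_factory, tiny_fixture):
    model = PopulationModel("BC1", n_offspring=6, include_parents=True)
    inds = simulate_cross(tiny_fixture, model, seed=2)
    sheet = design_tags(len(inds), seed=2, sample_ids=[i.name for i in inds])
    cfg = ReadConfig(read_length=76, mean_depth=8.0, depth_dist="fixed",
                     error_rate=0.0, seed=9)
    out = make_reads(inds, tiny_fixture, ECORI_MSEI, sheet, cfg,
                     tmp_path_factory.mktemp("reads"))
    return inds, sheet, cfg, out


def _parse_fastq(path):
    with open(path) as f:
        lines = [l.rstrip("\n") for l in f]
    for i in range(0, len(lines), 4):
        yield lines[i][1:], lines[i + 1], lines[i + 3]


def test_zero_error_reads_are_exact_fragment_substrings(read_sim, tiny_fixture):
    """Each read is tag + remnant-anchored fragment bases, differing from the
    founder-1 template only at SNP offsets (where it shows founder 2)."""
    inds, sheet, cfg, out = read_sim
    windows = {}
    for frag, (snps) in zip(out.fragments, out.window_snps):
        seq = tiny_fixture.chromosomes[frag.chrom][frag.start:frag.end]
        template = (seq if frag.rare_left else revcomp(seq))[: cfg.read_length - 5]
        windows[(frag.chrom, frag.start, frag.end)] = (template, snps)
    n = 0
    for rid, bases, quals in _parse_fastq(out.fastq[0]):
        sample, loc, hap, _ = rid.split("|")
        assert bases[:5] == sheet.tags[sample]
        chrom, rest = loc[1:].split(":")
        start, end = map(int, rest.split("-"))
        template, snps = windows[(int(chrom), start, end)]
        core = bases[5:]
        assert core[:5] == "AATTC"  # EcoRI remnant retained
        snp_offsets = {off for _, off, _ in snps}
        diffs = {i for i, (x, y) in enumerate(zip(core, template)) if x != y}
        assert diffs <= snp_offsets
        n += 1
    assert n == out.n_reads > 0


def test_het_individuals_emit_both_alleles(read_sim, tiny_fixture):
    """At a SNP-bearing fragment, a heterozygote's reads show both founder
    alleles (fair per-read haplotype sampling at exact 8x depth)."""
    inds, sheet, cfg, out = read_sim
    by_ind_frag = {}
    for rid, bases, _ in _parse_fastq(out.fastq[0]):
        sample, loc, hap, _ = rid.split("|")
        by_ind_frag.setdefault((sample, loc), []).append(int(hap[1]))
    geno = {ind.name: ind.genotype for ind in inds}
    het_frags = 0
    both = 0
    for fi, (frag, snps) in enumerate(zip(out.fragments, out.window_snps)):
        if not snps:
            continue
        loc = f"c{frag.chrom}:{frag.start}-{frag.end}"
        for ind in inds:
            if any(geno[ind.name][s] == 1 for s, _, _ in snps):
                haps = by_ind_frag.get((ind.name, loc), [])
                if len(haps) >= 4:
                    het_frags += 1
                    if len(set(haps)) == 2:
                        both += 1
    assert het_frags > 0
    assert both / het_frags > 0.9  # P(one-sided at depth>=4) <= 2*0.5^4


def test_fastq_bytes_reproducible_under_seed(tmp_path, tiny_fixture):
    model = PopulationModel("BC1", n_offspring=3, include_parents=False)
    inds = simulate_cross(tiny_fixture, model, seed=4)
    sheet = design_tags(3, seed=4, sample_ids=[i.name for i in inds])
    cfg = ReadConfig(mean_depth=5.0, error_rate=0.005, seed=21)
    out1 = make_reads(inds, tiny_fixture, ECORI_MSEI, sheet, cfg, tmp_path / "a")
    out2 = make_reads(inds, tiny_fixture, ECORI_MSEI, sheet, cfg, tmp_path / "b")
    assert out1.fastq[0].read_bytes() == out2.fastq[0].read_bytes()
    assert out1.n_reads == out2.n_reads


def test_observed_error_rate_matches_phred_profile(tmp_path, tiny_fixture):
    """At a Q30 profile the realised substitution rate over >=1e6 non-SNP
    bases is ~1e-3 (binomial check)."""
    model = PopulationModel("BC1", n_offspring=4, include_parents=False)
    inds = simulate_cross(tiny_fixture, model, seed=6)
    sheet = design_tags(4, seed=6, sample_ids=[i.name for i in inds])
    cfg = ReadConfig(mean_depth=60.0, depth_dist="fixed", error_rate=1e-3, seed=8)
    out = make_reads(inds, tiny_fixture, ECORI_MSEI, sheet, cfg, tmp_path)
    windows = {}
    for frag, snps in zip(out.fragments, out.window_snps):
        seq = tiny_fixture.chromosomes[frag.chrom][frag.start:frag.end]
        template = (seq if frag.rare_left else revcomp(seq))[: cfg.read_length - 5]
        windows[f"c{frag.chrom}:{frag.start}-{frag.end}"] = (template, {o for _, o, _ in snps})
    mism = 0
    total = 0
    for rid, bases, _ in _parse_fastq(out.fastq[0]):
        sample, loc, _, _ = rid.split("|")
        template, snp_off = windows[loc]
        core = bases[5:]
        for i, (x, y) in enumerate(zip(core, template)):
            if i in snp_off:
                continue
            total += 1
            mism += x != y
    assert total >= 1_000_000
    rate = mism / total
    se = (1e-3 * (1 - 1e-3) / total) ** 0.5
    assert abs(rate - 1e-3) < 4 * se + 1e-5


def test_tagless_sample_rejected(tiny_fixture, tmp_path):
    model = PopulationModel("BC1", n_offspring=2, include_parents=False)
    inds = simulate_cross(tiny_fixture, model, seed=1)
    sheet = design_tags(2, seed=1, sample_ids=["X1", "X2"])  # names do not match
    with pytest.raises(ValueError, match="without a tag"):
        make_reads(inds, tiny_fixture, ECORI_MSEI, sheet, ReadConfig(), tmp_path)
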