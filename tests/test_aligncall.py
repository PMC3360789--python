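"""Genotype caller: likelihood oracle, read assignment and threshold logic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbg.aligncall import (
    Assignments,
    CallerThresholds,
    HET,
    HOM_ALT,
    HOM_REF,
    ReadAssigner,
    assign_counts,
    assign_read,
    call_variants,
    merge_loci,
    site_likelihoods,
)
from sbg.refbuild import Contig, ReferenceSet


# ---------------------------------------------------------------------------
# Independent likelihood oracle: per-read probability products, no grouping.
# ---------------------------------------------------------------------------


def oracle_logliks(alleles, quals, floor=1e-4):
    """alleles: list of 'R'/'A' per read; returns log10 L for (RR, RA, AA)."""
    out = []
    for geno in ("RR", "RA", "AA"):
        log_l = 0.0
        for allele, q in zip(alleles, quals):
            e = max(10.0 ** (-q / 10.0), floor)
            p_match, p_mis = 1.0 - e, e / 3.0
            if geno == "RR":
                p = p_match if allele == "R" else p_mis
            elif geno == "AA":
                p = p_match if allele == "A" else p_mis
            else:
                p_from_r = p_match if allele == "R" else p_mis
                p_from_a = p_match if allele == "A" else p_mis
                p = 0.5 * p_from_r + 0.5 * p_from_a
            log_l += math.log10(p)
        out.append(log_l)
    return out


def test_caller_agrees_with_oracle_on_all_small_pileups():
    """Every pileup of <=10 reads over two alleles, at mixed qualities."""
    qual_cycle = [30, 20, 41, 35]
    checked = 0
    for n in range(1, 11):
        for n_ref in range(n + 1):
            quals = [qual_cycle[i % 4] for i in range(n)]
            alleles = ["R"] * n_ref + ["A"] * (n - n_ref)
            lik = site_likelihoods(n_ref, n - n_ref, quals)
            expect = oracle_logliks(alleles, quals)
            assert np.allclose(lik.loglik, expect, atol=1e-6)
            checked += 1
    assert checked == 65


def test_documented_pl_example():
    """Eight Q30 reads of one allele give PL ~ (0, 24, 278) and GQ ~ 24."""
    lik = site_likelihoods(8, 0, [30] * 8)
    assert lik.pl[HOM_REF] == 0.0
    assert round(lik.pl[HET]) == 24
    assert round(lik.pl[HOM_ALT]) == 278
    assert round(lik.gq) == 24
    assert lik.best == HOM_REF


def test_balanced_pileup_prefers_het_and_is_symmetric():
    lik = site_likelihoods(1, 1, [30, 30])
    assert lik.best == HET
    lik44 = site_likelihoods(4, 4, [30] * 8)
    assert lik44.pl[HET] == 0.0
    assert lik44.pl[HOM_REF] == pytest.approx(lik44.pl[HOM_ALT])


def test_min_pl_is_zero_and_gq_capped():
    lik = site_likelihoods(40, 0, [41] * 40)
    assert min(lik.pl) == 0.0
    assert lik.gq == 99.0


def test_empty_pileup_rejected():
    with pytest.raises(ValueError):
        site_likelihoods(0, 0, [])


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    n_ref=st.integers(0, 6),
    n_alt=st.integers(0, 6),
    qs=st.lists(st.integers(10, 41), min_size=12, max_size=12),
)
def test_likelihood_property_matches_oracle(n_ref, n_alt, qs):
    if n_ref + n_alt == 0:
        return
    quals = qs[: n_ref + n_alt]
    lik = site_likelihoods(n_ref, n_alt, quals)
    expect = oracle_logliks(["R"] * n_ref + ["A"] * n_alt, quals)
    assert np.allclose(lik.loglik, expect, atol=1e-6)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def refs():
    return ReferenceSet(
        [
            Contig("SBG_000001", "AAAAAAAAAA", 90),
            Contig("SBG_000002", "AAAAAAATTT", 50),
            Contig("SBG_000003", "GGGGGGGGGG", 40),
        ],
        lower=1,
        upper=1000,
    )


def test_assign_exact_match(refs):
    assert assign_read("AAAAAAAAAA", refs, 3) == ("SBG_000001", 0)


def test_assign_unique_best_with_mismatches(refs):
    assert assign_read("GGGGGGGGGC", refs, 3) == ("SBG_000003", 1)


def test_assign_tie_discarded(refs):
    # distance 2 to contig 1 (TT at 7,8) and 1 to contig 2? craft symmetric tie
    read = "AAAAAAATAA"  # d=1 to contig1, d=2 to contig2
    assert assign_read(read, refs, 3) == ("SBG_000001", 1)
    tie = "AAAAAAAGTA"  # equidistant: 2 mismatches to contigs 1 and 2
    a = sum(x != y for x, y in zip(tie, "AAAAAAAAAA"))
    b = sum(x != y for x, y in zip(tie, "AAAAAAATTT"))
    assert a == b == 2
    assert assign_read(tie, refs, 3) is None


def test_assign_over_max_mismatch_or_length(refs):
    assert assign_read("CCCCCCCCCC", refs, 3) is None
    assert assign_read("AAAA", refs, 3) is None


def test_merge_allelic_contigs(refs):
    loci = merge_loci(refs, 3)
    grouped = sorted(tuple(c.id for c in locus) for locus in loci)
    assert grouped == [("SBG_000001", "SBG_000002"), ("SBG_000003",)]


# ---------------------------------------------------------------------------
# call_variants
# ---------------------------------------------------------------------------

Q30S = chr(30 + 33) * 10


def _assignments(refs, entries):
    """entries: {contig_id: {(seq, qual): {sample: count}}}"""
    total = sum(n for d in entries.values() for s in d.values() for n in s.values())
    return Assignments(entries, {}, total)


def _mk_samples(n):
    return [f"S{i}" for i in range(n)]


def test_invariant_site_not_emitted(refs):
    samples = _mk_samples(3)
    entries = {
        "SBG_000003": {
            ("GGGGGGGGGG", Q30S): {s: 10 for s in samples},
        }
    }
    sites = call_variants(_assignments(refs, entries), refs, samples)
    assert sites == []


def test_het_site_called_with_oracle_quality(refs):
    """One sample 4/4 at Q30 (het), others hom at depth 10."""
    samples = _mk_samples(4)
    hom = {s: 10 for s in samples[1:]}
    entries = {
        "SBG_000001": {
            ("AAAAAAAAAA", Q30S): {**hom, samples[0]: 4},
            ("AAAAAAACAA", Q30S): {samples[0]: 4},
        }
    }
    sites = call_variants(_assignments(refs, entries), refs, samples,
                          CallerThresholds(min_snpq=10))
    assert len(sites) == 1
    site = sites[0]
    assert (site.major, site.minor) == ("A", "C")
    rec = site.calls[samples[0]]
    assert rec.genotype == HET and rec.depth == 8
    expect = oracle_logliks(["R"] * 4 + ["A"] * 4, [30] * 8)
    expect_gq = min(10 * (max(expect) - sorted(expect)[1]), 99.0)
    assert rec.gq == pytest.approx(expect_gq, abs=1e-6)
    # SNPQ is the summed evidence against all-major-hom, dominated by the het
    assert site.snpq == pytest.approx(sum(
        c.pl[HOM_REF] for c in site.calls.values()), abs=1e-6)


def test_depth_below_seven_is_missing(refs):
    samples = _mk_samples(4)
    entries = {
        "SBG_000001": {
            ("AAAAAAAAAA", Q30S): {samples[0]: 3, samples[2]: 10, samples[3]: 10},
            ("AAAAAAACAA", Q30S): {samples[0]: 3, samples[1]: 10},
        }
    }
    sites = call_variants(_assignments(refs, entries), refs, samples,
                          CallerThresholds(min_dp=7, min_snpq=10))
    assert len(sites) == 1
    assert sites[0].calls[samples[0]].genotype is None
    assert sites[0].calls[samples[0]].depth == 6


def test_missingness_monotone_in_thresholds(refs):
    samples = _mk_samples(6)
    rng = np.random.default_rng(0)
    entries = {"SBG_000001": {("AAAAAAAAAA", Q30S): {}, ("AAAAAAACAA", Q30S): {}}}
    for s in samples:
        entries["SBG_000001"][("AAAAAAAAAA", Q30S)][s] = int(rng.integers(0, 12))
        entries["SBG_000001"][("AAAAAAACAA", Q30S)][s] = int(rng.integers(0, 12))

    def called(th):
        sites = call_variants(_assignments(refs, entries), refs, samples, th)
        if not sites:
            return set()
        return {s for s, c in sites[0].calls.items() if c.genotype is not None}

    base = called(CallerThresholds(min_dp=4, min_gq=10, min_snpq=10))
    stricter = called(CallerThresholds(min_dp=8, min_gq=25, min_snpq=10))
    assert stricter <= base


# ---------------------------------------------------------------------------
# Calibration and dropout behaviour of the model
# ---------------------------------------------------------------------------


def _simulate_pileup(rng, truth, depth, q=30):
    """Read counts for a true genotype with Phred-q substitution errors;
    an error converts a read to the other allele with probability e/3."""
    e = 10.0 ** (-q / 10.0)
    if truth == HET:
        n_ref_true = rng.binomial(depth, 0.5)
    elif truth == HOM_REF:
        n_ref_true = depth
    else:
        n_ref_true = 0
    n_alt_true = depth - n_ref_true
    flips_to_alt = rng.binomial(n_ref_true, e / 3.0)
    flips_to_ref = rng.binomial(n_alt_true, e / 3.0)
    return n_ref_true - flips_to_alt + flips_to_ref, n_alt_true - flips_to_ref + flips_to_alt


def test_genotype_error_rate_below_one_percent_at_gq20():
    """At Q30 and the default 7x/GQ20 thresholds, fewer than 1.1% of the
    retained genotype calls are wrong (the validated-accuracy regime)."""
    rng = np.random.default_rng(2024)
    n = 20_000
    errors = 0
    called = 0
    for _ in range(n):
        truth = rng.choice([HOM_REF, HET, HOM_ALT], p=[0.25, 0.5, 0.25])
        depth = int(rng.poisson(10))
        if depth == 0:
            continue
        n_ref, n_alt = _simulate_pileup(rng, truth, depth)
        lik = site_likelihoods(n_ref, n_alt, [30] * depth)
        if depth < 7 or lik.gq < 20:
            continue
        called += 1
        errors += lik.best != truth
    assert called > 5000
    assert errors / called < 0.011


def test_het_dropout_rate_at_low_depth():
    """With exactly 4 reads a true het is called homozygous iff all reads
    sample one haplotype: rate ~ 2 * 0.5^4 = 12.5%."""
    rng = np.random.default_rng(7)
    n = 20_000
    hom_calls = 0
    for _ in range(n):
        n_ref, n_alt = _simulate_pileup(rng, HET, 4)
        lik = site_likelihoods(n_ref, n_alt, [30] * 4)
        hom_calls += lik.best != HET
    rate = hom_calls / n
    assert abs(rate - 0.125) < 0.01
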