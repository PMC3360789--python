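"""Read assignment and diploid genotype calling on clustered references.

Restriction fragments have fixed starts and uniform read length, so reads
are compared to contigs by ungapped Hamming distance: a read is assigned to
its unique best contig when the distance is at most ``max_mm``; ties are
discarded to avoid conflating paralogous loci.  Contigs that are allelic
variants of one locus (pairwise distance <= ``max_mm``) are merged into a
single locus before calling, with the most abundant contig as the reference.

Genotypes come from a flat-prior diploid likelihood model.  For a read with
base ``b`` and Phred error probability ``e``::

    P(b | hom-X) = 1 - e      if b == X else e / 3
    P(b | het)   = (1/2) P(b | allele-1 model) + (1/2) P(b | allele-2 model)

Per-genotype log10 likelihoods are summed over the pileup reads and turned
into Phred-scaled PL values normalised to a minimum of 0; GQ is the
second-smallest PL (capped at 99).  A genotype is reported missing when its
informative depth (major + minor allele reads) falls below ``min_dp`` or its
GQ below ``min_gq``.  Site quality (SNPQ) is the summed evidence against the
all-major-homozygote configuration -- the sum over samples of the PL of the
hom-major genotype -- capped at 9999; sites below ``min_snpq``, invariant
sites, and sites with more than two alleles above a 5% pileup fraction are
dropped.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._seq import encode
from .refbuild import Contig, ReferenceSet

MULTIALLELIC_FRACTION = 0.05
SNPQ_CAP = 9999.0
GQ_CAP = 99.0


@dataclass(frozen=True)
class CallerThresholds:
    """Validation thresholds for genotypes and sites."""

    min_dp: int = 7
    min_gq: float = 20.0
    min_snpq: float = 30.0
    max_mm: int = 3
    error_floor: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.min_dp, self.min_gq, self.min_snpq, self.max_mm) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.error_floor < 0.5:
            raise ValueError("error_floor must be in (0, 0.5)")


# ---------------------------------------------------------------------------
# Likelihood model
# ---------------------------------------------------------------------------

HOM_REF, HET, HOM_ALT = 0, 1, 2


@dataclass
class GenotypeLikelihood:
    """Log10 genotype likelihoods and their Phred-scaled normalised form."""

    loglik: tuple[float, float, float]  # (hom-ref, het, hom-alt), log10
    pl: tuple[float, float, float]
    gq: float

    @property
    def best(self) -> int:
        return int(np.argmax(self.loglik))


def _grouped_loglik(
    groups: Iterable[tuple[bool, float, int]], error_floor: float
) -> tuple[float, float, float]:
    """Genotype log10-likelihoods from (is_ref_allele, phred, count) groups."""
    l_rr = l_het = l_aa = 0.0
    for is_ref, q, n in groups:
        e = max(10.0 ** (-q / 10.0), error_floor)
        match = math.log10(1.0 - e)
        mismatch = math.log10(e / 3.0)
        het = math.log10(0.5 * (1.0 - e) + 0.5 * (e / 3.0))
        if is_ref:
            l_rr += n * match
            l_aa += n * mismatch
        else:
            l_rr += n * mismatch
            l_aa += n * match
        l_het += n * het
    return l_rr, l_het, l_aa


def site_likelihoods(
    count_ref: int,
    count_alt: int,
    quals: Sequence[float],
    error_floor: float = 1e-4,
) -> GenotypeLikelihood:
    """PL triple and GQ for a biallelic pileup.

    ``quals`` holds one Phred score per read: the first ``count_ref`` entries
    belong to reads supporting the reference (major) allele, the remaining
    ``count_alt`` to the alternate (minor) allele.
    """
    if count_ref + count_alt != len(quals):
        raise ValueError("count_ref + count_alt must equal len(quals)")
    if not quals:
        raise ValueError("empty pileup")
    groups = [(True, q, 1) for q in quals[:count_ref]]
    groups += [(False, q, 1) for q in quals[count_ref:]]
    return _likelihood_from_groups(groups, error_floor)


def _likelihood_from_groups(groups, error_floor: float) -> GenotypeLikelihood:
    ll = _grouped_loglik(groups, error_floor)
    lmax = max(ll)
    pl = tuple(10.0 * (lmax - l) for l in ll)
    gq = min(sorted(pl)[1], GQ_CAP)
    return GenotypeLikelihood(ll, pl, gq)


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------


class ReadAssigner:
    """Assign reads to contigs by unique best ungapped Hamming distance."""

    def __init__(self, refs: ReferenceSet, max_mm: int):
        self.refs = refs
        self.max_mm = max_mm
        self.ids = refs.ids
        seqs = [c.sequence for c in refs.contigs]
        self.length = len(seqs[0]) if seqs else 0
        if any(len(s) != self.length for s in seqs):
            raise ValueError("contigs must have uniform length")
        self._exact = {c.sequence: c.id for c in refs.contigs}
        self._matrix = encode(seqs)

    def assign(self, seq: str) -> Optional[tuple[str, int]]:
        if len(seq) != self.length or not self.ids:
            return None
        hit = self._exact.get(seq)
        if hit is not None:
            return hit, 0
        q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        dists = (self._matrix != q).sum(axis=1)
        best = int(dists.min())
        if best > self.max_mm:
            return None
        idx = np.nonzero(dists == best)[0]
        if idx.size != 1:
            return None  # tie: ambiguous, discard
        return self.ids[int(idx[0])], best


def assign_read(read, refs: ReferenceSet, max_mm: int) -> Optional[tuple[str, int]]:
    """Single-read convenience wrapper around :class:`ReadAssigner`.

    ``read`` may be a sequence string or an object with ``.bases``.
    """
    seq = getattr(read, "bases", read)
    return ReadAssigner(refs, max_mm).assign(seq)


@dataclass
class Assignments:
    """Reads pooled per contig, keyed by (sequence, quality string)."""

    per_contig: dict[str, dict[tuple[str, str], dict[str, int]]]
    unassigned: dict[str, int]
    n_assigned: int


def assign_counts(
    counters: Mapping[str, Mapping[tuple[str, str], int]],
    refs: ReferenceSet,
    max_mm: int,
) -> Assignments:
    """Assign per-sample read multisets (as produced by demux) to contigs."""
    assigner = ReadAssigner(refs, max_mm)
    cache: dict[str, Optional[str]] = {}
    per_contig: dict[str, dict[tuple[str, str], dict[str, int]]] = defaultdict(dict)
    unassigned = Counter()
    n_assigned = 0
    for sample, counter in counters.items():
        for key, n in counter.items():
            seq, qual = key if isinstance(key, tuple) else (key, None)
            if seq in cache:
                cid = cache[seq]
            else:
                if len(seq) != assigner.length:
                    cache[seq] = None
                    unassigned["length_mismatch"] += n
                    continue
                hit = assigner.assign(seq)
                cid = hit[0] if hit else None
                cache[seq] = cid
            if cid is None:
                if len(seq) != assigner.length:
                    unassigned["length_mismatch"] += n
                else:
                    unassigned["no_unique_best"] += n
                continue
            entry = per_contig[cid].setdefault((seq, qual), {})
            entry[sample] = entry.get(sample, 0) + n
            n_assigned += n
    return Assignments(dict(per_contig), dict(unassigned), n_assigned)


def merge_loci(refs: ReferenceSet, max_mm: int) -> list[list[Contig]]:
    """Group contigs whose sequences differ by <= ``max_mm`` into loci.

    Each locus is returned with its majority (highest-count) contig first;
    that contig serves as the locus reference during calling, so an allele
    split across two contigs cannot mask its SNP.
    """
    contigs = refs.contigs
    n = len(contigs)
    if n == 0:
        return []
    mat = encode([c.sequence for c in contigs])
    rows = []
    cols = []
    chunk = max(1, 2_000_000 // max(1, n * mat.shape[1]))
    for i0 in range(0, n, chunk):
        i1 = min(n, i0 + chunk)
        d = (mat[i0:i1, None, :] != mat[None, :, :]).sum(axis=2)
        r, c = np.nonzero(d <= max_mm)
        rows.extend((r + i0).tolist())
        cols.extend(c.tolist())
    adj = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups: list[list[Contig]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(contigs[i])
    for g in groups:
        g.sort(key=lambda c: (-c.count, c.id))
    groups.sort(key=lambda g: g[0].id)
    return groups


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


@dataclass
class GenotypeCallRec:
    """Per-sample genotype at one site.

    ``genotype`` is 0 (hom-major), 1 (het), 2 (hom-minor) or None (missing:
    below the depth or GQ threshold, or no reads).
    """

    sample: str
    genotype: Optional[int]
    depth: int
    pl: tuple[float, float, float]
    gq: float


@dataclass
class SiteCall:
    """One biallelic site on a locus reference contig (0-based position)."""

    contig: str
    pos: int
    major: str
    minor: str
    snpq: float
    calls: dict[str, GenotypeCallRec]

    def genotype(self, sample: str) -> Optional[int]:
        rec = self.calls.get(sample)
        return rec.genotype if rec else None


def _phred_of(qual_str: Optional[str], pos: int, default: float = 30.0) -> float:
    if qual_str is None:
        return default
    return ord(qual_str[pos]) - 33.0


def call_variants(
    assignments: Assignments,
    refs: ReferenceSet,
    samples: Sequence[str],
    th: CallerThresholds = CallerThresholds(),
) -> list[SiteCall]:
    """Call biallelic SNP genotypes over all merged loci.

    Candidate sites are positions where assigned reads disagree with the
    locus reference; the two most frequent alleles are kept and all other
    bases treated as noise.  A site is emitted when its SNPQ passes
    ``min_snpq`` and at least one non-missing genotype is not hom-major.
    """
    loci = merge_loci(refs, th.max_mm)
    sites: list[SiteCall] = []
    for locus in loci:
        ref = locus[0]
        entries: list[tuple[str, Optional[str], dict[str, int]]] = []
        for contig in locus:
            for (seq, qual), per_sample in assignments.per_contig.get(contig.id, {}).items():
                entries.append((seq, qual, per_sample))
        if not entries:
            continue
        ref_arr = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)
        candidate: set[int] = set()
        for seq, _, _ in entries:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            candidate.update(np.nonzero(arr != ref_arr)[0].tolist())
        for pos in sorted(candidate):
            pooled = Counter()
            for seq, _, per_sample in entries:
                pooled[seq[pos]] += sum(per_sample.values())
            total = sum(pooled.values())
            ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
            above = [b for b, n in ranked if n > MULTIALLELIC_FRACTION * total]
            if len(above) > 2:
                continue  # multi-allelic: dropped
            if len(ranked) < 2:
                continue
            major, minor = ranked[0][0], ranked[1][0]
            calls: dict[str, GenotypeCallRec] = {}
            snpq = 0.0
            informative = False
            for sample in samples:
                groups: list[tuple[bool, float, int]] = []
                depth = 0
                for seq, qual, per_sample in entries:
                    n = per_sample.get(sample, 0)
                    if n == 0:
                        continue
                    base = seq[pos]
                    if base == major:
                        groups.append((True, _phred_of(qual, pos), n))
                        depth += n
                    elif base == minor:
                        groups.append((False, _phred_of(qual, pos), n))
                        depth += n
                if not groups:
                    calls[sample] = GenotypeCallRec(sample, None, 0, (0.0, 0.0, 0.0), 0.0)
                    continue
                lik = _likelihood_from_groups(groups, th.error_floor)
                snpq += lik.pl[HOM_REF]
                geno: Optional[int] = lik.best
                if depth < th.min_dp or lik.gq < th.min_gq:
                    geno = None
                calls[sample] = GenotypeCallRec(sample, geno, depth, lik.pl, lik.gq)
                if geno in (HET, HOM_ALT):
                    informative = True
            snpq = min(snpq, SNPQ_CAP)
            if snpq < th.min_snpq or not informative:
                continue
            sites.append(SiteCall(ref.id, int(pos), major, minor, snpq, calls))
    return sites


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", None: "./."}


def write_sites_tsv(sites: Sequence[SiteCall], samples: Sequence[str], path: str | Path) -> None:
    """Minimal VCF-like TSV: per-sample GT:DP:GQ:PL, positions 1-based."""
    with open(path, "w") as f:
        f.write("contig\tpos\tmajor\tminor\tsnpq\t" + "\t".join(samples) + "\n")
        for s in sites:
            cells = []
            for sample in samples:
                rec = s.calls.get(sample)
                if rec is None:
                    cells.append("./.:0:0:0,0,0")
                    continue
                pl = ",".join(str(int(round(x))) for x in rec.pl)
                cells.append(f"{_GT_STR[rec.genotype]}:{rec.depth}:{int(round(rec.gq))}:{pl}")
            f.write(f"{s.contig}\t{s.pos + 1}\t{s.major}\t{s.minor}\t"
                    f"{s.snpq:.1f}\t" + "\t".join(cells) + "\n")


def read_sites_tsv(path: str | Path) -> tuple[list[SiteCall], list[str]]:
    """Round-trip reader for :func:`write_sites_tsv`."""
    sites: list[SiteCall] = []
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        samples = header[5:]
        for line in f:
            parts = line.rstrip("\n").split("\t")
            contig, pos, major, minor, snpq = parts[:5]
            calls = {}
            for sample, cell in zip(samples, parts[5:]):
                gt, dp, gq, pl = cell.split(":")
                geno = {v: k for k, v in _GT_STR.items()}[gt]
                pls = tuple(float(x) for x in pl.split(","))
                calls[sample] = GenotypeCallRec(sample, geno, int(dp), pls, float(gq))
            sites.append(SiteCall(contig, int(pos) - 1, major, minor, float(snpq), calls))
    return sites, samples


def write_vcf(
    sites: Sequence[SiteCall],
    refs: ReferenceSet,
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write calls as VCF 4.2 (uncompressed) via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=sbg")
    needed = {s.contig for s in sites}
    for contig in refs.contigs:
        if contig.id in needed:
            header.contigs.add(contig.id, length=len(contig.sequence))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Informative depth (major+minor allele reads)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (second-smallest PL, capped 99)")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.info.add("SNPQ", 1, "Float", "Summed evidence against all-major-homozygote")
    for sample in samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in sites:
            rec = vf.new_record(
                contig=s.contig,
                start=s.pos,
                stop=s.pos + 1,
                alleles=(s.major, s.minor),
                qual=round(s.snpq, 1),
            )
            rec.info["SNPQ"] = float(s.snpq)
            for sample in samples:
                call = s.calls.get(sample)
                fmt = rec.samples[sample]
                if call is None or call.genotype is None:
                    fmt["GT"] = (None, None)
                else:
                    fmt["GT"] = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}[call.genotype]
                if call is not None:
                    fmt["DP"] = call.depth
                    fmt["GQ"] = int(round(call.gq))
                    fmt["PL"] = tuple(int(round(x)) for x in call.pl)
            vf.write(rec)
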