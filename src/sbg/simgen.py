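"""Synthetic data generator: founder genomes, mapping populations and
in-silico reduced-representation sequencing.

The generator emulates AFLP-style complexity reduction: genomic DNA is cut
with a rare and a frequent restriction enzyme (optionally a third, excluding
enzyme), only rare-frequent fragments amplify with the two adapter/primer
pairs, fragments outside a size window are removed, and each fragment is
sequenced from the rare-cutter end behind a 5-nt inline sample tag followed
by the enzyme's restriction-site remnant.  Meiosis follows the Haldane
(no-interference) model: crossover counts are Poisson with mean equal to the
chromosome's genetic length in Morgan, crossover positions uniform in cM.

Every simulation is deterministic under its seed and writes truth tables so
downstream stages can be validated against known genotypes.
"""

from __future__ import annotations

import dataclasses
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import BASES, complement, find_all, revcomp

# ---------------------------------------------------------------------------
# Enzymes and digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    """A palindromic restriction enzyme.

    ``remnant`` is the part of the recognition site left on each fragment end
    after cutting and fill-in; it is also the motif expected at the start of a
    read sequenced from that end.  For a site of length ``m`` cut leaving a
    remnant of length ``k``, the fragment downstream of an occurrence at
    ``s`` begins at ``s + m - k`` and the fragment upstream ends at
    ``s + k`` (the two fragments share the overhang, as after fill-in).
    """

    name: str
    site: str
    remnant: str

    def __post_init__(self) -> None:
        if revcomp(self.site) != self.site:
            raise ValueError(f"{self.name}: only palindromic sites are supported")
        if self.remnant not in (self.site[-len(self.remnant):],):
            raise ValueError(f"{self.name}: remnant must be a suffix of the site")

    @property
    def right_start_offset(self) -> int:
        return len(self.site) - len(self.remnant)

    @property
    def left_end_offset(self) -> int:
        return len(self.remnant)


# Standard AFLP remnant conventions.
ECORI = Enzyme("EcoRI", "GAATTC", "AATTC")
MSEI = Enzyme("MseI", "TTAA", "TAA")
PSTI = Enzyme("PstI", "CTGCAG", "TGCAG")
TAQI = Enzyme("TaqI", "TCGA", "CGA")


@dataclass(frozen=True)
class EnzymeScheme:
    """Complexity-reduction scheme: which fragments reach the sequencer.

    Only fragments flanked by one rare-cutter end and one frequent-cutter end
    amplify (they alone carry both adapter types); rare-rare and
    frequent-frequent fragments are dropped.  If an ``excluder`` enzyme is
    configured it also cuts, so no surviving fragment contains its site.
    Fragments outside ``[min_fragment_len, max_fragment_len]`` are removed,
    mirroring post-ligation size selection.
    """

    rare: Enzyme
    frequent: Enzyme
    excluder: Optional[Enzyme] = None
    min_fragment_len: int = 200
    max_fragment_len: int = 1000

    def __post_init__(self) -> None:
        if self.min_fragment_len < 0:
            raise ValueError("min_fragment_len must be >= 0")
        if self.max_fragment_len < self.min_fragment_len:
            raise ValueError("max_fragment_len < min_fragment_len")

    @property
    def enzymes(self) -> tuple[Enzyme, ...]:
        enz = (self.rare, self.frequent)
        return enz + ((self.excluder,) if self.excluder else ())

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(e.site for e in self.enzymes)


#: Two-enzyme scheme used for small, SNP-dense genomes (arabidopsis-like).
ECORI_MSEI = EnzymeScheme(ECORI, MSEI)

#: Three-enzyme scheme with an excluding frequent cutter (lettuce-like).
PSTI_TAQI_MSEI = EnzymeScheme(PSTI, TAQI, excluder=MSEI)

SCHEMES = {"ecori-msei": ECORI_MSEI, "psti-taqi-msei": PSTI_TAQI_MSEI}

#: Motifs avoided when placing SNPs, so both founders share one digest.
DEFAULT_AVOID_MOTIFS = (ECORI.site, MSEI.site, PSTI.site, TAQI.site)


@dataclass(frozen=True)
class Fragment:
    """A selected restriction fragment, 0-based half-open on its chromosome.

    ``rare_left`` records orientation: True when the rare-cutter end is the
    fragment's left (lower-coordinate) end.
    """

    chrom: int
    start: int
    end: int
    rare_left: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_select(sequence: str, scheme: EnzymeScheme, chrom: int = 0) -> list[Fragment]:
    """In-silico digest + selection of one chromosome sequence.

    Returns the rare-frequent fragments within the scheme's size window.
    Fragments touching the sequence boundaries have an undefined end and are
    never returned.
    """
    if not sequence:
        return []
    cuts: list[tuple[int, Enzyme]] = []
    for enz in scheme.enzymes:
        cuts.extend((pos, enz) for pos in find_all(sequence, enz.site))
    cuts.sort(key=lambda c: c[0])
    out: list[Fragment] = []
    for (s1, e1), (s2, e2) in zip(cuts, cuts[1:]):
        pair = {e1.name, e2.name}
        if pair != {scheme.rare.name, scheme.frequent.name}:
            continue
        start = s1 + e1.right_start_offset
        end = s2 + e2.left_end_offset
        if end <= start:
            continue  # overlapping site occurrences
        if not scheme.min_fragment_len <= end - start <= scheme.max_fragment_len:
            continue
        out.append(Fragment(chrom, start, end, rare_left=(e1.name == scheme.rare.name)))
    return out


# ---------------------------------------------------------------------------
# Founder genomes
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixture:
    """A pair of founder genomes differing only at known SNP positions.

    ``chromosomes`` holds founder-1 sequences; founder 2 is founder 1 with
    the alternate allele substituted at every ``snp_table`` entry
    ``(chrom, pos, founder1_allele, founder2_allele)``.  SNPs are placed so
    that neither allele creates or destroys an occurrence of the avoided
    restriction-site motifs, hence both founders produce identical digests.
    """

    chromosomes: list[str]
    chrom_cM: list[float]
    snp_table: list[tuple[int, int, str, str]]
    seed: int

    @property
    def n_chrom(self) -> int:
        return len(self.chromosomes)

    def _per_chrom(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        cache = self.__dict__.get("_chrom_cache")
        if cache is None:
            cache = {c: [[], []] for c in range(self.n_chrom)}
            for i, (c, p, _, _) in enumerate(self.snp_table):
                cache[c][0].append(p)
                cache[c][1].append(i)
            cache = {
                c: (np.array(pos, dtype=np.int64), np.array(idx, dtype=np.int64))
                for c, (pos, idx) in cache.items()
            }
            self.__dict__["_chrom_cache"] = cache
        return cache

    def snp_positions(self, chrom: int) -> np.ndarray:
        return self._per_chrom()[chrom][0]

    def snp_indices(self, chrom: int) -> np.ndarray:
        return self._per_chrom()[chrom][1]

    def snp_cm(self, chrom: int) -> np.ndarray:
        """Genetic position of each SNP on ``chrom`` (linear bp->cM map)."""
        pos = self.snp_positions(chrom)
        return pos / len(self.chromosomes[chrom]) * self.chrom_cM[chrom]

    def founder_sequence(self, which: int, chrom: int) -> str:
        seq = self.chromosomes[chrom]
        if which == 0:
            return seq
        arr = bytearray(seq, "ascii")
        for c, p, _, a2 in self.snp_table:
            if c == chrom:
                arr[p] = ord(a2)
        return arr.decode("ascii")


def _motif_neutral(seq: str, pos: int, alt: str, motifs: Sequence[str]) -> bool:
    """True when substituting ``alt`` at ``pos`` changes no motif occurrence."""
    m = max((len(x) for x in motifs), default=1)
    lo = max(0, pos - m + 1)
    hi = min(len(seq), pos + m)
    ref_win = seq[lo:hi]
    alt_win = ref_win[: pos - lo] + alt + ref_win[pos - lo + 1:]
    return all(find_all(ref_win, mot) == find_all(alt_win, mot) for mot in motifs)


def make_founders(
    n_chrom: int = 5,
    chrom_bp: int = 1_000_000,
    chrom_cM: float = 125.0,
    snp_density: float = 10.0,
    gc: float = 0.5,
    seed: int = 0,
    avoid_motifs: Sequence[str] = DEFAULT_AVOID_MOTIFS,
) -> GenomeFixture:
    """Generate a founder pair: random chromosomes plus a SNP table.

    Parameters
    ----------
    snp_density
        SNPs per kb; each chromosome receives ``round(density * bp / 1000)``
        SNPs at uniformly drawn, motif-neutral positions.
    gc
        GC fraction of the background sequence.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    n_snp = int(round(snp_density * chrom_bp / 1000.0))
    if snp_density <= 0 or n_snp < 2:
        raise ValueError("snp_density must yield at least 2 SNPs per chromosome")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    chromosomes: list[str] = []
    snp_table: list[tuple[int, int, str, str]] = []
    for c in range(n_chrom):
        seq = rng.choice(base_arr, size=chrom_bp, p=probs).tobytes().decode("ascii")
        chromosomes.append(seq)
        candidates = rng.choice(chrom_bp, size=min(chrom_bp, max(4 * n_snp, n_snp + 64)),
                                replace=False)
        chosen: dict[int, tuple[str, str]] = {}
        for pos in candidates:
            pos = int(pos)
            ref = seq[pos]
            alt = BASES[int(rng.integers(4))]
            while alt == ref:
                alt = BASES[int(rng.integers(4))]
            if _motif_neutral(seq, pos, alt, avoid_motifs):
                chosen[pos] = (ref, alt)
                if len(chosen) == n_snp:
                    break
        if len(chosen) < n_snp:
            raise ValueError(
                f"chromosome {c}: only {len(chosen)} motif-neutral SNP positions "
                f"found for requested {n_snp} (chrom_bp too small for snp_density)"
            )
        for pos in sorted(chosen):
            ref, alt = chosen[pos]
            snp_table.append((c, pos, ref, alt))
    return GenomeFixture(chromosomes, [float(chrom_cM)] * n_chrom, snp_table, seed)


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """Mapping-population design: first backcross or selfed RIL."""

    kind: str  # "BC1" | "RIL_selfed"
    n_offspring: int
    generations: int = 8  # RIL only; F1 is generation 1
    include_parents: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("BC1", "RIL_selfed"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.kind == "RIL_selfed" and self.generations < 2:
            raise ValueError("RIL generations must be >= 2")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")


# A haplotype mosaic: (segment start positions in cM, founder labels 0/1).
Mosaic = tuple[np.ndarray, np.ndarray]


def _pure(label: int) -> Mosaic:
    return (np.array([0.0]), np.array([label], dtype=np.int8))


def _eval_mosaic(hap: Mosaic, cm: np.ndarray) -> np.ndarray:
    starts, labels = hap
    return labels[np.searchsorted(starts, cm, side="right") - 1]


def _gamete(hap_a: Mosaic, hap_b: Mosaic, length_cm: float, rng: np.random.Generator) -> Mosaic:
    """One meiotic product under Haldane: Poisson crossovers, uniform in cM."""
    k = int(rng.poisson(length_cm / 100.0))
    first = int(rng.integers(2))
    if k == 0:
        return (hap_a, hap_b)[first]
    cuts = np.sort(rng.uniform(0.0, length_cm, size=k))
    haps = (hap_a, hap_b)
    edges = np.concatenate(([0.0], cuts, [length_cm]))
    starts: list[float] = []
    labels: list[int] = []
    for i in range(len(edges) - 1):
        a, b = edges[i], edges[i + 1]
        s, l = haps[(first + i) % 2]
        j0 = int(np.searchsorted(s, a, side="right") - 1)
        j1 = int(np.searchsorted(s, b, side="left"))
        for j in range(j0, j1):
            seg_start = max(float(s[j]), a)
            lab = int(l[j])
            if labels and labels[-1] == lab:
                continue
            starts.append(seg_start)
            labels.append(lab)
    starts[0] = 0.0
    return (np.array(starts), np.array(labels, dtype=np.int8))


@dataclass
class IndividualTruth:
    """True haplotype mosaics and per-SNP genotype of one individual.

    ``genotype[i]`` counts founder-2 alleles at ``snp_table[i]``:
    0 = hom founder-1, 1 = het, 2 = hom founder-2.
    """

    name: str
    mosaics: list[tuple[Mosaic, Mosaic]]  # per chromosome
    genotype: np.ndarray

    def hap_labels(self, fixture: GenomeFixture, chrom: int, cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h0, h1 = self.mosaics[chrom]
        return _eval_mosaic(h0, cm), _eval_mosaic(h1, cm)


def _truth_from_mosaics(name: str, mosaics, fixture: GenomeFixture) -> IndividualTruth:
    geno = np.empty(len(fixture.snp_table), dtype=np.int8)
    for c in range(fixture.n_chrom):
        idx = fixture.snp_indices(c)
        if idx.size == 0:
            continue
        cm = fixture.snp_cm(c)
        h0, h1 = mosaics[c]
        geno[idx] = _eval_mosaic(h0, cm).astype(np.int16) + _eval_mosaic(h1, cm)
    return IndividualTruth(name, mosaics, geno)


def founder_individual(fixture: GenomeFixture, which: int, name: str) -> IndividualTruth:
    mosaics = [(_pure(which), _pure(which)) for _ in range(fixture.n_chrom)]
    return _truth_from_mosaics(name, mosaics, fixture)


def simulate_cross(fixture: GenomeFixture, model: PopulationModel, seed: int = 0) -> list[IndividualTruth]:
    """Simulate a mapping population.

    BC1: each offspring is an F1 gamete fertilised by a recurrent-parent
    (founder 2) gamete, so no offspring is ever homozygous founder-1.
    RIL_selfed: ``generations - 1`` rounds of selfing from the F1.
    Parents (pure founders, named P1/P2) are prepended when
    ``model.include_parents`` is set.
    """
    rng = np.random.default_rng(seed)
    lengths = fixture.chrom_cM
    f1 = [(_pure(0), _pure(1)) for _ in range(fixture.n_chrom)]
    out: list[IndividualTruth] = []
    if model.include_parents:
        out.append(founder_individual(fixture, 0, "P1"))
        out.append(founder_individual(fixture, 1, "P2"))
    for i in range(model.n_offspring):
        name = f"S{i + 1:04d}"
        if model.kind == "BC1":
            mosaics = [(_gamete(*f1[c], lengths[c], rng), _pure(1))
                       for c in range(fixture.n_chrom)]
        else:
            pair = f1
            for _ in range(model.generations - 1):
                pair = [
                    (
                        _gamete(*pair[c], lengths[c], rng),
                        _gamete(*pair[c], lengths[c], rng),
                    )
                    for c in range(fixture.n_chrom)
                ]
            mosaics = pair
        out.append(_truth_from_mosaics(name, mosaics, fixture))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadConfig:
    """Sequencing configuration.

    ``mean_depth`` is per fragment per individual.  ``depth_dist`` may be
    "poisson" (default), "nbinom" (with ``nb_dispersion`` as the shape
    parameter; smaller = more overdispersed) or "fixed" (exact coverage, the
    noise-free setting).  ``error_rate`` is the per-base substitution
    probability; the emitted quality string is the constant Phred score
    matching it (capped at Q41, also used when the error rate is zero).
    """

    read_length: int = 76
    paired: bool = False
    mean_depth: float = 20.0
    depth_dist: str = "poisson"
    nb_dispersion: float = 2.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_dist not in ("poisson", "nbinom", "fixed"):
            raise ValueError(f"unknown depth_dist {self.depth_dist!r}")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def qual(self) -> int:
        if self.error_rate <= 0:
            return 41
        return min(41, int(round(-10.0 * math.log10(self.error_rate))))


@dataclass
class SimOutput:
    """Artifacts written by :func:`make_reads`."""

    fastq: list[Path]
    snps_tsv: Path
    genotypes_tsv: Path
    fragments_tsv: Path
    n_reads: int
    fragments: list[Fragment]
    window_snps: list[list[tuple[int, int, bool]]]  # per fragment: (snp idx, read offset, complemented)


def _depth_matrix(cfg: ReadConfig, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    if cfg.depth_dist == "fixed":
        return np.full(shape, int(round(cfg.mean_depth)), dtype=np.int64)
    if cfg.depth_dist == "poisson":
        return rng.poisson(cfg.mean_depth, size=shape)
    k = cfg.nb_dispersion
    p = k / (k + cfg.mean_depth)
    return rng.negative_binomial(k, p, size=shape)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = base_arr[base_arr != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def _fragment_windows(
    fragments: list[Fragment],
    fixture: GenomeFixture,
    window_len: int,
    from_rare: bool,
) -> list[tuple[str, list[tuple[int, int, bool]]]]:
    """Per fragment: the read template (first ``window_len`` bases seen from
    the rare or the frequent end) and the SNPs falling inside it as
    ``(snp index, offset in template, complemented)``."""
    out = []
    for frag in fragments:
        seq = fixture.chromosomes[frag.chrom][frag.start:frag.end]
        forward = frag.rare_left if from_rare else not frag.rare_left
        template = seq if forward else revcomp(seq)
        template = template[:window_len]
        pos = fixture.snp_positions(frag.chrom)
        idx = fixture.snp_indices(frag.chrom)
        inside = (pos >= frag.start) & (pos < frag.end)
        snps: list[tuple[int, int, bool]] = []
        for p, i in zip(pos[inside], idx[inside]):
            off = int(p - frag.start) if forward else int(frag.end - 1 - p)
            if off < len(template):
                snps.append((int(i), off, not forward))
        out.append((template, snps))
    return out


class _VariantCache:
    """Read strings per (template, window-SNP allele tuple)."""

    def __init__(self, template: str, snps: list[tuple[int, int, bool]],
                 fixture: GenomeFixture, prefix: str = ""):
        self.template = template
        self.snps = snps
        self.fixture = fixture
        self.prefix = prefix
        self._cache: dict[tuple, str] = {}

    def read(self, labels: tuple[int, ...]) -> str:
        got = self._cache.get(labels)
        if got is None:
            arr = bytearray(self.template, "ascii")
            for (snp_idx, off, comp), lab in zip(self.snps, labels):
                _, _, a1, a2 = self.fixture.snp_table[snp_idx]
                allele = a2 if lab else a1
                if comp:
                    allele = complement(allele)
                arr[off] = ord(allele)
            got = self.prefix + arr.decode("ascii")
            self._cache[labels] = got
        return got


def make_reads(
    individuals: list[IndividualTruth],
    fixture: GenomeFixture,
    scheme: EnzymeScheme,
    sheet: "SampleSheet",
    cfg: ReadConfig,
    out_dir: str | Path,
) -> SimOutput:
    """Simulate multiplexed FASTQ for a population and write truth tables.

    Read 1 is ``[5-nt tag][rare remnant][fragment bases]`` up to the read
    length; in paired mode read 2 starts from the frequent-cutter end
    (its remnant first, no tag).  Per-read haplotype choice is a fair coin,
    so heterozygous individuals emit both alleles at binomially distributed
    ratios.  Read ids encode full provenance:
    ``sample|c<chrom>:<start>-<end>|h<hap>|<serial>``.
    """
    from .demux import SampleSheet  # local import to avoid a cycle at import time

    assert isinstance(sheet, SampleSheet)
    names = [ind.name for ind in individuals]
    missing = [n for n in names if n not in sheet.tags]
    if missing:
        raise ValueError(f"samples without a tag in the sheet: {missing[:5]}")
    tag_len = sheet.tag_length
    if cfg.read_length <= tag_len + len(scheme.rare.remnant):
        raise ValueError("read_length must exceed tag + remnant length")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    fragments: list[Fragment] = []
    for c, seq in enumerate(fixture.chromosomes):
        fragments.extend(digest_select(seq, scheme, chrom=c))

    win1 = _fragment_windows(fragments, fixture, cfg.read_length - tag_len, from_rare=True)
    win2 = (
        _fragment_windows(fragments, fixture, cfg.read_length, from_rare=False)
        if cfg.paired
        else None
    )

    # Per-individual founder labels of each haplotype at every SNP.
    n_snp = len(fixture.snp_table)
    lab0 = np.zeros((len(individuals), n_snp), dtype=np.int8)
    lab1 = np.zeros_like(lab0)
    for c in range(fixture.n_chrom):
        idx = fixture.snp_indices(c)
        if idx.size == 0:
            continue
        cm = fixture.snp_cm(c)
        for i, ind in enumerate(individuals):
            l0, l1 = ind.hap_labels(fixture, c, cm)
            lab0[i, idx] = l0
            lab1[i, idx] = l1

    depth = _depth_matrix(cfg, (len(fragments), len(individuals)), rng)
    from_h0 = rng.binomial(depth, 0.5)

    qual1 = chr(cfg.qual + 33) * cfg.read_length
    paths = [out_dir / ("reads_R1.fastq" if cfg.paired else "reads.fastq")]
    if cfg.paired:
        paths.append(out_dir / "reads_R2.fastq")
    handles = [open(p, "w") for p in paths]
    serial = 0
    try:
        for fi, frag in enumerate(fragments):
            t1, snps1 = win1[fi]
            caches = [_VariantCache(t1, snps1, fixture)]
            if cfg.paired:
                t2, snps2 = win2[fi]
                caches.append(_VariantCache(t2, snps2, fixture))
            chunks: list[list[str]] = [[] for _ in handles]
            for ii, ind in enumerate(individuals):
                d = int(depth[fi, ii])
                if d == 0:
                    continue
                tag = sheet.tags[ind.name]
                per_hap = (int(from_h0[fi, ii]), d - int(from_h0[fi, ii]))
                labs = (lab0[ii], lab1[ii])
                for hap in (0, 1):
                    n_reads = per_hap[hap]
                    if n_reads == 0:
                        continue
                    reads = []
                    for cache in caches:
                        allele_key = tuple(int(labs[hap][s]) for s, _, _ in cache.snps)
                        reads.append(cache.read(allele_key))
                    r1 = (tag + reads[0])[: cfg.read_length]
                    for _ in range(n_reads):
                        serial += 1
                        rid = f"{ind.name}|c{frag.chrom}:{frag.start}-{frag.end}|h{hap}|{serial}"
                        seq1 = r1 if cfg.error_rate == 0 else _apply_errors(r1, cfg.error_rate, rng)
                        chunks[0] += [f"@{rid}" + ("/1" if cfg.paired else ""),
                                      seq1, "+", qual1[: len(seq1)]]
                        if cfg.paired:
                            r2 = reads[1][: cfg.read_length]
                            seq2 = r2 if cfg.error_rate == 0 else _apply_errors(r2, cfg.error_rate, rng)
                            chunks[1] += [f"@{rid}/2", seq2, "+", qual1[: len(seq2)]]
            for h, chunk in zip(handles, chunks):
                if chunk:
                    h.write("\n".join(chunk) + "\n")
    finally:
        for h in handles:
            h.close()

    snps_tsv = out_dir / "truth_snps.tsv"
    with open(snps_tsv, "w") as f:
        f.write("snp_id\tchrom\tpos\tfounder1\tfounder2\n")
        for i, (c, p, a1, a2) in enumerate(fixture.snp_table):
            f.write(f"snp{i:06d}\t{c}\t{p}\t{a1}\t{a2}\n")

    genotypes_tsv = out_dir / "truth_genotypes.tsv"
    geno = np.stack([ind.genotype for ind in individuals], axis=1)
    with open(genotypes_tsv, "w") as f:
        f.write("snp_id\t" + "\t".join(names) + "\n")
        for i in range(n_snp):
            f.write(f"snp{i:06d}\t" + "\t".join(map(str, geno[i])) + "\n")

    fragments_tsv = out_dir / "fragments.tsv"
    with open(fragments_tsv, "w") as f:
        f.write("chrom\tstart\tend\trare_end\n")
        for frag in fragments:
            f.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t"
                    f"{'left' if frag.rare_left else 'right'}\n")

    return SimOutput(
        fastq=paths,
        snps_tsv=snps_tsv,
        genotypes_tsv=genotypes_tsv,
        fragments_tsv=fragments_tsv,
        n_reads=serial,
        fragments=fragments,
        window_snps=[s for _, s in win1],
    )
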