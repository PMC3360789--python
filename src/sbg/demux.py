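"""Inline-tag demultiplexing and read quality control.

Reads carry a 5-nt sample identification tag at position 0, immediately
followed by the restriction-site remnant of the rare cutter.  Tags are
designed at pairwise Hamming distance >= 2, which rules out unambiguous
single-error correction, so matching is exact: a read whose first bases match
no tag is rejected rather than rescued.  After the tag check, reads pass
through the quality filters in a fixed order (remnant, undetermined
nucleotides, homopolymer run, mean Phred, blocklist k-mers); the first
failing check names the rejection category, and every input read lands in
exactly one category of the report.

The tag is trimmed from accepted reads; the remnant is retained so that
clustered references keep their restriction-site context.
"""

from __future__ import annotations

import itertools
import json
import re
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# ---------------------------------------------------------------------------
# Sample sheet and tag design
# ---------------------------------------------------------------------------


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


class SampleSheet:
    """Ordered mapping sample-id -> inline tag.

    Tags must be unique, of uniform length and at pairwise Hamming
    distance >= 2.
    """

    def __init__(self, tags: "OrderedDict[str, str] | dict[str, str]", min_dist: int = 2):
        self.tags: OrderedDict[str, str] = OrderedDict(tags)
        self.min_dist = min_dist
        values = list(self.tags.values())
        if not values:
            raise ValueError("empty sample sheet")
        if len(set(values)) != len(values):
            raise ValueError("duplicate tags in sample sheet")
        if len({len(t) for t in values}) != 1:
            raise ValueError("tags must have uniform length")
        for a, b in itertools.combinations(values, 2):
            if hamming(a, b) < min_dist:
                raise ValueError(f"tags {a} and {b} closer than Hamming distance {min_dist}")
        self.by_tag = {t: s for s, t in self.tags.items()}

    @property
    def samples(self) -> list[str]:
        return list(self.tags)

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.tags.values())))

    def __len__(self) -> int:
        return len(self.tags)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            f.write("sample_id\ttag\n")
            for s, t in self.tags.items():
                f.write(f"{s}\t{t}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        tags: OrderedDict[str, str] = OrderedDict()
        with open(path) as f:
            header = f.readline()
            for line in f:
                if not line.strip():
                    continue
                sample, tag = line.rstrip("\n").split("\t")[:2]
                tags[sample] = tag
        return cls(tags)


def design_tags(
    n: int,
    length: int = 5,
    min_dist: int = 2,
    seed: int = 0,
    sample_ids: Optional[list[str]] = None,
) -> SampleSheet:
    """Greedy construction of ``n`` tags at pairwise Hamming >= ``min_dist``.

    Candidates are the full ``4^length`` code in lexicographic order, shuffled
    deterministically under ``seed``; candidates are kept greedily while they
    respect the distance to all tags already kept.  When the shuffled pass
    cannot reach ``n``, a second greedy pass over the unshuffled
    lexicographic order is tried (for distance 2 this recovers the full
    parity lexicode of ``4^(length-1)`` words).  Raises with the best
    achievable count when ``n`` tags still cannot be found.
    """
    if n < 1 or length < 1 or min_dist < 1:
        raise ValueError("n, length and min_dist must be positive")
    lexicographic = ["".join(p) for p in itertools.product("ACGT", repeat=length)]
    shuffled = list(lexicographic)
    rng = np.random.default_rng(seed)
    rng.shuffle(shuffled)
    kept: list[str] = []
    for candidates in (shuffled, lexicographic):
        trial: list[str] = []
        for cand in candidates:
            if all(hamming(cand, t) >= min_dist for t in trial):
                trial.append(cand)
                if len(trial) == n:
                    break
        if len(trial) > len(kept):
            kept = trial
        if len(kept) == n:
            break
    if len(kept) < n:
        raise ValueError(
            f"cannot design {n} tags of length {length} at min distance "
            f"{min_dist}; best achievable here is {len(kept)}"
        )
    ids = sample_ids if sample_ids is not None else [f"S{i + 1:04d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("sample_ids length must equal n")
    return SampleSheet(OrderedDict(zip(ids, kept)), min_dist=min_dist)


# ---------------------------------------------------------------------------
# Read records and QC configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``quals`` is the Phred+33 string."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.quals.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def blocklist_kmers(fasta_path: str | Path, k: int = 31) -> set[str]:
    """Exact k-mer set (both strands) from a contaminant FASTA blocklist."""
    from Bio import SeqIO
    from ._seq import revcomp

    kmers: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        s = str(rec.seq).upper()
        for i in range(len(s) - k + 1):
            km = s[i: i + k]
            kmers.add(km)
            kmers.add(revcomp(km))
    return kmers


@dataclass
class QCConfig:
    """Read-quality filters applied after tag assignment.

    The homopolymer / mean-quality / N thresholds are declared defaults of
    this implementation (exposed and logged), not literature reproductions.
    """

    remnants: tuple[str, ...] = ("AATTC",)
    max_homopolymer: int = 10
    max_n: int = 0
    min_mean_q: float = 20.0
    blocklist_k: int = 31
    blocklist: Optional[set[str]] = None

    def __post_init__(self) -> None:
        if self.max_homopolymer < 0 or self.max_n < 0 or self.min_mean_q < 0:
            raise ValueError("QC thresholds must be >= 0")
        run = self.max_homopolymer + 1
        self._homopolymer_re = re.compile(
            "|".join(f"{b}{{{run},}}" for b in "ACGT")
        )


REJECT_REASONS = ("no_tag", "no_remnant", "Ns", "homopolymer", "low_quality", "blocklist_hit")


def _mean_phred(quals: str) -> float:
    return sum(map(ord, quals)) / len(quals) - 33.0


def classify_read(
    read: ReadRecord,
    sheet: SampleSheet,
    qc: QCConfig,
    _mean_cache: Optional[dict] = None,
) -> tuple[str, ReadRecord] | str:
    """Assign one read to a sample or return its rejection reason.

    Checks run in fixed order: exact tag at position 0, expected remnant
    immediately after the tag, N count, homopolymer run, mean Phred,
    blocklist k-mer hit.  On success returns ``(sample, trimmed read)`` with
    the tag (only) removed.
    """
    tl = sheet.tag_length
    sample = sheet.by_tag.get(read.bases[:tl])
    if sample is None:
        return "no_tag"
    rest = read.bases[tl:]
    if not any(rest.startswith(r) for r in qc.remnants):
        return "no_remnant"
    if rest.count("N") > qc.max_n:
        return "Ns"
    if qc._homopolymer_re.search(rest):
        return "homopolymer"
    rq = read.quals[tl:]
    if _mean_cache is not None:
        mq = _mean_cache.get(rq)
        if mq is None:
            mq = _mean_phred(rq)
            if len(_mean_cache) < 100_000:
                _mean_cache[rq] = mq
    else:
        mq = _mean_phred(rq)
    if mq < qc.min_mean_q:
        return "low_quality"
    if qc.blocklist:
        k = qc.blocklist_k
        for i in range(len(rest) - k + 1):
            if rest[i: i + k] in qc.blocklist:
                return "blocklist_hit"
    return sample, ReadRecord(read.id, rest, rq)


@dataclass
class DemuxReport:
    """Accounting of every input read: assigned per sample or rejected."""

    assigned: dict[str, int]
    rejected: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.assigned.values()) + sum(self.rejected.values())

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def fraction_assigned(self) -> float:
        return self.n_assigned / self.total if self.total else 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "total_reads": self.total,
                    "assigned": self.n_assigned,
                    "fraction_assigned": self.fraction_assigned,
                    "per_sample": self.assigned,
                    "rejected": self.rejected,
                },
                f,
                indent=2,
            )


# Per-sample multiset of trimmed reads keyed by (sequence, quality string).
SampleCounters = dict[str, Counter]


def _fastq_records(path: str | Path) -> Iterable[tuple[str, str, str]]:
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            index += 1
            yield rec


def run_demux(
    fastq_in: str | Path,
    sheet: SampleSheet,
    qc: QCConfig,
    out_dir: Optional[str | Path] = None,
    write_fastq: bool = True,
    fastq_in2: Optional[str | Path] = None,
    qc2: Optional[QCConfig] = None,
) -> tuple[DemuxReport, SampleCounters]:
    """Demultiplex a FASTQ file (optionally a read pair) into per-sample sets.

    Returns the accounting report plus, per sample, a Counter over trimmed
    ``(sequence, quality)`` reads (read 1 side).  In paired mode the second
    file shares the fate of read 1 (the tag sits on read 1 only) and is also
    QC-checked with ``qc2``; a second per-sample Counter dict is attached to
    the report as ``report.mate_counters``.
    """
    assigned = Counter()
    rejected = Counter({r: 0 for r in REJECT_REASONS})
    counters: SampleCounters = {s: Counter() for s in sheet.samples}
    mate_counters: Optional[SampleCounters] = None
    writers = {}
    mean_cache: dict[str, float] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    paired = fastq_in2 is not None
    if paired:
        mate_counters = {s: Counter() for s in sheet.samples}
        qc2 = qc2 or qc

    def _emit(sample: str, rec: ReadRecord, mate: Optional[ReadRecord]) -> None:
        counters[sample][(rec.bases, rec.quals)] += 1
        if mate is not None:
            mate_counters[sample][(mate.bases, mate.quals)] += 1
        if out_dir is not None and write_fastq:
            w = writers.get(sample)
            if w is None:
                w = open(out_dir / f"{sample}.fastq", "w")
                writers[sample] = w
            w.write(f"@{rec.id}\n{rec.bases}\n+\n{rec.quals}\n")

    try:
        stream1 = _fastq_records(fastq_in)
        stream2 = _fastq_records(fastq_in2) if paired else None
        for rec1 in stream1:
            rid, seq, qual = rec1
            read = ReadRecord(rid, seq, qual)
            result = classify_read(read, sheet, qc, mean_cache)
            mate_rec = None
            if paired:
                try:
                    rid2, seq2, qual2 = next(stream2)
                except StopIteration:
                    raise ValueError("read-2 FASTQ shorter than read-1 FASTQ")
                mate_rec = ReadRecord(rid2, seq2, qual2)
            if isinstance(result, str):
                rejected[result] += 1
                continue
            sample, trimmed = result
            if paired:
                verdict = _qc_untagged(mate_rec, qc2, mean_cache)
                if verdict is not None:
                    rejected[verdict] += 1
                    continue
            assigned[sample] += 1
            _emit(sample, trimmed, mate_rec)
    finally:
        for w in writers.values():
            w.close()

    report = DemuxReport(
        assigned={s: assigned.get(s, 0) for s in sheet.samples},
        rejected=dict(rejected),
    )
    report.mate_counters = mate_counters  # type: ignore[attr-defined]
    if out_dir is not None:
        report.to_json(out_dir / "demux_report.json")
    return report, counters


def _qc_untagged(read: ReadRecord, qc: QCConfig, mean_cache: dict) -> Optional[str]:
    """QC checks for a read without an inline tag (read 2 of a pair)."""
    if not any(read.bases.startswith(r) for r in qc.remnants):
        return "no_remnant"
    if read.bases.count("N") > qc.max_n:
        return "Ns"
    if qc._homopolymer_re.search(read.bases):
        return "homopolymer"
    mq = mean_cache.get(read.quals)
    if mq is None:
        mq = _mean_phred(read.quals)
        if len(mean_cache) < 100_000:
            mean_cache[read.quals] = mq
    if mq < qc.min_mean_q:
        return "low_quality"
    if qc.blocklist:
        k = qc.blocklist_k
        for i in range(len(read.bases) - k + 1):
            if read.bases[i: i + k] in qc.blocklist:
                return "blocklist_hit"
    return None
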