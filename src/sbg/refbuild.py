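"""Reference construction by 100%-identity clustering of full-length reads.

Clustering at 100% identity is exact deduplication: each unique trimmed
sequence is its own cluster and its own representative.  Only full-length
reads (trimmed length equal to the configured cycle count) participate.
Unique sequences observed fewer than ``lower`` times (default: the number of
samples, an approximation of the population size) or more than ``upper``
times (default 100,000; suspect repeats) are discarded; the survivors become
reference contigs.

Allelic variants of one locus intentionally form separate contigs here;
:mod:`sbg.aligncall` reunites them by best-mismatch assignment and a
contig-merging post-pass.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

UPPER_DEFAULT = 100_000


@dataclass
class UniqueReadCounts:
    """Exact multiset of full-length trimmed read sequences."""

    counts: dict[str, int]
    total_reads: int
    full_length_reads: int

    @property
    def not_full_length(self) -> int:
        return self.total_reads - self.full_length_reads

    @property
    def n_unique(self) -> int:
        return len(self.counts)


def _iter_seq_counts(reads) -> Iterable[tuple[str, int]]:
    """Accept a Counter keyed by seq or (seq, qual), or an iterable of seqs."""
    if isinstance(reads, Mapping):
        for key, n in reads.items():
            seq = key[0] if isinstance(key, tuple) else key
            yield seq, int(n)
    else:
        for seq in reads:
            yield seq, 1


def count_unique(reads_per_sample: Mapping[str, object], expected_length: int) -> UniqueReadCounts:
    """Aggregate exact sequence counts over all samples.

    Reads whose length differs from ``expected_length`` are excluded from the
    counts and tallied separately (the full-length rule).
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    counts: Counter = Counter()
    total = 0
    full = 0
    for reads in reads_per_sample.values():
        for seq, n in _iter_seq_counts(reads):
            total += n
            if len(seq) == expected_length:
                full += n
                counts[seq] += n
    return UniqueReadCounts(dict(counts), total, full)


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    count: int


@dataclass
class ReferenceSet:
    """Abundance-filtered unique reads promoted to reference contigs."""

    contigs: list[Contig]
    lower: int
    upper: int
    source: Optional[UniqueReadCounts] = None

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    def sequence(self, contig_id: str) -> str:
        return self._by_id()[contig_id].sequence

    def _by_id(self) -> dict[str, Contig]:
        if not hasattr(self, "_index"):
            self._index = {c.id: c for c in self.contigs}
        return self._index

    def __len__(self) -> int:
        return len(self.contigs)

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(c.sequence), id=c.id, description=f"count={c.count}")
            for c in self.contigs
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, lower: int = 0, upper: int = UPPER_DEFAULT) -> "ReferenceSet":
        from Bio import SeqIO

        contigs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            count = 0
            for tok in rec.description.split():
                if tok.startswith("count="):
                    count = int(tok[6:])
            contigs.append(Contig(rec.id, str(rec.seq), count))
        return cls(contigs, lower, upper)

    def summary(self) -> dict:
        out = {
            "n_clusters": len(self.contigs),
            "reads_used_in_clustering": sum(c.count for c in self.contigs),
            "lower_threshold": self.lower,
            "upper_threshold": self.upper,
        }
        if self.source is not None:
            src = self.source
            out.update(
                filtered_reads=src.total_reads,
                full_length_reads=src.full_length_reads,
                pct_full_length=round(100.0 * src.full_length_reads / src.total_reads, 1)
                if src.total_reads
                else 0.0,
                unique_reads=src.n_unique,
            )
        return out

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=2)


def build_reference(counts: UniqueReadCounts, lower: int, upper: int = UPPER_DEFAULT) -> ReferenceSet:
    """Keep unique sequences with ``lower <= count <= upper`` as contigs.

    Contig ids ``SBG_000001...`` are assigned by descending count, ties
    broken lexicographically by sequence, so ids are stable under re-runs.
    """
    if lower > upper:
        raise ValueError("lower threshold exceeds upper threshold")
    kept = [(seq, n) for seq, n in counts.counts.items() if lower <= n <= upper]
    kept.sort(key=lambda item: (-item[1], item[0]))
    contigs = [
        Contig(f"SBG_{i + 1:06d}", seq, n) for i, (seq, n) in enumerate(kept)
    ]
    return ReferenceSet(contigs, lower, upper, source=counts)


def write_counts_tsv(counts: UniqueReadCounts, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("sequence\tcount\n")
        for seq, n in sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            f.write(f"{seq}\t{n}\n")
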