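"""Parent-based co-dominant A/B/H genotype scoring.

SNPs are restricted to sites where both parental samples are present
(non-missing) and fixed for alternate alleles; offspring genotypes are then
translated relative to the parents: homozygous for the parent-1 allele -> A,
homozygous for the parent-2 allele -> B, heterozygous -> H.  The A label is
anchored to the parent given first (in a BC1 with parent 2 recurrent, A is
the pedigree-impossible class and its frequency estimates the genotyping
error rate).

Class frequencies in the summaries are computed over non-missing offspring
calls; the parents themselves are carried in the matrix (coded A and B at
every SNP) but excluded from the frequencies, which would otherwise have a
floor of one A and one B per SNP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligncall import HET, HOM_ALT, HOM_REF, SiteCall

MISSING = "-"
CODES = ("A", "B", "H")


@dataclass
class ABHMatrix:
    """SNP x sample matrix of co-dominant codes in {A, B, H, '-'}.

    ``parents`` holds (A-parent, B-parent) sample ids; either may be None in
    germplasm mode.  ``poptype`` is "bc1" or "ril".
    """

    df: pd.DataFrame  # values "A" | "B" | "H" | "-"
    parents: tuple[Optional[str], Optional[str]]
    poptype: str

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def offspring(self) -> list[str]:
        return [s for s in self.df.columns if s not in set(filter(None, self.parents))]

    def offspring_frame(self) -> pd.DataFrame:
        return self.df[self.offspring]

    def class_counts(self) -> dict[str, int]:
        vals = self.offspring_frame().to_numpy()
        return {c: int((vals == c).sum()) for c in CODES} | {
            "missing": int((vals == MISSING).sum())
        }

    def summary(self) -> dict:
        """SNP count, genotypes/SNP and class frequencies over non-missing
        offspring calls (the columns of the per-dataset genotyping tables)."""
        counts = self.class_counts()
        called = sum(counts[c] for c in CODES)
        n_snp = len(self.df)
        out = {
            "n_snps": n_snp,
            "n_genotypes": called,
            "genotypes_per_snp": round(called / n_snp, 1) if n_snp else 0.0,
        }
        for c in CODES:
            out[f"count_{c}"] = counts[c]
            out[f"freq_{c}"] = round(counts[c] / called, 4) if called else 0.0
        out["count_missing"] = counts["missing"]
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            f.write(f"#poptype={self.poptype}\n")
            f.write(f"#parent_a={self.parents[0] or ''}\n")
            f.write(f"#parent_b={self.parents[1] or ''}\n")
            self.df.to_csv(f, sep="\t", index_label="snp_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ABHMatrix":
        meta = {}
        with open(path) as f:
            pos = 0
            while True:
                line = f.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].rstrip("\n").partition("=")
                    meta[key] = val
                    pos = f.tell()
                else:
                    f.seek(pos)
                    break
            df = pd.read_csv(f, sep="\t", index_col="snp_id", dtype=str)
        df = df.fillna(MISSING)
        parents = (meta.get("parent_a") or None, meta.get("parent_b") or None)
        return cls(df, parents, meta.get("poptype", "bc1"))

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=2)


def informative_sites(
    sites: Sequence[SiteCall], parent1: str, parent2: str
) -> list[SiteCall]:
    """Keep sites where both parents are called, homozygous and different."""
    out = []
    for s in sites:
        if parent1 not in s.calls or parent2 not in s.calls:
            raise ValueError(f"parent sample missing from site {s.contig}:{s.pos}")
        g1 = s.calls[parent1].genotype
        g2 = s.calls[parent2].genotype
        if g1 in (HOM_REF, HOM_ALT) and g2 in (HOM_REF, HOM_ALT) and g1 != g2:
            out.append(s)
    return out


def snp_id(site: SiteCall) -> str:
    return f"{site.contig}:{site.pos + 1}"


def to_abh(
    sites: Sequence[SiteCall],
    parent1: str,
    parent2: str,
    samples: Optional[Sequence[str]] = None,
    poptype: str = "bc1",
) -> ABHMatrix:
    """Translate informative sites into A/B/H codes relative to the parents.

    Offspring homozygous for an allele carried by neither parent would be
    coded missing; with a biallelic caller and fixed alternate parents this
    cannot arise, but the guard is kept for externally loaded calls.
    """
    if samples is None:
        samples = sorted({s for site in sites for s in site.calls})
        samples = [parent1, parent2] + [s for s in samples if s not in (parent1, parent2)]
    rows = []
    ids = []
    n_out_of_pedigree = 0
    for site in sites:
        g1 = site.calls[parent1].genotype
        a_geno = g1  # parent-1's homozygous genotype code (HOM_REF or HOM_ALT)
        b_geno = HOM_ALT if a_geno == HOM_REF else HOM_REF
        row = []
        for sample in samples:
            g = site.genotype(sample)
            if g is None:
                row.append(MISSING)
            elif g == HET:
                row.append("H")
            elif g == a_geno:
                row.append("A")
            elif g == b_geno:
                row.append("B")
            else:  # out-of-pedigree allele
                n_out_of_pedigree += 1
                row.append(MISSING)
        rows.append(row)
        ids.append(snp_id(site))
    df = pd.DataFrame(rows, index=ids, columns=list(samples), dtype=str)
    matrix = ABHMatrix(df, (parent1, parent2), poptype)
    matrix.n_out_of_pedigree = n_out_of_pedigree  # type: ignore[attr-defined]
    return matrix


def export_raw_biallelic(sites: Sequence[SiteCall], samples: Sequence[str]) -> pd.DataFrame:
    """Germplasm mode: raw biallelic genotypes, no parental labelling.

    Values are VCF-style "0/0", "0/1", "1/1" or "./." relative to the
    major/minor alleles of each site.
    """
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", None: "./."}
    rows = [[gt_str[site.genotype(s)] for s in samples] for site in sites]
    return pd.DataFrame(rows, index=[snp_id(s) for s in sites], columns=list(samples))


def abh_from_truth(
    genotypes: np.ndarray,
    sample_names: Sequence[str],
    snp_ids: Optional[Sequence[str]] = None,
    poptype: str = "bc1",
    parents: tuple[Optional[str], Optional[str]] = (None, None),
) -> ABHMatrix:
    """Build an ABH matrix directly from simulator truth genotypes.

    ``genotypes`` is SNP x sample with 0 = hom founder-1 (A), 1 = het (H),
    2 = hom founder-2 (B); -1 marks missing.
    """
    lut = np.array(["A", "H", "B"], dtype="<U1")
    vals = np.where(genotypes >= 0, lut[np.clip(genotypes, 0, 2)], MISSING)
    ids = snp_ids if snp_ids is not None else [f"snp{i:06d}" for i in range(genotypes.shape[0])]
    df = pd.DataFrame(vals, index=list(ids), columns=list(sample_names), dtype=str)
    return ABHMatrix(df, parents, poptype)
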