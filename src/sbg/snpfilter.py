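"""False-positive SNP removal by missingness and genotypic-frequency rules.

A SNP is removed when more than ``max_missing`` of its offspring genotypes
are missing, or when any genotypic-class frequency (computed over
non-missing offspring calls) falls outside its preset band.  The BC1 preset
bounds the segregating classes B and H to [25%, 75%] and caps the
pedigree-impossible A class at 3% -- since A acts as an error-rate proxy,
every retained BC1 SNP is guaranteed an accuracy of at least 97% under that
proxy.  The RIL preset bounds the homozygote classes A and B to [25%, 75%]
and caps residual heterozygosity H at 15%.

"More than" thresholds are strict (a SNP at exactly 60% missing or exactly
3% A is retained); band bounds are inclusive at 0.25 and 0.75.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parentgeno import ABHMatrix, CODES, MISSING


@dataclass(frozen=True)
class FilterPreset:
    """Per-class frequency bands (inclusive) and a missingness ceiling."""

    name: str
    max_missing: float = 0.60
    freq_bounds: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        for cls, lo, hi in self.freq_bounds:
            if cls not in CODES or not (0 <= lo <= hi <= 1):
                raise ValueError(f"invalid bound for class {cls}: [{lo}, {hi}]")

    def with_overrides(self, max_missing=None, **class_bounds) -> "FilterPreset":
        bounds = {cls: (lo, hi) for cls, lo, hi in self.freq_bounds}
        for cls, bound in class_bounds.items():
            bounds[cls] = bound
        return FilterPreset(
            self.name,
            self.max_missing if max_missing is None else max_missing,
            tuple((c, lo, hi) for c, (lo, hi) in bounds.items()),
        )


BC1_PRESET = FilterPreset(
    "bc1",
    max_missing=0.60,
    freq_bounds=(("B", 0.25, 0.75), ("H", 0.25, 0.75), ("A", 0.0, 0.03)),
)

RIL_PRESET = FilterPreset(
    "ril",
    max_missing=0.60,
    freq_bounds=(("A", 0.25, 0.75), ("B", 0.25, 0.75), ("H", 0.0, 0.15)),
)

PRESETS = {"bc1": BC1_PRESET, "ril": RIL_PRESET}


def filter_matrix(
    abh: ABHMatrix, preset: FilterPreset
) -> tuple[ABHMatrix, pd.DataFrame, dict]:
    """Apply a preset; returns (retained matrix, per-SNP verdicts, summary).

    Verdicts record every violated rule jointly (the removal outcome is the
    same whether the rules are applied sequentially or at once).  Genotype
    values are never altered; only SNP rows are dropped.
    """
    off = abh.offspring_frame()
    vals = off.to_numpy()
    n = vals.shape[1]
    verdict_rows = []
    keep = []
    if n == 0:
        empty = ABHMatrix(abh.df.iloc[0:0], abh.parents, abh.poptype)
        return empty, pd.DataFrame(columns=["snp_id", "retained", "violations"]), {
            "warning": "empty matrix"
        }
    counts = {c: (vals == c).sum(axis=1) for c in CODES}
    missing = (vals == MISSING).sum(axis=1)
    called = n - missing
    for i, snp in enumerate(abh.snp_ids):
        violations = []
        if missing[i] / n > preset.max_missing:
            violations.append(f"missing>{preset.max_missing:g}")
        denom = called[i]
        for cls, lo, hi in preset.freq_bounds:
            freq = counts[cls][i] / denom if denom else 0.0
            if denom and not (lo <= freq <= hi):
                violations.append(f"freq_{cls}={freq:.3f}!in[{lo:g},{hi:g}]")
        retained = not violations
        keep.append(retained)
        verdict_rows.append((snp, retained, ";".join(violations)))
    verdicts = pd.DataFrame(verdict_rows, columns=["snp_id", "retained", "violations"])
    retained_df = abh.df.loc[np.array(keep, dtype=bool)]
    out = ABHMatrix(retained_df, abh.parents, abh.poptype)
    summary = {
        "preset": preset.name,
        "n_input_snps": len(abh.df),
        "n_retained_snps": len(retained_df),
        "n_removed_snps": int(len(abh.df) - len(retained_df)),
        "before": abh.summary(),
        "after": out.summary(),
    }
    return out, verdicts, summary


def write_verdicts(verdicts: pd.DataFrame, path: str | Path) -> None:
    verdicts.to_csv(path, sep="\t", index=False)
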