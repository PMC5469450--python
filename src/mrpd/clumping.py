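"""Greedy p-value-ranked LD clumping of GWAS summary statistics.

Candidates below the significance threshold are ranked from smallest to
largest p-value.  Walking down the ranking, a variant becomes an index SNP
unless it lies within the physical window of an already-selected index on the
same chromosome AND is in linkage disequilibrium with it at or above the r^2
threshold; such variants are assigned to that index's clump.  Variants merely
near an index but in linkage equilibrium remain candidates, and listed r^2
between chromosomes is ignored.

LD is consumed, never computed from a reference panel: supply pairwise r^2
as an :class:`LDInfo` table (absent pairs count as r^2 = 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .summary_io import VariantAssociation

__all__ = ["LDInfo", "ClumpConfig", "clump", "genotype_r_squared"]


class LDInfo:
    """Symmetric pairwise r^2 lookup with absent-pair default of 0."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[frozenset, float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r^2 must be in [0, 1]: ({a}, {b}) = {r2}")
        if a == b and r2 != 1.0:
            raise ValueError(f"self-pair ({a}, {a}) must have r^2 = 1")
        self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDInfo":
        """Read a 3-column (id_a, id_b, r2) tab-delimited file; header optional."""
        info = cls()
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                try:
                    r2 = float(row[2])
                except ValueError:
                    continue  # header line
                info.add(row[0], row[1], r2)
        return info


@dataclass(frozen=True)
class ClumpConfig:
    """Clumping thresholds: genome-wide significance, LD, physical window."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (self.p_threshold > 0 and self.r2_threshold > 0 and self.window_kb > 0):
            raise ValueError("all clumping thresholds must be strictly positive")
        if self.r2_threshold > 1:
            raise ValueError("r2_threshold must be <= 1")


def clump(
    variants: Iterable[VariantAssociation],
    ld: LDInfo,
    config: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Select independent index SNPs by greedy ascending-p clumping.

    Returns the variant_ids of the index SNPs, in selection (ascending-p)
    order.  Ties in p-value are broken by variant_id so the output does not
    depend on input row order.
    """
    candidates = [v for v in variants if v.p_value < config.p_threshold]
    for v in candidates:
        if v.position is None or v.chromosome is None:
            raise ValueError(
                f"{v.variant_id}: chromosome/position required for clumping"
            )
    candidates.sort(key=lambda v: (v.p_value, v.variant_id))

    window_bp = config.window_kb * 1000.0
    index: list[VariantAssociation] = []
    for cand in candidates:
        absorbed = False
        for idx in index:
            if idx.chromosome != cand.chromosome:
                continue
            if abs(idx.position - cand.position) >= window_bp:
                continue
            if ld.r2(idx.variant_id, cand.variant_id) >= config.r2_threshold:
                absorbed = True
                break
        if not absorbed:
            index.append(cand)
    return [v.variant_id for v in index]


def genotype_r_squared(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise r^2 as squared Pearson correlation of allele dosages.

    Test helper for building :class:`LDInfo` tables from a small (n x k)
    dosage matrix; not a substitute for reference-panel LD.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be an (n, k) matrix")
    sd = g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic column(s): r^2 undefined")
    return np.corrcoef(g, rowvar=False) ** 2
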