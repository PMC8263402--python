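"""Concordance metrics, MAF categories and the SNP-selection rules.

Cohen's kappa is computed on the 3x3 confusion table of true genotype
versus hard-called imputed genotype, with missing hard calls excluded
pairwise before tabulation (kappa needs categories; hard calls are the
representation the downstream interaction analysis actually uses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .impute import MISSING

__all__ = [
    "ConfusionTable",
    "SnpSummaryRow",
    "confusion_table",
    "cohens_kappa",
    "maf_category",
    "maf_concordance",
    "select_independent_snps",
    "match_null_snp",
]

MAF_CATEGORIES = ("low", "medium_low", "medium_high", "high")


@dataclass
class ConfusionTable:
    """3x3 genotype confusion counts: rows = true {0,1,2}, cols = imputed."""

    counts: np.ndarray
    n_missing_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be a 3x3 matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("confusion table must contain at least one pair")
        if self.n_missing_excluded < 0:
            raise ValueError("n_missing_excluded must be nonnegative")


def confusion_table(
    true_genotypes: Sequence[int] | np.ndarray, hard_calls: Sequence[int] | np.ndarray
) -> ConfusionTable:
    """Tabulate true vs imputed genotypes, excluding missing calls pairwise."""
    t = np.asarray(true_genotypes)
    h = np.asarray(hard_calls)
    if t.shape != h.shape:
        raise ValueError("vectors must have equal length")
    keep = h != MISSING
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (t[keep], h[keep]), 1)
    return ConfusionTable(counts=counts, n_missing_excluded=int((~keep).sum()))


def cohens_kappa(table: ConfusionTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the diagonal share and p_e the product-of-margins share.  When
    both margins are degenerate on a single category (p_e = 1) kappa is
    undefined; it is returned as 0.0 with a RuntimeWarning flag.
    """
    counts = table.counts.astype(float)
    total = counts.sum()
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-12:
        warnings.warn(
            "kappa undefined: both margins degenerate on one category; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def maf_category(maf: float) -> str:
    """MAF stratum: low < 0.05 <= medium_low < 0.15 <= medium_high < 0.25 <= high."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5] (minor-allele convention)")
    if maf < 0.05:
        return "low"
    if maf < 0.15:
        return "medium_low"
    if maf < 0.25:
        return "medium_high"
    return "high"


def maf_concordance(
    true_genotypes: Sequence[int] | np.ndarray,
    dosages: Sequence[float] | np.ndarray,
    panel_maf: float,
) -> Dict[str, float]:
    """Compare MAF estimates between truth, imputation and the panel."""
    t = np.asarray(true_genotypes, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if t.size == 0 or d.size == 0:
        raise ValueError("inputs must be non-empty")
    true_maf = float(t.mean() / 2.0)
    imputed_maf = float(d.mean() / 2.0)
    return {
        "true_maf": true_maf,
        "imputed_maf": imputed_maf,
        "panel_maf": float(panel_maf),
        "abs_true_minus_imputed": abs(true_maf - imputed_maf),
        "abs_imputed_minus_panel": abs(imputed_maf - panel_maf),
    }


@dataclass(frozen=True)
class SnpSummaryRow:
    """Summary of one candidate SNP for the selection rules."""

    snp_id: str
    chromosome: str
    position: int
    main_effect_or: float
    case_maf: float
    assoc_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.case_maf <= 0.5:
            raise ValueError("case_maf must lie in [0, 0.5]")
        if not 0.0 < self.assoc_p <= 1.0:
            raise ValueError("assoc_p must lie in (0, 1]")


def _redundant(a: SnpSummaryRow, b: SnpSummaryRow) -> bool:
    return (
        a.chromosome == b.chromosome
        and abs(a.main_effect_or - b.main_effect_or) <= 0.02
        and abs(a.case_maf - b.case_maf) <= 0.02
        and abs(a.position - b.position) <= 15_000
    )


def select_independent_snps(rows: Sequence[SnpSummaryRow]) -> List[SnpSummaryRow]:
    """Greedy pairwise pruning of candidate SNPs.

    A pair is redundant when, on the same chromosome, the main-effect OR
    difference is <= 0.02, the case-MAF difference is <= 0.02 and the
    physical distance is <= 15 kb.  SNPs are visited in ascending
    association-p order (most significant kept first); the returned list
    preserves the input order and contains no redundant pair.
    """
    ordered = sorted(rows, key=lambda r: (r.assoc_p, r.snp_id))
    kept: List[SnpSummaryRow] = []
    for row in ordered:
        if not any(_redundant(row, other) for other in kept):
            kept.append(row)
    kept_ids = {r.snp_id for r in kept}
    return [r for r in rows if r.snp_id in kept_ids]


def match_null_snp(
    candidates: Sequence[SnpSummaryRow],
    main_effect_row: SnpSummaryRow,
    rng: np.random.Generator,
) -> SnpSummaryRow:
    """Draw a matched null SNP for a main-effect SNP.

    Eligible candidates lie on the same chromosome and differ in case MAF
    by at most 0.01; one is chosen uniformly at random (seeded).  Raises
    when no candidate qualifies.
    """
    if not candidates:
        raise ValueError("candidate pool is empty")
    eligible = [
        c
        for c in candidates
        if c.snp_id != main_effect_row.snp_id
        and c.chromosome == main_effect_row.chromosome
        and abs(c.case_maf - main_effect_row.case_maf) <= 0.01
    ]
    if not eligible:
        raise ValueError(
            f"no candidate matches {main_effect_row.snp_id} "
            "(same chromosome, case-MAF difference <= 0.01)"
        )
    return eligible[int(rng.integers(0, len(eligible)))]
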