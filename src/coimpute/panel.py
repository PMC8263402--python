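"""Synthetic phased haplotype panels, case ascertainment and exposure states.

This is the study-data generator: it replaces the real reference panel and
patient genotypes with a single-block synthetic neighbourhood in which the
linkage disequilibrium (r²) between each tag SNP and the target SNP is
controlled exactly.  Construction: a tag haplotype copies the target's
allele with probability c = sqrt(r²) and otherwise draws an independent
allele at the target's minor-allele frequency; the squared allele
correlation then converges to r² as the panel grows.  Tags therefore share
the target's MAF whenever r² > 0 — heterogeneous MAFs cap the attainable r²
and are rejected rather than silently clipped.

Cases are ascertained from the same panel by rejection sampling under the
logistic disease model, which is what makes case haplotype frequencies at
main-effect loci deviate systematically from the panel — the mechanism whose
effect on imputation the pipeline studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import DiseaseModel
from .power import ExposureProfile

__all__ = [
    "PanelSpec",
    "HaplotypePanel",
    "CaseSample",
    "generate_reference_panel",
    "sample_diplotype",
    "ascertain_cases",
    "assign_exposure",
]

#: hard cap on rejection-sampling draws, as a multiple of the expected number
_MAX_DRAW_FACTOR = 50.0


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic reference panel.

    ``tag_snps`` is a sequence of ``(desired_r2, maf, position)`` triples;
    the target SNP sits at ``target_position`` with frequency ``target_maf``.
    """

    n_haplotypes: int
    target_maf: float
    tag_snps: Tuple[Tuple[float, float, int], ...]
    seed: int
    target_position: int = 500_000

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "tag_snps", tuple((float(r), float(m), int(p)) for r, m, p in self.tag_snps)
        )
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if not 0.0 < self.target_maf <= 0.5:
            raise ValueError("target_maf must lie in (0, 0.5]")
        if self.target_position < 1:
            raise ValueError("positions are 1-based")
        positions = [p for _, _, p in self.tag_snps] + [self.target_position]
        if len(set(positions)) != len(positions):
            raise ValueError("tag/target positions must be unique")
        for r2, maf, pos in self.tag_snps:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"desired r2 must lie in [0, 1], got {r2}")
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"tag maf must lie in (0, 0.5], got {maf}")
            if pos < 1:
                raise ValueError("positions are 1-based")


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (1 = minor allele at generation time).

    ``alleles`` is a (haplotypes x sites) {0,1} matrix; ``positions`` are
    1-based basepair coordinates, strictly increasing; ``target_index``
    points at the target SNP among the sites.
    """

    alleles: np.ndarray
    positions: np.ndarray
    site_ids: Tuple[str, ...]
    target_index: int

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_ids = tuple(str(s) for s in self.site_ids)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x sites matrix")
        if self.alleles.shape[0] < 2:
            raise ValueError("a panel needs at least 2 haplotypes")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        n_sites = self.alleles.shape[1]
        if self.positions.shape != (n_sites,) or len(self.site_ids) != n_sites:
            raise ValueError("positions/site_ids must match the number of sites")
        if n_sites == 0:
            raise ValueError("a panel needs at least one site")
        if len(set(self.site_ids)) != n_sites:
            raise ValueError("site_ids must be unique")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not 0 <= self.target_index < n_sites:
            raise ValueError("target_index out of range")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def target_position(self) -> int:
        return int(self.positions[self.target_index])

    def allele_frequencies(self) -> np.ndarray:
        """Per-site frequency of the minor (coded 1) allele in the panel."""
        return self.alleles.mean(axis=0)

    def target_frequency(self) -> float:
        """Realized frequency of the target's minor allele in the panel."""
        return float(self.alleles[:, self.target_index].mean())


@dataclass
class CaseSample:
    """Ascertained cases: phased diplotypes over all panel sites.

    ``diplotypes`` has shape (n_cases, 2, n_sites); ``true_target_genotype``
    is the minor-allele count {0,1,2} at the target; ``exposure`` is the
    binary exposure state (may be reassigned by the tier-2 simulation).
    """

    diplotypes: np.ndarray
    true_target_genotype: np.ndarray
    exposure: Optional[np.ndarray] = None
    target_index: int = 0

    def __post_init__(self) -> None:
        self.diplotypes = np.asarray(self.diplotypes, dtype=np.uint8)
        self.true_target_genotype = np.asarray(self.true_target_genotype, dtype=np.int8)
        if self.diplotypes.ndim != 3 or self.diplotypes.shape[1] != 2:
            raise ValueError("diplotypes must have shape (n_cases, 2, n_sites)")
        if self.diplotypes.shape[0] < 1:
            raise ValueError("n_cases must be > 0")
        expected = self.diplotypes[:, :, self.target_index].sum(axis=1)
        if not np.array_equal(expected.astype(np.int8), self.true_target_genotype):
            raise ValueError("true_target_genotype inconsistent with diplotypes")
        if self.exposure is not None:
            self.exposure = np.asarray(self.exposure, dtype=np.int8)
            if self.exposure.shape != (self.n_cases,):
                raise ValueError("exposure length must equal n_cases")

    @property
    def n_cases(self) -> int:
        return self.diplotypes.shape[0]


def generate_reference_panel(spec: PanelSpec) -> HaplotypePanel:
    """Generate a panel whose tag-to-target r² converges to the spec values.

    A tag with ``desired_r2 > 0`` must share the target's MAF; otherwise the
    copying construction cannot attain the requested correlation and the
    spec is rejected.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_haplotypes
    target = (rng.random(n) < spec.target_maf).astype(np.uint8)

    columns = []
    for r2, maf, _pos in spec.tag_snps:
        if r2 > 0.0 and not math.isclose(maf, spec.target_maf, rel_tol=0.0, abs_tol=1e-12):
            raise ValueError(
                f"tag MAF {maf} != target MAF {spec.target_maf} with desired r2 "
                f"{r2} > 0: unattainable by the copying construction"
            )
        copy_mask = rng.random(n) < math.sqrt(r2)
        independent = (rng.random(n) < maf).astype(np.uint8)
        columns.append(np.where(copy_mask, target, independent).astype(np.uint8))

    positions = np.array([p for _, _, p in spec.tag_snps] + [spec.target_position])
    ids = [f"tag{i:03d}" for i in range(len(spec.tag_snps))] + ["target"]
    matrix = np.column_stack(columns + [target]) if columns else target[:, None]
    order = np.argsort(positions)
    target_index = int(np.nonzero(order == len(positions) - 1)[0][0])
    return HaplotypePanel(
        alleles=matrix[:, order],
        positions=positions[order],
        site_ids=tuple(ids[i] for i in order),
        target_index=target_index,
    )


def sample_diplotype(panel: HaplotypePanel, rng: np.random.Generator) -> np.ndarray:
    """Draw one diplotype: two haplotype rows, uniformly with replacement."""
    idx = rng.integers(0, panel.n_haplotypes, size=2)
    return panel.alleles[idx].copy()


def ascertain_cases(
    panel: HaplotypePanel,
    model: DiseaseModel,
    n_cases: int,
    rng: np.random.Generator,
    flip_prob: float = 0.0,
) -> CaseSample:
    """Rejection-sample cases from the panel under the disease model.

    Repeatedly draw a diplotype (two uniform panel rows), the dominant
    carrier indicator G at the target, and E ~ Bernoulli(p_exposure), then
    accept with probability P(D=1|G,E).  The carrier frequency among the
    accepted cases converges to ``carrier_freq_in_cases(model)``.

    ``flip_prob`` optionally flips each allele of the accepted diplotypes
    independently, to model divergence between the study sample and the
    panel; genotypes are recomputed after flipping, and ascertainment uses
    the pre-flip target genotype.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be > 0")
    pen = model.penetrance_table()
    if not np.isfinite(pen).all() or pen.max() <= 0.0:
        raise RuntimeError("acceptance probability is numerically zero in all cells; "
                           "increase baseline_odds or the odds ratios")
    carrier_freq = 1.0 - (1.0 - panel.target_frequency()) ** 2
    p_accept = float(
        np.array([1.0 - carrier_freq, carrier_freq])
        @ pen
        @ np.array([1.0 - model.p_exposure, model.p_exposure])
    )
    p_accept = max(p_accept, 1e-12)

    target_col = panel.alleles[:, panel.target_index]
    kept_idx: list[np.ndarray] = []
    kept_e: list[np.ndarray] = []
    accepted = 0
    drawn = 0
    max_draws = _MAX_DRAW_FACTOR * n_cases / p_accept + 1e6
    while accepted < n_cases:
        batch = int(min(2_000_000, max(20_000, 1.5 * (n_cases - accepted) / p_accept)))
        idx = rng.integers(0, panel.n_haplotypes, size=(batch, 2))
        g = (target_col[idx[:, 0]] + target_col[idx[:, 1]] > 0).astype(np.intp)
        e = (rng.random(batch) < model.p_exposure).astype(np.intp)
        accept = rng.random(batch) < pen[g, e]
        kept_idx.append(idx[accept])
        kept_e.append(e[accept])
        accepted += int(accept.sum())
        drawn += batch
        if accepted == 0 and drawn > max_draws:
            raise RuntimeError(
                f"rejection sampling accepted 0 of {drawn} draws "
                f"(estimated acceptance {p_accept:.2e}); model is degenerate"
            )

    idx = np.concatenate(kept_idx)[:n_cases]
    exposure = np.concatenate(kept_e)[:n_cases].astype(np.int8)
    diplotypes = panel.alleles[idx]  # (n_cases, 2, n_sites), fancy indexing copies
    if flip_prob > 0.0:
        flips = rng.random(diplotypes.shape) < flip_prob
        diplotypes = np.where(flips, 1 - diplotypes, diplotypes).astype(np.uint8)
    genotypes = diplotypes[:, :, panel.target_index].sum(axis=1).astype(np.int8)
    return CaseSample(
        diplotypes=diplotypes,
        true_target_genotype=genotypes,
        exposure=exposure,
        target_index=panel.target_index,
    )


def assign_exposure(
    case_genotypes: Sequence[int] | np.ndarray,
    profile: ExposureProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw binary exposures from genotype-specific case probabilities.

    Carriers (genotype >= 1) are exposed with ``p_exposed_carrier_case``,
    non-carriers with ``p_exposed_noncarrier_case``.  Probabilities of
    exactly 0 or 1 are accepted and yield constant columns.
    """
    g = np.asarray(case_genotypes)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("case_genotypes must be true genotypes in {0, 1, 2}")
    p = np.where(g >= 1, profile.p_exposed_carrier_case, profile.p_exposed_noncarrier_case)
    return (rng.random(g.shape) < p).astype(np.int8)
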