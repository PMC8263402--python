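"""Tier 1: mask the target SNP, LD-thin the base, and impute by haplotype copying.

The imputation engine is a deliberately small haploid Li–Stephens model: each
case haplotype is modelled as an imperfect mosaic of the reference panel
haplotypes, with a constant per-site probability of switching the copied
haplotype and an allele-miscopy probability ε at typed sites.  A
forward–backward pass over the retained (typed) sites yields the copying
posterior at the masked target position — forward messages carried in from
the nearest retained site on the left, backward messages from the right,
one transition step each — and the probability that the haplotype carries
the minor allele is the posterior-weighted frequency of the minor allele
among the reference haplotypes.  The two haploid posteriors of a case are
convolved into a diploid posterior over {0, 1, 2} copies.

This is a stand-in for production imputation software (minimac4 behind the
Michigan Imputation Server), not a reimplementation: no recombination map,
no per-site error estimation, no state-space compression.

The LD-thinning schedule reproduces the ten pruning rounds of the study
design: round 1 leaves the base untouched (only the target is masked), and
round n (n = 2..10) retains only sites with r² < (11 - n)/10 to the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .panel import CaseSample, HaplotypePanel

__all__ = [
    "HMMParams",
    "PruneSchedule",
    "ImputedTarget",
    "FilterResult",
    "ld_r2",
    "prune_base",
    "impute_target",
    "minimac_r2",
    "hard_call",
    "filter_target",
]

MISSING = -1  # hard-call code for "no genotype confident enough"


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters: per-site switch probability and miscopy ε."""

    switch_prob: float = 0.01
    mismatch_prob: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.switch_prob < 1.0:
            raise ValueError("switch_prob must lie in (0, 1)")
        if not 0.0 < self.mismatch_prob < 0.5:
            raise ValueError("mismatch_prob must lie in (0, 0.5)")


@dataclass(frozen=True)
class PruneSchedule:
    """Ordered r² cutoffs; ``None`` means no pruning (round 1)."""

    thresholds: Tuple[Optional[float], ...] = (None, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "thresholds",
            tuple(None if t is None else float(t) for t in self.thresholds),
        )
        if len(self.thresholds) == 0:
            raise ValueError("schedule must contain at least one round")
        numeric = [t for t in self.thresholds if t is not None]
        if any(t is None for t in self.thresholds[1:]):
            raise ValueError("'no pruning' (None) is only allowed as the first round")
        if any(not 0.0 < t <= 1.0 for t in numeric):
            raise ValueError("cutoffs must lie in (0, 1]")
        if any(b >= a for a, b in zip(numeric, numeric[1:])):
            raise ValueError("cutoffs must be strictly decreasing")

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple("none" if t is None else f"{t:g}" for t in self.thresholds)


@dataclass
class ImputedTarget:
    """Per-case posteriors, dosages, hard calls and quality for one target SNP."""

    posteriors: np.ndarray  # (n_cases, 3), rows sum to 1
    dosages: np.ndarray  # (n_cases,), expected minor-allele count in [0, 2]
    hard_calls: np.ndarray  # (n_cases,) int8 in {0, 1, 2, MISSING}
    r2_score: float
    imputed_maf: float
    missing_rate: float

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.hard_calls = np.asarray(self.hard_calls, dtype=np.int8)
        if self.posteriors.ndim != 2 or self.posteriors.shape[1] != 3:
            raise ValueError("posteriors must have shape (n_cases, 3)")
        if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")
        expected = self.posteriors @ np.array([0.0, 1.0, 2.0])
        if not np.allclose(expected, self.dosages, atol=1e-9):
            raise ValueError("dosages must equal the posterior expectation")
        if not 0.0 <= self.imputed_maf <= 1.0:
            raise ValueError("imputed_maf must lie in [0, 1]")

    @property
    def n_cases(self) -> int:
        return self.posteriors.shape[0]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the post-imputation exclusion filters."""

    passed: bool
    reasons: Tuple[str, ...]


def ld_r2(panel: HaplotypePanel, site_a: int, site_b: int) -> float:
    """Squared Pearson correlation of the allele indicators at two sites."""
    a = panel.alleles[:, site_a].astype(float)
    b = panel.alleles[:, site_b].astype(float)
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("r2 is undefined for a monomorphic site")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def _r2_to_target(panel: HaplotypePanel) -> np.ndarray:
    """Vector of r² of every site to the target; monomorphic sites get 0."""
    alleles = panel.alleles.astype(float)
    target = alleles[:, panel.target_index]
    if target.std() == 0.0:
        raise ValueError("target SNP is monomorphic in the panel")
    centered = alleles - alleles.mean(axis=0)
    t_centered = target - target.mean()
    denom = np.sqrt((centered**2).sum(axis=0)) * np.sqrt((t_centered**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered.T @ t_centered) / denom
    r2 = np.where(denom > 0.0, r**2, 0.0)
    return np.minimum(r2, 1.0)


def prune_base(panel: HaplotypePanel, threshold: Optional[float]) -> np.ndarray:
    """Site indices retained in the imputation base (target always excluded).

    ``threshold=None`` keeps every non-target site; otherwise a site is kept
    iff its r² to the target is *strictly* below the threshold.  Monomorphic
    sites carry no LD information and are treated as r² = 0 (kept).  An
    empty retained set is legal: imputation then falls back to the panel
    allele frequency.
    """
    non_target = np.array([i for i in range(panel.n_sites) if i != panel.target_index])
    if threshold is None:
        return non_target
    r2 = _r2_to_target(panel)
    return non_target[r2[non_target] < threshold]


def minimac_r2(dosages: Sequence[float] | np.ndarray) -> float:
    """Imputation quality: empirical dosage variance over its HWE expectation.

    score = Var(dosage) / (2 p (1-p)) with p = mean(dosage)/2 and the
    population-variance denominator N.  Defined as 0 for constant dosages or
    p in {0, 1}.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size < 2:
        raise ValueError("minimac R2 needs at least 2 dosages")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0 or (d == d[0]).all():
        return 0.0
    return float(d.var() / (2.0 * p * (1.0 - p)))


def hard_call(posteriors: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Convert posteriors to hard genotype calls.

    The argmax genotype is called when its posterior is >= threshold
    (boundary inclusive), otherwise MISSING; posterior ties resolve to the
    smaller genotype.
    """
    post = np.asarray(posteriors, dtype=float)
    best = post.argmax(axis=1)  # first maximum -> smaller genotype on ties
    calls = best.astype(np.int8)
    calls[post.max(axis=1) < threshold] = MISSING
    return calls


def filter_target(
    imputed: ImputedTarget, min_maf: float = 0.005, max_missing_rate: float = 0.2
) -> FilterResult:
    """Apply the post-imputation exclusion filters.

    A target fails when its imputed MAF is below ``min_maf`` or its
    hard-call missing rate exceeds ``max_missing_rate``; all triggered
    reasons are reported.
    """
    reasons = []
    if imputed.imputed_maf < min_maf:
        reasons.append("maf")
    if imputed.missing_rate > max_missing_rate:
        reasons.append("missing")
    return FilterResult(passed=not reasons, reasons=tuple(reasons))


def _transition(prob: np.ndarray, switch_prob: float) -> np.ndarray:
    """One copying-model transition step applied to normalized messages."""
    n_states = prob.shape[-1]
    return (1.0 - switch_prob) * prob + switch_prob * prob.sum(axis=-1, keepdims=True) / n_states


def impute_target(
    case: CaseSample,
    panel: HaplotypePanel,
    retained: Iterable[int] | np.ndarray,
    params: HMMParams = HMMParams(),
    hard_call_threshold: float = 0.8,
) -> ImputedTarget:
    """Impute the masked target genotype of every case from the retained sites.

    Runs the haploid copying-model forward–backward over the reference
    haplotypes for each case haplotype (vectorized over haplotypes), takes
    the copying posterior at the target position, and reads the minor-allele
    probability as the posterior-weighted panel allele at the target.  With
    no retained sites the copying posterior is the uniform prior and every
    dosage equals twice the panel target frequency.
    """
    retained = np.asarray(sorted(set(int(i) for i in np.asarray(retained, dtype=int).ravel())))
    if retained.size and (retained.min() < 0 or retained.max() >= panel.n_sites):
        raise ValueError("retained sites must be a subset of the panel sites")
    if panel.target_index in retained:
        raise ValueError("the target site cannot drive its own imputation")
    if case.diplotypes.shape[2] != panel.n_sites:
        raise ValueError("case diplotypes must cover all panel sites")

    n_cases = case.n_cases
    n_states = panel.n_haplotypes
    eps = params.mismatch_prob
    switch = params.switch_prob
    obs = case.diplotypes.reshape(n_cases * 2, panel.n_sites)  # haplotype-major
    target_col = panel.alleles[:, panel.target_index].astype(float)

    left = retained[retained < panel.target_index]
    right = retained[retained > panel.target_index]

    def emission(site: int) -> np.ndarray:
        match = obs[:, site, None] == panel.alleles[None, :, site]
        return np.where(match, 1.0 - eps, eps)

    # forward over the left flank, one extra transition into the target
    alpha = np.full((obs.shape[0], n_states), 1.0 / n_states)
    for k, site in enumerate(left):
        alpha = (alpha if k == 0 else _transition(alpha, switch)) * emission(site)
        alpha /= alpha.sum(axis=1, keepdims=True)
    if left.size:
        alpha = _transition(alpha, switch)

    # backward over the right flank, one extra transition into the target
    beta = np.ones((obs.shape[0], n_states))
    for k, site in enumerate(right[::-1]):
        beta = emission(site) * (beta if k == 0 else _transition(beta, switch))
        beta /= beta.sum(axis=1, keepdims=True)
    if right.size:
        beta = _transition(beta, switch)

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    p_minor = (post @ target_col).reshape(n_cases, 2)

    pa, pb = p_minor[:, 0], p_minor[:, 1]
    posteriors = np.column_stack(
        [(1.0 - pa) * (1.0 - pb), pa + pb - 2.0 * pa * pb, pa * pb]
    )
    dosages = pa + pb
    calls = hard_call(posteriors, hard_call_threshold)
    return ImputedTarget(
        posteriors=posteriors,
        dosages=dosages,
        hard_calls=calls,
        r2_score=minimac_r2(dosages) if n_cases >= 2 else 0.0,
        imputed_maf=float(dosages.mean() / 2.0),
        missing_rate=float((calls == MISSING).mean()),
    )
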