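"""Tier 2: the case-only logistic test and the exposure-replicate engine.

The case-only model regresses exposure on dominant carrier status within
cases, logit P(E=1) = beta0 + beta1 * G, and tests beta1 with a two-sided
Wald test.  With a single binary covariate the maximum-likelihood fit has
the 2x2-table closed form beta1 = log(ad/bc), se = sqrt(1/a + 1/b + 1/c +
1/d) for cells a = exposed carriers, b = unexposed carriers, c = exposed
non-carriers, d = unexposed non-carriers; the closed form is used directly
so that behaviour under separation is deterministic: any zero cell triggers
the Haldane–Anscombe continuity correction (0.5 added to all four cells).

The replicate engine re-simulates exposures from the *true* genotypes of a
fixed case sample (imputation does not depend on exposure, so tier-1 output
is computed once per scenario and reused) and fits the model with the true
and with each hard-called imputed genotype vector.  Power is the proportion
of replicates with p < alpha (strict), counting undefined fits as
non-rejections; bias is the mean of true-based beta1 minus imputation-based
beta1 over complete pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from ._rng import child_rng
from .impute import MISSING, HMMParams, PruneSchedule, impute_target, prune_base
from .model import DiseaseModel
from .panel import HaplotypePanel, ascertain_cases
from .power import ExposureProfile, carrier_freq_in_cases, case_exposure_probabilities

__all__ = [
    "COFit",
    "ReplicateSet",
    "BiasEstimate",
    "dominant_encode",
    "fit_case_only",
    "simulate_replicates",
    "run_replicates",
    "estimate_power",
    "estimate_bias",
    "simulate_power_true_genotypes",
]

_REPLICATE_CHUNK = 2048  # exposure replicates simulated per block


def dominant_encode(genotypes: Sequence[int] | np.ndarray) -> np.ndarray:
    """Collapse genotypes {0,1,2} to carrier status {0,1}; MISSING passes through."""
    g = np.asarray(genotypes)
    out = np.where(g > 0, 1, 0).astype(np.int8)
    out[g < 0] = MISSING
    return out


@dataclass(frozen=True)
class COFit:
    """One case-only logistic fit (closed form on the 2x2 exposure table)."""

    beta0: float
    beta1: float
    se1: float
    wald_z: float
    p_value: float
    converged: bool
    correction_applied: bool


def _fit_tables(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form fit over arrays of 2x2 tables.

    Returns (beta0, beta1, se1, p_value, corrected); any zero cell in a
    table triggers the 0.5 continuity correction for that table.
    """
    cells = np.stack([np.asarray(x, dtype=float) for x in (a, b, c, d)])
    corrected = (cells == 0.0).any(axis=0)
    cells = cells + 0.5 * corrected
    a_, b_, c_, d_ = cells
    beta0 = np.log(c_ / d_)
    beta1 = np.log(a_ * d_ / (b_ * c_))
    se1 = np.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    p = 2.0 * norm.sf(np.abs(beta1) / se1)
    return beta0, beta1, se1, p, corrected


def fit_case_only(
    exposure: Sequence[int] | np.ndarray, g: Sequence[int] | np.ndarray
) -> COFit:
    """Fit logit P(E=1) = beta0 + beta1*G within cases (no covariates).

    Cases with missing genotype are dropped; if either carrier group is then
    empty the fit is undefined and a ValueError is raised.
    """
    e = np.asarray(exposure)
    gv = np.asarray(g)
    if e.shape != gv.shape:
        raise ValueError("exposure and genotype vectors must have equal length")
    keep = gv != MISSING
    e, gv = e[keep], gv[keep]
    carriers = gv == 1
    if carriers.sum() == 0 or (~carriers).sum() == 0:
        raise ValueError("case-only fit undefined: a carrier group is empty")
    a = float(np.sum(e[carriers] == 1))
    b = float(np.sum(e[carriers] == 0))
    c = float(np.sum(e[~carriers] == 1))
    d = float(np.sum(e[~carriers] == 0))
    beta0, beta1, se1, p, corrected = _fit_tables(a, b, c, d)
    return COFit(
        beta0=float(beta0),
        beta1=float(beta1),
        se1=float(se1),
        wald_z=float(beta1 / se1),
        p_value=float(p),
        converged=True,
        correction_applied=bool(corrected),
    )


@dataclass
class ReplicateSet:
    """Per-replicate interaction estimates for one scenario.

    Undefined fits (an empty carrier group after dropping missing hard
    calls) are recorded as NaN, never raised, so downstream summaries can
    count them as non-rejections.
    """

    scenario_id: str
    seed: int
    n_reps: int
    beta1_true_based: np.ndarray
    p_true: np.ndarray
    beta1_imputed_based: Dict[str, np.ndarray] = field(default_factory=dict)
    p_imputed: Dict[str, np.ndarray] = field(default_factory=dict)


def simulate_replicates(
    true_genotypes: np.ndarray,
    profile: ExposureProfile,
    n_reps: int,
    seed: int,
    genotype_sets: Optional[Mapping[str, np.ndarray]] = None,
    scenario_id: str = "scenario",
) -> ReplicateSet:
    """Re-simulate exposures ``n_reps`` times and fit the CO model each time.

    Exposures are always drawn from the *true* genotypes via ``profile``;
    ``genotype_sets`` maps labels (e.g. pruning thresholds) to hard-called
    genotype vectors (MISSING allowed) that are additionally fitted against
    the same exposures.  Deterministic given ``seed``.
    """
    g_true = dominant_encode(true_genotypes)
    if np.any(g_true == MISSING):
        raise ValueError("true genotypes must not be missing")
    n = g_true.size
    p_case = np.where(
        g_true == 1, profile.p_exposed_carrier_case, profile.p_exposed_noncarrier_case
    )
    genotype_sets = dict(genotype_sets or {})
    encoded = {label: dominant_encode(g) for label, g in genotype_sets.items()}

    # per-genotype-vector carrier/non-carrier indicator columns
    def indicators(gv: np.ndarray) -> Optional[Tuple[np.ndarray, np.ndarray]]:
        carrier = (gv == 1).astype(float)
        noncarrier = (gv == 0).astype(float)
        if carrier.sum() == 0 or noncarrier.sum() == 0:
            return None
        return carrier, noncarrier

    columns = {"__true__": indicators(g_true)}
    if columns["__true__"] is None:
        raise ValueError("true-genotype sample has an empty carrier group")
    for label, gv in encoded.items():
        columns[label] = indicators(gv)

    beta = {k: np.full(n_reps, np.nan) for k in columns}
    pval = {k: np.full(n_reps, np.nan) for k in columns}
    rng = child_rng(seed, "exposure", scenario_id)
    done = 0
    max_block = max(1, min(_REPLICATE_CHUNK, 8_000_000 // max(n, 1)))
    while done < n_reps:
        block = min(max_block, n_reps - done)
        exposures = (rng.random((block, n)) < p_case).astype(np.float64)
        for key, cols in columns.items():
            if cols is None:
                continue
            carrier, noncarrier = cols
            a = exposures @ carrier
            c = exposures @ noncarrier
            b = carrier.sum() - a
            d = noncarrier.sum() - c
            _, b1, _, p, _ = _fit_tables(a, b, c, d)
            beta[key][done : done + block] = b1
            pval[key][done : done + block] = p
        done += block

    return ReplicateSet(
        scenario_id=scenario_id,
        seed=seed,
        n_reps=n_reps,
        beta1_true_based=beta.pop("__true__"),
        p_true=pval.pop("__true__"),
        beta1_imputed_based=beta,
        p_imputed=pval,
    )


def run_replicates(
    panel: HaplotypePanel,
    model: DiseaseModel,
    n_cases: int,
    n_reps: int,
    seed: int,
    profile: Optional[ExposureProfile] = None,
    schedule: PruneSchedule = PruneSchedule(),
    params: HMMParams = HMMParams(),
    scenario_id: str = "scenario",
):
    """Full scenario run: ascertain cases, impute once, replicate exposures.

    ``profile=None`` simulates the null of no interaction (all cases exposed
    at the model's population frequency).  Returns ``(ReplicateSet,
    imputed_by_label, case_sample)``; imputation is computed once per
    pruning round since it does not depend on exposure.
    """
    if profile is None:
        profile = ExposureProfile.null(model.p_exposure)
    cases = ascertain_cases(panel, model, n_cases, child_rng(seed, "ascertain", scenario_id))
    imputed = {}
    for label, threshold in zip(schedule.labels, schedule.thresholds):
        retained = prune_base(panel, threshold)
        imputed[label] = impute_target(cases, panel, retained, params)
    genotype_sets = {label: imp.hard_calls for label, imp in imputed.items()}
    reps = simulate_replicates(
        cases.true_target_genotype, profile, n_reps, seed,
        genotype_sets=genotype_sets, scenario_id=scenario_id,
    )
    return reps, imputed, cases


def estimate_power(p_values: np.ndarray, alpha: float = 0.05) -> float:
    """Proportion of replicates with p < alpha (strict).

    NaN entries (undefined fits) count as non-rejections but stay in the
    denominator — a conservative convention.  Raises if every fit is
    undefined.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).all():
        raise ValueError("power undefined: all replicate fits are missing")
    return float(np.sum(p < alpha) / p.size)


@dataclass(frozen=True)
class BiasEstimate:
    """Bias of the imputation-based interaction estimate (true minus imputed)."""

    mean: float
    median: float
    iqr: float
    n_pairs: int


def estimate_bias(
    beta_true_based: np.ndarray, beta_imputed_based: np.ndarray
) -> BiasEstimate:
    """Mean (plus median/IQR) of true-based beta1 minus imputation-based beta1.

    Pairs with a missing member are dropped; raises if no complete pair
    remains.
    """
    bt = np.asarray(beta_true_based, dtype=float)
    bi = np.asarray(beta_imputed_based, dtype=float)
    if bt.shape != bi.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(bt) | np.isnan(bi))
    if not keep.any():
        raise ValueError("bias undefined: no complete pairs")
    diff = bt[keep] - bi[keep]
    q1, q3 = np.quantile(diff, [0.25, 0.75])
    return BiasEstimate(
        mean=float(diff.mean()),
        median=float(np.median(diff)),
        iqr=float(q3 - q1),
        n_pairs=int(keep.sum()),
    )


def simulate_power_true_genotypes(
    model: DiseaseModel,
    n_cases: int,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Unconditional empirical power of the CO test with true genotypes.

    Each replicate redraws the case carrier count from Binomial(n,
    P(G=1|D=1)) and the exposure counts from the genotype-specific case
    probabilities, then applies the closed-form Wald fit.  Redrawing the
    genotypes matches the expected group sizes of the analytic power
    formula, so this is the simulation the analytic solver is checked
    against.
    """
    freq = carrier_freq_in_cases(model)
    profile = case_exposure_probabilities(model)
    rng = child_rng(seed, "true-genotype-power")
    n1 = rng.binomial(n_cases, freq, size=n_reps)
    n0 = n_cases - n1
    a = rng.binomial(n1, profile.p_exposed_carrier_case)
    c = rng.binomial(n0, profile.p_exposed_noncarrier_case)
    _, _, _, p, _ = _fit_tables(a, n1 - a, c, n0 - c)
    p = np.where((n1 == 0) | (n0 == 0), np.nan, p)
    return estimate_power(p, alpha)
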