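"""Headline desk-scale study computations.

Two end-to-end experiments summarise the pipeline's calibration:

* :func:`design_power_check` — solve the interaction OR that the analytic
  Wald formula says is detectable at the design power, then estimate the
  empirical power of the case-only test with true genotypes by simulation.
  Each replicate redraws the case genotypes (carrier counts from
  P(G=1|D=1)) and exposures, matching the expected group sizes the
  analytic formula assumes.

* :func:`low_maf_null_type1` — the validity check in the difficult regime:
  low-MAF main-effect target SNPs, imputed from an LD-pruned base and
  hard-called, analysed under the null of no interaction.  Reports the
  median empirical type-I error across scenarios; small expected cell
  counts make the Wald test conservative here.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from ._rng import child_rng
from .caseonly import estimate_power, simulate_power_true_genotypes, simulate_replicates
from .impute import HMMParams, impute_target, prune_base
from .model import DiseaseModel
from .panel import PanelSpec, ascertain_cases, generate_reference_panel
from .power import ExposureProfile, PowerQuery, solve_interaction_or

__all__ = ["design_power_check", "low_maf_null_type1"]


def design_power_check(
    seed: int,
    n_cases: int = 719,
    maf: float = 0.25,
    or_g: float = 1.5,
    or_e: float = 1.5,
    p_exposure: float = 0.30,
    baseline_odds: float = 1e-3,
    alpha: float = 0.05,
    target_power: float = 0.8,
    n_reps: int = 10_000,
) -> Dict[str, float]:
    """Solve the design interaction OR and verify it by simulation."""
    model = DiseaseModel(
        baseline_odds=baseline_odds, or_g=or_g, or_e=or_e,
        maf=maf, p_exposure=p_exposure,
    )
    or_ge = solve_interaction_or(PowerQuery(n_cases, model, alpha, target_power))
    solved = model.replace(or_ge=or_ge)
    power = simulate_power_true_genotypes(solved, n_cases, n_reps, seed, alpha=alpha)
    return {"or_ge": or_ge, "empirical_power": power, "n_reps": n_reps}


def low_maf_null_type1(
    seed: int,
    n_scenarios: int = 10,
    n_haplotypes: int = 1000,
    n_tags: int = 50,
    or_g: float = 2.0,
    or_e: float = 1.5,
    baseline_odds: float = 1e-3,
    prune_threshold: float = 0.5,
    n_cases: int = 719,
    n_reps: int = 2000,
    exposure_freq: float = 0.10,
    alpha: float = 0.05,
) -> Dict[str, object]:
    """Median null rejection rate across low-MAF imputed-genotype scenarios.

    Each scenario: target MAF uniform in [0.01, 0.05), a reference panel
    with ``n_tags`` tag SNPs spanning r² 0.1–0.9, cases ascertained under a
    genetic main effect, the masked target imputed after pruning the base
    at the given r² cutoff and hard-called at 0.8, and ``n_reps`` null
    exposure replicates analysed case-only on the hard calls.
    """
    rates: List[float] = []
    mafs: List[float] = []
    maf_rng = child_rng(seed, "scenario-mafs")
    for s in range(n_scenarios):
        maf = float(maf_rng.uniform(0.01, 0.05))
        mafs.append(maf)
        tag_r2 = np.linspace(0.1, 0.9, n_tags)
        tags = tuple(
            (float(r2), maf, 10_000 * (i + 1)) for i, r2 in enumerate(tag_r2)
        )
        panel_seed = int(child_rng(seed, "panel", s).integers(0, 2**31 - 1))
        spec = PanelSpec(
            n_haplotypes=n_haplotypes, target_maf=maf, tag_snps=tags,
            seed=panel_seed, target_position=10_000 * (n_tags + 1),
        )
        panel = generate_reference_panel(spec)
        model = DiseaseModel(
            baseline_odds=baseline_odds, or_g=or_g, or_e=or_e,
            maf=maf, p_exposure=exposure_freq,
        )
        cases = ascertain_cases(panel, model, n_cases, child_rng(seed, "cases", s))
        retained = prune_base(panel, prune_threshold)
        imputed = impute_target(cases, panel, retained, HMMParams())
        reps = simulate_replicates(
            cases.true_target_genotype,
            ExposureProfile.null(exposure_freq),
            n_reps,
            seed,
            genotype_sets={"imputed": imputed.hard_calls},
            scenario_id=f"lowmaf{s}",
        )
        p_values = reps.p_imputed["imputed"]
        if np.isnan(p_values).all():
            rates.append(0.0)  # no carrier calls: the test can never reject
        else:
            rates.append(estimate_power(p_values, alpha))
    return {
        "median_type1": float(np.median(rates)),
        "per_scenario": rates,
        "mafs": mafs,
        "n_reps": n_reps,
    }
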