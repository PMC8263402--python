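"""Scenario orchestration: tier 1 (imputation quality) and tier 2 (G×E power).

A pipeline run is described by one structured config document (YAML or
JSON) holding shared settings plus a list of scenarios, each of which
defines a target SNP (MAF, main-effect OR, LD neighbourhood).  Tier 1
generates the panel, ascertains cases, imputes the masked target at every
pruning round and tabulates quality (kappa, R², imputed MAF, missing
rate).  Tier 2 solves the interaction OR that meets the target power,
derives genotype-specific exposure probabilities, and runs the replicate
engine under the interaction and under the null profile, yielding power,
type-I error and bias per pruning round.

Scenarios are independent units with order-free child-seed derivation, so
any execution order produces identical results; re-running with the same
config and seed reproduces the output CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from .caseonly import estimate_bias, estimate_power, simulate_replicates
from .impute import (
    FilterResult,
    HMMParams,
    ImputedTarget,
    PruneSchedule,
    filter_target,
    impute_target,
    prune_base,
)
from .metrics import cohens_kappa, confusion_table, maf_category
from .model import DiseaseModel
from .panel import CaseSample, HaplotypePanel, PanelSpec, ascertain_cases, generate_reference_panel
from .power import (
    ExposureProfile,
    PowerQuery,
    case_exposure_probabilities,
    solve_interaction_or,
)

__all__ = [
    "ScenarioConfig",
    "PipelineConfig",
    "Tier1Result",
    "run_tier1",
    "run_tier2",
    "summarize",
    "run_pipeline",
]

logger = logging.getLogger("coimpute")

DEFAULT_TAG_R2 = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class ScenarioConfig:
    """One target-SNP scenario: its disease model and LD neighbourhood."""

    scenario_id: str
    model: DiseaseModel
    n_haplotypes: int = 1000
    tag_r2: Tuple[float, ...] = DEFAULT_TAG_R2

    def panel_spec(self, seed: int) -> PanelSpec:
        tags = tuple(
            (r2, self.model.maf, 100_000 + 10_000 * i) for i, r2 in enumerate(self.tag_r2)
        )
        return PanelSpec(
            n_haplotypes=self.n_haplotypes,
            target_maf=self.model.maf,
            tag_snps=tags,
            seed=seed,
            target_position=100_000 + 10_000 * len(self.tag_r2),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Shared settings plus the scenario grid."""

    scenarios: Tuple[ScenarioConfig, ...]
    exposure_frequencies: Tuple[float, ...] = (0.10, 0.30)
    schedule: PruneSchedule = PruneSchedule()
    hmm: HMMParams = HMMParams()
    n_cases: int = 719
    n_reps: int = 10_000
    alpha: float = 0.05
    target_power: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("config must define at least one scenario")
        ids = [s.scenario_id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique")
        if any(not 0.0 < f < 1.0 for f in self.exposure_frequencies):
            raise ValueError("exposure frequencies must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: Union[str, Path], seed: Optional[int] = None) -> "PipelineConfig":
        """Load a YAML or JSON config document (YAML is a JSON superset)."""
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc, seed=seed)

    @classmethod
    def from_dict(cls, doc: dict, seed: Optional[int] = None) -> "PipelineConfig":
        scenarios = []
        for item in doc.get("scenarios", []):
            item = dict(item)
            scenario_id = str(item.pop("id"))
            n_haplotypes = int(item.pop("n_haplotypes", 1000))
            tag_r2 = tuple(float(r) for r in item.pop("tag_r2", DEFAULT_TAG_R2))
            model = DiseaseModel(**item)
            scenarios.append(
                ScenarioConfig(scenario_id, model, n_haplotypes=n_haplotypes, tag_r2=tag_r2)
            )
        kwargs = {}
        if "exposure_frequencies" in doc:
            kwargs["exposure_frequencies"] = tuple(float(f) for f in doc["exposure_frequencies"])
        if "prune_thresholds" in doc:
            kwargs["schedule"] = PruneSchedule(
                tuple(None if t in (None, "none") else float(t) for t in doc["prune_thresholds"])
            )
        if "hmm" in doc:
            kwargs["hmm"] = HMMParams(**doc["hmm"])
        for key in ("n_cases", "n_reps", "seed"):
            if key in doc:
                kwargs[key] = int(doc[key])
        for key in ("alpha", "target_power"):
            if key in doc:
                kwargs[key] = float(doc[key])
        if seed is not None:
            kwargs["seed"] = int(seed)
        return cls(scenarios=tuple(scenarios), **kwargs)


@dataclass
class Tier1Result:
    """Panel, case sample and per-round imputation for one scenario."""

    scenario_id: str
    panel: HaplotypePanel
    cases: CaseSample
    imputed: Dict[str, ImputedTarget]
    kappa: Dict[str, float]
    filter_result: FilterResult
    quality: pd.DataFrame = field(repr=False, default=None)


def run_tier1(config: PipelineConfig) -> Dict[str, Tier1Result]:
    """Mask, prune and impute the target of every scenario; tabulate quality.

    A scenario failing the post-imputation filters (on the unpruned round)
    is flagged and later excluded from tier 2.
    """
    results: Dict[str, Tier1Result] = {}
    for scenario in config.scenarios:
        sid = scenario.scenario_id
        panel_seed = int(child_rng(config.seed, "panel", sid).integers(0, 2**31 - 1))
        panel = generate_reference_panel(scenario.panel_spec(panel_seed))
        cases = ascertain_cases(
            panel, scenario.model, config.n_cases, child_rng(config.seed, "ascertain", sid)
        )
        logger.info(
            "tier1 scenario=%s maf=%.3f or_g=%.2f panel_seed=%d",
            sid, scenario.model.maf, scenario.model.or_g, panel_seed,
        )
        imputed: Dict[str, ImputedTarget] = {}
        kappa: Dict[str, float] = {}
        rows = []
        for label, threshold in zip(config.schedule.labels, config.schedule.thresholds):
            retained = prune_base(panel, threshold)
            imp = impute_target(cases, panel, retained, config.hmm)
            imputed[label] = imp
            try:  # every hard call may be missing under heavy pruning
                table = confusion_table(cases.true_target_genotype, imp.hard_calls)
                kappa[label] = cohens_kappa(table)
            except ValueError:
                kappa[label] = float("nan")
            rows.append(
                {
                    "scenario": sid,
                    "threshold": label,
                    "n_retained": int(retained.size),
                    "r2_score": imp.r2_score,
                    "imputed_maf": imp.imputed_maf,
                    "missing_rate": imp.missing_rate,
                    "kappa": kappa[label],
                    "true_case_maf": float(cases.true_target_genotype.mean() / 2.0),
                    "panel_maf": panel.target_frequency(),
                }
            )
        filt = filter_target(imputed[config.schedule.labels[0]])
        results[sid] = Tier1Result(
            scenario_id=sid,
            panel=panel,
            cases=cases,
            imputed=imputed,
            kappa=kappa,
            filter_result=filt,
            quality=pd.DataFrame(rows),
        )
    return results


def _safe_power(p_values: np.ndarray, alpha: float) -> float:
    try:
        return estimate_power(p_values, alpha)
    except ValueError:
        return float("nan")


def run_tier2(
    config: PipelineConfig,
    tier1: Dict[str, Tier1Result],
    null_only: bool = False,
) -> pd.DataFrame:
    """Replicate exposures per scenario and exposure frequency.

    For each scenario passing the tier-1 filters: solve the interaction OR
    meeting the target power, derive the case exposure profile, run the
    replicate engine under interaction and null, and report per-round power,
    type-I error, bias and quality.  With ``null_only=True`` the interaction
    simulation is skipped.
    """
    rows = []
    for scenario in config.scenarios:
        sid = scenario.scenario_id
        t1 = tier1[sid]
        if not t1.filter_result.passed:
            logger.info("tier2 scenario=%s skipped (filters: %s)", sid, t1.filter_result.reasons)
            continue
        genotype_sets = {lbl: imp.hard_calls for lbl, imp in t1.imputed.items()}
        for p_e in config.exposure_frequencies:
            model_e = scenario.model.replace(p_exposure=p_e)
            or_ge = None
            reps_int = None
            if not null_only:
                try:
                    or_ge = solve_interaction_or(
                        PowerQuery(config.n_cases, model_e, config.alpha, config.target_power)
                    )
                except ValueError as exc:
                    raise ValueError(f"scenario {sid}, exposure {p_e}: {exc}") from exc
                profile = case_exposure_probabilities(model_e.replace(or_ge=or_ge))
                reps_int = simulate_replicates(
                    t1.cases.true_target_genotype, profile, config.n_reps,
                    config.seed, genotype_sets, scenario_id=f"{sid}|e{p_e}|int",
                )
            reps_null = simulate_replicates(
                t1.cases.true_target_genotype, ExposureProfile.null(p_e), config.n_reps,
                config.seed, genotype_sets, scenario_id=f"{sid}|e{p_e}|null",
            )
            labels = ["true"] + list(config.schedule.labels)
            for label in labels:
                if label == "true":
                    p_int = reps_int.p_true if reps_int else None
                    b_int = reps_int.beta1_true_based if reps_int else None
                    p_null = reps_null.p_true
                    quality = {}
                else:
                    p_int = reps_int.p_imputed[label] if reps_int else None
                    b_int = reps_int.beta1_imputed_based[label] if reps_int else None
                    p_null = reps_null.p_imputed[label]
                    imp = t1.imputed[label]
                    quality = {
                        "kappa": t1.kappa[label],
                        "r2_score": imp.r2_score,
                        "imputed_maf": imp.imputed_maf,
                        "missing_rate": imp.missing_rate,
                    }
                row = {
                    "scenario": sid,
                    "maf": scenario.model.maf,
                    "maf_category": maf_category(scenario.model.maf),
                    "exposure_freq": p_e,
                    "threshold": label,
                    "or_ge": or_ge,
                    "type1_error": _safe_power(p_null, config.alpha),
                    **quality,
                }
                if reps_int is not None:
                    row["power"] = _safe_power(p_int, config.alpha)
                    if label != "true":
                        try:
                            bias = estimate_bias(reps_int.beta1_true_based, b_int)
                            row["bias_mean"] = bias.mean
                            row["bias_median"] = bias.median
                        except ValueError:
                            row["bias_mean"] = float("nan")
                            row["bias_median"] = float("nan")
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame,
    values: Sequence[str] = ("power", "type1_error", "bias_mean", "kappa", "r2_score"),
) -> pd.DataFrame:
    """Grouped quantile tables (median and quartiles) of the tier-2 results.

    Groups by MAF category, pruning threshold and exposure frequency — the
    tabular counterpart of the study's boxplot summaries.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    present = [v for v in values if v in results.columns]
    grouped = results.groupby(["maf_category", "threshold", "exposure_freq"], dropna=False)
    frames = []
    for name in present:
        q = grouped[name].quantile([0.25, 0.5, 0.75]).unstack()
        q.columns = [f"{name}_q25", f"{name}_median", f"{name}_q75"]
        frames.append(q)
    return pd.concat(frames, axis=1).reset_index()


def run_pipeline(
    config: PipelineConfig, outdir: Union[str, Path], null_only: bool = False
) -> pd.DataFrame:
    """Run both tiers and write quality/power/bias/type-I CSVs plus the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tier1 = run_tier1(config)
    quality = pd.concat([t.quality for t in tier1.values()], ignore_index=True)
    quality.to_csv(outdir / "quality.csv", index=False)
    results = run_tier2(config, tier1, null_only=null_only)
    float_fmt = "%.10g"
    results.to_csv(outdir / "tier2_results.csv", index=False, float_format=float_fmt)
    if not results.empty:
        if "power" in results.columns:
            results[
                ["scenario", "maf_category", "exposure_freq", "threshold", "or_ge", "power"]
            ].to_csv(outdir / "power.csv", index=False, float_format=float_fmt)
            bias_cols = [c for c in ("bias_mean", "bias_median") if c in results.columns]
            results[results.threshold != "true"][
                ["scenario", "maf_category", "exposure_freq", "threshold"] + bias_cols
            ].to_csv(outdir / "bias.csv", index=False, float_format=float_fmt)
        results[
            ["scenario", "maf_category", "exposure_freq", "threshold", "type1_error"]
        ].to_csv(outdir / "type1.csv", index=False, float_format=float_fmt)
    echo = dataclasses.asdict(config)
    (outdir / "config_used.json").write_text(json.dumps(echo, indent=2, default=str))
    return results
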