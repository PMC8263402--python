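"""LD pruning, haplotype-copying imputation, quality score and filters."""

import numpy as np
import pytest

from coimpute import (
    DiseaseModel,
    HMMParams,
    HaplotypePanel,
    CaseSample,
    ImputedTarget,
    PanelSpec,
    PruneSchedule,
    ascertain_cases,
    cohens_kappa,
    confusion_table,
    filter_target,
    generate_reference_panel,
    hard_call,
    impute_target,
    ld_r2,
    minimac_r2,
    prune_base,
)
from coimpute.impute import MISSING


def panel_from_columns(*columns, target_index=None):
    cols = [np.asarray(c, dtype=np.uint8) for c in columns]
    n_sites = len(cols)
    return HaplotypePanel(
        alleles=np.column_stack(cols),
        positions=np.arange(1, n_sites + 1) * 1000,
        site_ids=tuple(f"s{i}" for i in range(n_sites)),
        target_index=n_sites - 1 if target_index is None else target_index,
    )


class TestLdR2:
    def test_identical_and_complementary_columns_give_one(self):
        col = [0, 1, 0, 1, 1, 0]
        panel = panel_from_columns(col, col, [1 - c for c in col])
        assert ld_r2(panel, 0, 1) == pytest.approx(1.0)
        assert ld_r2(panel, 0, 2) == pytest.approx(1.0)

    def test_textbook_haplotype_count_example(self):
        # haplotype counts (AB, Ab, aB, ab) = (40, 10, 10, 40):
        # D = 0.4 - 0.25 = 0.15, all margins 0.5 -> r2 = 0.15^2 / 0.5^4 = 0.36
        a = [1] * 50 + [0] * 50
        b = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        panel = panel_from_columns(a, b)
        assert ld_r2(panel, 0, 1) == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_site_is_an_error(self):
        panel = panel_from_columns([0, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(panel, 0, 1)

    def test_symmetry(self, small_panel):
        assert ld_r2(small_panel, 0, 3) == pytest.approx(ld_r2(small_panel, 3, 0))


class TestPruneBase:
    def test_no_threshold_retains_all_non_target_sites(self, small_panel):
        retained = prune_base(small_panel, None)
        assert len(retained) == small_panel.n_sites - 1
        assert small_panel.target_index not in retained

    def test_strict_cutoff(self):
        spec = PanelSpec(
            n_haplotypes=200_000,
            target_maf=0.3,
            tag_snps=((0.05, 0.3, 1000), (0.3, 0.3, 2000), (0.8, 0.3, 3000)),
            seed=13,
            target_position=4000,
        )
        panel = generate_reference_panel(spec)
        retained = prune_base(panel, 0.5)
        assert set(panel.site_ids[i] for i in retained) == {"tag000", "tag001"}

    def test_empty_retained_set_is_legal(self):
        panel = panel_from_columns([0, 1, 0, 1], [0, 1, 0, 1])
        assert prune_base(panel, 0.1).size == 0


class TestImputeTarget:
    def test_prior_fallback_with_empty_retained_set(self, small_panel, small_cases):
        imputed = impute_target(small_cases, small_panel, [])
        expected = 2 * small_panel.target_frequency()
        assert np.allclose(imputed.dosages, expected)
        assert imputed.r2_score == pytest.approx(0.0)

    def test_perfect_tag_recovers_true_genotypes(self, tight_hmm):
        spec = PanelSpec(
            n_haplotypes=1000, target_maf=0.3, tag_snps=((1.0, 0.3, 1000),),
            seed=21, target_position=2000,
        )
        panel = generate_reference_panel(spec)
        cases = ascertain_cases(panel, DiseaseModel(maf=0.3), 500, np.random.default_rng(2))
        retained = prune_base(panel, None)
        imputed = impute_target(cases, panel, retained, tight_hmm)
        agree = (imputed.hard_calls == cases.true_target_genotype).mean()
        assert agree >= 0.99
        assert imputed.r2_score >= 0.99

    def test_two_state_hand_bayes(self):
        """Panel {(tag,target)} = {(0,0), (1,1)}; observing tag allele 1 with
        miscopy 0.1 gives P(copying the minor haplotype) = 0.9 by Bayes."""
        panel = panel_from_columns([0, 1], [0, 1])
        case = CaseSample(
            diplotypes=np.array([[[1, 1], [0, 0]]]),
            true_target_genotype=[1],
            target_index=1,
        )
        params = HMMParams(switch_prob=1e-9, mismatch_prob=0.1)
        imputed = impute_target(case, panel, [0], params)
        assert imputed.posteriors[0] == pytest.approx([0.09, 0.82, 0.09], abs=1e-6)
        assert imputed.dosages[0] == pytest.approx(1.0, abs=1e-6)

    def test_posterior_invariants_on_real_scenario(self, small_panel, small_cases):
        imputed = impute_target(small_cases, small_panel, prune_base(small_panel, 0.5))
        assert np.allclose(imputed.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((imputed.dosages >= 0) & (imputed.dosages <= 2))
        assert 0.0 <= imputed.imputed_maf <= 1.0

    def test_retained_superset_rejected(self, small_panel, small_cases):
        with pytest.raises(ValueError, match="subset"):
            impute_target(small_cases, small_panel, [small_panel.n_sites + 1])
        with pytest.raises(ValueError, match="target"):
            impute_target(small_cases, small_panel, [small_panel.target_index])


class TestMonotoneDegradation:
    def test_quality_declines_along_prune_schedule(self):
        """Mean minimac R2 and kappa over 50 replicate case samples are
        non-increasing (within Monte-Carlo tolerance) as pruning tightens."""
        maf = 0.25
        tags = tuple((r2, maf, 10_000 * (i + 1)) for i, r2 in enumerate(
            np.linspace(0.1, 0.9, 18)))
        spec = PanelSpec(n_haplotypes=400, target_maf=maf, tag_snps=tags,
                         seed=77, target_position=400_000)
        panel = generate_reference_panel(spec)
        model = DiseaseModel(baseline_odds=1e-3, or_g=2.0, maf=maf)
        n_reps, n_cases = 50, 150
        # stack replicate case samples into one batch per threshold
        samples = [
            ascertain_cases(panel, model, n_cases, np.random.default_rng(1000 + r))
            for r in range(n_reps)
        ]
        stacked = CaseSample(
            diplotypes=np.concatenate([s.diplotypes for s in samples]),
            true_target_genotype=np.concatenate([s.true_target_genotype for s in samples]),
            target_index=panel.target_index,
        )
        schedule = PruneSchedule()
        mean_r2, mean_kappa = [], []
        import warnings

        for threshold in schedule.thresholds:
            retained = prune_base(panel, threshold)
            r2s, kappas = [], []
            for r in range(n_reps):
                sl = slice(r * n_cases, (r + 1) * n_cases)
                sub = CaseSample(
                    diplotypes=stacked.diplotypes[sl],
                    true_target_genotype=stacked.true_target_genotype[sl],
                    target_index=panel.target_index,
                )
                imp = impute_target(sub, panel, retained)
                r2s.append(imp.r2_score)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        kappa = cohens_kappa(
                            confusion_table(sub.true_target_genotype, imp.hard_calls)
                        )
                except ValueError:  # every hard call missing under heavy pruning
                    kappa = np.nan
                kappas.append(kappa)
            mean_r2.append(np.mean(r2s))
            mean_kappa.append(np.nanmean(kappas) if not np.isnan(kappas).all() else np.nan)
        tol = 0.01  # Monte-Carlo noise allowance on 50-replicate means
        assert all(b <= a + tol for a, b in zip(mean_r2, mean_r2[1:]))
        defined = [k for k in mean_kappa if not np.isnan(k)]
        assert all(b <= a + tol for a, b in zip(defined, defined[1:]))
        # and the degradation is real, not flat
        assert mean_r2[-1] < mean_r2[0] - 0.1
        assert defined[-1] < defined[0] - 0.1

    def test_main_effect_shrinks_imputed_maf_toward_panel(self):
        maf = 0.3
        tags = tuple((r2, maf, 10_000 * (i + 1)) for i, r2 in enumerate(
            np.linspace(0.1, 0.9, 12)))
        spec = PanelSpec(n_haplotypes=500, target_maf=maf, tag_snps=tags,
                         seed=5, target_position=200_000)
        panel = generate_reference_panel(spec)
        model = DiseaseModel(baseline_odds=1e-3, or_g=3.0, maf=maf)
        cases = ascertain_cases(panel, model, 2000, np.random.default_rng(9))
        true_maf = cases.true_target_genotype.mean() / 2
        panel_maf = panel.target_frequency()
        assert true_maf > panel_maf  # ascertainment enrichment
        lo = min(panel_maf, true_maf) - 0.01
        hi = max(panel_maf, true_maf) + 0.01
        gaps = []
        for threshold in (None, 0.3, 0.15):
            imp = impute_target(cases, panel, prune_base(panel, threshold))
            assert lo <= imp.imputed_maf <= hi
            gaps.append(abs(imp.imputed_maf - panel_maf))
        empty = impute_target(cases, panel, [])
        gaps.append(abs(empty.imputed_maf - panel_maf))
        assert gaps[-1] == pytest.approx(0.0, abs=1e-9)
        assert gaps[-1] < gaps[0]
        # imputed MAF under heavy pruning is closer to the panel than the truth is
        assert gaps[2] < abs(true_maf - panel_maf)


class TestMinimacR2:
    def test_constant_dosages_score_zero(self):
        assert minimac_r2([0.4, 0.4, 0.4]) == 0.0

    def test_hand_computed_example(self):
        # p = 0.5, Var = 0.5, denominator 2*0.25 = 0.5 -> score 1
        assert minimac_r2([0, 1, 2, 1]) == pytest.approx(1.0)

    def test_true_genotypes_at_hwe_score_near_one(self):
        rng = np.random.default_rng(17)
        genotypes = rng.binomial(2, 0.3, size=100_000)
        assert minimac_r2(genotypes) == pytest.approx(1.0, abs=0.02)

    def test_needs_two_dosages(self):
        with pytest.raises(ValueError):
            minimac_r2([1.0])


class TestHardCall:
    @pytest.mark.parametrize(
        "posterior,expected",
        [
            ((0.1, 0.85, 0.05), 1),
            ((0.5, 0.4, 0.1), MISSING),
            ((0.80, 0.15, 0.05), 0),  # boundary inclusive
            ((0.05, 0.15, 0.80), 2),
        ],
    )
    def test_threshold_rule(self, posterior, expected):
        assert hard_call(np.array([posterior]))[0] == expected

    def test_tie_breaks_toward_smaller_genotype(self):
        calls = hard_call(np.array([[0.45, 0.45, 0.10]]), threshold=0.4)
        assert calls[0] == 0


class TestFilterTarget:
    def _target(self, maf, missing):
        post = np.tile([1.0, 0.0, 0.0], (10, 1))
        return ImputedTarget(
            posteriors=post, dosages=np.zeros(10),
            hard_calls=np.zeros(10, dtype=np.int8),
            r2_score=1.0, imputed_maf=maf, missing_rate=missing,
        )

    def test_low_maf_fails(self):
        result = filter_target(self._target(0.004, 0.0))
        assert not result.passed and result.reasons == ("maf",)

    def test_high_missing_fails(self):
        result = filter_target(self._target(0.05, 0.25))
        assert not result.passed and result.reasons == ("missing",)

    def test_clean_target_passes(self):
        assert filter_target(self._target(0.05, 0.0)).passed


class TestPruneSchedule:
    def test_default_is_ten_rounds(self):
        schedule = PruneSchedule()
        assert len(schedule.thresholds) == 10
        assert schedule.thresholds[0] is None
        assert schedule.thresholds[1:] == tuple(np.round(np.arange(0.9, 0.05, -0.1), 1))

    def test_non_decreasing_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            PruneSchedule((0.5, 0.5))

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            PruneSchedule(())
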