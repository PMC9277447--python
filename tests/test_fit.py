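"""Flux estimation: least squares, bootstrap, model comparison, group tests."""

import numpy as np
import pytest

from tcaflux import (
    DEFAULT_START,
    FluxParameters,
    IsotopomerFluxModel,
    ScenarioSpec,
    compare_models,
    fit_fluxes,
    generate_dataset,
    group_compare,
    predict_ratios,
)
from tcaflux.model import FailedFit

TRUTH = FluxParameters(f_pdh=0.7, y_pc=0.25, pk=0.35, y_s=0.15)


@pytest.fixture(scope="module")
def clean_table():
    return predict_ratios(TRUTH)


@pytest.fixture(scope="module")
def noisy_table():
    return generate_dataset(ScenarioSpec("SIM", TRUTH, seed=11))


class TestPredictRatios:
    def test_fully_labeled_limit(self):
        tab = predict_ratios(FluxParameters(1, 0, 0, 0), tolerance=1e-16)
        assert tab.set_index("multiplet")["ratio"]["C4Q"] == 1.0

    def test_pdh_dilution_matches_oracle(self, network, tracer):
        """Half-strength PDH: C4 multiplet fractions agree with the
        20,000-molecule Monte-Carlo estimate within 3 binomial SE."""
        from tcaflux import multiplet_pattern

        f = FluxParameters(0.5, 0, 0, 0)
        tab = predict_ratios(f)
        c4 = tab[(tab.pool == "GLU") & (tab.position == 4)].set_index("multiplet")["ratio"]
        mc = network.sample_molecules(f, tracer, 20_000, seed=2, pools=("AKG_GLU",))
        c4_mc = multiplet_pattern(mc["AKG_GLU"], 4).components
        n_eff = 20_000 * mc["AKG_GLU"].marginal(4)
        for label, frac in c4_mc.items():
            se = np.sqrt(max(c4[label] * (1 - c4[label]), 1 / n_eff) / n_eff)
            assert abs(frac - c4[label]) <= 3 * se, label


class TestFit:
    def test_self_consistency_at_truth(self, clean_table):
        model = IsotopomerFluxModel(clean_table)
        res = model.fit(starts=[TRUTH])
        assert res.objective <= 1e-12
        for k, v in TRUTH.as_dict().items():
            assert getattr(res.params, k) == pytest.approx(v, abs=1e-6)

    def test_noiseless_recovery_from_default_start(self, clean_table):
        res = fit_fluxes(clean_table, starts=[DEFAULT_START])
        for k, v in TRUTH.as_dict().items():
            assert getattr(res.params, k) == pytest.approx(v, abs=1e-3)

    def test_best_of_starts(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=5, seed=0)
        assert res.objective <= min(obj for _, obj in res.starts) + 1e-10
        assert len(res.starts) == 5

    def test_reproducible_for_fixed_seed(self, noisy_table):
        a = fit_fluxes(noisy_table, n_starts=4, seed=3)
        b = fit_fluxes(noisy_table, n_starts=4, seed=3)
        assert a.params == b.params and a.objective == b.objective

    def test_constraint_pk_le_cataplerosis(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=3, seed=0)
        assert res.params.pk <= res.params.pepck + 1e-9
        res.params.validate()

    def test_directional_sensitivity(self):
        """Raising generator (pk, y_pc) raises the fitted (pk, y_pc)."""
        lo = predict_ratios(FluxParameters(0.75, 0.15, 0.10, 0.10))
        hi = predict_ratios(FluxParameters(0.60, 0.40, 0.35, 0.10))
        fit_lo = fit_fluxes(lo, n_starts=3, seed=1)
        fit_hi = fit_fluxes(hi, n_starts=3, seed=1)
        assert fit_hi.params.pk > fit_lo.params.pk
        assert fit_hi.params.y_pc > fit_lo.params.y_pc

    def test_degenerate_table_rejected(self, clean_table):
        broken = clean_table.copy()
        broken["ratio"] = 0.0
        with pytest.raises(ValueError, match="degenerate|zero"):
            IsotopomerFluxModel(broken)

    def test_variant_reduces_free_parameters(self, clean_table):
        res = fit_fluxes(clean_table, variant="no_cycling", n_starts=2, seed=0)
        assert res.params.pk == 0.0
        assert res.n_free == 3


class TestBootstrap:
    def test_noise_free_interval_degenerates(self, clean_table):
        res = fit_fluxes(clean_table, starts=[TRUTH]).bootstrap_ci(n_resamples=50, seed=0)
        for lo, hi in res.ci.values():
            assert hi - lo < 1e-3

    def test_same_seed_identical_intervals(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=2, seed=1)
        a = res.bootstrap_ci(n_resamples=60, seed=9)
        b = res.bootstrap_ci(n_resamples=60, seed=9)
        assert a.ci == b.ci

    def test_interval_brackets_estimate(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=2, seed=1).bootstrap_ci(n_resamples=60, seed=4)
        for k, (lo, hi) in res.ci.items():
            assert lo <= getattr(res.params, k) <= hi

    def test_too_few_resamples_rejected(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=2, seed=1)
        with pytest.raises(ValueError, match="n_resamples"):
            res.bootstrap_ci(n_resamples=10, seed=0)

    def test_summary_mentions_ci(self, noisy_table):
        res = fit_fluxes(noisy_table, n_starts=2, seed=1).bootstrap_ci(n_resamples=50, seed=0)
        text = res.summary()
        assert "ci_low" in text and "f_pdh" in text and "(reference)" in text


class TestCompareModels:
    def test_single_variant_matches_fit(self, noisy_table):
        ranking = compare_models(noisy_table, ("full",), n_starts=2, seed=0)
        direct = fit_fluxes(noisy_table, variant="full", n_starts=2, seed=0)
        assert len(ranking) == 1
        assert ranking[0].aicc == direct.aicc

    def test_cycling_data_prefers_full_model(self, noisy_table):
        ranking = compare_models(noisy_table, ("full", "no_cycling"), n_starts=2, seed=0)
        assert ranking[0].variant == "full"
        assert ranking[0].aicc < ranking[1].aicc

    def test_failed_variant_annotates_ranking(self, noisy_table):
        ranking = compare_models(noisy_table, ("full", "bogus"), n_starts=2, seed=0)
        failed = [r for r in ranking if isinstance(r, FailedFit)]
        assert len(failed) == 1 and failed[0].variant == "bogus"
        assert ranking[-1] is failed[0]


class TestGroupCompare:
    def test_hand_checked_welch_t(self):
        res = group_compare([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert abs(res.statistic) == pytest.approx(3.674, abs=0.001)
        assert res.pvalue == pytest.approx(0.0212, abs=0.0005)

    def test_identical_groups_p_one(self):
        res = group_compare([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert res.pvalue == 1.0

    def test_size_one_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_compare([0.1], [0.2, 0.3])

    def test_flux_parameter_groups(self):
        a = [FluxParameters(0.7, 0.2, 0.1, 0.1), FluxParameters(0.72, 0.22, 0.12, 0.1)]
        b = [FluxParameters(0.6, 0.4, 0.3, 0.1), FluxParameters(0.62, 0.38, 0.32, 0.1)]
        res = group_compare(a, b, flux_name="pk", alternative="less")
        assert res.pvalue < 0.05

    def test_flux_name_required_for_parameter_groups(self):
        a = [FluxParameters(0.7, 0.2, 0.1, 0.1)] * 2
        with pytest.raises(ValueError, match="flux_name"):
            group_compare(a, a)
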