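"""FP curve fitting, IC50 -> K_D conversion, fold changes and agreement."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mutprop.affinity_analysis import (
    DisplacementCurve,
    NON_BINDER,
    SaturationCurve,
    affinity_records_from_table,
    affinity_spearman,
    agreement_table,
    fit_displacement,
    fit_saturation,
    fold_change,
    ic50_to_kd,
    logistic4,
    saturation_model,
)
from mutprop.synthetic_data import SimulationConfig, simulate_fp_curves


class TestSaturation:
    def test_noiseless_round_trip_within_one_percent(self):
        sat, _, truth = simulate_fp_curves(SimulationConfig(seed=3, fp_noise_sd=0.0))
        fit = fit_saturation(sat)
        assert fit.ok
        assert abs(fit.kd / truth.saturation_kd - 1) < 0.01

    def test_excess_protein_limit_agrees_with_hyperbola(self):
        # probe 1000x below kd: quadratic model collapses to the hyperbola
        kd, probe = 1e-6, 1e-9
        protein = np.logspace(-8, -4, 10)
        mp = 50 + 200 * protein / (protein + kd)
        fit = fit_saturation(SaturationCurve(probe, protein, mp))
        assert abs(fit.kd / kd - 1) < 0.02

    def test_flat_series_is_flagged(self):
        curve = SaturationCurve(1e-8, np.logspace(-8, -4, 8), np.full(8, 120.0))
        fit = fit_saturation(curve)
        assert not fit.ok and math.isnan(fit.kd)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_saturation(SaturationCurve(1e-8, [1e-6] * 4, [1.0] * 4))


class TestDisplacement:
    @staticmethod
    def _curve_from_4pl(ic50, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        concs = np.logspace(-8, -3, 12)
        mp = logistic4(np.log10(concs), 200.0, 60.0, math.log10(ic50), 1.0)
        mp = mp + rng.normal(0, noise_sd, mp.shape)
        return DisplacementCurve(concs, mp, 1e-8, 1.5e-6, 1e-6)

    def test_noiseless_ic50_round_trip_within_one_percent(self):
        fit = fit_displacement(self._curve_from_4pl(1e-5))
        assert not fit.non_binder
        assert abs(fit.ic50 / 1e-5 - 1) < 0.01

    def test_two_percent_noise_recovered_within_ten_percent(self):
        fit = fit_displacement(self._curve_from_4pl(1e-5, noise_sd=4.0, seed=7))
        assert abs(fit.ic50 / 1e-5 - 1) < 0.10

    def test_no_displacement_flags_non_binder(self):
        _, curves, _ = simulate_fp_curves(
            SimulationConfig(seed=3), competitor_kds={"nb": 0.1})
        fit = fit_displacement(curves["nb"])
        assert fit.non_binder and math.isinf(fit.ic50)

    def test_flat_plateaus_flag_non_binder(self):
        concs = np.logspace(-8, -3, 12)
        fit = fit_displacement(DisplacementCurve(concs, np.full(12, 150.0), 1e-8, 1e-6, 1e-6))
        assert fit.non_binder

    def test_increasing_mp_is_anomalous(self):
        concs = np.logspace(-8, -3, 12)
        mp = np.linspace(60, 220, 12)
        fit = fit_displacement(DisplacementCurve(concs, mp, 1e-8, 1e-6, 1e-6))
        assert fit.anomalous


class TestIc50ToKd:
    def test_dilute_limit_within_two_permille(self):
        ic50 = 1e-5
        kd = ic50_to_kd(ic50, probe_conc=1e-9, probe_kd=1e-3, protein_conc=1e-9)
        assert abs(kd / ic50 - 1) < 0.002

    def test_never_exceeds_ic50(self):
        for protein in (1e-7, 1e-6, 5e-6):
            kd = ic50_to_kd(1e-5, 1e-8, 1e-6, protein)
            assert kd <= 1e-5

    def test_monotone_in_ic50_and_protein(self):
        kds = [ic50_to_kd(x, 1e-8, 1e-6, 1.5e-6) for x in (1e-6, 3e-6, 1e-5)]
        assert kds == sorted(kds)
        by_protein = [ic50_to_kd(1e-5, 1e-8, 1e-6, p) for p in (1e-7, 1e-6, 3e-6)]
        assert by_protein == sorted(by_protein, reverse=True)

    def test_recovers_planted_ki_from_exact_equilibrium(self):
        # independent oracle: three-species equilibrium solved numerically
        probe, probe_kd = 1e-8, 1e-6
        protein = 1.5e-6

        def bound_probe(i_total, ki):
            def f(p_free):
                pl = p_free * probe / (probe_kd + p_free)
                pi = p_free * i_total / (ki + p_free)
                return p_free + pl + pi - protein
            p_free = brentq(f, 0, protein, rtol=1e-14)
            return p_free * probe / (probe_kd + p_free)

        for ki in (1e-7, 1e-6, 2e-5):
            pl0 = bound_probe(0.0, ki)
            ic50 = brentq(lambda it: bound_probe(it, ki) - pl0 / 2, 1e-12, 1e3, rtol=1e-12)
            assert abs(ic50_to_kd(ic50, probe, probe_kd, protein) / ki - 1) < 0.05

    def test_invalid_inputs_are_errors(self):
        with pytest.raises(ValueError):
            ic50_to_kd(-1.0, 1e-8, 1e-6, 1e-6)
        with pytest.raises(ValueError):
            ic50_to_kd(1e-5, 0.0, 1e-6, 1e-6)


class TestFoldChange:
    def test_keap1_sqstm1_direction(self):
        fc = fold_change(0.9, 23.0)
        assert fc.fold == pytest.approx(1 / 25.6, rel=0.01)
        assert fc.fold < 1 and not fc.capped  # mutation diminishes binding

    def test_non_binding_wild_type_caps_at_plus_4_3(self):
        fc = fold_change(NON_BINDER, 39.0)
        assert (fc.fold, fc.log2_fold, fc.capped) == (20.0, 4.3, True)

    def test_non_binding_mutant_caps_at_minus_4_3(self):
        fc = fold_change(135.0, NON_BINDER)
        assert (fc.fold, fc.log2_fold, fc.capped) == (0.05, -4.3, True)

    def test_equal_affinities(self):
        fc = fold_change(5.0, 5.0)
        assert (fc.fold, fc.log2_fold) == (1.0, 0.0)

    def test_reciprocal_property(self):
        assert fold_change(3.0, 7.0).fold * fold_change(7.0, 3.0).fold == pytest.approx(1.0)

    def test_double_non_binder_is_error(self):
        with pytest.raises(ValueError):
            fold_change(NON_BINDER, NON_BINDER)


class TestAgreement:
    def test_validation_table_gives_19_of_24(self):
        records = affinity_records_from_table()
        assert len(records) == 24
        assert agreement_table(records) == (19, 24, 79)

    def test_agreement_is_order_invariant(self):
        records = affinity_records_from_table()
        assert agreement_table(list(reversed(records))) == agreement_table(records)

    def test_subthreshold_fold_never_agrees(self):
        from mutprop.affinity_analysis import AffinityRecord
        rec = AffinityRecord("b", "x", kd_wt=3.1, kd_mut=4.7, enrichment_score=-6.0)
        assert rec.agrees() is False  # 1.5-fold, below the twofold rule

    def test_empty_input_signalled(self):
        with pytest.raises(ValueError):
            agreement_table([])

    def test_spearman_with_enrichment_scores_is_positive(self):
        assert affinity_spearman(affinity_records_from_table()) > 0
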