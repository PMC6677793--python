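"""Counts-to-concentration conversion, one-site fits, stoichiometry."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpmkit.binding import (
    Isotherm,
    OneSiteBindingModel,
    SpecificActivity,
    compare_conditions,
    cpm_to_concentration,
    dilution_to_specific_activity,
    fit_one_site,
    molar_ratio_per_junction,
    one_site,
)
from tpmkit.errors import DilutionError, FitError, ParameterError
from tpmkit.synth import gen_isotherm, serial_dilutions


class TestUnitConversion:
    def test_zero_counts_zero_concentration(self):
        assert cpm_to_concentration(0.0, SpecificActivity(125.0), 1e-6) == 0.0

    def test_known_dpm_gives_one_millimolar(self):
        # 277,500 dpm in 1 uL at 125 mCi/mmol -> 1 mM = 1000 uM
        conc = cpm_to_concentration(277_500.0, SpecificActivity(125.0), 1e-6)
        assert conc == pytest.approx(1000.0, rel=1e-12)

    @given(counts=st.floats(1.0, 1e7), factor=st.floats(1.5, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_counts_inverse_in_sa(self, counts, factor):
        sa = SpecificActivity(125.0)
        base = cpm_to_concentration(counts, sa, 25e-6)
        assert cpm_to_concentration(counts * factor, sa, 25e-6) == pytest.approx(
            base * factor, rel=1e-9
        )
        assert cpm_to_concentration(counts, SpecificActivity(125.0 * factor), 25e-6) == pytest.approx(
            base / factor, rel=1e-9
        )

    def test_counting_efficiency_scales_dpm(self):
        full = cpm_to_concentration(1000.0, SpecificActivity(125.0, 1.0), 1e-6)
        half = cpm_to_concentration(1000.0, SpecificActivity(125.0, 0.5), 1e-6)
        assert half == pytest.approx(2 * full)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            SpecificActivity(-1.0)
        with pytest.raises(ParameterError):
            SpecificActivity(125.0, 0.0)
        with pytest.raises(ParameterError):
            cpm_to_concentration(-5.0, SpecificActivity(125.0), 1e-6)


class TestDilution:
    def test_hot_stock_to_working_activity_needs_199_fold_cold(self):
        # 25 Ci/mmol diluted to 125 mCi/mmol: 200-fold activity reduction
        ratio = dilution_to_specific_activity(25_000.0, target_mci_per_mmol=125.0)
        assert ratio == pytest.approx(199.0)

    def test_no_cold_leaves_sa_unchanged(self):
        sa = dilution_to_specific_activity(25_000.0, cold_to_hot_ratio=0.0)
        assert sa.value == pytest.approx(25_000.0)

    def test_equimolar_cold_halves_sa(self):
        sa = dilution_to_specific_activity(25_000.0, cold_to_hot_ratio=1.0)
        assert sa.value == pytest.approx(12_500.0)

    def test_unreachable_target_rejected(self):
        with pytest.raises(DilutionError):
            dilution_to_specific_activity(100.0, target_mci_per_mmol=200.0)


def _noiseless_isotherm(kd=2.0, bmax=1.0):
    L = serial_dilutions()
    return Isotherm(pd.DataFrame({"concentration_uM": L, "bound_uM": one_site(L, bmax, kd)}))


class TestOneSiteFit:
    def test_noiseless_hyperbola_recovered_to_machine_precision(self):
        res = fit_one_site(_noiseless_isotherm(kd=2.0, bmax=1.0))
        assert res.kd == pytest.approx(2.0, rel=1e-6)
        assert res.bmax == pytest.approx(1.0, rel=1e-6)

    def test_predicted_curve_has_saturation_limits(self):
        res = fit_one_site(_noiseless_isotherm())
        assert res.predict(np.array([0.0]))[0] == 0.0
        assert res.predict(np.array([1e9]))[0] == pytest.approx(res.bmax, rel=1e-6)
        L = np.linspace(0.1, 60, 50)
        assert np.all(np.diff(res.predict(L)) > 0)

    def test_all_zero_bound_is_fit_error(self):
        L = serial_dilutions()
        iso = Isotherm(pd.DataFrame({"concentration_uM": L, "bound_uM": np.zeros_like(L)}))
        with pytest.raises(FitError):
            fit_one_site(iso)

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({"concentration_uM": [1.0, 2.0, 4.0], "bound_uM": [0.3, 0.5, 0.6]})
        with pytest.raises(ParameterError):
            OneSiteBindingModel(df)

    def test_poisson_noise_recovery_within_quarter(self):
        df, truth = gen_isotherm(seed=11, kd=2.0, bmax_uM=5.0, n_replicates=4)
        res = fit_one_site(Isotherm(df))
        assert res.kd == pytest.approx(truth["kd_uM"], rel=0.25)

    def test_ill_conditioned_range_warns(self):
        L = np.array([0.01, 0.02, 0.04, 0.08, 0.16])
        iso = Isotherm(pd.DataFrame({"concentration_uM": L, "bound_uM": one_site(L, 1.0, 50.0)}))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit_one_site(iso)

    def test_depletion_corrected_mode_recovers_truth(self):
        from tpmkit.binding import one_site_depleted

        Ltot = serial_dilutions()
        bound = one_site_depleted(Ltot, 5.0, 2.0)
        iso = Isotherm(pd.DataFrame({"concentration_uM": Ltot, "bound_uM": bound}))
        res = OneSiteBindingModel(iso, depletion=True).fit()
        assert res.kd == pytest.approx(2.0, rel=1e-6)
        assert res.bmax == pytest.approx(5.0, rel=1e-6)


class TestStoichiometry:
    def test_simple_ratio(self):
        assert molar_ratio_per_junction(5.0, 5.0) == pytest.approx(1.0)
        assert molar_ratio_per_junction(0.0, 5.0) == 0.0

    def test_finite_filament_correction(self):
        assert molar_ratio_per_junction(4.5, 5.0, junctions_per_dimer=0.9) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            molar_ratio_per_junction(1.0, 0.0)
        with pytest.raises(ParameterError):
            molar_ratio_per_junction(1.0, 5.0, junctions_per_dimer=1.5)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_joint_unit_scaling(self, scale):
        base = molar_ratio_per_junction(4.0, 5.0)
        assert molar_ratio_per_junction(4.0 * scale, 5.0 * scale) == pytest.approx(base, rel=1e-12)

    def test_saturating_generator_isotherm_gives_unit_stoichiometry(self):
        df, truth = gen_isotherm(seed=21, kd=2.0, bmax_uM=5.0, tpm_dimer_uM=5.0)
        res = fit_one_site(Isotherm(df))
        ratio = res.molar_ratio_per_junction(truth["tpm_dimer_uM"])
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestConditions:
    def test_identical_isotherms_no_flag(self):
        iso = _noiseless_isotherm(kd=2.0, bmax=5.0)
        cmp = compare_conditions(iso, iso)
        np.testing.assert_allclose(cmp.table["difference"], 0.0, atol=1e-12)
        assert not cmp.background_level

    def test_background_level_post_condition_flagged(self):
        df, _ = gen_isotherm(seed=5, post_fraction=0.05)
        pre = Isotherm(df[df.condition == "pre_incubation"].reset_index(drop=True))
        post = Isotherm(
            df[df.condition == "post_incubation"].reset_index(drop=True),
            condition="post_incubation",
        )
        cmp = compare_conditions(pre, post)
        assert cmp.background_level
        assert cmp.table["difference"].mean() > 0

    def test_post_above_pre_reported_not_flagged(self):
        pre = _noiseless_isotherm(kd=2.0, bmax=1.0)
        post = Isotherm(
            pre.data.assign(bound_uM=pre.data["bound_uM"] * 1.5),
            condition="post_incubation",
        )
        cmp = compare_conditions(pre, post)
        assert cmp.post_exceeds_pre and not cmp.background_level

    def test_disjoint_ranges_rejected(self):
        from tpmkit.errors import ComparisonError

        pre = _noiseless_isotherm()
        post = Isotherm(
            pre.data.assign(concentration_uM=pre.data["concentration_uM"] * 1000),
            condition="post_incubation",
        )
        with pytest.raises(ComparisonError):
            compare_conditions(pre, post)
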