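"""Rate-constant extraction, Kd derivation, salt dependence and LFER."""

import numpy as np
import pytest

from foldbind.containers import (
    BindingKinetics,
    DisplacementSeries,
    FitError,
    FluorescenceTrace,
    FoldbindError,
    PseudoFirstOrderSeries,
    SaltSeries,
)
from foldbind.kinetics import (
    compute_kd,
    fit_association,
    fit_displacement,
    fit_salt_dependence,
    fit_single_exponential,
    fold_change,
    lfer_regression,
    pearson_r2,
)
from foldbind.synthetic import KineticGroundTruth, gen_association_series, gen_displacement_series

# Measured rate constants for the five peptide variants (kon in µM⁻¹s⁻¹,
# koff in s⁻¹): wild type, two destabilised and two stabilised helices.
VARIANT_RATES = {
    "WT": (240.0, 4.0, 0.18, 0.01),
    "R266G": (230.0, 15.0, 0.70, 0.01),
    "R266A": (246.0, 15.0, 0.383, 0.001),
    "D267A": (222.0, 13.0, 0.07, 0.01),
    "D267L": (235.0, 19.0, 0.030, 0.001),
}


def make_trace(kobs, amplitude=1.0, offset=5.0, n=200):
    t = np.linspace(0.0, 5.0 / kobs, n)[1:]
    return FluorescenceTrace(
        times=t, signal=offset + amplitude * np.exp(-kobs * t), partner_conc=2.0
    )


class TestSingleExponential:
    def test_noiseless_recovery_to_solver_tolerance(self):
        fit = fit_single_exponential(make_trace(50.0))
        assert fit.kobs == pytest.approx(50.0, rel=1e-6)

    def test_constant_trace_flagged(self):
        trace = FluorescenceTrace(
            times=np.linspace(0, 1, 50)[1:], signal=np.full(49, 5.0), partner_conc=2.0
        )
        with pytest.raises(FitError, match="amplitude"):
            fit_single_exponential(trace)

    def test_amplitude_below_noise_flagged(self, rng):
        """An exponential buried well below the noise floor yields no kobs."""
        t = np.linspace(0, 1, 100)[1:]
        signal = 5.0 + 0.02 * np.exp(-5.0 * t) + rng.normal(0, 0.1, 99)
        trace = FluorescenceTrace(times=t, signal=signal, partner_conc=2.0)
        with pytest.raises(FitError):
            fit_single_exponential(trace)


class TestAssociation:
    def test_exact_points_recover_slope_and_intercept(self):
        series = PseudoFirstOrderSeries(
            concs=np.arange(1.0, 7.0), kobs_values=240.0 * np.arange(1.0, 7.0) + 0.18
        )
        fit = fit_association(series)
        assert fit.kon == pytest.approx(240.0)
        assert fit.intercept == pytest.approx(0.18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_exact_line_with_absent_se(self):
        series = PseudoFirstOrderSeries(concs=[1.0, 2.0], kobs_values=[240.0, 480.0])
        fit = fit_association(series)
        assert fit.kon == pytest.approx(240.0)
        assert fit.kon_se is None and fit.intercept_se is None

    def test_singular_design_rejected(self):
        with pytest.raises(FoldbindError):
            PseudoFirstOrderSeries(concs=[2.0, 2.0, 2.0], kobs_values=[1.0, 2.0, 3.0])


class TestDisplacement:
    def test_constant_series_returns_asymptote(self):
        series = DisplacementSeries(
            displacer_concs=[5.0, 20.0, 40.0, 60.0], kobs_values=[0.18] * 4
        )
        fit = fit_displacement(series)
        assert fit.koff == pytest.approx(0.18, rel=1e-6)
        assert abs(fit.amplitude) < 1e-6

    def test_exact_exponential_recovered(self):
        d = np.arange(5.0, 65.0, 5.0)
        series = DisplacementSeries(d, 0.18 + 2.0 * np.exp(-d / 10.0))
        fit = fit_displacement(series)
        assert fit.koff == pytest.approx(0.18, rel=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-5)
        assert fit.decay_scale == pytest.approx(10.0, rel=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(FoldbindError, match="3 points"):
            DisplacementSeries(displacer_concs=[5.0, 10.0], kobs_values=[1.0, 0.5])


class TestComputeKd:
    @pytest.mark.parametrize(
        "variant,expected_kd",
        [("R266G", 3.0), ("D267A", 0.32), ("D267L", 0.13)],
    )
    def test_measured_rates_reproduce_tabulated_kd(self, variant, expected_kd):
        from foldbind.pipeline import round_sig

        kon, kon_se, koff, koff_se = VARIANT_RATES[variant]
        kd, _ = compute_kd(kon, koff, kon_se, koff_se)
        assert kd == pytest.approx(koff / kon * 1e3)  # exact before rounding
        assert round_sig(kd, 2) == expected_kd  # 2 significant figures

    def test_propagated_se_matches_tabulated(self):
        kon, kon_se, koff, koff_se = VARIANT_RATES["R266G"]
        _, kd_se = compute_kd(kon, koff, kon_se, koff_se)
        assert kd_se == pytest.approx(0.2, abs=0.005)

    def test_zero_koff_gives_zero_kd(self):
        kd, kd_se = compute_kd(240.0, 0.0, 4.0, 0.0)
        assert kd == 0.0 and kd_se is None


class TestFoldChange:
    def test_salt_dependent_koff_ratio(self):
        assert fold_change(1.78, 0.18) == pytest.approx(9.9, abs=0.02)

    def test_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_kon_endpoints_ratio(self):
        # ~40-fold decrease across the salt range
        assert fold_change(413.0, 10.6) == pytest.approx(39.0, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(FoldbindError):
            fold_change(1.0, 0.0)


class TestSaltDependence:
    def test_salt_independent_series_gives_flat_basal(self):
        series = SaltSeries([100, 200, 400, 800], [5.0, 5.0, 5.0, 5.0])
        fit = fit_salt_dependence(series)
        assert fit.basal_rate == pytest.approx(5.0)
        assert fit.slope_beta == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_data_recovered(self):
        ionic = np.array([0.1, 0.2, 0.5, 0.8])
        rates = np.exp(np.log(5.0) + 1.0 * ionic**-0.5)
        fit = fit_salt_dependence(SaltSeries(ionic * 1e3, rates))
        assert fit.basal_rate == pytest.approx(5.0, rel=1e-9)
        assert fit.slope_beta == pytest.approx(1.0, rel=1e-9)

    def test_stabilised_variant_association_basal_rate(self):
        """Salt titration of the helix-stabilised variant: basal kon ~ 10."""
        series = SaltSeries(
            [100, 150, 200, 300, 500, 800],
            [178, 149, 142, 81, 45, 22],
            rate_kind="association",
        )
        fit = fit_salt_dependence(series)
        # closed-form OLS oracle on ln k vs I^(-1/2): intercept e^2.34 ~ 10.4
        x = (series.nacl_mM / 1e3) ** -0.5
        y = np.log(series.rate_values)
        dx = x - x.mean()
        slope = (dx @ (y - y.mean())) / (dx @ dx)
        intercept = y.mean() - slope * x.mean()
        assert fit.basal_rate == pytest.approx(np.exp(intercept), rel=1e-9)
        assert fit.basal_rate == pytest.approx(10.4, abs=0.05)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(FoldbindError):
            fit_salt_dependence(SaltSeries([100, 200, 400], [1.0, 0.0, 2.0]))


def _variant_kinetics(use_tabulated_kd=False):
    rows = []
    kd_tab = {"WT": 0.8, "R266G": 3.0, "R266A": 1.5, "D267A": 0.32, "D267L": 0.13}
    for vid, (kon, kon_se, koff, koff_se) in VARIANT_RATES.items():
        kd, kd_se = compute_kd(kon, koff, kon_se, koff_se)
        rows.append(
            BindingKinetics(vid, kon, kon_se, koff, koff_se, kd, kd_se)
        )
    kd_values = [kd_tab[r.variant_id] for r in rows] if use_tabulated_kd else None
    return rows, kd_values


class TestLfer:
    def test_identical_kon_gives_slopes_zero_one(self):
        rows = []
        for i, koff in enumerate([0.03, 0.1, 0.3, 1.0]):
            kd, _ = compute_kd(240.0, koff)
            rows.append(BindingKinetics(f"v{i}", 240.0, None, koff, None, kd, None))
        fit = lfer_regression(rows)
        assert fit.slope_kon_vs_kd == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_koff_vs_kd == pytest.approx(1.0, rel=1e-12)

    def test_slope_difference_identity_with_derived_kd(self):
        rows, _ = _variant_kinetics()
        fit = lfer_regression(rows)
        assert fit.slope_koff_vs_kd - fit.slope_kon_vs_kd == pytest.approx(
            1.0, abs=1e-12
        )

    def test_five_variant_slopes_match_closed_form_ols(self):
        """On tabulated affinities the dissociation-side slope is ~1.02 and the
        association-side slope ~0.008: affinity changes are koff-driven."""
        rows, kd_values = _variant_kinetics(use_tabulated_kd=True)
        fit = lfer_regression(rows, kd_values=kd_values)
        x = np.log10(kd_values)
        for slope, rates in (
            (fit.slope_kon_vs_kd, [r.kon for r in rows]),
            (fit.slope_koff_vs_kd, [r.koff for r in rows]),
        ):
            y = np.log10(rates)
            dx = x - x.mean()
            assert slope == pytest.approx((dx @ (y - y.mean())) / (dx @ dx), rel=1e-9)
        assert fit.slope_koff_vs_kd == pytest.approx(1.02, abs=0.005)
        assert fit.slope_kon_vs_kd == pytest.approx(0.008, abs=0.001)

    def test_fewer_than_three_variants_rejected(self):
        rows, _ = _variant_kinetics()
        with pytest.raises(FoldbindError):
            lfer_regression(rows[:2])


class TestPearsonR2:
    def test_collinear_is_one(self):
        assert pearson_r2([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert pearson_r2([-1, 0, 1], [1, -2, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_helicity_vs_log_koff(self):
        """Calibrated helicities vs log10 koff across the five variants."""
        hel = [2, 3, 5, 11, 14]
        koff = [0.70, 0.383, 0.18, 0.07, 0.030]
        r2 = pearson_r2(hel, np.log10(koff))
        assert r2 == pytest.approx(0.964, abs=0.001)

    def test_constant_input_flagged(self):
        with pytest.raises(FoldbindError, match="constant"):
            pearson_r2([1.0, 1.0, 1.0], [1, 2, 3])


class TestFullChainRecovery:
    def test_kd_recovered_within_5_percent_at_1_percent_noise(self):
        """Association + displacement generation -> fits -> Kd, at 1% noise."""
        truth = KineticGroundTruth(kon=240.0, koff=0.18, seed=11)
        concs = np.arange(1.0, 7.0)
        assoc_series = gen_association_series(
            truth, concs, noise_sd=0.01 * truth.kon * concs.mean()
        )
        disp_series = gen_displacement_series(
            truth,
            decay_scale=10.0,
            initial_kobs=10 * truth.koff,
            displacer_concs=np.arange(5.0, 65.0, 5.0),
            noise_sd=0.01 * truth.koff,
        )
        assoc = fit_association(assoc_series)
        disp = fit_displacement(disp_series)
        kd, _ = compute_kd(assoc.kon, disp.koff, assoc.kon_se, disp.koff_se)
        kd_true = truth.koff / truth.kon * 1e3
        assert kd == pytest.approx(kd_true, rel=0.05)
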