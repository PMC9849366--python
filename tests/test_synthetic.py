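"""Generator correctness: closed forms, determinism, and parameter recovery."""

import numpy as np
import pytest

from foldbind.containers import FoldbindError
from foldbind.kinetics import fit_association, fit_displacement, fit_single_exponential
from foldbind.refdata import FIXTURE_SEQUENCE, random_coil_for_sequence
from foldbind.structure import compute_scs, helicity_from_mre, region_helicity
from foldbind.synthetic import (
    HelixProfile,
    ItcGroundTruth,
    KineticGroundTruth,
    gen_association_series,
    gen_cd_spectrum,
    gen_displacement_series,
    gen_itc_isotherm,
    gen_shift_table,
    gen_trace,
)

TIMES = np.linspace(0.0, 0.02, 200)[1:]


class TestGenTrace:
    def test_noiseless_log_residual_slope_is_minus_kobs(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        trace = gen_trace(truth, partner_conc=1.0, times=TIMES)
        log_resid = np.log(trace.signal - truth.baseline)
        slope = np.polyfit(trace.times, log_resid, 1)[0]
        assert slope == pytest.approx(-240.18, rel=1e-9)
        assert trace.true_kobs == pytest.approx(240.18)

    def test_zero_amplitude_gives_constant_baseline(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18, fluorescence_amplitude=0.0)
        trace = gen_trace(truth, 1.0, TIMES)
        assert np.all(trace.signal == truth.baseline)

    def test_non_increasing_times_rejected(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        with pytest.raises(FoldbindError, match="increasing"):
            gen_trace(truth, 1.0, [0.0, 0.1, 0.1, 0.2] + list(range(1, 10)))

    def test_seed_determinism_bit_identical(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18, noise_sd=0.05, seed=42)
        a = gen_trace(truth, 2.0, TIMES)
        b = gen_trace(truth, 2.0, TIMES)
        assert np.array_equal(a.signal, b.signal)

    def test_noisy_trace_refit_matches_grid_search_oracle(self):
        """1% amplitude noise: refit recovers kobs within 2% and agrees with a
        brute-force grid search over kobs minimising the SSE."""
        truth = KineticGroundTruth(kon=240.0, koff=0.18, noise_sd=0.01, seed=1)
        kobs_true = 2 * 240.0 + 0.18
        times = np.linspace(0.0, 5.0 / kobs_true, 200)[1:]
        trace = gen_trace(truth, 2.0, times)
        fit = fit_single_exponential(trace)
        assert fit.kobs == pytest.approx(kobs_true, rel=0.02)
        # oracle: for each kobs on a grid, offset/amplitude solve linearly
        grid = np.linspace(0.9 * kobs_true, 1.1 * kobs_true, 2001)
        sse = []
        for k in grid:
            X = np.vstack([np.ones_like(times), np.exp(-k * times)]).T
            coef, *_ = np.linalg.lstsq(X, trace.signal, rcond=None)
            sse.append(((trace.signal - X @ coef) ** 2).sum())
        kobs_grid = grid[int(np.argmin(sse))]
        assert fit.kobs == pytest.approx(kobs_grid, rel=1e-3)


class TestGenAssociationSeries:
    def test_noiseless_linear_law(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        series = gen_association_series(truth, [1, 2, 3, 4, 5, 6])
        expected = [240.18, 480.18, 720.18, 960.18, 1200.18, 1440.18]
        assert series.kobs_values == pytest.approx(expected)

    def test_zero_kon_rejected(self):
        with pytest.raises(FoldbindError):
            KineticGroundTruth(kon=0.0, koff=0.18)

    def test_tiny_kon_gives_nearly_constant_series(self):
        truth = KineticGroundTruth(kon=1e-12, koff=0.18)
        series = gen_association_series(truth, [1, 2, 3])
        assert series.kobs_values == pytest.approx([0.18] * 3)

    def test_fewer_than_two_concentrations_rejected(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        with pytest.raises(FoldbindError, match="distinct"):
            gen_association_series(truth, [2.0, 2.0])

    def test_noisy_slope_recovery_against_closed_form_ols(self):
        """N(0, 5) noise per point: the fitted slope equals the closed-form
        OLS slope and lies within 3 exact sampling SEs of the truth."""
        truth = KineticGroundTruth(kon=240.0, koff=0.18, seed=7)
        series = gen_association_series(truth, [1, 2, 3, 4, 5, 6], noise_sd=5.0)
        fit = fit_association(series)
        x, y = series.concs, series.kobs_values
        dx = x - x.mean()
        slope_oracle = (dx @ (y - y.mean())) / (dx @ dx)
        assert fit.kon == pytest.approx(slope_oracle, rel=1e-12)
        se_exact = 5.0 / np.sqrt(dx @ dx)  # known noise sd
        assert abs(fit.kon - 240.0) < 3 * se_exact


class TestGenDisplacementSeries:
    def test_closed_form_at_saturating_displacer(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        series = gen_displacement_series(
            truth, decay_scale=10.0, initial_kobs=2.18, displacer_concs=[5, 30, 60]
        )
        assert series.kobs_values[-1] == pytest.approx(0.18 + 2.0 * np.exp(-6.0))

    def test_initial_equal_to_koff_gives_constant_series(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        series = gen_displacement_series(truth, 10.0, 0.18, [5, 10, 20, 40])
        assert series.kobs_values == pytest.approx([0.18] * 4)

    def test_non_positive_decay_scale_rejected(self):
        truth = KineticGroundTruth(kon=240.0, koff=0.18)
        with pytest.raises(FoldbindError, match="decay_scale"):
            gen_displacement_series(truth, 0.0, 2.18, [5, 10, 20])

    def test_noisy_asymptote_recovery(self):
        """Noise at 1% of koff: the asymptote fit recovers koff within 5%,
        agreeing with a two-stage grid oracle (asymptote grid + log-linear)."""
        truth = KineticGroundTruth(kon=240.0, koff=0.18, seed=3)
        series = gen_displacement_series(
            truth, 10.0, 2.18, np.arange(5.0, 65.0, 5.0), noise_sd=0.01 * 0.18
        )
        fit = fit_displacement(series)
        assert fit.koff == pytest.approx(0.18, rel=0.05)
        d, y = series.displacer_concs, series.kobs_values
        best_a, best_sse = None, np.inf
        for a in np.linspace(0.0, y.min() * 0.999, 4000):
            z = np.log(y - a)
            coef = np.polyfit(d, z, 1)
            pred = a + np.exp(np.polyval(coef, d))
            sse = ((y - pred) ** 2).sum()
            if sse < best_sse:
                best_a, best_sse = a, sse
        assert fit.koff == pytest.approx(best_a, abs=0.01 * 0.18)


class TestGenItcIsotherm:
    def test_zero_enthalpy_gives_zero_heats(self):
        exp = gen_itc_isotherm(ItcGroundTruth(dh=0.0))
        assert np.allclose(exp.heats, 0.0)

    def test_stoichiometric_limit_steps_at_molar_ratio_one(self):
        """Kd -> 0 with n=1: constant heats until molar ratio 1, then ~0."""
        truth = ItcGroundTruth(kd=1e-6, dh=-68.0, n=1.0)
        exp = gen_itc_isotherm(truth)
        vols = exp.injection_volumes
        ratio = np.cumsum(vols) * truth.syringe_conc / (
            truth.cell_volume * truth.cell_conc
        )
        pre = exp.heats[1:][ratio[1:] < 0.8]
        post = exp.heats[1:][ratio[1:] > 1.3]
        assert np.std(pre) / np.abs(np.mean(pre)) < 0.02
        assert np.all(np.abs(post) < 0.05 * np.abs(np.mean(pre)))

    def test_determinism(self):
        truth = ItcGroundTruth(heat_noise_sd=0.1, seed=5)
        assert np.array_equal(
            gen_itc_isotherm(truth).heats, gen_itc_isotherm(truth).heats
        )


class TestGenCdSpectrum:
    @pytest.mark.parametrize(
        "fraction,mre222", [(0.0, -3000.0), (1.0, -42000.0), (0.13, -8070.0)]
    )
    def test_anchor_points_at_222nm(self, fraction, mre222):
        spectrum = gen_cd_spectrum(fraction)
        assert spectrum.mre_at(222.0) == pytest.approx(mre222)

    def test_round_trip_through_helicity(self):
        assert helicity_from_mre(gen_cd_spectrum(0.13)) == pytest.approx(13.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(FoldbindError, match="helix_fraction"):
            gen_cd_spectrum(1.2)


class TestGenShiftTable:
    def setup_method(self):
        self.rc = random_coil_for_sequence(FIXTURE_SEQUENCE)
        self.n = len(FIXTURE_SEQUENCE)

    def test_zero_fraction_gives_zero_scs(self):
        profile = HelixProfile(FIXTURE_SEQUENCE, np.zeros(self.n))
        table = gen_shift_table(profile, self.rc)
        scs = compute_scs(table, self.rc)
        assert np.allclose(scs.scs_ca_ppm, 0.0)

    def test_full_helix_gives_reference_scs(self):
        profile = HelixProfile(FIXTURE_SEQUENCE, np.ones(self.n))
        scs = compute_scs(gen_shift_table(profile, self.rc), self.rc)
        assert np.allclose(scs.scs_ca_ppm, 3.1)

    def test_missing_random_coil_residue_named(self):
        profile = HelixProfile(FIXTURE_SEQUENCE, np.zeros(self.n))
        short = random_coil_for_sequence(FIXTURE_SEQUENCE[:-1])
        with pytest.raises(FoldbindError, match="272"):
            gen_shift_table(profile, short)

    def test_region_mean_flows_to_downstream_helicity(self):
        """Region mean SCS of 0.5 ppm corresponds to ~16% helix downstream."""
        fractions = np.zeros(self.n)
        numbers = np.arange(244, 244 + self.n)
        fractions[(numbers >= 262) & (numbers <= 266)] = 0.5 / 3.1
        profile = HelixProfile(FIXTURE_SEQUENCE, fractions)
        scs = compute_scs(gen_shift_table(profile, self.rc), self.rc)
        hel = region_helicity(scs, (262, 266))
        assert hel.percent_helix == pytest.approx(100 * 0.5 / 3.1, rel=1e-9)
        assert round(hel.percent_helix) == 16
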