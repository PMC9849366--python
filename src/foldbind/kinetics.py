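"""Binding-kinetics models for coupled folding and binding.

The workhorse experiment is stopped-flow fluorescence under pseudo-first-order
mixing: each mixing yields a single-exponential trace whose rate constant
kobs is linear in titrant concentration for the association arm
(kobs = kon·[partner] + koff), while displacement of a preformed labelled
complex by excess unlabelled competitor yields kobs values that decay to the
dissociation rate constant koff. The equilibrium constant follows as
Kd = koff/kon. Two further analyses build on the fitted rate constants:

* ionic-strength dependence — ln k regressed on I^(−1/2) (the high-screening
  Debye–Hückel limit), whose intercept exp(β₀) is the *basal* rate constant,
  i.e. the rate with electrostatic steering fully screened;
* the linear free-energy relationship (LFER) — log kon and log koff regressed
  on log Kd across variants, separating association- and dissociation-side
  contributions to affinity changes.

Every fit is exposed both as a statsmodels-style model object
(``Model(data).fit() -> Results``) and as a plain function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .containers import (
    BindingKinetics,
    DisplacementSeries,
    FitError,
    FluorescenceTrace,
    FoldbindError,
    PseudoFirstOrderSeries,
    SaltSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SingleExponentialModel",
    "RateFitResults",
    "AssociationModel",
    "AssociationResults",
    "DisplacementModel",
    "DisplacementResults",
    "SaltDependenceModel",
    "BasalRateResults",
    "LferModel",
    "LferResults",
    "fit_single_exponential",
    "fit_association",
    "fit_displacement",
    "fit_salt_dependence",
    "lfer_regression",
    "compute_kd",
    "fold_change",
    "pearson_r2",
]


# ---------------------------------------------------------------------------
# single-exponential trace fit
# ---------------------------------------------------------------------------

@dataclass
class RateFitResults:
    """Result of fitting signal = offset + amplitude·exp(−kobs·t)."""

    kobs: float
    kobs_se: float
    amplitude: float
    offset: float
    residual_sse: float
    n_points: int

    def summary(self) -> str:
        return (
            "Single-exponential trace fit\n"
            f"  kobs      {self.kobs:.6g} s^-1  (SE {self.kobs_se:.2g})\n"
            f"  amplitude {self.amplitude:.6g}\n"
            f"  offset    {self.offset:.6g}\n"
            f"  SSE       {self.residual_sse:.4g}  ({self.n_points} points)"
        )


class SingleExponentialModel:
    """Fit one averaged stopped-flow trace to a single exponential.

    The model is ``signal(t) = offset + amplitude·exp(−kobs·t)``, valid under
    pseudo-first-order conditions (partner ≥ 10× labelled species; a warning
    is logged otherwise). Initialisation estimates kobs from the half-amplitude
    crossing time (kobs ≈ ln 2 / t_half) and the offset from the mean of the
    final 5% of the trace.
    """

    def __init__(self, trace: FluorescenceTrace):
        self.trace = trace
        if not trace.is_pseudo_first_order:
            logger.warning(
                "partner conc %.3g uM is below 10x labeled conc %.3g uM: "
                "pseudo-first-order assumption questionable",
                trace.partner_conc,
                trace.labeled_conc,
            )

    @staticmethod
    def _model(t: np.ndarray, offset: float, amplitude: float, kobs: float):
        return offset + amplitude * np.exp(-kobs * t)

    def _initial_guess(self) -> Tuple[float, float, float]:
        t, y = self.trace.times, self.trace.signal
        n_tail = max(1, int(0.05 * y.size))
        offset0 = float(np.mean(y[-n_tail:]))
        amplitude0 = float(y[0] - offset0)
        # half-amplitude crossing -> kobs ~ ln2 / t_half
        if amplitude0 != 0.0:
            half = offset0 + amplitude0 / 2.0
            crossing = np.nonzero(
                np.sign(y - half) != np.sign(y[0] - half)
            )[0]
            t_half = t[crossing[0]] if crossing.size else t[t.size // 2]
        else:
            t_half = t[t.size // 2]
        t_half = max(float(t_half), float(t[1] - t[0]))
        return offset0, amplitude0, float(np.log(2.0) / t_half)

    def fit(self) -> RateFitResults:
        t, y = self.trace.times, self.trace.signal
        p0 = self._initial_guess()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    self._model, t, y, p0=p0, maxfev=10000
                )
        except RuntimeError as exc:  # pragma: no cover - rare
            raise FitError(f"single-exponential fit did not converge: {exc}")
        offset, amplitude, kobs = popt
        resid = y - self._model(t, *popt)
        sse = float(resid @ resid)
        noise = float(np.std(resid, ddof=3)) if y.size > 3 else 0.0
        if abs(amplitude) < 3.0 * noise or amplitude == 0.0:
            raise FitError(
                "amplitude indistinguishable from zero "
                f"(|A|={abs(amplitude):.3g}, 3*noise={3 * noise:.3g}); "
                "no kobs reported"
            )
        if kobs <= 0:
            raise FitError(f"fitted kobs {kobs:.3g} is non-positive")
        kobs_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
        return RateFitResults(
            kobs=float(kobs),
            kobs_se=kobs_se,
            amplitude=float(amplitude),
            offset=float(offset),
            residual_sse=sse,
            n_points=int(y.size),
        )


def fit_single_exponential(trace: FluorescenceTrace) -> RateFitResults:
    """Extract kobs from one trace; see :class:`SingleExponentialModel`."""
    return SingleExponentialModel(trace).fit()


# ---------------------------------------------------------------------------
# association arm: kobs linear in titrant concentration
# ---------------------------------------------------------------------------

@dataclass
class AssociationResults:
    """OLS fit of kobs on concentration: slope = kon, intercept ≈ koff."""

    kon: float  # µM⁻¹ s⁻¹
    kon_se: Optional[float]
    intercept: float  # s⁻¹
    intercept_se: Optional[float]
    r_squared: float
    n_points: int

    def summary(self) -> str:
        se = "n/a" if self.kon_se is None else f"{self.kon_se:.2g}"
        return (
            "Association kinetics (kobs vs concentration, OLS)\n"
            f"  kon       {self.kon:.6g} uM^-1 s^-1  (SE {se})\n"
            f"  intercept {self.intercept:.6g} s^-1\n"
            f"  R^2       {self.r_squared:.4f}  ({self.n_points} points)"
        )


class AssociationModel:
    """Ordinary least squares of the pseudo-first-order rate law."""

    def __init__(self, series: PseudoFirstOrderSeries):
        self.series = series

    def fit(self) -> AssociationResults:
        x, y = self.series.concs, self.series.kobs_values
        if np.unique(x).size < 2:
            raise FoldbindError("singular design: all concentrations equal")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        if x.size > 2:
            intercept_se, slope_se = (float(s) for s in res.bse)
        else:
            # two points define the line exactly; SE is undefined
            intercept_se = slope_se = None
        return AssociationResults(
            kon=float(slope),
            kon_se=slope_se,
            intercept=float(intercept),
            intercept_se=intercept_se,
            r_squared=float(res.rsquared),
            n_points=int(x.size),
        )


def fit_association(series: PseudoFirstOrderSeries) -> AssociationResults:
    """kon as the slope of kobs versus titrant concentration."""
    return AssociationModel(series).fit()


# ---------------------------------------------------------------------------
# displacement arm: decay to the koff asymptote
# ---------------------------------------------------------------------------

@dataclass
class DisplacementResults:
    """Fit of kobs(d) = koff + A·exp(−d/c); the asymptote estimates koff."""

    koff: float
    koff_se: float
    amplitude: float
    decay_scale: float
    residual_sse: float
    n_points: int

    def summary(self) -> str:
        return (
            "Displacement kinetics (decay to asymptote)\n"
            f"  koff        {self.koff:.6g} s^-1  (SE {self.koff_se:.2g})\n"
            f"  amplitude   {self.amplitude:.6g} s^-1\n"
            f"  decay scale {self.decay_scale:.6g} uM\n"
            f"  SSE         {self.residual_sse:.4g}  ({self.n_points} points)"
        )


class DisplacementModel:
    """Three-parameter exponential decay with a free asymptote.

    Initialisation: asymptote ← min(kobs), amplitude ← range, decay scale ←
    median displacer concentration. A non-decreasing series (Spearman ρ ≥ 0)
    triggers a warning since the asymptote then carries little information.
    """

    def __init__(self, series: DisplacementSeries):
        self.series = series
        if series.displacer_concs.size >= 3 and np.ptp(series.kobs_values) > 0:
            rho = stats.spearmanr(series.displacer_concs, series.kobs_values)[0]
            if not (rho < 0):
                logger.warning(
                    "displacement series is not overall decreasing "
                    "(Spearman rho=%.2f); koff asymptote may be ill-determined",
                    rho,
                )

    @staticmethod
    def _model(d: np.ndarray, koff: float, amplitude: float, scale: float):
        return koff + amplitude * np.exp(-d / scale)

    def fit(self) -> DisplacementResults:
        d, y = self.series.displacer_concs, self.series.kobs_values
        p0 = (float(y.min()), float(y.max() - y.min()), float(np.median(d)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    self._model,
                    d,
                    y,
                    p0=p0,
                    maxfev=20000,
                    bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                )
        except RuntimeError as exc:
            raise FitError(f"displacement fit did not converge: {exc}")
        koff, amplitude, scale = popt
        if koff <= 0:
            raise FitError(f"fitted koff {koff:.3g} is non-positive")
        resid = y - self._model(d, *popt)
        koff_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
        return DisplacementResults(
            koff=float(koff),
            koff_se=koff_se,
            amplitude=float(amplitude),
            decay_scale=float(scale),
            residual_sse=float(resid @ resid),
            n_points=int(y.size),
        )


def fit_displacement(series: DisplacementSeries) -> DisplacementResults:
    """koff as the asymptote of the displacement kobs decay."""
    return DisplacementModel(series).fit()


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def compute_kd(
    kon: float,
    koff: float,
    kon_se: Optional[float] = None,
    koff_se: Optional[float] = None,
) -> Tuple[float, Optional[float]]:
    """Kd in nM from kon (µM⁻¹ s⁻¹) and koff (s⁻¹), with propagated SE.

    Kd = koff/kon × 10³ converts the µM-scale ratio to nM. The standard error
    combines relative errors in quadrature:
    SE(Kd) = Kd·sqrt((SE_kon/kon)² + (SE_koff/koff)²).

    A non-positive koff yields Kd = 0 (koff = 0) with a warning, since only an
    upper bound would be meaningful.
    """
    if kon <= 0:
        raise FoldbindError("kon must be positive")
    if koff < 0:
        raise FoldbindError("koff must be non-negative")
    kd = koff / kon * 1e3
    if koff == 0:
        logger.warning("koff is zero: Kd reported as 0, upper bound unavailable")
        return 0.0, None
    if kon_se is None or koff_se is None:
        return float(kd), None
    kd_se = kd * np.sqrt((kon_se / kon) ** 2 + (koff_se / koff) ** 2)
    return float(kd), float(kd_se)


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio rate_a/rate_b (report at 2 significant figures)."""
    if rate_b == 0:
        raise FoldbindError("fold change undefined for zero denominator")
    return rate_a / rate_b


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise FoldbindError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FoldbindError("correlation undefined for constant input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def make_binding_kinetics(
    variant_id: str,
    association: AssociationResults,
    displacement: DisplacementResults,
) -> BindingKinetics:
    """Assemble a Table-1-style row from the two fitted arms."""
    kd, kd_se = compute_kd(
        association.kon, displacement.koff, association.kon_se, displacement.koff_se
    )
    return BindingKinetics(
        variant_id=variant_id,
        kon=association.kon,
        kon_se=association.kon_se,
        koff=displacement.koff,
        koff_se=displacement.koff_se,
        kd=kd,
        kd_se=kd_se,
    )


# ---------------------------------------------------------------------------
# ionic-strength dependence and basal rates
# ---------------------------------------------------------------------------

@dataclass
class BasalRateResults:
    """Extrapolation of a salt series to infinite ionic strength.

    ``basal_rate = exp(intercept)`` of the OLS fit of ln(rate) on I^(−1/2);
    as I → ∞ the regressor vanishes, so the intercept is the fully screened
    (electrostatics-free) rate constant.
    """

    basal_rate: float
    basal_se: float
    slope_beta: float  # d ln k / d I^(-1/2), in M^(1/2)
    slope_se: float
    r_squared: float
    rate_kind: str
    variant_id: str

    def summary(self) -> str:
        unit = "uM^-1 s^-1" if self.rate_kind == "association" else "s^-1"
        return (
            f"Ionic-strength dependence ({self.variant_id or 'unnamed'}, "
            f"{self.rate_kind})\n"
            f"  basal rate {self.basal_rate:.4g} {unit}  (SE {self.basal_se:.2g})\n"
            f"  slope      {self.slope_beta:.4g} per M^-1/2\n"
            f"  R^2        {self.r_squared:.4f}"
        )


class SaltDependenceModel:
    """ln(rate) regressed on I^(−1/2), with I the NaCl molarity.

    The 50 mM HEPES buffer contribution to ionic strength is ignored; rate
    tables are indexed by NaCl alone. The SE of the basal rate follows from
    the intercept SE by the delta method (SE(exp β₀) = exp(β₀)·SE(β₀)).
    """

    def __init__(self, series: SaltSeries):
        if np.any(series.rate_values <= 0):
            raise FoldbindError("all rates must be positive for the log transform")
        self.series = series

    def fit(self) -> BasalRateResults:
        ionic_M = self.series.nacl_mM / 1e3
        x = ionic_M ** -0.5
        y = np.log(self.series.rate_values)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        intercept_se, slope_se = res.bse
        basal = float(np.exp(intercept))
        return BasalRateResults(
            basal_rate=basal,
            basal_se=basal * float(intercept_se),
            slope_beta=float(slope),
            slope_se=float(slope_se),
            r_squared=float(res.rsquared),
            rate_kind=self.series.rate_kind,
            variant_id=self.series.variant_id,
        )


def fit_salt_dependence(series: SaltSeries) -> BasalRateResults:
    """Basal (electrostatics-free) rate constant from a salt titration."""
    return SaltDependenceModel(series).fit()


# ---------------------------------------------------------------------------
# linear free-energy relationship
# ---------------------------------------------------------------------------

@dataclass
class LferResults:
    """Slopes of log10 kon and log10 koff against log10 Kd across variants.

    When every Kd is computed as koff/kon from the same rate constants,
    log koff − log kon = log Kd + const, so the two slopes differ by exactly 1.
    """

    slope_kon_vs_kd: float
    slope_kon_se: float
    intercept_kon: float
    slope_koff_vs_kd: float
    slope_koff_se: float
    intercept_koff: float
    r_squared_kon: float
    r_squared_koff: float
    n_variants: int

    def summary(self) -> str:
        return (
            "Linear free-energy relationship (log rate vs log Kd)\n"
            f"  slope(log kon)  {self.slope_kon_vs_kd:+.4f}  "
            f"(SE {self.slope_kon_se:.2g}, R^2 {self.r_squared_kon:.3f})\n"
            f"  slope(log koff) {self.slope_koff_vs_kd:+.4f}  "
            f"(SE {self.slope_koff_se:.2g}, R^2 {self.r_squared_koff:.3f})\n"
            f"  ({self.n_variants} variants)"
        )


class LferModel:
    """OLS of log10 rate constants on log10 Kd across peptide variants.

    ``kd_values`` overrides the per-variant Kd used on the abscissa (e.g. to
    use independently tabulated affinities); by default the Kd stored in each
    :class:`BindingKinetics` row is used.
    """

    def __init__(
        self,
        kinetics: Sequence[BindingKinetics],
        kd_values: Optional[Sequence[float]] = None,
    ):
        if len(kinetics) < 3:
            raise FoldbindError("LFER regression needs at least 3 variants")
        self.kinetics = list(kinetics)
        if kd_values is not None and len(kd_values) != len(kinetics):
            raise FoldbindError("kd_values length mismatch")
        self.kd_values = None if kd_values is None else np.asarray(kd_values, float)

    def fit(self) -> LferResults:
        kd = (
            self.kd_values
            if self.kd_values is not None
            else np.array([k.kd for k in self.kinetics])
        )
        lkd = np.log10(kd)
        lkon = np.log10(np.array([k.kon for k in self.kinetics]))
        lkoff = np.log10(np.array([k.koff for k in self.kinetics]))
        X = sm.add_constant(lkd)
        res_on = sm.OLS(lkon, X).fit()
        res_off = sm.OLS(lkoff, X).fit()
        return LferResults(
            slope_kon_vs_kd=float(res_on.params[1]),
            slope_kon_se=float(res_on.bse[1]),
            intercept_kon=float(res_on.params[0]),
            slope_koff_vs_kd=float(res_off.params[1]),
            slope_koff_se=float(res_off.bse[1]),
            intercept_koff=float(res_off.params[0]),
            r_squared_kon=float(res_on.rsquared),
            r_squared_koff=float(res_off.rsquared),
            n_variants=len(self.kinetics),
        )


def lfer_regression(
    kinetics: Sequence[BindingKinetics],
    kd_values: Optional[Sequence[float]] = None,
) -> LferResults:
    """LFER slopes across variants; see :class:`LferModel`."""
    return LferModel(kinetics, kd_values=kd_values).fit()
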