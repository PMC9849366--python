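"""One-site ITC binding model: forward isotherm, fitting and derived energetics.

Isothermal titration calorimetry measures the heat released per injection of
titrant into the cell. For a single set of identical sites the cumulative
heat after injection *i* is

    Q(i) = (n·Mt·ΔH·V0/2) · [ 1 + Xt/(n·Mt) + Kd/(n·Mt)
                               − sqrt( (1 + Xt/(n·Mt) + Kd/(n·Mt))² − 4·Xt/(n·Mt) ) ]

where Mt and Xt are the running total cell and titrant concentrations, V0 the
active cell volume, n the stoichiometry and ΔH the molar binding enthalpy.
Injections displace cell liquid, so the totals are diluted with the standard
instrument (perfusion-cell) convention and the per-injection heat includes a
midpoint correction for the displaced volume:

    ΔQ(i) = Q(i) − Q(i−1) + (dVi/V0)·(Q(i) + Q(i−1))/2.

Fitting ΔQ against measured heats yields Kd, ΔH and n; ΔG = R·T·ln(Kd in M)
and −TΔS = ΔG − ΔH follow. The isotherm shape is governed by the Wiseman
c-value, c = n·Mt/Kd; Kd is well determined only for c roughly in [1, 1000].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .containers import FitError, FoldbindError, ItcExperiment, ThermoParams

logger = logging.getLogger(__name__)

__all__ = [
    "R_GAS",
    "CAL_TO_J",
    "one_site_heats",
    "one_site_cumulative_heats",
    "derive_thermo",
    "OneSiteBindingModel",
    "fit_one_site",
    "wiseman_c",
]

#: Gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314
#: Thermochemical calorie, J.
CAL_TO_J = 4.184


def _diluted_totals(
    injection_volumes_uL: np.ndarray,
    cell_volume_uL: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Running cell-species and titrant totals (µM) after each injection.

    Perfusion-cell convention: injected liquid displaces an equal volume of
    the (mixed) cell content, so after cumulative injected volume ΔV the cell
    species is diluted by (1 − ΔV/2V0)/(1 + ΔV/2V0) and the titrant total is
    X0·(ΔV/V0)/(1 + ΔV/2V0).
    """
    dv_cum = np.cumsum(injection_volumes_uL)
    ratio = dv_cum / (2.0 * cell_volume_uL)
    mt = cell_conc_uM * (1.0 - ratio) / (1.0 + ratio)
    xt = syringe_conc_uM * (dv_cum / cell_volume_uL) / (1.0 + ratio)
    return mt, xt


def _cumulative_heat_ucal(
    kd_nM: float,
    dh_kJ: float,
    n: float,
    mt_uM: np.ndarray,
    xt_uM: np.ndarray,
    cell_volume_uL: float,
) -> np.ndarray:
    """Cumulative heat Q(i) in µcal from the one-site binding polynomial."""
    kd_uM = kd_nM * 1e-3
    nmt = n * mt_uM
    term = 1.0 + xt_uM / nmt + kd_uM / nmt
    disc = term * term - 4.0 * xt_uM / nmt
    if np.any(disc < 0):
        raise FoldbindError("negative discriminant in binding polynomial")
    frac_bound = 0.5 * (term - np.sqrt(disc))  # bound fraction of n·Mt
    # moles bound = frac * n * Mt * V0 ; µM * µL = 1e-12 mol
    moles_bound = frac_bound * nmt * cell_volume_uL * 1e-12
    dh_ucal_per_mol = dh_kJ * 1e3 / CAL_TO_J * 1e6  # kJ/mol -> µcal/mol
    return moles_bound * dh_ucal_per_mol


def one_site_cumulative_heats(
    kd_nM: float,
    dh_kJ: float,
    n: float,
    injection_volumes_uL: np.ndarray,
    cell_volume_uL: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
) -> np.ndarray:
    """Cumulative heat Q(i) in µcal after each injection (dilution-corrected).

    The per-injection heats of :func:`one_site_heats` are the successive
    differences of this sequence plus the displaced-volume midpoint term, so
    the differences alone telescope exactly to Q(final).
    """
    vols = np.asarray(injection_volumes_uL, dtype=float)
    mt, xt = _diluted_totals(vols, cell_volume_uL, cell_conc_uM, syringe_conc_uM)
    return _cumulative_heat_ucal(kd_nM, dh_kJ, n, mt, xt, cell_volume_uL)


def one_site_heats(
    kd_nM: float,
    dh_kJ: float,
    n: float,
    injection_volumes_uL: np.ndarray,
    cell_volume_uL: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
) -> np.ndarray:
    """Predicted per-injection heats (µcal) for a one-set-of-sites titration.

    Applies the displaced-volume dilution to the running totals and the
    midpoint displaced-volume correction to each injection's heat.
    """
    if kd_nM <= 0:
        raise FoldbindError("kd must be positive")
    if n <= 0:
        raise FoldbindError("stoichiometry must be positive")
    vols = np.asarray(injection_volumes_uL, dtype=float)
    mt, xt = _diluted_totals(vols, cell_volume_uL, cell_conc_uM, syringe_conc_uM)
    q = _cumulative_heat_ucal(kd_nM, dh_kJ, n, mt, xt, cell_volume_uL)
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (vols / cell_volume_uL) * (q + q_prev) / 2.0


def wiseman_c(kd_nM: float, cell_conc_uM: float, n: float = 1.0) -> float:
    """Wiseman c-value n·Mt/Kd governing isotherm sharpness."""
    return n * cell_conc_uM / (kd_nM * 1e-3)


def derive_thermo(
    kd_nM: float, dh_kJ: float, temperature_K: float = 298.15
) -> Tuple[float, float]:
    """ΔG and −TΔS (kJ/mol) from Kd (nM) and ΔH (kJ/mol).

    ΔG = R·T·ln(Kd·10⁻⁹) referenced to the 1 M standard state;
    −TΔS = ΔG − ΔH, so ΔG = ΔH + (−TΔS) holds exactly.
    """
    if kd_nM <= 0:
        raise FoldbindError("kd must be positive")
    dg = R_GAS * temperature_K * np.log(kd_nM * 1e-9) / 1e3
    return float(dg), float(dg - dh_kJ)


@dataclass
class ThermoResults:
    """Fitted one-site ITC thermodynamics with fit diagnostics."""

    params: ThermoParams
    residual_sse: float
    c_value: float
    n_injections_used: int
    converged: bool = True

    def summary(self) -> str:
        p = self.params
        se = lambda v: "n/a" if v is None else f"{v:.2g}"  # noqa: E731
        return (
            "One-site ITC fit\n"
            f"  Kd     {p.kd:.4g} nM  (SE {se(p.kd_se)})\n"
            f"  N      {p.n:.4g}  (SE {se(p.n_se)})\n"
            f"  dH     {p.dh:.4g} kJ/mol  (SE {se(p.dh_se)})\n"
            f"  dG     {p.dg:.4g} kJ/mol\n"
            f"  -TdS   {p.minus_tds:.4g} kJ/mol\n"
            f"  c      {self.c_value:.3g}  "
            f"({self.n_injections_used} injections, SSE {self.residual_sse:.4g})"
        )


class OneSiteBindingModel:
    """Nonlinear least-squares fit of an ITC isotherm to the one-site model.

    Kd is parameterised as log10(Kd) during optimisation for positivity and
    conditioning. Initialisation: n from the molar ratio at the steepest heat
    change, ΔH from the first usable heat per mole injected, Kd ← Mt/10.
    The first injection (small, diffusion-compromised) is excluded by default,
    mirroring standard instrument practice.
    """

    def __init__(self, experiment: ItcExperiment, exclude_first: bool = True):
        self.experiment = experiment
        self.exclude_first = exclude_first and not experiment.first_injection_excluded
        n_usable = experiment.heats.size - (1 if self.exclude_first else 0)
        if n_usable < 6:
            raise FoldbindError("need at least 6 usable injections to fit")

    # -- helpers ------------------------------------------------------------
    def _molar_ratio(self) -> np.ndarray:
        exp = self.experiment
        mt, xt = _diluted_totals(
            exp.injection_volumes, exp.cell_volume, exp.cell_conc, exp.syringe_conc
        )
        return xt / mt

    def _initial_guess(self, mask: np.ndarray) -> Tuple[float, float, float]:
        exp = self.experiment
        heats = exp.heats
        ratio = self._molar_ratio()
        d = np.diff(heats)
        if d.size:
            n0 = float(np.clip(ratio[1:][np.argmax(np.abs(d))], 0.2, 5.0))
        else:  # pragma: no cover
            n0 = 1.0
        first = int(np.flatnonzero(mask)[0])
        moles_inj = exp.syringe_conc * exp.injection_volumes[first] * 1e-12
        dh0_ucal_per_mol = heats[first] / moles_inj if moles_inj else -1e10
        dh0 = dh0_ucal_per_mol * 1e-6 * CAL_TO_J / 1e3  # -> kJ/mol
        if not np.isfinite(dh0) or dh0 == 0:
            dh0 = -40.0
        kd0_nM = exp.cell_conc / 10.0 * 1e3  # Mt/10, in nM
        return kd0_nM, float(dh0), n0

    def _predict(self, log10_kd_nM: float, dh: float, n: float) -> np.ndarray:
        exp = self.experiment
        return one_site_heats(
            10.0 ** log10_kd_nM,
            dh,
            n,
            exp.injection_volumes,
            exp.cell_volume,
            exp.cell_conc,
            exp.syringe_conc,
        )

    # -- fit ----------------------------------------------------------------
    def fit(self) -> ThermoResults:
        exp = self.experiment
        mask = np.ones(exp.heats.size, dtype=bool)
        if self.exclude_first:
            mask[0] = False
        heats = exp.heats
        if np.max(np.abs(heats[mask])) == 0 or np.allclose(heats[mask], 0.0):
            logger.warning("all heats are ~0: dH ~ 0 and Kd is unidentifiable")
            dg, mtds = 0.0, 0.0
            params = ThermoParams(
                kd=np.nan, kd_se=None, n=np.nan, n_se=None,
                dh=0.0, dh_se=None, dg=np.nan, minus_tds=np.nan,
                temperature_K=exp.temperature_K,
            )
            return ThermoResults(
                params=params, residual_sse=0.0, c_value=np.nan,
                n_injections_used=int(mask.sum()), converged=False,
            )
        kd0, dh0, n0 = self._initial_guess(mask)

        def model(_x, log_kd, dh, n):
            return self._predict(log_kd, dh, n)[mask]

        x = np.arange(mask.sum())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model,
                    x,
                    heats[mask],
                    p0=(np.log10(kd0), dh0, n0),
                    bounds=([-6.0, -1e4, 1e-3], [9.0, 1e4, 100.0]),
                    maxfev=40000,
                )
        except RuntimeError as exc:
            raise FitError(f"one-site ITC fit did not converge: {exc}")
        log_kd, dh, n = popt
        kd = float(10.0 ** log_kd)
        resid = heats[mask] - model(x, *popt)
        sse = float(resid @ resid)
        if np.all(np.isfinite(pcov)):
            log_kd_se, dh_se, n_se = np.sqrt(np.diag(pcov))
            kd_se = float(kd * np.log(10.0) * log_kd_se)  # delta method
            dh_se, n_se = float(dh_se), float(n_se)
        else:
            kd_se = dh_se = n_se = None
        c = wiseman_c(kd, exp.cell_conc, n)
        if not (1.0 <= c <= 1000.0):
            logger.warning(
                "Wiseman c-value %.3g outside [1, 1000]: Kd poorly determined", c
            )
        dg, minus_tds = derive_thermo(kd, float(dh), exp.temperature_K)
        params = ThermoParams(
            kd=kd, kd_se=kd_se, n=float(n), n_se=n_se,
            dh=float(dh), dh_se=dh_se, dg=dg, minus_tds=minus_tds,
            temperature_K=exp.temperature_K,
        )
        return ThermoResults(
            params=params,
            residual_sse=sse,
            c_value=float(c),
            n_injections_used=int(mask.sum()),
        )


def fit_one_site(experiment: ItcExperiment, exclude_first: bool = True) -> ThermoResults:
    """Fit Kd, ΔH and N to an ITC isotherm; see :class:`OneSiteBindingModel`."""
    return OneSiteBindingModel(experiment, exclude_first=exclude_first).fit()
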