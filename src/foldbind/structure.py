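"""Helicity quantification from NMR chemical shifts and CD spectra.

Two independent routes estimate the fractional α-helix content of a
disordered peptide:

* **NMR secondary chemical shifts (SCS).** The observed Cα shift minus a
  random-coil reference is positive in helix; dividing the mean SCS over a
  residue interval by the full-helix reference of 3.1 ppm gives the percent
  helix of that region.
* **CD mean residue ellipticity (MRE).** Raw ellipticity converts to MRE via
  [θ]λ = θ°λ·MRW/(10·l·c); the helix fraction follows from the ellipticity at
  222 nm as −([θ]₂₂₂ + 3000)/39000, anchored at [θ]₂₂₂ = −3000 for coil and
  −42000 for full helix.

Because the two observables report on different length scales (a short region
versus the whole peptide), an empirical linear calibration maps CD-derived
percentages onto the NMR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import (
    CalibrationLine,
    ChemicalShiftTable,
    FoldbindError,
    MreSpectrum,
    RandomCoilTable,
    RegionHelicity,
    ScsProfile,
)

__all__ = [
    "FULL_HELIX_SCS_PPM",
    "MRE_COIL_222",
    "MRE_FULL_HELIX_222",
    "compute_scs",
    "region_helicity",
    "compute_mre",
    "helicity_from_mre",
    "tfe_titration_summary",
    "CalibrationModel",
    "CalibrationResults",
    "fit_calibration",
    "apply_calibration",
    "report_percent",
]

#: Cα SCS of an ideal 100% α-helix, ppm.
FULL_HELIX_SCS_PPM = 3.1
#: MRE at 222 nm of pure random coil, deg·cm²·dmol⁻¹.
MRE_COIL_222 = -3000.0
#: MRE at 222 nm of 100% α-helix, deg·cm²·dmol⁻¹.
MRE_FULL_HELIX_222 = -42000.0


def report_percent(value: float) -> int:
    """Round a percent to integer for reporting (half away from zero)."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


# ---------------------------------------------------------------------------
# NMR route
# ---------------------------------------------------------------------------

def compute_scs(shifts: ChemicalShiftTable, rc: RandomCoilTable) -> ScsProfile:
    """Secondary chemical shifts: observed minus random-coil reference.

    Only assigned residues enter the profile. When both tables carry Cβ
    shifts, the ΔδCα − ΔδCβ comparison metric is attached as well.

    Raises
    ------
    FoldbindError
        If the random-coil table misses an assigned residue (the offending
        residue number is named).
    """
    mask = shifts.assigned
    residues = shifts.residue_number[mask]
    missing = residues[~rc.covers(residues)]
    if missing.size:
        raise FoldbindError(
            f"random-coil table missing residue(s) {', '.join(map(str, missing))}"
        )
    rc_index = {int(r): i for i, r in enumerate(rc.residue_number)}
    idx = np.array([rc_index[int(r)] for r in residues])
    scs_ca = shifts.ca_ppm[mask] - rc.rc_ca_ppm[idx]
    ca_minus_cb = None
    if shifts.cb_ppm is not None and rc.rc_cb_ppm is not None:
        scs_cb = shifts.cb_ppm[mask] - rc.rc_cb_ppm[idx]
        ca_minus_cb = scs_ca - scs_cb
    return ScsProfile(
        residue_number=residues,
        scs_ca_ppm=scs_ca,
        scs_ca_minus_cb_ppm=ca_minus_cb,
    )


def region_helicity(
    profile: ScsProfile,
    region: Tuple[int, int],
    reference: float = FULL_HELIX_SCS_PPM,
    clip_max: float = 110.0,
) -> RegionHelicity:
    """Percent helix of a residue interval from the mean Cα SCS.

    ``region`` is an inclusive interval in full-protein numbering. The percent
    is 100·mean(SCS)/reference, clipped to [0, ``clip_max``] — values slightly
    above 100% occur for strongly helical regions and are reported as such.
    Unassigned residues never enter the mean.
    """
    lo, hi = region
    if lo > hi:
        raise FoldbindError(f"empty region ({lo}, {hi})")
    mask = (profile.residue_number >= lo) & (profile.residue_number <= hi)
    if not mask.any():
        raise FoldbindError(
            f"no assigned residues in region {lo}-{hi}"
        )
    mean_scs = float(np.mean(profile.scs_ca_ppm[mask]))
    percent = 100.0 * mean_scs / reference
    percent = float(np.clip(percent, 0.0, clip_max))
    return RegionHelicity(
        region=(lo, hi),
        mean_scs_ppm=mean_scs,
        percent_helix=percent,
        reference_scs_ppm=reference,
        n_residues=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# CD route
# ---------------------------------------------------------------------------

def compute_mre(
    raw_theta: float, mrw: float, path_cm: float, conc_g_per_ml: float
) -> float:
    """Mean residue ellipticity [θ]λ = θ°λ·MRW/(10·l·c).

    Parameters are the raw machine ellipticity in degrees, the mean residue
    weight (molecular weight over number of residues, g/mol), the cuvette
    path length in cm and the concentration in g/mL.
    """
    if mrw <= 0 or path_cm <= 0 or conc_g_per_ml <= 0:
        raise FoldbindError("mrw, path length and concentration must be positive")
    return raw_theta * mrw / (10.0 * path_cm * conc_g_per_ml)


def helicity_from_mre(spectrum: MreSpectrum) -> float:
    """Percent α-helix from the mean residue ellipticity at 222 nm.

    fraction = −([θ]₂₂₂ + 3000)/39000, clipped to [0, 1] and returned as a
    percent. Helical signals are *negative* at 222 nm, so the fraction grows
    as the ellipticity deepens from the −3000 coil anchor towards the −42000
    full-helix anchor.
    """
    mre222 = spectrum.mre_at(222.0)
    fraction = (mre222 - MRE_COIL_222) / (MRE_FULL_HELIX_222 - MRE_COIL_222)
    fraction = float(np.clip(fraction, 0.0, 1.0))
    return 100.0 * fraction


def tfe_titration_summary(spectra: Sequence[MreSpectrum]) -> pd.DataFrame:
    """Helicity versus TFE concentration for one peptide.

    TFE (2,2,2-trifluoroethanol) promotes helix formation; titrating it maps
    the helix susceptibility of a peptide. Returns a frame with columns
    ``tfe_percent`` and ``percent_helix``, sorted by TFE.
    """
    if len(spectra) < 2:
        raise FoldbindError("a TFE titration needs at least 2 spectra")
    tfe = [s.tfe_percent for s in spectra]
    if len(set(tfe)) != len(tfe):
        raise FoldbindError("duplicate TFE concentrations in titration")
    rows = sorted(
        ((s.tfe_percent, helicity_from_mre(s)) for s in spectra),
        key=lambda r: r[0],
    )
    return pd.DataFrame(rows, columns=["tfe_percent", "percent_helix"])


# ---------------------------------------------------------------------------
# NMR–CD calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResults:
    """OLS calibration of NMR-scale percent (Y) on CD percent (x)."""

    line: CalibrationLine
    slope_se: Optional[float]
    intercept_se: Optional[float]
    residuals: np.ndarray
    n_points: int

    def predict(self, cd_percent: float) -> float:
        return apply_calibration(self.line, cd_percent)

    def summary(self) -> str:
        return (
            "NMR-CD helicity calibration (OLS)\n"
            f"  Y = {self.line.slope:.4g} x {self.line.intercept:+.4g}\n"
            f"  R^2 = {self.line.r_squared:.4f}  ({self.n_points} points)"
        )


class CalibrationModel:
    """Fit the linear map from CD-derived to NMR-derived percent helicity."""

    def __init__(self, nmr_percent: Sequence[float], cd_percent: Sequence[float]):
        nmr = np.asarray(nmr_percent, dtype=float)
        cd = np.asarray(cd_percent, dtype=float)
        if nmr.size != cd.size or nmr.size < 3:
            raise FoldbindError("calibration needs >=3 paired points")
        self.nmr = nmr
        self.cd = cd

    def fit(self) -> CalibrationResults:
        res = sm.OLS(self.nmr, sm.add_constant(self.cd)).fit()
        intercept, slope = res.params
        line = CalibrationLine(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(res.rsquared),
        )
        return CalibrationResults(
            line=line,
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            residuals=np.asarray(res.resid, dtype=float),
            n_points=int(self.nmr.size),
        )


def fit_calibration(
    nmr_percent: Sequence[float], cd_percent: Sequence[float]
) -> CalibrationLine:
    """OLS line mapping CD percent (x) to NMR-scale percent (Y)."""
    return CalibrationModel(nmr_percent, cd_percent).fit().line


def apply_calibration(line: CalibrationLine, cd_percent: float) -> float:
    """Transform a CD-derived helicity onto the NMR scale.

    Negative predictions are floored at zero (a fractional population cannot
    be negative); the flooring is logged through the returned value itself.
    """
    if not np.isfinite(cd_percent):
        raise FoldbindError("calibration input must be finite")
    value = line.slope * cd_percent + line.intercept
    return float(max(value, 0.0))
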