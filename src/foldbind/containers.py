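"""Data containers for the coupled folding-and-binding analysis pipeline.

Lightweight, validated dataclasses holding the experimental observables the
pipeline consumes: stopped-flow fluorescence traces, pseudo-first-order rate
series, displacement series, ionic-strength series, NMR chemical-shift tables,
CD spectra and ITC isotherms — plus the result rows each analysis produces.
All arrays are stored as float64 numpy arrays; validation happens at
construction so downstream fitting code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FoldbindError",
    "FitError",
    "FluorescenceTrace",
    "PseudoFirstOrderSeries",
    "DisplacementSeries",
    "SaltSeries",
    "BindingKinetics",
    "ChemicalShiftTable",
    "RandomCoilTable",
    "ScsProfile",
    "RegionHelicity",
    "MreSpectrum",
    "CalibrationLine",
    "ItcExperiment",
    "ThermoParams",
    "VariantRecord",
]


class FoldbindError(ValueError):
    """Invalid input to a pipeline operation."""


class FitError(FoldbindError):
    """A fit failed to converge or produced a flagged, unusable estimate."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise FoldbindError(f"{name} must be one-dimensional")
    return arr


@dataclass
class FluorescenceTrace:
    """One averaged stopped-flow time course under pseudo-first-order mixing.

    Parameters
    ----------
    times : array
        Time points in seconds, strictly increasing, at least 10 points.
    signal : array
        Fluorescence in arbitrary units, same length as ``times``.
    partner_conc : float
        Concentration of the unlabelled binding partner (µM). Pseudo-first-order
        conditions require this to be in at least 10-fold excess over
        ``labeled_conc``.
    labeled_conc : float
        Concentration of the fluorescently labelled species (µM).
    temperature : float
        Temperature in °C.
    salt : float
        NaCl concentration in mM.
    true_kobs : float, optional
        Ground-truth observed rate constant (s⁻¹) when the trace is synthetic.
    """

    times: np.ndarray
    signal: np.ndarray
    partner_conc: float
    labeled_conc: float = 0.1
    temperature: float = 10.0
    salt: float = 100.0
    true_kobs: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.signal = _as_float_array(self.signal, "signal")
        if self.times.size != self.signal.size:
            raise FoldbindError("times and signal must have equal length")
        if self.times.size < 10:
            raise FoldbindError("a trace needs at least 10 points")
        if not np.all(np.diff(self.times) > 0):
            raise FoldbindError("times must be strictly increasing")

    @property
    def is_pseudo_first_order(self) -> bool:
        return self.partner_conc >= 10.0 * self.labeled_conc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "signal": self.signal})


@dataclass
class PseudoFirstOrderSeries:
    """Observed rate constants versus titrant concentration (association arm)."""

    concs: np.ndarray
    kobs_values: np.ndarray
    kobs_ses: Optional[np.ndarray] = None
    true_kon: Optional[float] = None
    true_koff: Optional[float] = None

    def __post_init__(self) -> None:
        self.concs = _as_float_array(self.concs, "concs")
        self.kobs_values = _as_float_array(self.kobs_values, "kobs_values")
        if self.concs.size != self.kobs_values.size:
            raise FoldbindError("concs and kobs_values must have equal length")
        if np.unique(self.concs).size < 2:
            raise FoldbindError("need at least 2 distinct concentrations")
        if self.kobs_ses is not None:
            self.kobs_ses = _as_float_array(self.kobs_ses, "kobs_ses")
            if self.kobs_ses.size != self.concs.size:
                raise FoldbindError("kobs_ses length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"conc_uM": self.concs, "kobs_s": self.kobs_values})


@dataclass
class DisplacementSeries:
    """Observed rate constants versus displacer concentration (dissociation arm).

    At saturating competitor the observed rate approaches the dissociation rate
    constant koff, which the asymptote of a decay fit estimates.
    """

    displacer_concs: np.ndarray
    kobs_values: np.ndarray
    true_koff: Optional[float] = None

    def __post_init__(self) -> None:
        self.displacer_concs = _as_float_array(self.displacer_concs, "displacer_concs")
        self.kobs_values = _as_float_array(self.kobs_values, "kobs_values")
        if self.displacer_concs.size != self.kobs_values.size:
            raise FoldbindError("displacer_concs and kobs_values must have equal length")
        if self.displacer_concs.size < 3:
            raise FoldbindError("asymptote fit needs at least 3 points")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"conc_uM": self.displacer_concs, "kobs_s": self.kobs_values}
        )


@dataclass
class SaltSeries:
    """Rate constants measured across NaCl concentrations for one variant."""

    nacl_mM: np.ndarray
    rate_values: np.ndarray
    rate_kind: str = "association"  # or "dissociation"
    variant_id: str = ""

    def __post_init__(self) -> None:
        self.nacl_mM = _as_float_array(self.nacl_mM, "nacl_mM")
        self.rate_values = _as_float_array(self.rate_values, "rate_values")
        if self.nacl_mM.size != self.rate_values.size:
            raise FoldbindError("nacl_mM and rate_values must have equal length")
        if self.nacl_mM.size < 3:
            raise FoldbindError("basal-rate extrapolation needs at least 3 salt points")
        if np.any(self.nacl_mM <= 0):
            raise FoldbindError("NaCl concentrations must be positive")
        if self.rate_kind not in ("association", "dissociation"):
            raise FoldbindError("rate_kind must be 'association' or 'dissociation'")


@dataclass
class BindingKinetics:
    """Per-variant binding kinetics: kon, koff and the derived Kd with SEs.

    Units follow convention for tight binders: kon in µM⁻¹ s⁻¹, koff in s⁻¹,
    Kd = koff/kon in nM. The Kd stored here is always the unrounded
    koff/kon ratio; rounding is a reporting concern.
    """

    variant_id: str
    kon: float
    kon_se: Optional[float]
    koff: float
    koff_se: Optional[float]
    kd: float
    kd_se: Optional[float]

    def __post_init__(self) -> None:
        for se in (self.kon_se, self.koff_se, self.kd_se):
            if se is not None and se < 0:
                raise FoldbindError("standard errors must be non-negative")


@dataclass
class ChemicalShiftTable:
    """Assigned backbone Cα (and optional Cβ) chemical shifts.

    Residue numbers use full-protein numbering (e.g. 244–272 for a 29-residue
    construct). Unassigned residues carry NaN shifts and ``assigned=False``;
    they are excluded from region averages rather than imputed.
    """

    residue_number: np.ndarray
    residue_type: Sequence[str]
    ca_ppm: np.ndarray
    cb_ppm: Optional[np.ndarray] = None
    assigned: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.ca_ppm = _as_float_array(self.ca_ppm, "ca_ppm")
        self.residue_type = list(self.residue_type)
        n = self.residue_number.size
        if len(self.residue_type) != n or self.ca_ppm.size != n:
            raise FoldbindError("chemical-shift table columns must have equal length")
        if np.unique(self.residue_number).size != n or not np.all(
            np.diff(self.residue_number) > 0
        ):
            raise FoldbindError("residue numbers must be unique and increasing")
        if self.cb_ppm is not None:
            self.cb_ppm = _as_float_array(self.cb_ppm, "cb_ppm")
            if self.cb_ppm.size != n:
                raise FoldbindError("cb_ppm length mismatch")
        if self.assigned is None:
            self.assigned = np.isfinite(self.ca_ppm)
        else:
            self.assigned = np.asarray(self.assigned, dtype=bool)
            if self.assigned.size != n:
                raise FoldbindError("assigned length mismatch")
        if np.any(~np.isfinite(self.ca_ppm[self.assigned])):
            raise FoldbindError("assigned residues must have finite Cα shifts")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "residue_number": self.residue_number,
                "residue_type": self.residue_type,
                "ca_ppm": self.ca_ppm,
            }
        )
        frame["cb_ppm"] = self.cb_ppm if self.cb_ppm is not None else np.nan
        return frame


@dataclass
class RandomCoilTable:
    """Random-coil reference Cα (and optional Cβ) shifts per residue."""

    residue_number: np.ndarray
    rc_ca_ppm: np.ndarray
    rc_cb_ppm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.rc_ca_ppm = _as_float_array(self.rc_ca_ppm, "rc_ca_ppm")
        if self.residue_number.size != self.rc_ca_ppm.size:
            raise FoldbindError("random-coil table columns must have equal length")
        if self.rc_cb_ppm is not None:
            self.rc_cb_ppm = _as_float_array(self.rc_cb_ppm, "rc_cb_ppm")
            if self.rc_cb_ppm.size != self.residue_number.size:
                raise FoldbindError("rc_cb_ppm length mismatch")

    def covers(self, residues: np.ndarray) -> np.ndarray:
        """Boolean mask of which requested residues the table covers."""
        return np.isin(residues, self.residue_number)


@dataclass
class ScsProfile:
    """Per-residue secondary chemical shifts (observed minus random coil).

    Consecutive positive Cα SCS values indicate α-helical structure; the
    optional ΔδCα − ΔδCβ column is a common cross-check metric.
    """

    residue_number: np.ndarray
    scs_ca_ppm: np.ndarray
    scs_ca_minus_cb_ppm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.scs_ca_ppm = _as_float_array(self.scs_ca_ppm, "scs_ca_ppm")
        if self.residue_number.size != self.scs_ca_ppm.size:
            raise FoldbindError("profile columns must have equal length")
        if self.scs_ca_minus_cb_ppm is not None:
            self.scs_ca_minus_cb_ppm = _as_float_array(
                self.scs_ca_minus_cb_ppm, "scs_ca_minus_cb_ppm"
            )


@dataclass
class RegionHelicity:
    """Helicity summary of a residue interval, from the mean Cα SCS."""

    region: Tuple[int, int]
    mean_scs_ppm: float
    percent_helix: float
    reference_scs_ppm: float = 3.1
    n_residues: int = 0


@dataclass
class MreSpectrum:
    """A far-UV CD spectrum in mean residue ellipticity units (deg·cm²·dmol⁻¹)."""

    wavelengths: np.ndarray
    mre: np.ndarray
    tfe_percent: float = 0.0
    peptide_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.mre = _as_float_array(self.mre, "mre")
        if self.wavelengths.size != self.mre.size:
            raise FoldbindError("wavelengths and mre must have equal length")

    def mre_at(self, wavelength: float, tol: float = 1.0) -> float:
        """MRE at the grid point nearest ``wavelength`` (within ``tol`` nm)."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > tol:
            raise FoldbindError(
                f"spectrum does not cover {wavelength} nm "
                f"(nearest point {self.wavelengths[idx]} nm)"
            )
        return float(self.mre[idx])


@dataclass
class CalibrationLine:
    """Linear map from CD-derived to NMR-scale percent helicity."""

    slope: float
    intercept: float
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise FoldbindError("calibration coefficients must be finite")


@dataclass
class ItcExperiment:
    """An ITC titration: injection schedule, per-injection heats and geometry."""

    injection_volumes: np.ndarray  # µL, in injection order
    heats: np.ndarray  # µcal per injection
    cell_volume: float  # active cell volume, µL
    cell_conc: float  # cell species (peptide), µM
    syringe_conc: float  # titrant (hub domain), µM
    temperature: float = 25.0  # °C
    first_injection_excluded: bool = False
    truth: Optional[object] = None

    def __post_init__(self) -> None:
        self.injection_volumes = _as_float_array(
            self.injection_volumes, "injection_volumes"
        )
        self.heats = _as_float_array(self.heats, "heats")
        if self.injection_volumes.size != self.heats.size:
            raise FoldbindError("heats and injection volumes must have equal length")
        if np.any(self.injection_volumes <= 0):
            raise FoldbindError("injection volumes must be positive")
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise FoldbindError("concentrations and cell volume must be positive")

    @property
    def temperature_K(self) -> float:
        return self.temperature + 273.15

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_idx": np.arange(1, self.heats.size + 1),
                "volume_uL": self.injection_volumes,
                "heat_ucal": self.heats,
            }
        )


@dataclass
class ThermoParams:
    """Fitted one-site binding thermodynamics (a Table-3-style row).

    ``dg = dh + minus_tds`` holds by construction, and ``dg`` equals
    R·T·ln(Kd in molar) with R = 8.314 J mol⁻¹ K⁻¹.
    """

    kd: float  # nM
    kd_se: Optional[float]
    n: float
    n_se: Optional[float]
    dh: float  # kJ/mol
    dh_se: Optional[float]
    dg: float  # kJ/mol
    minus_tds: float  # kJ/mol
    temperature_K: float


@dataclass
class VariantRecord:
    """Everything the study knows about one peptide variant, joined by id."""

    variant_id: str
    kinetics: Optional[BindingKinetics] = None
    free_helicity_percent: Optional[float] = None
    bound_helicity_percent: Optional[float] = None
    cd_helicity_percent: Optional[float] = None
    nmr_scale_percent: Optional[float] = None
    thermo: Optional[ThermoParams] = None
    basal_rates: dict = field(default_factory=dict)
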