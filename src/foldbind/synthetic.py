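"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator draws additive i.i.d. Gaussian noise from a single explicit
seed and records its ground truth on the returned object, so every downstream
fitter can be tested by parameter recovery without any measured data. The
defaults mirror the study conditions of the stopped-flow / NMR / CD / ITC
experiments the pipeline models: 0.1 µM labelled peptide mixed with 1–6 µM
partner for association, 5–60 µM competitor for displacement, an 18-injection
ITC schedule (0.5 µL then 17 × 2 µL) with ~10 µM peptide in the cell and
~96 µM partner in the syringe, and far-UV CD scans covering 190–250 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import (
    ChemicalShiftTable,
    DisplacementSeries,
    FluorescenceTrace,
    FoldbindError,
    ItcExperiment,
    MreSpectrum,
    PseudoFirstOrderSeries,
    RandomCoilTable,
)
from .structure import FULL_HELIX_SCS_PPM, MRE_COIL_222, MRE_FULL_HELIX_222
from .thermo import one_site_heats
from . import refdata

__all__ = [
    "KineticGroundTruth",
    "ItcGroundTruth",
    "HelixProfile",
    "gen_trace",
    "gen_association_series",
    "gen_displacement_series",
    "gen_itc_isotherm",
    "gen_cd_spectrum",
    "gen_shift_table",
]


@dataclass
class KineticGroundTruth:
    """True kinetic parameters behind a synthetic stopped-flow data set."""

    kon: float  # µM⁻¹ s⁻¹
    koff: float  # s⁻¹
    fluorescence_amplitude: float = 1.0
    baseline: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise FoldbindError("kon must be positive")
        if self.koff < 0:
            raise FoldbindError("koff must be non-negative")
        if self.noise_sd < 0:
            raise FoldbindError("noise_sd must be non-negative")

    def kobs(self, conc_uM: float) -> float:
        """Pseudo-first-order observed rate at the given partner conc."""
        return self.kon * conc_uM + self.koff


@dataclass
class ItcGroundTruth:
    """True thermodynamic parameters and geometry of a synthetic titration."""

    kd: float = 84.0  # nM
    dh: float = -68.0  # kJ/mol
    n: float = 0.84
    cell_conc: float = 10.0  # µM
    syringe_conc: float = 96.0  # µM
    cell_volume: float = 200.0  # µL
    injection_volumes: Sequence[float] = field(
        default_factory=lambda: [0.5] + [2.0] * 17
    )
    heat_noise_sd: float = 0.0  # µcal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n <= 0:
            raise FoldbindError("kd and n must be positive")
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise FoldbindError("concentrations and cell volume must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise FoldbindError("injection volumes must be positive")


@dataclass
class HelixProfile:
    """Per-residue helix-fraction profile of a peptide (fractions in [0, 1])."""

    sequence: str
    per_residue_helix_fraction: np.ndarray
    first_residue: int = refdata.FIXTURE_FIRST_RESIDUE

    def __post_init__(self) -> None:
        self.per_residue_helix_fraction = np.asarray(
            self.per_residue_helix_fraction, dtype=float
        )
        if len(self.sequence) != self.per_residue_helix_fraction.size:
            raise FoldbindError("sequence and fraction lengths must match")
        f = self.per_residue_helix_fraction
        if np.any((f < 0) | (f > 1)):
            raise FoldbindError("helix fractions must lie in [0, 1]")

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.first_residue, self.first_residue + len(self.sequence))


# ---------------------------------------------------------------------------
# stopped-flow generators
# ---------------------------------------------------------------------------

def gen_trace(
    truth: KineticGroundTruth,
    partner_conc: float,
    times: Sequence[float],
    labeled_conc: float = 0.1,
) -> FluorescenceTrace:
    """Single-exponential fluorescence trace under pseudo-first-order mixing.

    signal(t) = baseline + amplitude·exp(−kobs·t) + N(0, noise_sd),
    with kobs = kon·[partner] + koff recorded as the ground truth.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise FoldbindError("times must be strictly increasing")
    kobs = truth.kobs(partner_conc)
    signal = truth.baseline + truth.fluorescence_amplitude * np.exp(-kobs * t)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        signal = signal + rng.normal(0.0, truth.noise_sd, size=t.size)
    return FluorescenceTrace(
        times=t,
        signal=signal,
        partner_conc=partner_conc,
        labeled_conc=labeled_conc,
        true_kobs=kobs,
    )


def gen_association_series(
    truth: KineticGroundTruth,
    concs: Sequence[float],
    noise_sd: float = 0.0,
) -> PseudoFirstOrderSeries:
    """kobs versus titrant concentration: kobs_i = kon·c_i + koff (+ noise)."""
    c = np.asarray(concs, dtype=float)
    if np.unique(c).size < 2:
        raise FoldbindError("need at least 2 distinct concentrations")
    kobs = truth.kon * c + truth.koff
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        kobs = kobs + rng.normal(0.0, noise_sd, size=c.size)
    return PseudoFirstOrderSeries(
        concs=c, kobs_values=kobs, true_kon=truth.kon, true_koff=truth.koff
    )


def gen_displacement_series(
    truth: KineticGroundTruth,
    decay_scale: float,
    initial_kobs: float,
    displacer_concs: Sequence[float],
    noise_sd: float = 0.0,
) -> DisplacementSeries:
    """Displacement kobs decaying to the koff asymptote.

    kobs(d) = koff + (initial_kobs − koff)·exp(−d/decay_scale) (+ noise).
    The exponential decay shape is a modelling choice; the asymptote — the
    quantity of interest — is robust to it.
    """
    if decay_scale <= 0:
        raise FoldbindError("decay_scale must be positive")
    d = np.asarray(displacer_concs, dtype=float)
    if np.any(d <= 0) or not np.all(np.diff(d) > 0):
        raise FoldbindError("displacer concentrations must be positive and increasing")
    kobs = truth.koff + (initial_kobs - truth.koff) * np.exp(-d / decay_scale)
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        kobs = kobs + rng.normal(0.0, noise_sd, size=d.size)
    return DisplacementSeries(
        displacer_concs=d, kobs_values=kobs, true_koff=truth.koff
    )


# ---------------------------------------------------------------------------
# ITC generator
# ---------------------------------------------------------------------------

def gen_itc_isotherm(truth: ItcGroundTruth) -> ItcExperiment:
    """One-site ITC isotherm with displaced-volume correction plus heat noise."""
    vols = np.asarray(truth.injection_volumes, dtype=float)
    heats = one_site_heats(
        truth.kd,
        truth.dh,
        truth.n,
        vols,
        truth.cell_volume,
        truth.cell_conc,
        truth.syringe_conc,
    )
    total_titrant = truth.syringe_conc * vols.sum() / truth.cell_volume
    if total_titrant < truth.n * truth.cell_conc:
        import logging

        logging.getLogger(__name__).warning(
            "syringe load does not saturate the cell (%.3g < n*Mt=%.3g uM): "
            "incomplete isotherm",
            total_titrant,
            truth.n * truth.cell_conc,
        )
    if truth.heat_noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        heats = heats + rng.normal(0.0, truth.heat_noise_sd, size=heats.size)
    return ItcExperiment(
        injection_volumes=vols,
        heats=heats,
        cell_volume=truth.cell_volume,
        cell_conc=truth.cell_conc,
        syringe_conc=truth.syringe_conc,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# CD generator
# ---------------------------------------------------------------------------

def _helix_basis(wl: np.ndarray) -> np.ndarray:
    """Synthetic 100%-helix MRE curve: double minima near 208/222 nm, positive
    band near 193 nm; pinned exactly to −42000 at 222 nm."""
    shape = (
        -np.exp(-0.5 * ((wl - 222.0) / 7.5) ** 2)
        - 0.95 * np.exp(-0.5 * ((wl - 208.0) / 6.0) ** 2)
        + 1.6 * np.exp(-0.5 * ((wl - 193.0) / 5.0) ** 2)
    )
    return shape * (MRE_FULL_HELIX_222 / shape[np.argmin(np.abs(wl - 222.0))])


def _coil_basis(wl: np.ndarray) -> np.ndarray:
    """Synthetic random-coil MRE curve: deep minimum near 198 nm, weak signal
    at 222 nm; pinned exactly to −3000 at 222 nm."""
    shape = -0.12 - np.exp(-0.5 * ((wl - 198.0) / 7.0) ** 2)
    return shape * (MRE_COIL_222 / shape[np.argmin(np.abs(wl - 222.0))])


def gen_cd_spectrum(
    helix_fraction: float,
    wavelengths: Sequence[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    tfe_percent: float = 0.0,
    peptide_id: str = "",
) -> MreSpectrum:
    """Two-component CD spectrum for a given helix fraction.

    MRE(λ) = f·helix_basis(λ) + (1−f)·coil_basis(λ) + N(0, noise_sd). The
    basis curves are synthetic smooth shapes pinned to the 222 nm anchors
    (−42000 for helix, −3000 for coil), so MRE(222) = −(39000·f + 3000)
    exactly and the 222 nm inversion recovers f; full spectral realism is not
    attempted.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise FoldbindError("helix_fraction must lie in [0, 1]")
    wl = (
        np.arange(190.0, 250.5, 0.5)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    if np.min(np.abs(wl - 222.0)) > 1.0:
        raise FoldbindError("wavelength grid must cover 222 nm")
    mre = helix_fraction * _helix_basis(wl) + (1.0 - helix_fraction) * _coil_basis(wl)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mre = mre + rng.normal(0.0, noise_sd, size=wl.size)
    return MreSpectrum(
        wavelengths=wl, mre=mre, tfe_percent=tfe_percent, peptide_id=peptide_id
    )


# ---------------------------------------------------------------------------
# chemical-shift generator
# ---------------------------------------------------------------------------

def gen_shift_table(
    profile: HelixProfile,
    random_coil: Optional[RandomCoilTable] = None,
    full_helix_scs: float = FULL_HELIX_SCS_PPM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ChemicalShiftTable:
    """Observed Cα shift table consistent with a helix-fraction profile.

    observed Cα(i) = random-coil Cα(i) + f(i)·full_helix_scs + N(0, noise_sd).
    Cβ shifts are carried through unchanged from the reference (the Cα SCS
    carries the helicity signal). Defaults to the packaged random-coil table
    for the profile's sequence.
    """
    if random_coil is None:
        random_coil = refdata.random_coil_for_sequence(
            profile.sequence, profile.first_residue
        )
    residues = profile.residue_numbers
    missing = residues[~random_coil.covers(residues)]
    if missing.size:
        raise FoldbindError(
            f"random-coil table missing residue(s) {', '.join(map(str, missing))}"
        )
    rc_index = {int(r): i for i, r in enumerate(random_coil.residue_number)}
    idx = np.array([rc_index[int(r)] for r in residues])
    ca = random_coil.rc_ca_ppm[idx] + profile.per_residue_helix_fraction * full_helix_scs
    cb = (
        random_coil.rc_cb_ppm[idx].copy()
        if random_coil.rc_cb_ppm is not None
        else None
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ca = ca + rng.normal(0.0, noise_sd, size=ca.size)
    return ChemicalShiftTable(
        residue_number=residues,
        residue_type=list(profile.sequence),
        ca_ppm=ca,
        cb_ppm=cb,
    )
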