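"""Delimited-text readers and writers for every pipeline file format.

All files are comma-separated with a header row and '.' decimal separator:

====================  =================================================
traces                ``time_s, signal``
rate series           ``conc_uM, kobs_s``
salt series           ``nacl_mM, rate``
ITC isotherms         ``injection_idx, volume_uL, heat_ucal``
CD spectra            ``wavelength_nm, mre``
chemical shifts       ``residue_number, residue_type, ca_ppm, cb_ppm``
random-coil tables    ``residue_number, rc_ca_ppm, rc_cb_ppm``
====================  =================================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ChemicalShiftTable,
    DisplacementSeries,
    FluorescenceTrace,
    FoldbindError,
    ItcExperiment,
    MreSpectrum,
    PseudoFirstOrderSeries,
    RandomCoilTable,
    SaltSeries,
)

PathLike = Union[str, Path]


def _read(path: PathLike, required: tuple) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FoldbindError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


# --- traces -----------------------------------------------------------------

def write_trace(trace: FluorescenceTrace, path: PathLike) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path: PathLike, partner_conc: float, **kwargs) -> FluorescenceTrace:
    frame = _read(path, ("time_s", "signal"))
    return FluorescenceTrace(
        times=frame["time_s"].to_numpy(),
        signal=frame["signal"].to_numpy(),
        partner_conc=partner_conc,
        **kwargs,
    )


# --- rate series ------------------------------------------------------------

def write_series(series, path: PathLike) -> None:
    series.to_frame().to_csv(path, index=False)


def read_association_series(path: PathLike) -> PseudoFirstOrderSeries:
    frame = _read(path, ("conc_uM", "kobs_s"))
    return PseudoFirstOrderSeries(
        concs=frame["conc_uM"].to_numpy(), kobs_values=frame["kobs_s"].to_numpy()
    )


def read_displacement_series(path: PathLike) -> DisplacementSeries:
    frame = _read(path, ("conc_uM", "kobs_s"))
    return DisplacementSeries(
        displacer_concs=frame["conc_uM"].to_numpy(),
        kobs_values=frame["kobs_s"].to_numpy(),
    )


# --- salt series ------------------------------------------------------------

def write_salt_series(series: SaltSeries, path: PathLike) -> None:
    pd.DataFrame({"nacl_mM": series.nacl_mM, "rate": series.rate_values}).to_csv(
        path, index=False
    )


def read_salt_series(
    path: PathLike, rate_kind: str = "association", variant_id: str = ""
) -> SaltSeries:
    frame = _read(path, ("nacl_mM", "rate"))
    return SaltSeries(
        nacl_mM=frame["nacl_mM"].to_numpy(),
        rate_values=frame["rate"].to_numpy(),
        rate_kind=rate_kind,
        variant_id=variant_id,
    )


# --- ITC --------------------------------------------------------------------

def write_isotherm(experiment: ItcExperiment, path: PathLike) -> None:
    experiment.to_frame().to_csv(path, index=False)


def read_isotherm(
    path: PathLike,
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    temperature: float = 25.0,
) -> ItcExperiment:
    frame = _read(path, ("injection_idx", "volume_uL", "heat_ucal"))
    frame = frame.sort_values("injection_idx")
    return ItcExperiment(
        injection_volumes=frame["volume_uL"].to_numpy(),
        heats=frame["heat_ucal"].to_numpy(),
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        temperature=temperature,
    )


# --- CD spectra -------------------------------------------------------------

def write_spectrum(spectrum: MreSpectrum, path: PathLike) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "mre": spectrum.mre}
    ).to_csv(path, index=False)


def read_spectrum(
    path: PathLike, tfe_percent: float = 0.0, peptide_id: str = ""
) -> MreSpectrum:
    frame = _read(path, ("wavelength_nm", "mre"))
    return MreSpectrum(
        wavelengths=frame["wavelength_nm"].to_numpy(),
        mre=frame["mre"].to_numpy(),
        tfe_percent=tfe_percent,
        peptide_id=peptide_id,
    )


# --- chemical shifts --------------------------------------------------------

def write_shift_table(table: ChemicalShiftTable, path: PathLike) -> None:
    table.to_frame().to_csv(path, index=False)


def read_shift_table(path: PathLike) -> ChemicalShiftTable:
    frame = _read(path, ("residue_number", "residue_type", "ca_ppm"))
    cb = frame["cb_ppm"].to_numpy() if "cb_ppm" in frame.columns else None
    return ChemicalShiftTable(
        residue_number=frame["residue_number"].to_numpy(),
        residue_type=list(frame["residue_type"]),
        ca_ppm=frame["ca_ppm"].to_numpy(),
        cb_ppm=cb,
    )


def write_random_coil(table: RandomCoilTable, path: PathLike) -> None:
    frame = pd.DataFrame(
        {"residue_number": table.residue_number, "rc_ca_ppm": table.rc_ca_ppm}
    )
    frame["rc_cb_ppm"] = (
        table.rc_cb_ppm if table.rc_cb_ppm is not None else np.nan
    )
    frame.to_csv(path, index=False)


def read_random_coil(path: PathLike) -> RandomCoilTable:
    frame = _read(path, ("residue_number", "rc_ca_ppm"))
    cb = frame["rc_cb_ppm"].to_numpy() if "rc_cb_ppm" in frame.columns else None
    return RandomCoilTable(
        residue_number=frame["residue_number"].to_numpy(),
        rc_ca_ppm=frame["rc_ca_ppm"].to_numpy(),
        rc_cb_ppm=cb,
    )


# --- configuration ----------------------------------------------------------

def load_config(path: PathLike) -> dict:
    """Load a study configuration (YAML key-value with nesting)."""
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise FoldbindError(f"{path}: configuration must be a mapping")
    return config


def save_config(config: dict, path: PathLike) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=False)
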