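"""Study orchestration: per-variant kinetics, structure and thermodynamics.

``run_study`` drives the full analysis from a YAML configuration listing
per-variant data files, producing delimited report tables (rate constants and
Kd per variant; basal rates from salt series; helicity summaries; ITC
thermodynamics) plus a correlation/LFER summary. ``make_fixture_study``
materialises a complete synthetic five-variant study — a wild type, two
helix-destabilised and two helix-stabilised peptides — with known ground
truths, so the whole pipeline can be demonstrated and tested end to end
without measured data.

Reports come in two flavours per table: a full-precision machine-readable
CSV (``*_table.csv``) and a rendered report (``*_report.csv``) using the
field's customary rounding (2 significant figures for rate constants and Kd,
integer percent, one decimal for kJ/mol). Log output (with timestamps) is
confined to ``study.log`` so report files are byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import io as fio
from . import refdata
from .containers import FoldbindError, VariantRecord
from .kinetics import (
    SingleExponentialModel,
    fit_association,
    fit_displacement,
    fit_salt_dependence,
    fold_change,
    lfer_regression,
    make_binding_kinetics,
)
from .structure import (
    CalibrationModel,
    apply_calibration,
    compute_scs,
    fit_calibration,
    helicity_from_mre,
    region_helicity,
    report_percent,
)
from .synthetic import (
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
from .thermo import fit_one_site

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "make_fixture_study",
    "correlate_helicity_koff",
    "correlate_free_bound",
    "CorrelationResult",
    "round_sig",
]


def round_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for rendered reports only)."""
    if value == 0 or not np.isfinite(value):
        return value
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """OLS summary of one correlation analysis."""

    name: str
    slope: float
    intercept: float
    r_squared: float
    scale: str
    n: int


def _ols(x: np.ndarray, y: np.ndarray, name: str, scale: str) -> CorrelationResult:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CorrelationResult(
        name=name,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        scale=scale,
        n=int(x.size),
    )


def correlate_helicity_koff(
    records: Sequence[VariantRecord], scale: str = "log"
) -> CorrelationResult:
    """Regress koff on free-state helicity percent across variants.

    ``scale`` selects the koff axis: ``"log"`` regresses log10(koff),
    ``"linear"`` regresses koff itself. The helicity used is the NMR-scale
    (calibrated) percent when available, the raw free-state percent otherwise.
    """
    if scale not in ("log", "linear"):
        raise FoldbindError("scale must be 'log' or 'linear'")
    pairs = [
        (
            r.nmr_scale_percent
            if r.nmr_scale_percent is not None
            else r.free_helicity_percent,
            r.kinetics.koff,
        )
        for r in records
        if r.kinetics is not None
        and (r.nmr_scale_percent is not None or r.free_helicity_percent is not None)
    ]
    if len(pairs) < 3:
        raise FoldbindError("need >=3 variants with helicity and koff")
    hel = np.array([p[0] for p in pairs])
    koff = np.array([p[1] for p in pairs])
    y = np.log10(koff) if scale == "log" else koff
    return _ols(hel, y, "helicity_vs_koff", scale)


def correlate_free_bound(records: Sequence[VariantRecord]) -> CorrelationResult:
    """Regress bound-state on free-state helicity percent across variants."""
    pairs = [
        (r.free_helicity_percent, r.bound_helicity_percent)
        for r in records
        if r.free_helicity_percent is not None and r.bound_helicity_percent is not None
    ]
    if len(pairs) < 3:
        raise FoldbindError("need >=3 variants with free and bound helicity")
    free = np.array([p[0] for p in pairs])
    bound = np.array([p[1] for p in pairs])
    if np.ptp(bound) == 0 or np.ptp(free) == 0:
        raise FoldbindError("correlation undefined: constant helicity values")
    return _ols(free, bound, "free_vs_bound_helicity", "linear")


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Parsed study configuration.

    ``variants`` maps variant id to a dict of per-data-type file paths (all
    relative to ``base_dir``): ``association_series``, ``displacement_series``,
    ``salt_series`` (list of ``{path, rate_kind}``), ``shifts_free``,
    ``shifts_bound``, ``random_coil``, ``cd_spectra`` (list of
    ``{path, tfe_percent}``) and ``itc`` (``{path, cell_volume_uL,
    cell_conc_uM, syringe_conc_uM, temperature_C}``).
    """

    variants: Dict[str, dict]
    base_dir: Path
    output_dir: Path
    seed: int = 0
    reference_scs_ppm: float = 3.1
    region_free: Tuple[int, int] = (262, 266)
    region_bound: Tuple[int, int] = (261, 267)
    calibration_region: Tuple[int, int] = (244, 272)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], seed: Optional[int] = None):
        path = Path(path)
        raw = fio.load_config(path)
        regions = raw.get("regions", {})
        return cls(
            variants=raw.get("variants", {}),
            base_dir=path.parent,
            output_dir=path.parent / raw.get("output_dir", "out"),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            reference_scs_ppm=float(raw.get("reference_scs_ppm", 3.1)),
            region_free=tuple(regions.get("free", (262, 266))),
            region_bound=tuple(regions.get("bound", (261, 267))),
            calibration_region=tuple(raw.get("calibration_region", (244, 272))),
        )


@dataclass
class StudyReport:
    """Bundle of result tables produced by one study run."""

    records: List[VariantRecord]
    kinetics_table: Optional[pd.DataFrame] = None
    salt_table: Optional[pd.DataFrame] = None
    structure_table: Optional[pd.DataFrame] = None
    thermo_table: Optional[pd.DataFrame] = None
    correlation_table: Optional[pd.DataFrame] = None
    output_dir: Optional[Path] = None


# ---------------------------------------------------------------------------
# per-stage runners
# ---------------------------------------------------------------------------

def _run_kinetics(cfg: StudyConfig, vid: str, spec: dict, record: VariantRecord):
    assoc_path = spec.get("association_series")
    disp_path = spec.get("displacement_series")
    if not (assoc_path and disp_path):
        logger.warning("%s: kinetics data missing, stage skipped", vid)
        return
    assoc = fit_association(fio.read_association_series(cfg.base_dir / assoc_path))
    disp = fit_displacement(fio.read_displacement_series(cfg.base_dir / disp_path))
    record.kinetics = make_binding_kinetics(vid, assoc, disp)
    logger.info(
        "%s kinetics: kon=%.6g (SE %s), koff=%.6g (SE %s), Kd=%.6g nM",
        vid, assoc.kon, assoc.kon_se, disp.koff, disp.koff_se, record.kinetics.kd,
    )


def _run_salt(cfg: StudyConfig, vid: str, spec: dict, record: VariantRecord):
    for entry in spec.get("salt_series", []):
        series = fio.read_salt_series(
            cfg.base_dir / entry["path"],
            rate_kind=entry.get("rate_kind", "association"),
            variant_id=vid,
        )
        result = fit_salt_dependence(series)
        fc = fold_change(
            series.rate_values[np.argmax(series.nacl_mM)],
            series.rate_values[np.argmin(series.nacl_mM)],
        )
        record.basal_rates[series.rate_kind] = {
            "basal_rate": result.basal_rate,
            "basal_se": result.basal_se,
            "slope_beta": result.slope_beta,
            "r_squared": result.r_squared,
            "fold_change_high_over_low": fc,
        }
        logger.info(
            "%s salt (%s): basal=%.6g (SE %.3g), fold=%.3g",
            vid, series.rate_kind, result.basal_rate, result.basal_se, fc,
        )


def _run_structure(cfg: StudyConfig, vid: str, spec: dict, record: VariantRecord):
    rc = None
    if spec.get("random_coil"):
        rc = fio.read_random_coil(cfg.base_dir / spec["random_coil"])
    for state, region, attr in (
        ("shifts_free", cfg.region_free, "free_helicity_percent"),
        ("shifts_bound", cfg.region_bound, "bound_helicity_percent"),
    ):
        path = spec.get(state)
        if not path:
            continue
        if rc is None:
            logger.warning("%s: %s given without random_coil table, skipped", vid, state)
            continue
        shifts = fio.read_shift_table(cfg.base_dir / path)
        profile = compute_scs(shifts, rc)
        hel = region_helicity(profile, region, reference=cfg.reference_scs_ppm)
        setattr(record, attr, hel.percent_helix)
        logger.info(
            "%s %s: mean SCS %.4g ppm over %s -> %.4g%% helix",
            vid, state, hel.mean_scs_ppm, region, hel.percent_helix,
        )
        if state == "shifts_free":
            whole = region_helicity(
                profile, cfg.calibration_region, reference=cfg.reference_scs_ppm
            )
            record.__dict__["_whole_peptide_nmr_percent"] = whole.percent_helix
    spectra = spec.get("cd_spectra", [])
    zero_tfe = [s for s in spectra if float(s.get("tfe_percent", 0.0)) == 0.0]
    if zero_tfe:
        spectrum = fio.read_spectrum(
            cfg.base_dir / zero_tfe[0]["path"], tfe_percent=0.0, peptide_id=vid
        )
        record.cd_helicity_percent = helicity_from_mre(spectrum)
        logger.info("%s CD: %.4g%% helix at 0%% TFE", vid, record.cd_helicity_percent)


def _run_thermo(cfg: StudyConfig, vid: str, spec: dict, record: VariantRecord):
    itc = spec.get("itc")
    if not itc:
        return
    experiment = fio.read_isotherm(
        cfg.base_dir / itc["path"],
        cell_volume=float(itc["cell_volume_uL"]),
        cell_conc=float(itc["cell_conc_uM"]),
        syringe_conc=float(itc["syringe_conc_uM"]),
        temperature=float(itc.get("temperature_C", 25.0)),
    )
    result = fit_one_site(experiment)
    record.thermo = result.params
    logger.info(
        "%s ITC: Kd=%.6g nM, N=%.4g, dH=%.6g kJ/mol (c=%.3g)",
        vid, result.params.kd, result.params.n, result.params.dh, result.c_value,
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _kinetics_tables(records: List[VariantRecord]):
    rows = [
        {
            "variant": r.variant_id,
            "kon_uM_s": r.kinetics.kon,
            "kon_se": r.kinetics.kon_se,
            "koff_s": r.kinetics.koff,
            "koff_se": r.kinetics.koff_se,
            "kd_nM": r.kinetics.kd,
            "kd_se": r.kinetics.kd_se,
        }
        for r in records
        if r.kinetics is not None
    ]
    if not rows:
        return None, None
    table = pd.DataFrame(rows)
    report = table.copy()
    for col in ("kon_uM_s", "koff_s", "kd_nM"):
        report[col] = report[col].map(lambda v: round_sig(v, 2))
    for col in ("kon_se", "koff_se", "kd_se"):
        report[col] = report[col].map(
            lambda v: round_sig(v, 1) if v is not None and np.isfinite(v) else v
        )
    return table, report


def _salt_tables(records: List[VariantRecord]):
    rows = []
    for r in records:
        for kind, info in r.basal_rates.items():
            rows.append({"variant": r.variant_id, "rate_kind": kind, **info})
    if not rows:
        return None, None
    table = pd.DataFrame(rows)
    report = table.copy()
    for col in ("basal_rate", "fold_change_high_over_low"):
        report[col] = report[col].map(lambda v: round_sig(v, 2))
    return table, report


def _structure_tables(records: List[VariantRecord]):
    rows = [
        {
            "variant": r.variant_id,
            "free_percent": r.free_helicity_percent,
            "bound_percent": r.bound_helicity_percent,
            "cd_percent": r.cd_helicity_percent,
            "nmr_scale_percent": r.nmr_scale_percent,
        }
        for r in records
        if any(
            v is not None
            for v in (
                r.free_helicity_percent,
                r.bound_helicity_percent,
                r.cd_helicity_percent,
            )
        )
    ]
    if not rows:
        return None, None
    table = pd.DataFrame(rows)
    report = table.copy()
    for col in report.columns[1:]:
        report[col] = report[col].map(
            lambda v: report_percent(v) if v is not None and np.isfinite(v) else v
        )
    return table, report


def _thermo_tables(records: List[VariantRecord]):
    rows = [
        {
            "variant": r.variant_id,
            "kd_nM": r.thermo.kd,
            "kd_se": r.thermo.kd_se,
            "n": r.thermo.n,
            "n_se": r.thermo.n_se,
            "dh_kJ_mol": r.thermo.dh,
            "dh_se": r.thermo.dh_se,
            "minus_tds_kJ_mol": r.thermo.minus_tds,
            "dg_kJ_mol": r.thermo.dg,
        }
        for r in records
        if r.thermo is not None
    ]
    if not rows:
        return None, None
    table = pd.DataFrame(rows)
    report = table.copy()
    report["kd_nM"] = report["kd_nM"].map(lambda v: round_sig(v, 2))
    for col in ("dh_kJ_mol", "minus_tds_kJ_mol", "dg_kJ_mol"):
        report[col] = report[col].map(lambda v: round(v, 1))
    report["n"] = report["n"].map(lambda v: round(v, 2))
    return table, report


def _correlation_table(records: List[VariantRecord]) -> Optional[pd.DataFrame]:
    rows = []
    for builder in (
        lambda: correlate_helicity_koff(records, scale="log"),
        lambda: correlate_helicity_koff(records, scale="linear"),
        lambda: correlate_free_bound(records),
    ):
        try:
            c = builder()
        except FoldbindError as exc:
            logger.warning("correlation skipped: %s", exc)
            continue
        rows.append(
            {
                "analysis": f"{c.name}[{c.scale}]",
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "n": c.n,
            }
        )
    kin = [r.kinetics for r in records if r.kinetics is not None]
    if len(kin) >= 3:
        lfer = lfer_regression(kin)
        rows.append(
            {
                "analysis": "lfer_log_kon_vs_log_kd",
                "slope": lfer.slope_kon_vs_kd,
                "intercept": lfer.intercept_kon,
                "r_squared": lfer.r_squared_kon,
                "n": lfer.n_variants,
            }
        )
        rows.append(
            {
                "analysis": "lfer_log_koff_vs_log_kd",
                "slope": lfer.slope_koff_vs_kd,
                "intercept": lfer.intercept_koff,
                "r_squared": lfer.r_squared_koff,
                "n": lfer.n_variants,
            }
        )
    return pd.DataFrame(rows) if rows else None


# ---------------------------------------------------------------------------
# the study driver
# ---------------------------------------------------------------------------

def run_study(
    config: Union[StudyConfig, str, Path], seed: Optional[int] = None
) -> StudyReport:
    """Run the full per-variant study described by a configuration.

    Stages with missing data are skipped with a logged warning, never
    silently. Returns the report bundle and writes all tables under the
    configured output directory; the run log (the only place timestamps
    appear) goes to ``study.log`` there.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config, seed=seed)
    config.output_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(config.output_dir / "study.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("foldbind")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("study start: seed=%d, %d variants", config.seed, len(config.variants))
        records: List[VariantRecord] = []
        for vid, spec in config.variants.items():
            record = VariantRecord(variant_id=vid)
            _run_kinetics(config, vid, spec, record)
            _run_salt(config, vid, spec, record)
            _run_structure(config, vid, spec, record)
            _run_thermo(config, vid, spec, record)
            records.append(record)

        # NMR-CD calibration: whole-peptide NMR percent vs CD percent, then
        # transform every CD value onto the NMR scale.
        pairs = [
            (r.__dict__.get("_whole_peptide_nmr_percent"), r.cd_helicity_percent)
            for r in records
        ]
        train = [(n, c) for n, c in pairs if n is not None and c is not None]
        if len(train) >= 3:
            line = fit_calibration([p[0] for p in train], [p[1] for p in train])
            logger.info(
                "calibration: Y = %.4g x %+.4g (R^2 %.4f, n=%d)",
                line.slope, line.intercept, line.r_squared, len(train),
            )
            for r in records:
                if r.cd_helicity_percent is not None:
                    r.nmr_scale_percent = apply_calibration(line, r.cd_helicity_percent)
        else:
            logger.warning("calibration skipped: fewer than 3 NMR+CD variants")

        report = StudyReport(records=records, output_dir=config.output_dir)
        stages = {
            "kinetics": _kinetics_tables(records),
            "salt": _salt_tables(records),
            "structure": _structure_tables(records),
            "thermo": _thermo_tables(records),
        }
        for name, (table, rendered) in stages.items():
            if table is None:
                logger.warning("%s report absent: no data", name)
                continue
            setattr(report, f"{name}_table", table)
            table.to_csv(config.output_dir / f"{name}_table.csv", index=False)
            rendered.to_csv(config.output_dir / f"{name}_report.csv", index=False)
        corr = _correlation_table(records)
        if corr is not None:
            report.correlation_table = corr
            corr.to_csv(config.output_dir / "correlations.csv", index=False)
        logger.info("study complete")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# the synthetic five-variant demonstration study
# ---------------------------------------------------------------------------

#: Study-condition ground truths per variant: (kon µM⁻¹s⁻¹, koff s⁻¹).
FIXTURE_KINETICS = {
    "WT": (240.0, 0.18),
    "R266G": (230.0, 0.70),
    "R266A": (246.0, 0.383),
    "D267A": (222.0, 0.07),
    "D267L": (235.0, 0.030),
}

#: Free-state region mean SCS (ppm, D262-R266) and bound-state (V261-D267).
FIXTURE_NMR_SCS = {
    "R266G": (0.2, 2.4),
    "WT": (0.5, 2.9),
    "D267L": (1.6, 3.1),
}

#: CD helix fraction at 0% TFE per variant.
FIXTURE_CD_FRACTION = {
    "R266G": 0.11,
    "R266A": 0.11,
    "WT": 0.13,
    "D267A": 0.17,
    "D267L": 0.19,
}

#: ITC ground truths per variant: (Kd nM, ΔH kJ/mol, N).
FIXTURE_ITC = {
    "WT": (84.0, -68.0, 0.84),
    "R266G": (369.0, -56.0, 0.85),
    "D267L": (66.0, -69.0, 0.91),
}

#: Salt-series ground truths: (rate_kind, basal rate, slope per M^(-1/2)).
FIXTURE_SALT = {
    "R266G": ("association", 6.4, 1.055),
    "D267L": ("association", 10.4, 1.005),
    "WT": ("dissociation", 4.6, -1.062),
}

#: Whole-peptide free-state helix percent targets (NMR scale) per variant.
_FIXTURE_WHOLE_PEPTIDE_PERCENT = {"R266G": 2.0, "WT": 5.0, "D267L": 14.0}


def _fixture_profile(region_scs: float, whole_percent: float) -> np.ndarray:
    """Helix-fraction profile with an exact region mean and whole-peptide mean."""
    seq = refdata.FIXTURE_SEQUENCE
    first = refdata.FIXTURE_FIRST_RESIDUE
    numbers = np.arange(first, first + len(seq))
    fractions = np.zeros(len(seq))
    in_region = (numbers >= 262) & (numbers <= 266)
    fractions[in_region] = region_scs / 3.1
    target_sum = whole_percent / 100.0 * len(seq)
    tail = (target_sum - fractions.sum()) / (~in_region).sum()
    fractions[~in_region] = max(tail, 0.0)
    return np.clip(fractions, 0.0, 1.0)


def make_fixture_study(
    outdir: Union[str, Path],
    seed: int = 0,
    trace_noise_fraction: float = 0.01,
) -> Path:
    """Write a complete synthetic five-variant study and its configuration.

    Association kobs values are obtained the way the instrument pipeline
    obtains them — single-exponential fits of generated traces with Gaussian
    noise at ``trace_noise_fraction`` of the amplitude — then written as
    kobs-vs-concentration series. Displacement, salt, NMR, CD and ITC inputs
    are generated from the module-level ground-truth constants. Returns the
    path of the written ``study.yaml``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    for sub in ("kinetics", "salt", "nmr", "cd", "itc"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    rc_table = refdata.random_coil_for_sequence(refdata.FIXTURE_SEQUENCE)
    fio.write_random_coil(rc_table, outdir / "nmr" / "random_coil.csv")

    variants_cfg: Dict[str, dict] = {}
    for vid, (kon, koff) in FIXTURE_KINETICS.items():
        spec: dict = {}
        # --- association: traces -> single-exponential fits -> kobs series
        concs = np.arange(1.0, 7.0)
        kobs_fitted = []
        for conc in concs:
            truth = KineticGroundTruth(
                kon=kon,
                koff=koff,
                fluorescence_amplitude=1.0,
                baseline=5.0,
                noise_sd=trace_noise_fraction,
                seed=int(rng.integers(2**31)),
            )
            kobs_true = truth.kobs(conc)
            times = np.linspace(0.0, 5.0 / kobs_true, 200)[1:]
            trace = gen_trace(truth, conc, times)
            kobs_fitted.append(SingleExponentialModel(trace).fit().kobs)
        assoc = gen_association_series(
            KineticGroundTruth(kon=kon, koff=koff), concs
        )
        assoc.kobs_values = np.asarray(kobs_fitted)
        fio.write_series(assoc, outdir / "kinetics" / f"{vid}_association.csv")
        spec["association_series"] = f"kinetics/{vid}_association.csv"

        # --- displacement series decaying to koff
        disp = gen_displacement_series(
            KineticGroundTruth(
                kon=kon,
                koff=koff,
                noise_sd=0.0,
                seed=int(rng.integers(2**31)),
            ),
            decay_scale=10.0,
            initial_kobs=10.0 * koff,
            displacer_concs=np.arange(5.0, 65.0, 5.0),
            noise_sd=trace_noise_fraction * koff,
        )
        fio.write_series(disp, outdir / "kinetics" / f"{vid}_displacement.csv")
        spec["displacement_series"] = f"kinetics/{vid}_displacement.csv"

        # --- salt series
        if vid in FIXTURE_SALT:
            kind, basal, slope = FIXTURE_SALT[vid]
            nacl = np.array([100.0, 150.0, 200.0, 300.0, 500.0, 800.0])
            ln_rate = np.log(basal) + slope * (nacl / 1e3) ** -0.5
            noise = rng.normal(0.0, 0.01, nacl.size)
            from .containers import SaltSeries

            series = SaltSeries(
                nacl_mM=nacl,
                rate_values=np.exp(ln_rate + noise),
                rate_kind=kind,
                variant_id=vid,
            )
            fio.write_salt_series(series, outdir / "salt" / f"{vid}_{kind}.csv")
            spec["salt_series"] = [
                {"path": f"salt/{vid}_{kind}.csv", "rate_kind": kind}
            ]

        # --- NMR shift tables
        if vid in FIXTURE_NMR_SCS:
            free_scs, bound_scs = FIXTURE_NMR_SCS[vid]
            free_profile = HelixProfile(
                sequence=refdata.FIXTURE_SEQUENCE,
                per_residue_helix_fraction=_fixture_profile(
                    free_scs, _FIXTURE_WHOLE_PEPTIDE_PERCENT[vid]
                ),
            )
            bound_fractions = np.zeros(len(refdata.FIXTURE_SEQUENCE))
            numbers = free_profile.residue_numbers
            bound_fractions[(numbers >= 261) & (numbers <= 267)] = bound_scs / 3.1
            bound_fractions[(numbers >= 255) & (numbers <= 260)] = 0.5 * bound_scs / 3.1
            bound_profile = HelixProfile(
                sequence=refdata.FIXTURE_SEQUENCE,
                per_residue_helix_fraction=np.clip(bound_fractions, 0, 1),
            )
            for state, profile in (("free", free_profile), ("bound", bound_profile)):
                table = gen_shift_table(
                    profile, rc_table, seed=int(rng.integers(2**31))
                )
                fio.write_shift_table(table, outdir / "nmr" / f"{vid}_{state}.csv")
                spec[f"shifts_{state}"] = f"nmr/{vid}_{state}.csv"
            spec["random_coil"] = "nmr/random_coil.csv"

        # --- CD spectra: 0% TFE plus a titration
        f0 = FIXTURE_CD_FRACTION[vid]
        spec["cd_spectra"] = []
        for tfe in (0.0, 20.0, 40.0, 60.0):
            fraction = f0 + (0.8 - f0) * tfe / 80.0
            spectrum = gen_cd_spectrum(
                fraction,
                noise_sd=0.0,
                seed=int(rng.integers(2**31)),
                tfe_percent=tfe,
                peptide_id=vid,
            )
            name = f"cd/{vid}_tfe{int(tfe):02d}.csv"
            fio.write_spectrum(spectrum, outdir / name)
            spec["cd_spectra"].append({"path": name, "tfe_percent": tfe})

        # --- ITC isotherm
        if vid in FIXTURE_ITC:
            kd, dh, n = FIXTURE_ITC[vid]
            truth = ItcGroundTruth(
                kd=kd,
                dh=dh,
                n=n,
                heat_noise_sd=0.05,
                seed=int(rng.integers(2**31)),
            )
            experiment = gen_itc_isotherm(truth)
            fio.write_isotherm(experiment, outdir / "itc" / f"{vid}.csv")
            spec["itc"] = {
                "path": f"itc/{vid}.csv",
                "cell_volume_uL": truth.cell_volume,
                "cell_conc_uM": truth.cell_conc,
                "syringe_conc_uM": truth.syringe_conc,
                "temperature_C": 25.0,
            }

        variants_cfg[vid] = spec

    config = {
        "seed": seed,
        "output_dir": "out",
        "reference_scs_ppm": 3.1,
        "regions": {"free": [262, 266], "bound": [261, 267]},
        "calibration_region": [244, 272],
        "variants": variants_cfg,
    }
    config_path = outdir / "study.yaml"
    fio.save_config(config, config_path)
    return config_path
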