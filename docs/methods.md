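# Methods

This note documents the models implemented in `foldbind`, their assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open. No empirical claim appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stopped-flow kinetics

**Model.** Under pseudo-first-order conditions (unlabelled partner in ≥10-fold
excess over the labelled peptide; checked, and warned about when violated) an
averaged mixing trace relaxes as a single exponential,
`F(t) = F0 + A·exp(−kobs·t)`. The fit is unweighted nonlinear least squares
(scipy `curve_fit`); the kobs standard error comes from the covariance of the
fit. Initialisation: the offset from the mean of the final 5% of the trace,
the amplitude from the first point, and kobs from the half-amplitude crossing
(`kobs ≈ ln 2 / t_half`). A fit whose amplitude is smaller than three times
the residual noise estimate is flagged as a failure and reports no kobs —
a constant or noise-dominated trace carries no rate information.

**Association.** kobs is linear in titrant concentration,
`kobs = kon·c + koff`. kon is the OLS slope. With exactly two concentrations
the line is determined but its standard errors are reported as absent rather
than zero. All OLS fits in the package are unweighted; per-point kobs errors
are carried but not used as weights by default.

**Displacement.** Mixing preformed labelled complex with excess unlabelled
competitor gives kobs values that approach koff at saturating competitor. The
implementation fits a three-parameter decay `kobs(d) = koff + A·exp(−d/c)`
with a free asymptote, initialised at (min(kobs), range, median d). The
*asymptote* is the quantity of interest and is robust to the particular decay
shape; the exponential form is this package's choice, not an experimental
fact. A series that is not overall decreasing (Spearman ρ ≥ 0) triggers a
warning because the asymptote is then poorly constrained.

**Affinity.** `Kd[nM] = koff/kon × 10³`. The SE combines relative errors in
quadrature. Kd is stored unrounded; rendering to the customary 2 significant
figures happens only in reports.

## Ionic-strength dependence and basal rates

Rates across NaCl are fit as `ln k = β0 + β1·I^(−1/2)` with I the NaCl
molarity alone (the ~50 mM buffer contribution is ignored, matching how such
tables are indexed). This is the high-screening Debye–Hückel limit; as
I → ∞ the regressor vanishes, so `exp(β0)` is the rate constant free of
electrostatic steering — the *basal* rate. Its SE follows from the intercept
SE by the delta method. The functional form is a documented package choice:
it is linear in a physically motivated variable and reproduces the
tabulated basal rates of the motivating study within their stated errors
(checked in `tests/test_acceptance.py`). At least three salt points are
required; non-positive rates are rejected before the log transform.

## Helicity from NMR secondary chemical shifts

`SCS(i) = δCα_obs(i) − δCα_rc(i)`. The random-coil reference ships as a
packaged per-residue-type table of standard literature values and is always
overridable by a user file; sequence-dependent neighbour corrections are
expected to be supplied in that file, not computed here. Unassigned residues
are excluded from all means, never imputed. Region helicity is
`100·mean(SCS)/3.1` with 3.1 ppm the full-helix Cα reference; the value is
clipped to [0, 110] — slightly-above-100% values occur for strongly helical
segments and are meaningful, so 100 is not a hard ceiling. Default regions
follow the motivating system: free-state residual helix D262–R266, bound-state
helix V261–D267 (inclusive intervals, full-protein numbering). When Cβ shifts
are present on both sides, the ΔδCα − ΔδCβ metric is attached for
cross-checking. Integer rounding (half away from zero) happens only at the
reporting layer.

## Helicity from CD

Mean residue ellipticity `[θ]λ = θ°λ·MRW/(10·l·c)` (θ° in degrees, MRW in
g/mol per residue, l in cm, c in g/mL). Percent helix derives from the
222 nm point as `fraction = −([θ]222 + 3000)/39000`, anchored at −3000
(0% helix) and −42000 (100%). The sign convention is explicit because helical
signals are negative at 222 nm: the formula is implemented so that deeper
(more negative) ellipticity means more helix and the printed anchor
percentages are reproduced; the fraction is clipped to [0, 1]. The nearest
wavelength within 1 nm of 222 nm is used; spectra not covering 222 nm are
rejected. TFE titrations are summarised per peptide by applying the 222 nm
inversion at each TFE level.

## NMR–CD calibration

NMR- and CD-derived percentages report on different length scales (a short
region versus the whole peptide), so CD values are mapped onto the NMR scale
by an OLS line Y = a·x + b fitted on peptides measured by both methods
(≥3 pairs). The NMR-side training values are accepted as data — the package
does not prescribe which NMR summary enters the calibration; the
demonstration study uses the whole-peptide region mean. Negative transformed
values are floored at 0 (a population cannot be negative).

## One-site ITC

Forward model: the single-site binding polynomial gives the bound fraction
after each injection; cumulative heat is `Q = [MX]·ΔH·V0`. Injections
displace cell liquid, handled with the standard perfusion-cell convention —
after cumulative injected volume ΔV the cell species is diluted by
`(1 − ΔV/2V0)/(1 + ΔV/2V0)` and the titrant total is
`X0·(ΔV/V0)/(1 + ΔV/2V0)` — and the per-injection heat carries the midpoint
displaced-volume term `ΔQ(i) = Q(i) − Q(i−1) + (dVi/V0)(Q(i)+Q(i−1))/2`.
Heats are modelled in µcal; ΔH converts to kJ/mol only at the reporting
boundary (4.184 J/cal). The fit optimises (log10 Kd, ΔH, n) — the log
parameterisation keeps Kd positive and well conditioned — with n initialised
from the molar ratio at the steepest heat change, ΔH from the first usable
heat per mole injected, and Kd at Mt/10. The first injection is excluded by
default, the standard instrument practice for the diffusion-compromised
first 0.5 µL. A Wiseman c-value (n·Mt/Kd) outside [1, 1000] triggers a
warning that Kd is poorly determined. Derived quantities:
`ΔG = RT·ln(Kd·10⁻⁹)` (R = 8.314 J mol⁻¹ K⁻¹, 1 M standard state) and
`−TΔS = ΔG − ΔH`, so the identity ΔG = ΔH + (−TΔS) holds to machine
precision by construction. All-zero heats return a flagged, non-converged
result with ΔH = 0 and Kd undefined rather than an arbitrary number.

## LFER and correlations

Across variants, log10 kon and log10 koff are regressed on log10 Kd. When
every Kd is computed as koff/kon from the same rate constants, the two slopes
differ by exactly 1 (an algebraic identity, tested to machine precision).
The abscissa can instead be supplied externally (e.g. independently tabulated
affinities), in which case the identity need not hold exactly. Correlation
analyses (helicity vs koff, free- vs bound-state helicity) report OLS slope,
intercept and R²; where the axis convention is ambiguous (linear vs log koff)
both are always reported rather than choosing one.

## Synthetic data generator

Every generator draws additive i.i.d. Gaussian noise from one explicit seed
and records its ground truth, making all fitters testable by parameter
recovery. Defaults encode the study conditions the package models: 0.1 µM
labelled peptide with 1–6 µM partner (association), 5–60 µM competitor
(displacement), NaCl series from 50–100 to 800 mM, an 18-injection ITC
schedule (0.5 µL + 17 × 2 µL, ~10 µM cell / ~96 µM syringe, 200 µL cell,
25 °C), far-UV CD grids covering 190–250 nm, and a 29-residue peptide
numbered 244–272. Trace noise of 1% of the fluorescence amplitude and ITC
heat noise of ~2% of the largest injection heat are used as the realistic
noise levels in the demonstration study and the recovery tests.

What the generator does **not** emulate: raw pre-averaging photomultiplier
traces and stopped-flow dead time; NMR spectra (peaks/FIDs) — shift tables
are generated directly; realistic CD band shapes beyond two smooth basis
curves pinned to the 222 nm anchors; heats of dilution or baseline drift in
ITC; any physical TFE model beyond shifting the helix fraction. Passing
recovery tests therefore demonstrate the correctness of the estimators under
the stated noise model, not robustness to instrument systematics. The
fixture's peptide sequence is a synthetic stand-in (the analysed positions
are placed correctly; the rest is filler), so absolute chemical-shift values
in fixtures are not those of any real peptide — only differences (SCS)
matter anywhere in the pipeline.

## Numerical conventions and degenerate inputs

* OLS fits use statsmodels; nonlinear fits use scipy `curve_fit` with the
  initialisations above; no global multi-trace fitting.
* Internal values are never rounded; rendering (2 significant figures for
  rates/Kd, integer percent, one decimal kJ/mol) is confined to report files.
* Determinism: identical seeds and inputs give byte-identical generator
  output and report files; timestamps appear only in `study.log`.
* Degenerate inputs fail loudly with named-residue/units-bearing messages:
  non-increasing time vectors, singular designs, constant series where a
  correlation or asymptote is undefined, missing random-coil entries,
  spectra not covering 222 nm, non-positive rates in log fits.
* The acceptance script and the demonstration study run in seconds; the
  heaviest test (100-seed ITC recovery) takes under a second per ensemble on
  one CPU. Problem sizes (200-point traces, 6-concentration series,
  12-point displacement series, 18-injection isotherms) mirror the
  experimental designs they emulate.

## Known limitations

* No induced-fit/conformational-selection flux partitioning; the kinetic
  analysis is model-agnostic about mechanism beyond the pseudo-first-order
  framework.
* No double-exponential traces, dead-time correction, or weighted OLS by
  default (weights are carried but off, matching common practice).
* No multi-site/competitive ITC models; no baseline integration of raw
  power traces.
* The CD route uses the single-wavelength 222 nm inversion only — no
  spectral deconvolution.
* The basal-rate extrapolation assumes the I^(−1/2) form over the fitted
  range; other screening models would extrapolate differently.
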