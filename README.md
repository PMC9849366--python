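# foldbind

Analysis toolkit for **coupled folding and binding**: interactions in which an
intrinsically disordered protein region folds into an α-helix upon binding a
folded partner domain. The package was built around the study design used for
hub-domain/transcription-factor systems — a wild-type peptide plus
helix-stabilised and helix-destabilised point variants, characterised by
stopped-flow fluorescence kinetics, NMR and CD secondary-structure analysis,
and isothermal titration calorimetry (ITC) — and ties the per-variant results
together with correlation and linear free-energy relationship (LFER)
analyses.

## What it computes

**Kinetics (stopped-flow fluorescence).** Under pseudo-first-order mixing each
averaged trace follows `F(t) = F0 + A·exp(−kobs·t)`. The association arm fits
`kobs = kon·[partner] + koff` by ordinary least squares; the displacement arm
fits `kobs(d) = koff + A·exp(−d/c)` with the asymptote estimating the
dissociation rate constant. The affinity follows as `Kd = koff/kon` (nM from
µM⁻¹s⁻¹ and s⁻¹) with standard errors propagated in quadrature.

**Ionic-strength dependence.** Rate constants measured across NaCl
concentrations are regressed as `ln k = β0 + β1·I^(−1/2)` (high-screening
Debye–Hückel limit, I = NaCl molarity). `exp(β0)` is the *basal* rate
constant — the rate with electrostatic steering fully screened.

**Helicity (NMR and CD).** Secondary Cα chemical shifts (observed minus
random-coil reference) quantify per-residue helix content; the mean SCS over a
region divided by the 3.1 ppm full-helix reference gives percent helix. From
CD, mean residue ellipticity `[θ]λ = θ°λ·MRW/(10·l·c)` and percent helix
`= −([θ]222 + 3000)/39000 × 100`. A linear calibration maps whole-peptide CD
percentages onto the NMR scale.

**Thermodynamics (ITC).** One-set-of-sites Wiseman isotherm with
displaced-volume bookkeeping, fit for Kd, ΔH and stoichiometry N;
`ΔG = RT·ln Kd` and `−TΔS = ΔG − ΔH`.

**Synthetic data.** Seeded generators (`foldbind.synthetic`) produce every
input format with known ground truth — traces, kobs series, salt series,
shift tables, CD spectra and ITC isotherms — so the whole pipeline is testable
by parameter recovery.

## Worked example

Materialise the synthetic five-variant demonstration study and run the full
analysis:

```sh
foldbind simulate demo --seed 7
foldbind study demo/study.yaml
```

which prints the correlation/LFER summary

```
                      analysis     slope  intercept  r_squared  n
         helicity_vs_koff[log] -0.098569  -0.127490   0.953435  5
      helicity_vs_koff[linear] -0.042229   0.560142   0.696436  5
free_vs_bound_helicity[linear]  0.414110  80.081140   0.716730  3
        lfer_log_kon_vs_log_kd  0.010378   2.371963   0.079420  5
       lfer_log_koff_vs_log_kd  1.010378  -0.628037   0.998779  5
```

and writes rendered reports under `demo/out/`, e.g. `kinetics_report.csv`:

```
variant,kon_uM_s,kon_se,koff_s,koff_se,kd_nM,kd_se
WT,240.0,2.0,0.18,0.001,0.74,0.007
R266G,230.0,0.7,0.7,0.003,3.0,0.01
R266A,250.0,0.9,0.38,0.002,1.6,0.01
D267A,220.0,1.0,0.07,0.0003,0.32,0.002
D267L,240.0,1.0,0.03,0.0001,0.13,0.001
```

Reading the output: association rates are flat across variants (LFER slope for
log kon ≈ 0.01) while log koff tracks log Kd with slope ≈ 1.01 — affinity
differences among the variants are dissociation-driven. The helicity-vs-koff
row shows that peptides with more residual helix in the free state dissociate
more slowly (R² ≈ 0.95 on the log scale): residual structure manifests in
complex lifetime. Full-precision machine-readable tables (`*_table.csv`) sit
next to each rendered report; `study.log` records every fitted parameter.

The same analyses are available as a library, statsmodels-style — a model
object per fit with a results object carrying estimates, standard errors and
a `summary()`:

```python
>>> from foldbind import SaltSeries, SaltDependenceModel
>>> series = SaltSeries([100, 150, 200, 300, 500, 800],
...                     [178, 149, 142, 81, 45, 22], "association")
>>> print(SaltDependenceModel(series).fit().summary())
Ionic-strength dependence (unnamed, association)
  basal rate 10.37 uM^-1 s^-1  (SE 4.4)
  slope      1.005 per M^-1/2
  R^2        0.8678
```

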