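# bindscreen

Quantitation of ligand–receptor interactions for screening receptor-targeting
molecules, combining the two standard single-interaction measurements:

* **SPR kinetics** — surface plasmon resonance sensorgrams (response in RU vs.
  time) for an analyte flowed over an immobilized receptor are fitted with the
  1:1 Langmuir interaction model to estimate the association and dissociation
  rate constants and the equilibrium dissociation constant.
* **AFM force spectroscopy** — force–distance retract curves from a
  ligand-functionalized cantilever are converted to forces, filtered, and the
  adhesion force is reported as the peak of a single Gaussian fitted to the
  rupture-force histogram.
* **Screening report** — candidates are ranked against a reference ligand on
  both axes (affinity = inverse of K_D; adhesion = rupture force).

Because raw instrument exports for this kind of screen are proprietary, the
package ships a first-class synthetic-data module that generates sensorgrams
and force curves with known ground truth, which is also the substrate of the
test suite.

## The model

For the interaction A + B ⇌ AB between analyte A at concentration *C* (M) and
immobilized receptor B, the SPR response follows

```
association:   R(t) = R_eq (1 − e^(−k_obs t)),   R_eq = C k_a R_max / (C k_a + k_d),
               k_obs = C k_a + k_d
dissociation:  R(t) = R_0 e^(−k_d t)
```

with *k_a* (1/(M·s)), *k_d* (1/s), surface capacity *R_max* (RU), and
**K_D = k_d / k_a** (M) — smaller K_D means higher affinity.  The default fit
is per-phase ("independent"): *k_d* pooled from the dissociation decays,
*k_a* from the line k_obs = C·k_a + k_d across concentrations; a joint
"global" fit sharing (k_a, k_d, R_max) over all curves is provided as a
cross-check.

On the AFM side, cantilever deflection *d* (nm) converts to force by Hooke's
law **F = k·d**, with the spring constant *k* (N/m) either supplied or
calibrated from the resonance via the Cleveland formula
**k = 2w(πfL)³ √(ρ³/E)** (width *w*, length *L*, resonant frequency *f*,
density *ρ*, Young's modulus *E*).  Retract curves with no detectable rupture
("zero interaction") or with two or more ruptures ("non-specific") are
excluded; the kept single-rupture forces are histogrammed and the Gaussian
peak location is the adhesion force.

## Worked example

```
$ python examples/spr_kinetic_fit.py
truth:        ka = 1.000e+05 1/(M s), kd = 1.770e-02 1/s, K_D = 1.770e-07 M
 independent: ka = 9.876e+04 1/(M s), kd = 1.761e-02 1/s, K_D = 1.783e-07 M  (converged=True)
      global: ka = 9.916e+04 1/(M s), kd = 1.766e-02 1/s, K_D = 1.781e-07 M  (converged=True)
```

Five sensorgrams (0.25–4 µM, 1 RU noise) are simulated from known constants
and refitted; both modes recover K_D within about 1% here — the discrepancy
is the noise, not the method.

```
$ python examples/afm_adhesion_force.py
calibrated spring constant: 0.168 N/m
kept 349 of 500 curves; rejected {'non-specific': 52, 'zero interaction': 99}
adhesion force (Gaussian peak): 210.20 pN (sigma 32.08 pN)
```

500 synthetic retract curves (specific ruptures ~ Normal(210, 30) pN, 20%
zero-interaction and 10% multi-rupture contamination) pass through the full
pipeline; the filters remove essentially all planted contaminants and the
fitted peak lands within one 10 pN bin of the injected 210 pN.

```
$ python examples/screen_candidates.py
Screening summary (reference: EGF)
  mAb: K_D = 2.07e-09 M (affinity rank 1), adhesion = 210.99 pN (rank 1) -- beats reference affinity, beats reference adhesion
  EGF: K_D = 1.77e-07 M (affinity rank 2), adhesion = 209.41 pN (rank 2) -- reference
  GE11: K_D = 0.000459 M (affinity rank 3), adhesion = 59.51 pN (rank 3) -- does not beat reference affinity, does not beat reference adhesion
```

## Command line

A thin CLI wraps the same library calls:

```
bindscreen simulate spr --config spr.yaml --seed 1 --out data/
bindscreen simulate afm --config afm.yaml --seed 1 --out curves/
bindscreen fit-spr --in data/sensorgrams.csv --mode independent --out fits/
bindscreen fit-afm --in curves/ --bin-width 10 --out fits/
bindscreen rank --spr spr.tsv --afm afm.tsv --reference EGF --out report/
bindscreen run --config run.yaml --seed 1 --out results/
```

File dialects are plain CSV/TSV with explicit headers
(`time_s,response_ru,phase,concentration_M`; `z_nm,deflection_nm,segment`
plus a JSON/YAML cantilever sidecar), documented in
`src/bindscreen/dataio.py`, so instrument exports can be converted with a few
lines of pandas.

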