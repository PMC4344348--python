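# Methods

## 1:1 interaction model and what it assumes

The kinetic arm models a single-site reversible interaction A + B ⇌ AB
between a flowed analyte and an immobilized receptor.  Writing the surface
signal R (RU) as a proxy for the complex concentration, the rate equation
dR/dt = k_a·C·(R_max − R) − k_d·R integrates to the mono-exponential
association curve R(t) = R_eq(1 − e^(−k_obs·t)) with k_obs = C·k_a + k_d and
R_eq = C·k_a·R_max/(C·k_a + k_d); dissociation in pure buffer follows
R(t) = R_0·e^(−k_d·t).  Time is phase-local: re-zeroed at the start of each
phase, which is also how the generator writes its traces.

Assumptions inherited from this model (and therefore from every fit in the
package): pseudo-first-order kinetics (C constant during injection), no
mass-transport limitation, a homogeneous ligand surface, monovalent analyte
and no rebinding during dissociation.  Two-state and bivalent models are
deliberately out of scope.

## Fitting strategy

**Default mode "independent"** fits each phase separately, which is what
standard evaluation software does:

1. each dissociation segment is fitted with nonlinear least squares
   (r_0·e^(−k_d·t)), initialized at the closed-form log-linear regression on
   positive samples; per-curve k_d estimates are pooled by inverse-variance
   weighting (variances from the Gauss–Newton covariance), degrading
   gracefully to the plain mean when residuals vanish;
2. each association segment is fitted for (R_eq, k_obs) — a single curve
   cannot separate k_a from k_d, which is a documented limitation of
   single-concentration analysis;
3. k_a comes from regressing k_obs on C with the intercept constrained to
   the pooled k_d; R_max is the across-curve mean of
   R_eq·k_obs/(C·k_a).

**Mode "global"** refits one shared (k_a, k_d, R_max) over every curve and
both phases, with the dissociation amplitude tied to the association value
at the end of injection.  Parameters are optimized on a log scale because
rate constants span decades, guaranteeing positivity without bounds.  On
noiseless data both modes agree to ~1e-14 relative; on noisy data the modes
serve as mutual cross-checks.  K_D = k_d/k_a in both.

Numerical settings: trust-region least squares (`scipy.optimize.
least_squares`), ftol/xtol/gtol = 1e-12, at most 2000 function evaluations.
Non-convergence sets `converged=False` on the result; it never raises.
Before fitting, responses are offset by the pre-injection baseline mean
(zero when no baseline samples exist), so a constant bulk shift leaves the
rate estimates unchanged.  An optional control-channel subtraction aligned
on the time grid is available as a pre-step.

## Force spectroscopy

Deflection converts to force as F[pN] = k[N/m] × d[nm] × 1000.  When the
spring constant is not supplied it is calibrated from the cantilever
resonance with the Cleveland formula k = 2w(πfL)³√(ρ³/E), which is
dimensionally consistent and reproduces the 0.09–0.18 N/m stiffness range
of typical soft contact-mode levers (the worked geometry w = 30 µm,
L = 200 µm, f = 30 kHz, ρ = 3100 kg/m³, E = 1.7×10¹¹ Pa gives 0.168 N/m).

Processing order: (1) baseline correction — a least-squares line fitted to
the far-from-surface 30% of the retract trace is subtracted, making the free
region zero-mean; (2) rupture detection — runs of samples below
−(threshold factor × noise floor) form dips, dips closer than a minimum
z-separation (default 10 nm) merge, and each event's rupture force is the
magnitude of its deepest point (the simplest reading of "maximum force at
separation"; no slope extrapolation); (3) filtering — zero events → "zero
interaction", ≥2 events → "non-specific", both rejected with a logged
reason; exactly one event is kept; (4) the kept forces are binned into
uniform bins from 0 (Freedman–Diaconis width with a 5 pN floor when not
given) and a single Gaussian A·e^(−(x−µ)²/2σ²) is least-squares fitted to
the counts, initialized at the modal bin.  µ is the reported adhesion force.
A maximum-likelihood normal fit on the raw forces exists as a cross-check
mode; the histogram fit is the primary route because that is what
force-spectroscopy reports conventionally quote.

Defaults that matter: threshold factor 5 (a 5σ excursion criterion; with a
5 pN noise floor this detects dips ≥ ~25 pN with a per-curve false-event
probability around 10⁻⁴), noise floor estimated as the s.d. of the far 30%
of the corrected retract force, minimum separation 10 nm.  An optional
maximum-rupture-distance cutoff (events beyond a configurable z flagged
non-specific) is available but off by default.

Degenerate inputs are pinned down explicitly: an all-rejected batch raises
an error naming the dominant rejection reason; a batch whose kept forces
are all identical (noiseless, σ_f = 0) reports that unique value with
σ = 0 and a `degenerate` flag instead of attempting a histogram fit; a
Gaussian fit needs at least four occupied bins.

## Screening report

Affinity is inverse to K_D, so the affinity ranking is ascending in K_D and
the adhesion ranking descending in force.  "Beats the reference" uses strict
inequality on both axes — equality is not a win, a conservative choice for
screening.  Ties break lexicographically and set a flag; ranking uses point
estimates only (uncertainties are reported alongside but do not reorder).

## What the synthetic generator emulates — and what it does not

Sensorgrams: exact 1:1 curves at the configured concentration series
(default 0.25, 0.5, 1, 2, 4 µM — the natural-ligand series; weak binders
get their own, higher series), 30 s baseline, 300 s association, 300 s
dissociation at 1 Hz, additive i.i.d. Gaussian noise (default experiments
use 1 RU ≈ 1% of R_max) and optional linear drift.  Per-concentration noise
streams are sub-seeded (seed + index) so adding a concentration never
perturbs the others.

Force curves: 0–200 nm piezo range at 0.5 nm steps, a linear contact ramp
below 3 nm, triangular adhesion dips (linear loading to the rupture point,
instantaneous release) with specific forces drawn from a zero-truncated
normal (reject-and-redraw), non-specific curves carrying two well-separated
dips, and Gaussian force noise (default 5 pN).  Class counts follow the
configured fractions exactly (rounded), with a seeded permutation deciding
order; labels and injected forces are retained as hidden ground truth.
Dwell time at contact and loading rate are metadata only.

Not emulated, by design: bulk refractive-index jumps, mass-transport
limitation, rebinding, nonlinear drift; polymer-tether stretching
(worm-like/freely-jointed chain) shapes, piezo hysteresis, multiple
simultaneous bonds within one dip.  Passing tests therefore demonstrate
correct recovery under the stated statistical structure, not robustness to
every instrumental artifact of real data.

## Problem sizes used in the shipped checks

The stochastic kinetic check uses 100 replicates of the 5-concentration
series at 1% noise (median K_D error observed ≈ 1%); the adhesion check
uses one 500-curve campaign with 20% + 10% contamination and 10 pN bins.
These sizes put the Monte-Carlo error well inside the asserted tolerances
while keeping the whole suite fast.

## Known limitations

* Single-curve association fits report k_obs only; separating k_a requires
  the multi-concentration analysis (or a fixed k_d).
* Very fast kinetics (k_obs ≳ 1 s⁻¹ at 1 Hz sampling) leave too few
  pre-plateau samples for a stable k_obs; choose concentrations and
  sampling accordingly.
* The histogram Gaussian fit is sensitive to bin width for small n; below
  ~30 kept forces prefer the MLE cross-check.
* The rejection rules classify by event count only; chemically specific
  multi-bond ruptures are indistinguishable from non-specific adhesion here.
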