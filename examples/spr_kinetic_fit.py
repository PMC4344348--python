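"""Fit 1:1 binding kinetics to a simulated multi-concentration SPR series.

Generates sensorgrams at 0.25-4 uM with 1 RU of instrument-like noise from
known rate constants, fits the association and dissociation phases, and
prints the recovered constants next to the ground truth.
"""

from bindscreen import sprkinetics as spr
from bindscreen import synthdata as sd

truth = spr.KineticParameters(ka=1e5, kd=1.77e-2, rmax=100.0)
protocol = sd.InjectionProtocol(
    t_assoc_start=30.0, t_assoc_end=330.0, t_diss_end=630.0,
    sampling_interval=1.0, concentrations=sd.EGF_CONCENTRATIONS_M,
)
noise = sd.SensorgramNoiseModel(sigma_ru=1.0, seed=1)
series = sd.simulate_sensorgram_series(truth, protocol, noise)

print(f"truth:        ka = {truth.ka:.3e} 1/(M s), kd = {truth.kd:.3e} 1/s, "
      f"K_D = {truth.kD:.3e} M")
for mode in ("independent", "global"):
    fit = spr.fit_global(series, mode=mode)
    print(f"{mode:>12s}: ka = {fit.ka_hat:.3e} 1/(M s), kd = {fit.kd_hat:.3e} 1/s, "
          f"K_D = {fit.kD_hat:.3e} M  (converged={fit.converged})")

# K_D = kd/ka is the equilibrium dissociation constant: the analyte
# concentration at which half the surface sites are occupied.  Smaller K_D
# means higher affinity; recovering it within a few percent at 1% noise is
# the expected behaviour for a well-conditioned 5-concentration series.
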