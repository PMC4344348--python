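"""Synthetic sensorgrams and force curves with known ground truth.

Instrument data for this kind of screen live only in vendor software, so the
test substrate is generated: multi-concentration 1:1 binding sensorgrams with
additive Gaussian noise (and optional linear drift), and batches of AFM
retract curves whose specific rupture forces are drawn from a truncated
normal, contaminated by a stated fraction of zero-interaction and
multi-rupture ("non-specific") curves.  Every generator is bit-reproducible
given identical parameters and seed; per-curve noise streams are derived from
the master seed by fixed sub-seeding so adding a concentration or curve does
not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afmforce import NM_NPM_TO_PN, CantileverSpec, ForceCurve
from .errors import InvalidCantileverError, InvalidInputError, InvalidProtocolError
from .sprkinetics import (
    KineticParameters,
    Sensorgram,
    SensorgramSeries,
    predicted_response,
)

__all__ = [
    "InjectionProtocol",
    "SensorgramNoiseModel",
    "AdhesionGroundTruth",
    "ForceCurveGeometry",
    "ForceBatch",
    "simulate_sensorgram",
    "simulate_sensorgram_series",
    "simulate_force_curve",
    "simulate_force_batch",
]

#: Analyte concentration series used for the natural-ligand screen (M).
EGF_CONCENTRATIONS_M = (0.25e-6, 0.5e-6, 1e-6, 2e-6, 4e-6)


@dataclass(frozen=True)
class InjectionProtocol:
    """Timing and concentration plan for a multi-cycle SPR experiment."""

    t_assoc_start: float  # s
    t_assoc_end: float  # s
    t_diss_end: float  # s
    sampling_interval: float = 1.0  # s
    concentrations: tuple[float, ...] = EGF_CONCENTRATIONS_M  # M

    def __post_init__(self) -> None:
        if not (self.t_assoc_start < self.t_assoc_end < self.t_diss_end):
            raise InvalidProtocolError(
                "need t_assoc_start < t_assoc_end < t_diss_end, got "
                f"({self.t_assoc_start}, {self.t_assoc_end}, {self.t_diss_end})"
            )
        if not (self.sampling_interval > 0):
            raise InvalidProtocolError(
                f"sampling_interval must be > 0, got {self.sampling_interval}"
            )
        if any(c <= 0 for c in self.concentrations):
            raise InvalidInputError("concentrations must all be positive")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise InvalidInputError("concentrations must be unique")

    def time_grid(self) -> np.ndarray:
        grid = np.arange(0.0, self.t_diss_end + 0.5 * self.sampling_interval,
                         self.sampling_interval)
        if grid.size == 0:
            raise InvalidProtocolError("protocol yields an empty time grid")
        return grid


@dataclass(frozen=True)
class SensorgramNoiseModel:
    """Additive i.i.d. Gaussian noise plus optional linear baseline drift."""

    sigma_ru: float = 0.0  # RU
    baseline_drift: float = 0.0  # RU/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma_ru >= 0):
            raise InvalidInputError(f"sigma_ru must be >= 0, got {self.sigma_ru}")


@dataclass(frozen=True)
class AdhesionGroundTruth:
    """Population parameters of a synthetic force-curve campaign.

    ``mu_f > 3*sigma_f`` keeps the truncated-normal redraws rare so the
    realized mean stays at mu_f.
    """

    mu_f: float = 210.0  # pN
    sigma_f: float = 30.0  # pN
    frac_zero: float = 0.2
    frac_nonspecific: float = 0.1
    n_curves: int = 500

    def __post_init__(self) -> None:
        if not (self.mu_f > 0):
            raise InvalidInputError(f"mu_f must be > 0, got {self.mu_f}")
        if not (self.sigma_f >= 0):
            raise InvalidInputError(f"sigma_f must be >= 0, got {self.sigma_f}")
        for name in ("frac_zero", "frac_nonspecific"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_zero + self.frac_nonspecific > 1.0:
            raise InvalidInputError("frac_zero + frac_nonspecific must be <= 1")
        if self.n_curves < 1:
            raise InvalidInputError(f"n_curves must be >= 1, got {self.n_curves}")


@dataclass(frozen=True)
class ForceCurveGeometry:
    """Shape of the generated traces (piezo range, contact, event placement)."""

    z_max: float = 200.0  # nm
    dz: float = 0.5  # nm
    contact_z: float = 3.0  # nm; approach/retract contact ramp extends below this
    contact_slope: float = 1.0  # nm deflection per nm compression
    dip_z_start: float = 8.0  # nm; where the specific adhesion dip begins loading
    dip_z_rupture: float = 25.0  # nm; rupture point of the specific dip
    second_dip_z_start: float = 45.0  # nm (non-specific curves)
    second_dip_z_rupture: float = 60.0  # nm
    noise_sd_pn: float = 5.0  # pN baseline noise on every sample
    drift_nm_per_100nm: float = 0.0  # linear baseline drift on the retract trace
    dwell_s: float = 3.0  # s held at contact; metadata only


@dataclass
class ForceBatch:
    """Generated curves with their hidden class labels and generating truth."""

    curves: list[ForceCurve]
    labels: list[str]  # "specific" | "zero" | "nonspecific" per curve
    injected_forces: list[float | None]  # pN; the specific draw, None otherwise
    truth: AdhesionGroundTruth
    cantilever: CantileverSpec

    def __len__(self) -> int:
        return len(self.curves)


def simulate_sensorgram(
    params: KineticParameters,
    protocol: InjectionProtocol,
    concentration: float,
    noise: SensorgramNoiseModel,
) -> Sensorgram:
    """One noisy 1:1 sensorgram at a single analyte concentration.

    The clean trace is zero before injection, follows the association model
    from ``t_assoc_start`` and decays exponentially from the association
    endpoint after ``t_assoc_end``; Gaussian noise and drift are added
    pointwise.
    """
    if not (concentration > 0):
        raise InvalidInputError(f"concentration must be > 0, got {concentration}")
    if not any(np.isclose(concentration, c) for c in protocol.concentrations):
        raise InvalidInputError(
            f"concentration {concentration} is not part of the protocol"
        )
    t = protocol.time_grid()
    clean = np.zeros_like(t)
    t0, t1, t2 = protocol.t_assoc_start, protocol.t_assoc_end, protocol.t_diss_end
    assoc = (t >= t0) & (t <= t1)
    clean[assoc] = predicted_response(params, concentration, t[assoc] - t0, "association")
    r0 = predicted_response(params, concentration, t1 - t0, "association")
    diss = t > t1
    clean[diss] = predicted_response(params, concentration, t[diss] - t1, "dissociation", r0=r0)

    rng = np.random.default_rng(noise.seed)
    out = clean + noise.baseline_drift * t
    if noise.sigma_ru > 0:
        out = out + rng.normal(0.0, noise.sigma_ru, size=t.shape)
    return Sensorgram(
        times=t, responses=out, phase_boundaries=(t0, t1, t2), concentration=concentration
    )


def simulate_sensorgram_series(
    params: KineticParameters,
    protocol: InjectionProtocol,
    noise: SensorgramNoiseModel,
) -> SensorgramSeries:
    """One sensorgram per protocol concentration, sharing (ka, kd, Rmax).

    Noise streams are sub-seeded as ``seed + index`` so each concentration's
    stream is independent of the others.  The generating parameters travel
    with the series for recovery tests.
    """
    if len(protocol.concentrations) < 2:
        raise InvalidInputError("series generation needs >= 2 concentrations")
    sensorgrams = []
    for i, c in enumerate(protocol.concentrations):
        sub = SensorgramNoiseModel(
            sigma_ru=noise.sigma_ru,
            baseline_drift=noise.baseline_drift,
            seed=noise.seed + i,
        )
        sensorgrams.append(simulate_sensorgram(params, protocol, c, sub))
    return SensorgramSeries(sensorgrams=sensorgrams, ground_truth=params)


def _draw_truncated_force(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Normal(mu, sigma) draw, redrawn until positive (forces are physical)."""
    if sigma == 0:
        return mu
    for _ in range(1000):
        f = rng.normal(mu, sigma)
        if f > 0:
            return float(f)
    raise InvalidInputError(
        f"could not draw a positive force from Normal({mu}, {sigma})"
    )


def _dip_profile(z: np.ndarray, z_start: float, z_rupture: float, depth_nm: float) -> np.ndarray:
    """Triangular adhesion dip: load linearly to -depth at z_rupture, then release."""
    out = np.zeros_like(z)
    loading = (z >= z_start) & (z <= z_rupture)
    out[loading] = -depth_nm * (z[loading] - z_start) / (z_rupture - z_start)
    return out


def simulate_force_curve(
    truth: AdhesionGroundTruth,
    cantilever: CantileverSpec,
    curve_class: str,
    seed: int,
    geometry: ForceCurveGeometry | None = None,
) -> tuple[ForceCurve, float | None]:
    """One approach/retract cycle of the stated class.

    specific: exactly one adhesion dip whose depth converts (F = k*d) to a
    truncated-normal draw from the truth distribution; zero: baseline noise
    only; nonspecific: two separated dips.  Returns the curve and the
    injected specific force (None unless class is specific).
    """
    if curve_class not in ("specific", "zero", "nonspecific"):
        raise InvalidInputError(f"unknown curve class {curve_class!r}")
    geometry = geometry or ForceCurveGeometry()
    k = cantilever.resolve_spring_constant()
    if not (k > 0):
        raise InvalidCantileverError(f"spring constant must be > 0, got {k}")
    rng = np.random.default_rng(seed)

    z = np.arange(0.0, geometry.z_max + 0.5 * geometry.dz, geometry.dz)
    noise_sd_nm = geometry.noise_sd_pn / (k * NM_NPM_TO_PN)

    contact = np.where(
        z < geometry.contact_z, geometry.contact_slope * (geometry.contact_z - z), 0.0
    )
    approach = contact + rng.normal(0.0, noise_sd_nm, size=z.shape)

    retract_clean = contact.copy()
    injected: float | None = None
    if curve_class == "specific":
        injected = _draw_truncated_force(rng, truth.mu_f, truth.sigma_f)
        retract_clean += _dip_profile(
            z, geometry.dip_z_start, geometry.dip_z_rupture, injected / (k * NM_NPM_TO_PN)
        )
    elif curve_class == "nonspecific":
        f1 = _draw_truncated_force(rng, truth.mu_f, truth.sigma_f)
        f2 = _draw_truncated_force(rng, 0.6 * truth.mu_f, max(truth.sigma_f, 1e-12))
        retract_clean += _dip_profile(
            z, geometry.dip_z_start, geometry.dip_z_rupture, f1 / (k * NM_NPM_TO_PN)
        )
        retract_clean += _dip_profile(
            z,
            geometry.second_dip_z_start,
            geometry.second_dip_z_rupture,
            f2 / (k * NM_NPM_TO_PN),
        )
    retract = (
        retract_clean
        + geometry.drift_nm_per_100nm * z / 100.0
        + rng.normal(0.0, noise_sd_nm, size=z.shape)
    )

    # approach stored far-to-near, retract near-to-far
    z_all = np.concatenate([z[::-1], z])
    d_all = np.concatenate([approach[::-1], retract])
    seg = np.array(["approach"] * z.size + ["retract"] * z.size)
    curve = ForceCurve(z_positions=z_all, deflections=d_all, segments=seg, cantilever=cantilever)
    return curve, injected


def simulate_force_batch(
    truth: AdhesionGroundTruth,
    cantilever: CantileverSpec,
    seed: int,
    geometry: ForceCurveGeometry | None = None,
) -> ForceBatch:
    """A seeded campaign of force curves with deterministic class allocation.

    Class counts are fixed by rounding the stated fractions (n_zero =
    round(frac_zero*n), likewise non-specific, remainder specific); the label
    order is a seeded permutation.  True labels and injected forces are
    retained for filter validation.
    """
    n = truth.n_curves
    n_zero = int(round(truth.frac_zero * n))
    n_nonspec = int(round(truth.frac_nonspecific * n))
    if n_zero + n_nonspec > n:
        raise InvalidInputError("class fractions allocate more curves than the batch size")
    labels = (
        ["zero"] * n_zero + ["nonspecific"] * n_nonspec + ["specific"] * (n - n_zero - n_nonspec)
    )
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n)]
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    curves, injected = [], []
    for label, child in zip(labels, child_seeds):
        curve, f = simulate_force_curve(truth, cantilever, label, int(child), geometry)
        curves.append(curve)
        injected.append(f)
    return ForceBatch(
        curves=curves,
        labels=labels,
        injected_forces=injected,
        truth=truth,
        cantilever=cantilever,
    )
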