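"""1:1 Langmuir kinetics for SPR sensorgrams.

The interaction A + B <-> AB between a flowed analyte (concentration ``C``, molar)
and an immobilized receptor produces a response ``R`` (resonance units, RU)
proportional to the amount of complex at the surface.  During association the
response follows

    R(t) = R_eq * (1 - exp(-k_obs * t)),   R_eq = C*ka*Rmax / (C*ka + kd),
    k_obs = C*ka + kd,

and during dissociation (buffer only)

    R(t) = R_0 * exp(-kd * t),

with phase-local time ``t`` re-zeroed at each phase start.  ``ka`` (1/(M*s)) and
``kd`` (1/s) are the association and dissociation rate constants, ``Rmax`` the
surface capacity, and the equilibrium dissociation constant is K_D = kd/ka (M);
smaller K_D means higher affinity.

This module provides the forward model, per-phase fits, the k_obs-vs-C
linearization, a pooled "independent" fit (the per-phase procedure most
evaluation software applies) and a joint "global" fit sharing (ka, kd, Rmax)
across all curves and phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UnfittableSegmentError,
)

__all__ = [
    "KineticParameters",
    "Sensorgram",
    "SensorgramSeries",
    "PhaseSegment",
    "DissociationFit",
    "AssociationFit",
    "KineticFitResult",
    "predicted_response",
    "steady_state_response",
    "split_phases",
    "subtract_reference",
    "fit_dissociation",
    "fit_association",
    "fit_kobs_linear",
    "fit_global",
    "compute_kd",
]

# Optimizer settings: rate constants span decades, so the global fit works on
# log-parameters; tolerances are tight because noiseless recovery tests demand
# near-machine accuracy at the optimum of zero-residual problems.
_FIT_TOL = 1e-12
_MAX_NFEV = 2000


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and surface capacity of the 1:1 interaction model."""

    ka: float  # association rate constant, 1/(M*s)
    kd: float  # dissociation rate constant, 1/s
    rmax: float  # surface binding capacity, RU

    def __post_init__(self) -> None:
        if not (self.ka > 0):
            raise InvalidInputError(f"ka must be > 0, got {self.ka}")
        if not (self.kd >= 0):
            raise InvalidInputError(f"kd must be >= 0, got {self.kd}")
        if not (self.rmax > 0):
            raise InvalidInputError(f"rmax must be > 0, got {self.rmax}")

    @property
    def kD(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return self.kd / self.ka


@dataclass
class Sensorgram:
    """Time-ordered SPR response for one analyte concentration.

    ``phase_boundaries`` is ``(t_assoc_start, t_assoc_end, t_diss_end)`` in the
    same time base as ``times``; samples before ``t_assoc_start`` are the
    pre-injection baseline.
    """

    times: np.ndarray  # s
    responses: np.ndarray  # RU
    phase_boundaries: tuple[float, float, float]
    concentration: float  # M

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.responses.shape:
            raise InvalidInputError("times and responses must be equal-length 1-D arrays")
        if self.times.size == 0:
            raise InvalidInputError("sensorgram is empty")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        t0, t1, t2 = self.phase_boundaries
        if not (t0 < t1 < t2):
            raise InvalidInputError(
                f"phase boundaries must satisfy t_assoc_start < t_assoc_end < t_diss_end, got {self.phase_boundaries}"
            )
        if t0 < self.times[0] - 1e-9 or t2 > self.times[-1] + 1e-9:
            raise InvalidInputError("phase boundaries lie outside the sampled time range")
        if not (self.concentration > 0):
            raise InvalidInputError(f"concentration must be > 0, got {self.concentration}")


@dataclass
class SensorgramSeries:
    """A multi-concentration set of sensorgrams sharing one surface.

    ``ground_truth`` carries the generating parameters when the series comes
    from the synthetic generator; it is ``None`` for instrument data.
    """

    sensorgrams: list[Sensorgram]
    ground_truth: KineticParameters | None = None

    def __post_init__(self) -> None:
        if not self.sensorgrams:
            raise InvalidInputError("series must contain at least one sensorgram")
        concs = [s.concentration for s in self.sensorgrams]
        if len(set(concs)) != len(concs):
            raise InvalidInputError("concentrations in a series must be unique")

    @property
    def concentrations(self) -> list[float]:
        return [s.concentration for s in self.sensorgrams]

    def __len__(self) -> int:
        return len(self.sensorgrams)

    def __iter__(self):
        return iter(self.sensorgrams)


@dataclass
class PhaseSegment:
    """One phase of a sensorgram with phase-local time (t=0 at phase start)."""

    times: np.ndarray
    responses: np.ndarray
    concentration: float
    phase: str  # "association" | "dissociation"


@dataclass
class DissociationFit:
    """Single-exponential decay fit R(t) = r0 * exp(-kd * t)."""

    kd_hat: float  # 1/s
    r0_hat: float  # RU
    rss: float  # RU^2
    kd_variance: float  # var(kd_hat) from the Jacobian, (1/s)^2
    converged: bool


@dataclass
class AssociationFit:
    """Mono-exponential association fit R(t) = R_eq * (1 - exp(-k_obs * t)).

    A single curve identifies only (R_eq, k_obs); ka and Rmax are resolved
    either with a fixed kd (``ka_hat``/``rmax_hat`` set) or by the
    multi-concentration analysis in :func:`fit_kobs_linear` / :func:`fit_global`.
    """

    kobs_hat: float  # 1/s
    req_hat: float  # RU
    rss: float
    converged: bool
    ka_hat: float | None = None
    rmax_hat: float | None = None


@dataclass
class KineticFitResult:
    """Joint kinetic estimate for a sensorgram series."""

    ka_hat: float  # 1/(M*s)
    kd_hat: float  # 1/s
    rmax_hat: float  # RU
    kD_hat: float  # M, always kd_hat/ka_hat
    per_phase_rss: dict[str, float]
    converged: bool
    n_curves_used: int
    mode: str = "independent"
    diagnostics: dict = field(default_factory=dict)


def predicted_response(
    params: KineticParameters,
    concentration: float,
    t: float | np.ndarray,
    phase: str = "association",
    r0: float | None = None,
):
    """Forward 1:1 model response at phase-local time ``t`` (RU).

    Association: ``R_eq*(1-exp(-k_obs t))``; dissociation: ``r0*exp(-kd t)``
    (``r0`` is the response at the end of association and must be supplied).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("phase-local time must be >= 0")
    if phase == "association":
        if not (concentration > 0):
            raise InvalidInputError(f"concentration must be > 0, got {concentration}")
        kobs = concentration * params.ka + params.kd
        req = concentration * params.ka * params.rmax / kobs
        out = req * (1.0 - np.exp(-kobs * t))
    elif phase == "dissociation":
        if r0 is None:
            raise InvalidInputError("dissociation phase requires r0")
        out = r0 * np.exp(-params.kd * t)
    else:
        raise InvalidInputError(f"unknown phase {phase!r}")
    return out if out.ndim else float(out)


def steady_state_response(params: KineticParameters, concentration: float) -> float:
    """Association plateau R_eq = Rmax*C/(C+K_D) (RU)."""
    if not (concentration > 0):
        raise InvalidInputError(f"concentration must be > 0, got {concentration}")
    kobs = concentration * params.ka + params.kd
    return concentration * params.ka * params.rmax / kobs


def split_phases(s: Sensorgram) -> tuple[PhaseSegment, PhaseSegment]:
    """Split a sensorgram into association and dissociation segments.

    Times are re-zeroed to the start of each phase and responses are offset by
    the mean of the pre-injection baseline (zero if no baseline samples exist),
    so fitted amplitudes are relative to the running-buffer level.
    """
    t0, t1, t2 = s.phase_boundaries
    baseline_mask = s.times < t0
    offset = float(s.responses[baseline_mask].mean()) if baseline_mask.any() else 0.0

    assoc_mask = (s.times >= t0) & (s.times <= t1)
    diss_mask = (s.times > t1) & (s.times <= t2)
    if assoc_mask.sum() < 4:
        raise InsufficientDataError(
            f"association segment has {int(assoc_mask.sum())} samples; need >= 4"
        )
    if diss_mask.sum() < 4:
        raise InsufficientDataError(
            f"dissociation segment has {int(diss_mask.sum())} samples; need >= 4"
        )
    assoc = PhaseSegment(
        times=s.times[assoc_mask] - t0,
        responses=s.responses[assoc_mask] - offset,
        concentration=s.concentration,
        phase="association",
    )
    diss = PhaseSegment(
        times=s.times[diss_mask] - t1,
        responses=s.responses[diss_mask] - offset,
        concentration=s.concentration,
        phase="dissociation",
    )
    return assoc, diss


def subtract_reference(s: Sensorgram, reference: Sensorgram, atol: float = 1e-9) -> Sensorgram:
    """Pointwise control-channel subtraction, aligned on time.

    The reference (a channel without immobilized receptor) must share the
    sample grid of ``s`` to within ``atol`` seconds.
    """
    if s.times.shape != reference.times.shape or not np.allclose(
        s.times, reference.times, atol=atol
    ):
        raise InvalidInputError("reference sensorgram is not sampled on the same time grid")
    return Sensorgram(
        times=s.times.copy(),
        responses=s.responses - reference.responses,
        phase_boundaries=s.phase_boundaries,
        concentration=s.concentration,
    )


def _loglinear_decay(times: np.ndarray, responses: np.ndarray) -> tuple[float, float]:
    """Closed-form log-linear regression for r0*exp(-kd*t) on positive samples."""
    pos = responses > 0
    if pos.sum() < 2:
        raise UnfittableSegmentError("fewer than 2 positive samples for log-linear start")
    slope, intercept = np.polyfit(times[pos], np.log(responses[pos]), 1)
    return max(-slope, 0.0), float(np.exp(intercept))


def fit_dissociation(segment: PhaseSegment) -> DissociationFit:
    """Nonlinear least-squares fit of the dissociation decay r0*exp(-kd*t).

    Initial values come from log-linear regression on the positive samples;
    non-convergence is flagged on the result rather than raised.
    """
    t, r = segment.times, segment.responses
    if t.size < 4:
        raise InsufficientDataError(f"dissociation fit needs >= 4 samples, got {t.size}")
    if np.all(r <= 0):
        raise UnfittableSegmentError("all dissociation responses are non-positive")
    kd0, r00 = _loglinear_decay(t, r)

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - r

    sol = least_squares(
        resid,
        x0=[max(r00, 1e-12), kd0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
        max_nfev=_MAX_NFEV,
    )
    r0_hat, kd_hat = sol.x
    rss = float(np.sum(sol.fun**2))
    kd_var = _param_variance(sol.jac, rss, t.size, index=1)
    return DissociationFit(
        kd_hat=float(kd_hat),
        r0_hat=float(r0_hat),
        rss=rss,
        kd_variance=kd_var,
        converged=bool(sol.success),
    )


def _param_variance(jac: np.ndarray, rss: float, n: int, index: int) -> float:
    """Variance of one parameter from the Gauss-Newton covariance s^2 (J'J)^-1."""
    p = jac.shape[1]
    if n <= p:
        return float("nan")
    s2 = rss / (n - p)
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return float("nan")
    return float(cov[index, index])


def fit_association(
    segment: PhaseSegment,
    concentration: float | None = None,
    kd_fixed: float | None = None,
) -> AssociationFit:
    """Fit R_eq*(1-exp(-k_obs*t)) to an association segment.

    A single curve cannot separate ka from kd: with ``kd_fixed`` supplied the
    fit resolves ``ka = (k_obs - kd)/C`` and ``Rmax = R_eq*k_obs/(C*ka)``;
    otherwise only (R_eq, k_obs) are reported and ka/Rmax are left ``None``
    for the multi-concentration analysis.
    """
    t, r = segment.times, segment.responses
    conc = segment.concentration if concentration is None else concentration
    if t.size < 4:
        raise InsufficientDataError(f"association fit needs >= 4 samples, got {t.size}")
    if not (conc > 0):
        raise InvalidInputError(f"concentration must be > 0, got {conc}")

    req0 = max(float(np.max(r)), 1e-9)
    above = np.nonzero(r >= (1.0 - np.exp(-1.0)) * req0)[0]
    t63 = t[above[0]] if above.size and t[above[0]] > 0 else max(t[-1] / 3.0, 1e-9)
    kobs0 = 1.0 / t63

    def resid(x):
        return x[0] * (1.0 - np.exp(-x[1] * t)) - r

    sol = least_squares(
        resid,
        x0=[req0, kobs0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
        max_nfev=_MAX_NFEV,
    )
    req_hat, kobs_hat = float(sol.x[0]), float(sol.x[1])
    if kobs_hat <= 1e-12:
        raise UnfittableSegmentError("fitted k_obs is not positive")
    rss = float(np.sum(sol.fun**2))
    fit = AssociationFit(
        kobs_hat=kobs_hat, req_hat=req_hat, rss=rss, converged=bool(sol.success)
    )
    if kd_fixed is not None:
        ka = (kobs_hat - kd_fixed) / conc
        if ka <= 0:
            raise UnfittableSegmentError(
                f"k_obs ({kobs_hat:.3g}) does not exceed the fixed kd ({kd_fixed:.3g})"
            )
        fit.ka_hat = ka
        fit.rmax_hat = req_hat * kobs_hat / (conc * ka)
    return fit


def fit_kobs_linear(series: SensorgramSeries) -> tuple[float, float, dict]:
    """Pseudo-first-order linearization: OLS of k_obs against concentration.

    k_obs = C*ka + kd, so the slope estimates ka and the intercept kd.  A
    negative intercept is floored at zero with a warning (it reflects noise
    when kd is small relative to the k_obs spread).
    """
    concs, kobs = [], []
    for s in series:
        try:
            assoc, _ = split_phases(s)
            fit = fit_association(assoc)
        except (InsufficientDataError, UnfittableSegmentError):
            continue
        concs.append(s.concentration)
        kobs.append(fit.kobs_hat)
    if len(set(concs)) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct concentrations with usable association fits, got {len(set(concs))}"
        )
    concs = np.asarray(concs)
    kobs = np.asarray(kobs)
    slope, intercept = np.polyfit(concs, kobs, 1)
    if slope <= 0:
        raise UnfittableSegmentError(
            "k_obs does not increase with concentration; ka estimate is non-positive"
        )
    if intercept < 0:
        warnings.warn("k_obs line intercept is negative; flooring kd at 0", stacklevel=2)
        intercept = 0.0
    diagnostics = {"concentrations": concs, "kobs": kobs}
    return float(slope), float(intercept), diagnostics


def _pooled_kd(fits: list[DissociationFit]) -> float:
    """Inverse-variance weighted mean of per-curve kd estimates.

    On (near-)noiseless data the per-fit variances vanish; a small common
    regularizer keeps the weights finite and degrades gracefully to the plain
    mean when all variances are comparable or zero.
    """
    kds = np.array([f.kd_hat for f in fits])
    variances = np.array([f.kd_variance for f in fits])
    variances = np.where(np.isfinite(variances), variances, np.nanmax(variances[np.isfinite(variances)]) if np.any(np.isfinite(variances)) else 1.0)
    eps = max(1e-12 * float(np.max(kds) ** 2 if np.max(kds) > 0 else 1.0), 1e-300)
    w = 1.0 / (variances + eps)
    return float(np.sum(w * kds) / np.sum(w))


def fit_global(series: SensorgramSeries, mode: str = "independent") -> KineticFitResult:
    """Estimate (ka, kd, Rmax, K_D) from a multi-concentration series.

    mode="independent" (default): fit each phase separately -- kd as the
    inverse-variance pooled mean of per-curve dissociation fits, ka from the
    k_obs-vs-C line constrained through that kd, Rmax averaged across curves.
    mode="global": one nonlinear least-squares over every curve and both
    phases sharing (ka, kd, Rmax) on a log scale, initialized from the
    independent fit.  Non-convergence is reported via ``converged``; K_D is
    kd_hat/ka_hat in both modes.
    """
    if mode not in ("independent", "global"):
        raise InvalidInputError(f"unknown fit mode {mode!r}")
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 concentrations for a series fit")

    segments = []  # (assoc, diss, C)
    diss_fits, assoc_fits = [], []
    for s in series:
        assoc, diss = split_phases(s)
        segments.append((assoc, diss, s.concentration))
        diss_fits.append(fit_dissociation(diss))
        assoc_fits.append(fit_association(assoc))

    kd_pooled = _pooled_kd(diss_fits)
    concs = np.array([c for _, _, c in segments])
    kobs = np.array([f.kobs_hat for f in assoc_fits])
    # constrained regression of k_obs on C with intercept fixed at kd_pooled
    ka_hat = float(np.sum(concs * (kobs - kd_pooled)) / np.sum(concs**2))
    if ka_hat <= 0:
        raise UnfittableSegmentError("pooled ka estimate is non-positive")
    rmax_per_curve = [
        f.req_hat * f.kobs_hat / (c * ka_hat) for f, c in zip(assoc_fits, concs)
    ]
    rmax_hat = float(np.mean(rmax_per_curve))
    converged = all(f.converged for f in diss_fits) and all(f.converged for f in assoc_fits)

    if mode == "global":
        x0 = np.log([ka_hat, max(kd_pooled, 1e-12), rmax_hat])

        def resid(x):
            ka, kd, rmax = np.exp(x)
            parts = []
            for assoc, diss, c in segments:
                kobs_c = c * ka + kd
                req = c * ka * rmax / kobs_c
                parts.append(req * (1.0 - np.exp(-kobs_c * assoc.times)) - assoc.responses)
                r0 = req * (1.0 - np.exp(-kobs_c * assoc.times[-1]))
                parts.append(r0 * np.exp(-kd * diss.times) - diss.responses)
            return np.concatenate(parts)

        sol = least_squares(
            resid, x0, ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_NFEV
        )
        ka_hat, kd_pooled, rmax_hat = (float(v) for v in np.exp(sol.x))
        converged = bool(sol.success)

    # per-phase residuals under the final shared parameters
    params = KineticParameters(ka=ka_hat, kd=max(kd_pooled, 0.0), rmax=rmax_hat)
    rss_assoc = rss_diss = 0.0
    for assoc, diss, c in segments:
        pred_a = predicted_response(params, c, assoc.times, "association")
        r0 = predicted_response(params, c, assoc.times[-1], "association")
        pred_d = predicted_response(params, c, diss.times, "dissociation", r0=r0)
        rss_assoc += float(np.sum((pred_a - assoc.responses) ** 2))
        rss_diss += float(np.sum((pred_d - diss.responses) ** 2))

    return KineticFitResult(
        ka_hat=ka_hat,
        kd_hat=kd_pooled,
        rmax_hat=rmax_hat,
        kD_hat=compute_kd(ka_hat, kd_pooled),
        per_phase_rss={"association": rss_assoc, "dissociation": rss_diss},
        converged=converged,
        n_curves_used=len(series),
        mode=mode,
        diagnostics={"kobs": kobs, "concentrations": concs},
    )


def compute_kd(ka_hat: float, kd_hat: float) -> float:
    """Equilibrium dissociation constant K_D = kd/ka (M)."""
    if not (ka_hat > 0):
        raise InvalidInputError(f"ka must be > 0, got {ka_hat}")
    return kd_hat / ka_hat
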