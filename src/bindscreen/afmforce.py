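"""AFM force-spectroscopy processing: from deflection traces to an adhesion force.

A functionalized cantilever tip is pressed onto a receptor-coated surface and
retracted; bound ligand-receptor pairs bend the cantilever until the bond
ruptures.  Deflection d (nm) converts to force through Hooke's law F = k*d,
with the spring constant k (N/m) either supplied or calibrated from the
cantilever's resonance via the Cleveland formula

    k = 2*w*(pi*f*L)^3 * sqrt(rho^3 / E),

where w and L are the cantilever width and length (m), f the resonant
frequency (Hz), rho the material density (kg/m^3) and E its Young's modulus
(Pa).  Retract traces are baseline-corrected, adhesion dips are detected and
classified -- curves with no event ("zero interaction") or two or more events
("non-specific") are excluded -- and the kept single-rupture forces are
binned into a histogram whose single-Gaussian peak location is reported as
the adhesion force (pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .errors import (
    InsufficientDataError,
    InvalidCantileverError,
    InvalidInputError,
)

__all__ = [
    "CantileverSpec",
    "ForceCurve",
    "RuptureEvent",
    "AdhesionHistogramFit",
    "AdhesionConfig",
    "spring_constant_from_resonance",
    "deflection_to_force",
    "correct_baseline",
    "estimate_noise_floor",
    "detect_ruptures",
    "classify_and_filter",
    "build_histogram",
    "fit_gaussian_peak",
    "fit_gaussian_mle",
    "extract_rupture_forces",
    "fit_adhesion_forces",
    "adhesion_pipeline",
]

NM_NPM_TO_PN = 1000.0  # 1 nm deflection at 1 N/m = 1000 pN
FAR_FRACTION = 0.3  # fraction of the retract trace (far from surface) used as baseline


@dataclass(frozen=True)
class CantileverSpec:
    """Cantilever stiffness, given directly or derivable from resonance.

    ``spring_constant`` (N/m) takes precedence when present; otherwise the
    geometric/material fields must all be set for the resonance calibration.
    """

    spring_constant: float | None = None  # N/m
    width_w: float | None = None  # m
    length_L: float | None = None  # m
    resonant_frequency_f: float | None = None  # Hz
    density_rho: float | None = None  # kg/m^3
    youngs_modulus_E: float | None = None  # Pa

    def resolve_spring_constant(self) -> float:
        if self.spring_constant is not None:
            if not (self.spring_constant > 0):
                raise InvalidCantileverError(
                    f"spring constant must be > 0, got {self.spring_constant}"
                )
            return float(self.spring_constant)
        return spring_constant_from_resonance(self)


@dataclass
class ForceCurve:
    """Approach/retract deflection-vs-piezo traces for one tip-surface cycle.

    z increases away from the surface; adhesion appears as negative deflection
    on the retract segment.
    """

    z_positions: np.ndarray  # nm
    deflections: np.ndarray  # nm
    segments: np.ndarray  # "approach" | "retract" per sample
    cantilever: CantileverSpec

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        self.deflections = np.asarray(self.deflections, dtype=float)
        self.segments = np.asarray(self.segments)
        if not (
            self.z_positions.shape == self.deflections.shape == self.segments.shape
        ):
            raise InvalidInputError("z, deflection and segment arrays must share a shape")

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.segments == name
        return self.z_positions[mask], self.deflections[mask]


@dataclass
class RuptureEvent:
    """One detected adhesion event on a retract trace."""

    rupture_force: float  # pN, >= 0
    z_at_rupture: float  # nm
    classification: str = "specific"  # specific | zero | nonspecific
    n_dips: int = 1


@dataclass
class AdhesionHistogramFit:
    """Rupture-force histogram with single-Gaussian parameters.

    ``mu`` (pN) is the reported adhesion force; ``degenerate`` marks the
    all-identical-forces fallback where no fit was possible and sigma is 0.
    """

    bin_edges: np.ndarray  # pN
    counts: np.ndarray
    amplitude: float
    mu: float  # pN
    sigma: float  # pN
    rss: float
    converged: bool = True
    n_forces: int = 0
    degenerate: bool = False


@dataclass
class AdhesionConfig:
    """Tunables of the adhesion pipeline."""

    threshold_factor: float = 5.0  # detection threshold = factor * noise floor
    noise_floor: float | None = None  # pN; estimated from the far region if None
    min_separation: float = 10.0  # nm; closer dips merge into one event
    bin_width: float | None = None  # pN; Freedman-Diaconis with 5 pN floor if None
    max_rupture_distance: float | None = None  # nm; events beyond flag non-specific (off)


def spring_constant_from_resonance(spec: CantileverSpec) -> float:
    """Cleveland resonance calibration k = 2w(pi f L)^3 sqrt(rho^3/E), N/m."""
    vals = {
        "width_w": spec.width_w,
        "length_L": spec.length_L,
        "resonant_frequency_f": spec.resonant_frequency_f,
        "density_rho": spec.density_rho,
        "youngs_modulus_E": spec.youngs_modulus_E,
    }
    for name, v in vals.items():
        if v is None or not (v > 0):
            raise InvalidCantileverError(f"{name} must be a positive number, got {v}")
    w, L, f = spec.width_w, spec.length_L, spec.resonant_frequency_f
    rho, E = spec.density_rho, spec.youngs_modulus_E
    return 2.0 * w * (np.pi * f * L) ** 3 * np.sqrt(rho**3 / E)


def deflection_to_force(d_nm, k: float):
    """Hooke's law F = k*d with units nm * (N/m) -> pN."""
    if not (k > 0):
        raise InvalidInputError(f"spring constant must be > 0, got {k}")
    return np.asarray(d_nm, dtype=float) * k * NM_NPM_TO_PN if np.ndim(d_nm) else float(d_nm) * k * NM_NPM_TO_PN


def _far_region(z: np.ndarray, fraction: float = FAR_FRACTION) -> np.ndarray:
    """Boolean mask selecting the ``fraction`` of samples farthest from the surface."""
    n_far = max(int(round(fraction * z.size)), 2)
    order = np.argsort(z)
    mask = np.zeros(z.size, dtype=bool)
    mask[order[-n_far:]] = True
    return mask


def correct_baseline(curve: ForceCurve) -> ForceCurve:
    """Remove linear drift from the retract trace.

    A least-squares line is fitted to the far-from-surface 30% of the retract
    segment (where the tip is free) and subtracted from the whole retract
    trace; the approach trace is left untouched.  Idempotent on drift-free data.
    """
    retract = curve.segments == "retract"
    if retract.sum() < 10:
        raise InsufficientDataError("retract segment too short for baseline correction")
    z_r = curve.z_positions[retract]
    d_r = curve.deflections[retract]
    far = _far_region(z_r)
    if far.sum() < 2:
        raise InsufficientDataError("far region too small for baseline fit")
    slope, intercept = np.polyfit(z_r[far], d_r[far], 1)
    corrected = curve.deflections.copy()
    corrected[retract] = d_r - (slope * z_r + intercept)
    return ForceCurve(
        z_positions=curve.z_positions.copy(),
        deflections=corrected,
        segments=curve.segments.copy(),
        cantilever=curve.cantilever,
    )


def estimate_noise_floor(curve: ForceCurve) -> float:
    """Noise floor (pN): s.d. of the far 30% of the baseline-corrected retract force."""
    z_r, d_r = curve.segment("retract")
    if z_r.size < 10:
        raise InsufficientDataError("retract segment too short for noise estimation")
    k = curve.cantilever.resolve_spring_constant()
    far = _far_region(z_r)
    return float(np.std(deflection_to_force(d_r[far], k)))


def detect_ruptures(
    curve: ForceCurve,
    noise_floor: float | None = None,
    min_separation: float = 10.0,
    threshold_factor: float = 5.0,
) -> list[RuptureEvent]:
    """Find adhesion dips on a baseline-corrected retract trace.

    A dip is a run of samples whose force is below ``-threshold_factor *
    noise_floor``; runs separated by less than ``min_separation`` nm merge.
    Each event's rupture force is the magnitude of the deepest point of its
    dip.  Events are returned in increasing-z order; an empty list is valid.
    """
    z_r, d_r = curve.segment("retract")
    if z_r.size == 0:
        raise InsufficientDataError("curve has no retract segment")
    k = curve.cantilever.resolve_spring_constant()
    force = deflection_to_force(d_r, k)
    if noise_floor is None:
        noise_floor = estimate_noise_floor(curve)
    threshold = -threshold_factor * noise_floor

    order = np.argsort(z_r)
    z_s, f_s = z_r[order], force[order]
    below = f_s < threshold
    if not below.any():
        return []
    # contiguous below-threshold runs
    idx = np.nonzero(below)[0]
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    # merge runs whose z-gap is below min_separation
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if z_s[start] - z_s[merged[-1][1]] < min_separation:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    for start, stop in merged:
        seg = slice(start, stop + 1)
        i_min = start + int(np.argmin(f_s[seg]))
        events.append(
            RuptureEvent(
                rupture_force=float(-f_s[i_min]),
                z_at_rupture=float(z_s[i_min]),
            )
        )
    return events


def classify_and_filter(
    events_per_curve: list[list[RuptureEvent]],
    noise_floor: float | None = None,
    max_rupture_distance: float | None = None,
) -> tuple[list[float], list[tuple[int, str]]]:
    """Apply the exclusion rules to per-curve event lists.

    Curves with no detected event are "zero interaction", curves with two or
    more events (or, optionally, an event beyond ``max_rupture_distance`` nm)
    are "non-specific"; both classes are rejected.  Exactly one event keeps
    its rupture force.  Returns the kept forces and a rejection log of
    ``(curve_index, reason)``.
    """
    kept: list[float] = []
    log: list[tuple[int, str]] = []
    for i, events in enumerate(events_per_curve):
        if len(events) == 0:
            log.append((i, "zero interaction"))
        elif len(events) >= 2:
            log.append((i, "non-specific"))
        elif (
            max_rupture_distance is not None
            and events[0].z_at_rupture > max_rupture_distance
        ):
            log.append((i, "non-specific"))
        else:
            kept.append(events[0].rupture_force)
    return kept, log


def build_histogram(
    forces: list[float] | np.ndarray, bin_width: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bin rupture forces into uniform bins spanning [0, max + one bin].

    ``bin_width=None`` selects the Freedman-Diaconis width with a 5 pN floor.
    Returns (bin_edges, counts).
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise InsufficientDataError("no rupture forces to histogram")
    if bin_width is None:
        iqr = float(np.subtract(*np.percentile(forces, [75, 25])))
        fd = 2.0 * iqr / forces.size ** (1.0 / 3.0)
        bin_width = max(fd, 5.0)
    if not (bin_width > 0):
        raise InvalidInputError(f"bin width must be > 0, got {bin_width}")
    top = float(np.max(forces)) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(forces, bins=edges)
    return edges, counts


def fit_gaussian_peak(
    bin_edges: np.ndarray, counts: np.ndarray, n_forces: int | None = None
) -> AdhesionHistogramFit:
    """Least-squares single-Gaussian fit A*exp(-(x-mu)^2/(2 sigma^2)) to bin counts.

    Initialized at the modal bin (mu, A) with sigma from the binned sample
    s.d.; requires >= 4 occupied bins.  ``mu`` is the adhesion force.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    occupied = int(np.count_nonzero(counts))
    if occupied < 4:
        raise InsufficientDataError(
            f"Gaussian fit needs >= 4 occupied bins, got {occupied}"
        )
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    i_mode = int(np.argmax(counts))
    mu0 = centers[i_mode]
    total = counts.sum()
    mean0 = float(np.sum(centers * counts) / total)
    var0 = float(np.sum((centers - mean0) ** 2 * counts) / total)
    sigma0 = max(np.sqrt(var0), (bin_edges[1] - bin_edges[0]) / 2.0)
    a0 = float(counts[i_mode])

    def model(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            model, centers, counts, p0=[a0, mu0, sigma0], maxfev=10000
        )
        converged = True
    except RuntimeError:
        popt, converged = (a0, mu0, sigma0), False
    a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    rss = float(np.sum((model(centers, a, mu, sigma) - counts) ** 2))
    return AdhesionHistogramFit(
        bin_edges=bin_edges,
        counts=counts.astype(int),
        amplitude=a,
        mu=mu,
        sigma=sigma,
        rss=rss,
        converged=converged,
        n_forces=int(n_forces) if n_forces is not None else int(total),
    )


def fit_gaussian_mle(forces) -> tuple[float, float]:
    """Maximum-likelihood normal fit on the raw forces (cross-check mode)."""
    forces = np.asarray(forces, dtype=float)
    if forces.size < 2:
        raise InsufficientDataError("MLE fit needs >= 2 forces")
    mu, sigma = norm.fit(forces)
    return float(mu), float(sigma)


def extract_rupture_forces(
    curves: list[ForceCurve], config: AdhesionConfig | None = None
) -> tuple[list[float], list[tuple[int, str]]]:
    """Baseline-correct, detect and filter: the per-curve half of the pipeline.

    Returns the kept single-rupture forces (pN) and the rejection log.
    Raises if every curve is rejected, naming the dominant rejection reason.
    """
    if not curves:
        raise InsufficientDataError("no force curves supplied")
    config = config or AdhesionConfig()
    events_per_curve = []
    for curve in curves:
        corrected = correct_baseline(curve)
        noise = (
            config.noise_floor
            if config.noise_floor is not None
            else estimate_noise_floor(corrected)
        )
        events_per_curve.append(
            detect_ruptures(
                corrected,
                noise_floor=noise,
                min_separation=config.min_separation,
                threshold_factor=config.threshold_factor,
            )
        )
    kept, log = classify_and_filter(
        events_per_curve, max_rupture_distance=config.max_rupture_distance
    )
    if not kept:
        reasons = [r for _, r in log]
        dominant = max(set(reasons), key=reasons.count)
        raise InsufficientDataError(
            f"all {len(curves)} curves rejected (dominant reason: {dominant})"
        )
    return kept, log


def fit_adhesion_forces(
    kept: list[float] | np.ndarray, config: AdhesionConfig | None = None
) -> AdhesionHistogramFit:
    """Histogram + single-Gaussian fit on already-filtered rupture forces.

    If every force is identical (a noiseless degenerate batch) the unique
    value is reported with sigma 0 and ``degenerate=True`` instead of
    attempting an unfittable histogram.
    """
    config = config or AdhesionConfig()
    forces = np.asarray(kept, dtype=float)
    if forces.size == 0:
        raise InsufficientDataError("no rupture forces to fit")
    if np.ptp(forces) < 1e-9:
        # all forces identical: histogram fit is degenerate by construction
        value = float(forces[0])
        bw = config.bin_width or 5.0
        edges, counts = build_histogram(forces, bin_width=bw)
        return AdhesionHistogramFit(
            bin_edges=edges,
            counts=counts,
            amplitude=float(forces.size),
            mu=value,
            sigma=0.0,
            rss=0.0,
            converged=True,
            n_forces=forces.size,
            degenerate=True,
        )
    edges, counts = build_histogram(forces, bin_width=config.bin_width)
    return fit_gaussian_peak(edges, counts, n_forces=forces.size)


def adhesion_pipeline(
    curves: list[ForceCurve], config: AdhesionConfig | None = None
) -> tuple[AdhesionHistogramFit, list[tuple[int, str]]]:
    """End-to-end adhesion analysis: correct, detect, filter, bin, fit.

    Deterministic given inputs and config.  Composes
    :func:`extract_rupture_forces` and :func:`fit_adhesion_forces`.
    """
    config = config or AdhesionConfig()
    kept, log = extract_rupture_forces(curves, config)
    return fit_adhesion_forces(kept, config), log
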