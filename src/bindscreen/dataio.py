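"""CSV/JSON/YAML readers and writers, run configuration, and the full pipeline.

File dialects (documented so instrument exports can be converted):

* Sensorgram CSV: header ``time_s,response_ru,phase,concentration_M`` with
  ``phase`` in {baseline, association, dissociation}; one concentration per
  file or several concatenated (grouped by ``concentration_M``).  Phase
  boundaries are reconstructed from the phase labels.
* Force-curve CSV: header ``z_nm,deflection_nm,segment`` with ``segment`` in
  {approach, retract}; cantilever metadata lives in a JSON or YAML sidecar
  holding either ``spring_constant_n_per_m`` or the full resonance-geometry
  fields.

Floats are written with 17 significant digits so write -> read round-trips
are bit-exact.  All internal units are fixed (s, RU, M, nm, pN, N/m);
conversion happens only at these boundaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afmforce, screenreport, sprkinetics, synthdata
from .errors import InvalidInputError, InvalidMetadataError

logger = logging.getLogger("bindscreen")

__all__ = [
    "RunConfig",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "read_force_curve_csv",
    "write_force_curve_csv",
    "write_kinetic_result",
    "write_adhesion_result",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"

SENSORGRAM_COLUMNS = ["time_s", "response_ru", "phase", "concentration_M"]
FORCE_COLUMNS = ["z_nm", "deflection_nm", "segment"]

_GEOMETRY_KEYS = {
    "width_w_m": "width_w",
    "length_L_m": "length_L",
    "resonant_frequency_hz": "resonant_frequency_f",
    "density_kg_per_m3": "density_rho",
    "youngs_modulus_pa": "youngs_modulus_E",
}


# ---------------------------------------------------------------------------
# sensorgram CSV


def write_sensorgram_csv(sensorgrams, path) -> None:
    """Write one or more sensorgrams to a tidy CSV (17-digit floats)."""
    if isinstance(sensorgrams, sprkinetics.Sensorgram):
        sensorgrams = [sensorgrams]
    frames = []
    for s in sensorgrams:
        t0, t1, _ = s.phase_boundaries
        phase = np.where(
            s.times < t0, "baseline", np.where(s.times <= t1, "association", "dissociation")
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "response_ru": s.responses,
                    "phase": phase,
                    "concentration_M": s.concentration,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any() or values.isna().any():
        row = int(np.nonzero(values.isna().to_numpy())[0][0])
        raise InvalidInputError(
            f"{path}: non-numeric value in column {column!r} at data row {row}"
        )
    return values.to_numpy(dtype=float)


def read_sensorgram_csv(path) -> list[sprkinetics.Sensorgram]:
    """Read sensorgrams, one per distinct concentration, validating as it goes."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SENSORGRAM_COLUMNS, path)
    times = _numeric(df, "time_s", path)
    responses = _numeric(df, "response_ru", path)
    concs = _numeric(df, "concentration_M", path)
    phases = df["phase"].astype(str).to_numpy()
    valid_phases = {"baseline", "association", "dissociation"}
    bad_phase = ~np.isin(phases, list(valid_phases))
    if bad_phase.any():
        row = int(np.nonzero(bad_phase)[0][0])
        raise InvalidInputError(
            f"{path}: unknown phase {phases[row]!r} at data row {row}; "
            f"expected one of {sorted(valid_phases)}"
        )

    out = []
    for conc in pd.unique(concs):
        mask = concs == conc
        t, r, ph = times[mask], responses[mask], phases[mask]
        steps = np.diff(t)
        if np.any(steps <= 0):
            row = int(np.nonzero(mask)[0][int(np.nonzero(steps <= 0)[0][0]) + 1])
            raise InvalidInputError(
                f"{path}: time not strictly increasing at data row {row}"
            )
        assoc = ph == "association"
        diss = ph == "dissociation"
        if not assoc.any() or not diss.any():
            raise InvalidInputError(
                f"{path}: concentration {conc} lacks association or dissociation rows"
            )
        boundaries = (float(t[assoc][0]), float(t[assoc][-1]), float(t[diss][-1]))
        out.append(
            sprkinetics.Sensorgram(
                times=t, responses=r, phase_boundaries=boundaries, concentration=float(conc)
            )
        )
    return out


# ---------------------------------------------------------------------------
# force-curve CSV + sidecar


def write_force_curve_csv(curve: afmforce.ForceCurve, path, sidecar_path=None) -> None:
    """Write a force curve; optionally write its cantilever sidecar (JSON/YAML)."""
    pd.DataFrame(
        {
            "z_nm": curve.z_positions,
            "deflection_nm": curve.deflections,
            "segment": curve.segments,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar_path is not None:
        spec = curve.cantilever
        meta = {}
        if spec.spring_constant is not None:
            meta["spring_constant_n_per_m"] = spec.spring_constant
        for file_key, attr in _GEOMETRY_KEYS.items():
            if getattr(spec, attr) is not None:
                meta[file_key] = getattr(spec, attr)
        sidecar_path = Path(sidecar_path)
        text = (
            json.dumps(meta, indent=2)
            if sidecar_path.suffix == ".json"
            else yaml.safe_dump(meta)
        )
        sidecar_path.write_text(text)


def _load_sidecar(sidecar_path) -> dict:
    sidecar_path = Path(sidecar_path)
    text = sidecar_path.read_text()
    data = json.loads(text) if sidecar_path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidMetadataError(f"{sidecar_path}: sidecar must be a mapping")
    return data


def cantilever_from_sidecar(sidecar_path) -> afmforce.CantileverSpec:
    """Resolve a CantileverSpec from a sidecar file.

    A direct ``spring_constant_n_per_m`` wins over geometry; if both are
    present and disagree, the direct value is used and a warning is issued.
    """
    meta = _load_sidecar(sidecar_path)
    direct = meta.get("spring_constant_n_per_m")
    geometry = {attr: meta.get(file_key) for file_key, attr in _GEOMETRY_KEYS.items()}
    has_geometry = all(v is not None for v in geometry.values())
    if direct is None and not has_geometry:
        raise InvalidMetadataError(
            f"{sidecar_path}: need spring_constant_n_per_m or the full geometry "
            f"fields {sorted(_GEOMETRY_KEYS)}"
        )
    spec = afmforce.CantileverSpec(spring_constant=direct, **geometry)
    if direct is not None and has_geometry:
        derived = afmforce.spring_constant_from_resonance(spec)
        if not np.isclose(derived, direct, rtol=0.05):
            warnings.warn(
                f"{sidecar_path}: direct spring constant {direct} N/m disagrees with "
                f"geometry-derived {derived:.4g} N/m; using the direct value",
                stacklevel=2,
            )
    return spec


def read_force_curve_csv(path, sidecar_path) -> afmforce.ForceCurve:
    """Read one force curve, resolving its cantilever from the sidecar."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FORCE_COLUMNS, path)
    z = _numeric(df, "z_nm", path)
    d = _numeric(df, "deflection_nm", path)
    seg = df["segment"].astype(str).to_numpy()
    bad = ~np.isin(seg, ["approach", "retract"])
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise InvalidInputError(
            f"{path}: unknown segment {seg[row]!r} at data row {row}"
        )
    return afmforce.ForceCurve(
        z_positions=z, deflections=d, segments=seg, cantilever=cantilever_from_sidecar(sidecar_path)
    )


# ---------------------------------------------------------------------------
# result writers


def write_kinetic_result(result: sprkinetics.KineticFitResult, out_dir, name: str) -> None:
    """JSON with full diagnostics plus a one-row TSV summary (ka, kd, KD)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "molecule": name,
        "ka_per_M_s": result.ka_hat,
        "kd_per_s": result.kd_hat,
        "rmax_ru": result.rmax_hat,
        "kD_M": result.kD_hat,
        "per_phase_rss_ru2": result.per_phase_rss,
        "converged": result.converged,
        "n_curves_used": result.n_curves_used,
        "mode": result.mode,
    }
    (out_dir / f"{name}_spr_fit.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        [{"molecule": name, "ka_per_M_s": result.ka_hat, "kd_per_s": result.kd_hat,
          "kD_M": result.kD_hat}]
    ).to_csv(out_dir / f"{name}_spr_summary.tsv", sep="\t", index=False,
             float_format=_FLOAT_FMT)


def write_adhesion_result(
    fit: afmforce.AdhesionHistogramFit,
    rejection_log: list[tuple[int, str]],
    kept_forces,
    out_dir,
    name: str,
) -> None:
    """Kept forces TSV, histogram TSV, Gaussian fit JSON and rejection log TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"force_pN": np.asarray(kept_forces)}).to_csv(
        out_dir / f"{name}_forces.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        {
            "bin_left_pN": fit.bin_edges[:-1],
            "bin_right_pN": fit.bin_edges[1:],
            "count": fit.counts,
        }
    ).to_csv(out_dir / f"{name}_histogram.tsv", sep="\t", index=False,
             float_format=_FLOAT_FMT)
    (out_dir / f"{name}_afm_fit.json").write_text(
        json.dumps(
            {
                "molecule": name,
                "adhesion_force_pN": fit.mu,
                "sigma_pN": fit.sigma,
                "amplitude": fit.amplitude,
                "rss": fit.rss,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
                "n_forces": fit.n_forces,
            },
            indent=2,
        )
    )
    pd.DataFrame(rejection_log, columns=["curve_id", "reason"]).to_csv(
        out_dir / f"{name}_rejections.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline


_TOP_KEYS = {"seed", "out_dir", "log_level", "reference", "molecules", "protocol",
             "noise", "afm", "spr"}
_MOLECULE_KEYS = {"name", "ka", "kd", "rmax", "mu_f", "sigma_f", "frac_zero",
                  "frac_nonspecific", "n_curves", "concentrations"}
_PROTOCOL_KEYS = {"t_assoc_start", "t_assoc_end", "t_diss_end", "sampling_interval",
                  "concentrations"}
_NOISE_KEYS = {"sigma_ru", "baseline_drift"}
_AFM_KEYS = {"bin_width", "threshold_factor", "min_separation", "noise_sd_pn",
             "spring_constant", "max_rupture_distance"}
_SPR_KEYS = {"mode"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise InvalidInputError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated configuration of a full simulate -> fit -> rank run."""

    seed: int = 0
    out_dir: str = "bindscreen_out"
    log_level: str = "INFO"
    reference: str | None = None
    molecules: list[dict] = field(default_factory=list)
    protocol: dict = field(default_factory=dict)
    noise: dict = field(default_factory=lambda: {"sigma_ru": 1.0})
    spr: dict = field(default_factory=lambda: {"mode": "independent"})
    afm: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise InvalidInputError("run config must be a mapping")
        _reject_unknown(data, _TOP_KEYS, "run config")
        for mol in data.get("molecules", []):
            _reject_unknown(mol, _MOLECULE_KEYS, f"molecule {mol.get('name', '?')!r}")
            if "name" not in mol:
                raise InvalidInputError("every molecule needs a 'name'")
        _reject_unknown(data.get("protocol", {}), _PROTOCOL_KEYS, "protocol")
        _reject_unknown(data.get("noise", {}), _NOISE_KEYS, "noise")
        _reject_unknown(data.get("afm", {}), _AFM_KEYS, "afm")
        _reject_unknown(data.get("spr", {}), _SPR_KEYS, "spr")
        return cls(**{k: v for k, v in data.items() if k in _TOP_KEYS})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _config_hash(config: RunConfig) -> str:
    # hash covers the scientific settings only, not where artifacts land
    payload = {k: v for k, v in asdict(config).items() if k not in ("out_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate each molecule, fit both arms, rank, and write artifacts.

    Every artifact lands under ``config.out_dir`` together with a manifest
    recording the config hash, seed and package version; identical config and
    seed reproduce identical numeric outputs.  Returns the manifest.
    """
    if not config.molecules:
        raise InvalidInputError("run config lists no molecules; nothing to do")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    proto_kwargs = {"t_assoc_start": 30.0, "t_assoc_end": 330.0, "t_diss_end": 630.0}
    proto_kwargs.update(config.protocol)
    if "concentrations" in proto_kwargs:
        proto_kwargs["concentrations"] = tuple(float(c) for c in proto_kwargs["concentrations"])

    def molecule_protocol(mol: dict) -> synthdata.InjectionProtocol:
        # weak binders are screened at their own, higher concentration series
        kwargs = dict(proto_kwargs)
        if "concentrations" in mol:
            kwargs["concentrations"] = tuple(float(c) for c in mol["concentrations"])
        return synthdata.InjectionProtocol(**kwargs)
    spring_constant = float(config.afm.get("spring_constant", 0.105))
    cantilever = afmforce.CantileverSpec(spring_constant=spring_constant)
    adhesion_cfg = afmforce.AdhesionConfig(
        threshold_factor=float(config.afm.get("threshold_factor", 5.0)),
        min_separation=float(config.afm.get("min_separation", 10.0)),
        bin_width=config.afm.get("bin_width"),
        max_rupture_distance=config.afm.get("max_rupture_distance"),
    )
    geometry = synthdata.ForceCurveGeometry(
        noise_sd_pn=float(config.afm.get("noise_sd_pn", 5.0))
    )
    mode = config.spr.get("mode", "independent")

    kd_map: dict[str, float] = {}
    force_map: dict[str, float] = {}
    for i, mol in enumerate(config.molecules):
        name = mol["name"]
        logger.info("processing molecule %s", name)
        params = sprkinetics.KineticParameters(
            ka=float(mol.get("ka", 1e5)),
            kd=float(mol.get("kd", 1e-2)),
            rmax=float(mol.get("rmax", 100.0)),
        )
        noise = synthdata.SensorgramNoiseModel(
            sigma_ru=float(config.noise.get("sigma_ru", 1.0)),
            baseline_drift=float(config.noise.get("baseline_drift", 0.0)),
            seed=config.seed + 1000 * i,
        )
        series = synthdata.simulate_sensorgram_series(params, molecule_protocol(mol), noise)
        write_sensorgram_csv(series.sensorgrams, out_dir / f"{name}_sensorgrams.csv")
        result = sprkinetics.fit_global(series, mode=mode)
        write_kinetic_result(result, out_dir, name)
        kd_map[name] = result.kD_hat

        truth = synthdata.AdhesionGroundTruth(
            mu_f=float(mol.get("mu_f", 210.0)),
            sigma_f=float(mol.get("sigma_f", 30.0)),
            frac_zero=float(mol.get("frac_zero", 0.2)),
            frac_nonspecific=float(mol.get("frac_nonspecific", 0.1)),
            n_curves=int(mol.get("n_curves", 300)),
        )
        batch = synthdata.simulate_force_batch(
            truth, cantilever, seed=config.seed + 1000 * i + 500, geometry=geometry
        )
        kept, log = afmforce.extract_rupture_forces(batch.curves, adhesion_cfg)
        fit = afmforce.fit_adhesion_forces(kept, adhesion_cfg)
        write_adhesion_result(fit, log, kept, out_dir, name)
        force_map[name] = fit.mu

    reference = config.reference or config.molecules[0]["name"]
    table = screenreport.compare_to_reference(kd_map, force_map, reference)
    table.to_dataframe().to_csv(
        out_dir / "screening.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    (out_dir / "screening_summary.txt").write_text(table.summary() + "\n")

    from . import __version__

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "molecules": [m["name"] for m in config.molecules],
        "reference": reference,
        "kD_M": kd_map,
        "adhesion_pN": force_map,
        "artifacts": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
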