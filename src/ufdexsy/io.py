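"""File formats and configuration.

Everything is plain delimited text so that datasets, exchange maps, fit
results and configs are diffable and portable:

* raw 2D matrices: whitespace-delimited rows with ``#``-prefixed header
  lines carrying the axes, echo time, noise level, seed and provenance;
* exchange maps: one row per mixing time
  ``(tau_M, w_11, w_12, w_21, w_22, residual)``;
* coil profiles: two columns ``(depth_m, sensitivity)``;
* configs and manifests: flat ``key = value`` lines with namespaced keys
  whose suffix states the unit (``instrument.B0_T``,
  ``encoding.delta_max_us``, ``sample.intra.D_m2s``, ...), converted to SI
  on read; unknown keys are rejected.
"""

from __future__ import annotations

import ast
import math
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np

from .inversion import ExchangeMap
from .kinetics import ExchangeFitResult
from .model_core import (CoilProfile, CpmgSpec, EncodingSpec, InstrumentSpec,
                         TwoSiteSample, build_coil_profile,
                         default_coil_profile)
from .readout import RawData2D
from .synthetic import Scenario

__all__ = [
    "read_matrix", "write_matrix",
    "read_maps", "write_maps",
    "read_coil_profile", "write_coil_profile",
    "write_fit_result",
    "read_config", "write_manifest", "read_manifest",
    "scenario_from_config",
]

_FMT = "%.17g"  # full double precision for lossless text round-trips


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------- raw data

def write_matrix(data: RawData2D, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "ufdexsy raw 2D matrix: rows = depth/frequency index, cols = echo index",
        f"shape: {data.matrix.shape[0]} {data.matrix.shape[1]}",
        f"echo_time_s: {data.echo_time!r}",
        f"noise_sigma: {data.noise_sigma!r}",
        f"seed: {data.seed if data.seed is not None else 'none'}",
        "depth_axis_m: " + " ".join(_FMT % v for v in data.depth_axis),
        "freq_axis_Hz: " + " ".join(_FMT % v for v in data.freq_axis),
    ]
    for key in sorted(data.provenance):
        lines.append(f"prov.{key}: {data.provenance[key]!r}")
    np.savetxt(path, data.matrix, fmt=_FMT, header="\n".join(lines))


def read_matrix(path: str | Path) -> RawData2D:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if ":" in text:
                key, _, value = text.partition(":")
                header[key.strip()] = value.strip()
    try:
        shape = tuple(int(v) for v in header["shape"].split())
        echo_time = float(header["echo_time_s"])
        sigma = float(header["noise_sigma"])
        seed = None if header["seed"] == "none" else int(header["seed"])
        depth = np.array([float(v) for v in header["depth_axis_m"].split()])
        freq = np.array([float(v) for v in header["freq_axis_Hz"].split()])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed or missing header field ({exc})") from exc
    matrix = np.loadtxt(path, ndmin=2)
    if matrix.shape != shape:
        raise ParseError(f"{path}: matrix shape {matrix.shape} != declared {shape}")
    if depth.size != shape[0] or freq.size != shape[0]:
        raise ParseError(f"{path}: axis length does not match {shape[0]} rows "
                         "(lines 'depth_axis_m'/'freq_axis_Hz')")
    bad = np.argwhere(~np.isfinite(matrix))
    if bad.size:
        q, n = bad[0]
        raise ParseError(f"{path}: non-finite entry at row {q}, column {n}")
    prov: dict[str, Any] = {}
    for key, value in header.items():
        if key.startswith("prov."):
            try:
                prov[key[5:]] = ast.literal_eval(value)
            except (ValueError, SyntaxError):
                try:
                    prov[key[5:]] = float(value)  # covers 'inf'
                except ValueError:
                    prov[key[5:]] = value
    return RawData2D(matrix=matrix, depth_axis=depth, freq_axis=freq,
                     echo_time=echo_time, noise_sigma=sigma, seed=seed,
                     provenance=prov)


# ------------------------------------------------------------ exchange maps

def write_maps(maps: list[ExchangeMap], path: str | Path) -> None:
    rows = np.array([
        [m.tau_M, *m.weights.ravel(), m.residual] for m in maps
    ])
    np.savetxt(path, rows, fmt=_FMT,
               header="tau_M_s w_11 w_12 w_21 w_22 residual")


def read_maps(path: str | Path) -> list[ExchangeMap]:
    rows = np.loadtxt(path, ndmin=2)
    if rows.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 columns "
                         "(tau_M w_11 w_12 w_21 w_22 residual)")
    maps = []
    for r in rows:
        w = r[1:5].reshape(2, 2)
        w = w / w.sum()  # guard against last-digit rounding in text form
        maps.append(ExchangeMap(tau_M=float(r[0]), weights=w, residual=float(r[5])))
    return maps


# ------------------------------------------------------------- coil profile

def write_coil_profile(profile: CoilProfile, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([profile.depths, profile.sensitivities]),
               fmt=_FMT, header="depth_m sensitivity")


def read_coil_profile(path: str | Path) -> CoilProfile:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (depth_m, sensitivity)")
    return build_coil_profile(arr)


# --------------------------------------------------------------- fit result

def write_fit_result(fit: ExchangeFitResult, path: str | Path) -> None:
    lines = [
        f"k_per_s = {fit.k!r}",
        f"k_err_per_s = {fit.k_err!r}",
        f"p_intra = {fit.p_intra!r}",
        f"p_intra_err = {fit.p_err!r}",
        f"k_intra_per_s = {fit.k_intra!r}",
        f"k_intra_err_per_s = {fit.k_intra_err!r}",
        f"k_extra_per_s = {fit.k_extra!r}",
        f"k_extra_err_per_s = {fit.k_extra_err!r}",
        f"tau_intra_s = {fit.tau_intra!r}",
        f"tau_intra_err_s = {fit.tau_intra_err!r}",
        f"identifiable = {fit.identifiable}",
        f"n_points = {fit.n_points}",
    ]
    if fit.covariance is not None:
        flat = " ".join(_FMT % v for v in np.asarray(fit.covariance).ravel())
        lines.append(f"covariance_row_major = {flat}")
    lines.append("tau_M_values_s = " + " ".join(_FMT % v for v in fit.tau_values))
    lines.append("residuals = " + " ".join(_FMT % v for v in fit.residuals))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------ config and manifest

def _parse_kv_lines(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in out:
            raise ParseError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = value
    return out


#: base config key -> {unit suffix: factor to SI}
_UNIT_KEYS = {
    "instrument.B0": {"_T": 1.0},
    "instrument.G": {"_Tm": 1.0, "_T_per_m": 1.0},
    "encoding.bandwidth": {"_Hz": 1.0, "_kHz": 1e3, "_MHz": 1e6},
    "encoding.delta_max": {"_s": 1.0, "_ms": 1e-3, "_us": 1e-6},
    "encoding.storage": {"_s": 1.0, "_ms": 1e-3},
    "cpmg.tE": {"_s": 1.0, "_ms": 1e-3, "_us": 1e-6},
    "cpmg.dwell": {"_s": 1.0, "_us": 1e-6},
    "sample.intra.D": {"_m2s": 1.0},
    "sample.extra.D": {"_m2s": 1.0},
    "sample.intra.T1": {"_s": 1.0, "_ms": 1e-3},
    "sample.intra.T2": {"_s": 1.0, "_ms": 1e-3},
    "sample.extra.T1": {"_s": 1.0, "_ms": 1e-3},
    "sample.extra.T2": {"_s": 1.0, "_ms": 1e-3},
    "sample.k": {"_per_s": 1.0},
    "mixing_times": {"_s": 1.0, "_ms": 1e-3},
}
_PLAIN_KEYS = {
    "encoding.edge_depth", "encoding.edge_width_frac",
    "cpmg.n_echoes", "cpmg.points_per_echo",
    "sample.intra.p",
    "snr", "seed", "grid.n_depth", "mixing.n_substeps",
    "amplitude.lo", "amplitude.hi", "coil.file",
}


def _canonicalize(key: str) -> tuple[str, float]:
    """Map a unit-suffixed key to its base name and SI conversion factor."""
    if key in _PLAIN_KEYS:
        return key, 1.0
    for base, units in _UNIT_KEYS.items():
        for suffix, factor in units.items():
            if key == base + suffix:
                return base, factor
    known = sorted(_PLAIN_KEYS | {b + s for b, u in _UNIT_KEYS.items() for s in u})
    raise ParseError(f"unknown config key {key!r}; known keys: {', '.join(known)}")


def read_config(path: str | Path) -> dict[str, Any]:
    """Parse a flat config file into SI-valued entries keyed by base name."""
    out: dict[str, Any] = {}
    for key, value in _parse_kv_lines(path).items():
        base, factor = _canonicalize(key)
        if base in out:
            raise ParseError(f"{path}: key {base!r} given more than once "
                             "(possibly with different unit suffixes)")
        if base == "coil.file":
            out[base] = value
        elif base == "mixing_times":
            out[base] = tuple(float(v) * factor for v in value.replace(",", " ").split())
        else:
            v = float(value) if value != "inf" else math.inf
            out[base] = v * factor
    return out


def scenario_from_config(path: str | Path | None, seed: int | None = None) -> Scenario:
    """Build a Scenario from a config file; missing keys take the reference
    (yeast-suspension) defaults.  ``path=None`` gives the pure defaults."""
    cfg = read_config(path) if path is not None else {}
    ref = Scenario.reference()
    instrument = InstrumentSpec(
        B0=cfg.get("instrument.B0", ref.instrument.B0),
        G=cfg.get("instrument.G", ref.instrument.G),
    )
    encoding = EncodingSpec(
        bandwidth=cfg.get("encoding.bandwidth", ref.encoding.bandwidth),
        delta_max=cfg.get("encoding.delta_max", ref.encoding.delta_max),
        storage_interval=cfg.get("encoding.storage", ref.encoding.storage_interval),
        edge_depth=cfg.get("encoding.edge_depth", ref.encoding.edge_depth),
        edge_width_frac=cfg.get("encoding.edge_width_frac", ref.encoding.edge_width_frac),
    )
    if "coil.file" in cfg:
        coil = read_coil_profile(cfg["coil.file"])
    else:
        coil = default_coil_profile(encoding.extent(instrument))
    instrument = replace(instrument, coil=coil)
    cpmg = CpmgSpec(
        echo_time=cfg.get("cpmg.tE", ref.cpmg.echo_time),
        n_echoes=int(cfg.get("cpmg.n_echoes", ref.cpmg.n_echoes)),
        points_per_echo=int(cfg.get("cpmg.points_per_echo", ref.cpmg.points_per_echo)),
        dwell_time=cfg.get("cpmg.dwell", ref.cpmg.dwell_time),
    )
    p_intra = cfg.get("sample.intra.p", ref.sample.sites[0].p)
    sample = TwoSiteSample.yeast_water(
        k=cfg.get("sample.k", ref.sample.k),
        p_intra=p_intra,
        D_intra=cfg.get("sample.intra.D", ref.sample.sites[0].D),
        D_extra=cfg.get("sample.extra.D", ref.sample.sites[1].D),
    )
    if seed is None:
        seed = int(cfg.get("seed", ref.seed))
    return Scenario(
        sample=sample, instrument=instrument, encoding=encoding, cpmg=cpmg,
        mixing_times=cfg.get("mixing_times", ref.mixing_times),
        snr=cfg.get("snr", ref.snr),
        seed=seed,
        n_depth=int(cfg.get("grid.n_depth", ref.n_depth)),
        n_substeps=int(cfg.get("mixing.n_substeps", ref.n_substeps)),
        amplitude_range=(cfg.get("amplitude.lo", ref.amplitude_range[0]),
                         cfg.get("amplitude.hi", ref.amplitude_range[1])),
    )


def write_manifest(scenario: Scenario, path: str | Path) -> None:
    """Ground-truth manifest: every scenario parameter, SI units, full
    precision, re-readable by ``read_config``/``scenario_from_config``."""
    s = scenario
    lines = [
        f"instrument.B0_T = {s.instrument.B0!r}",
        f"instrument.G_Tm = {s.instrument.G!r}",
        f"encoding.bandwidth_Hz = {s.encoding.bandwidth!r}",
        f"encoding.delta_max_s = {s.encoding.delta_max!r}",
        f"encoding.storage_s = {s.encoding.storage_interval!r}",
        f"encoding.edge_depth = {s.encoding.edge_depth!r}",
        f"encoding.edge_width_frac = {s.encoding.edge_width_frac!r}",
        f"cpmg.tE_s = {s.cpmg.echo_time!r}",
        f"cpmg.n_echoes = {s.cpmg.n_echoes}",
        f"cpmg.points_per_echo = {s.cpmg.points_per_echo}",
        f"cpmg.dwell_s = {s.cpmg.dwell_time!r}",
        f"sample.intra.D_m2s = {s.sample.sites[0].D!r}",
        f"sample.extra.D_m2s = {s.sample.sites[1].D!r}",
        f"sample.intra.p = {s.sample.sites[0].p!r}",
        f"sample.k_per_s = {s.sample.k!r}",
        "mixing_times_s = " + " ".join(repr(t) for t in s.mixing_times),
        f"snr = {s.snr!r}",
        f"seed = {s.seed}",
        f"grid.n_depth = {s.n_depth}",
        f"mixing.n_substeps = {s.n_substeps}",
        f"amplitude.lo = {s.amplitude_range[0]!r}",
        f"amplitude.hi = {s.amplitude_range[1]!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> Scenario:
    return scenario_from_config(path)
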