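"""File formats and configuration.

Trajectory files are long-format TSV with header ``trajectory\ttime\tcount``
and ``#key=value`` metadata comment lines (species, dt, t0, model
parameters, seed).  Spectrum files are TSV with header ``omega\tdensity``
and metadata comments (kind, mean_level, estimator details).  Configs are
YAML with a ``model`` name, a ``params`` block mirroring the model
constructors, and a ``run`` block (seed, n_traj, t_total, dt_record,
burn_in, thinning_dt).  Unknown keys are rejected.

Rates in gene-expression configs are in 1/min by convention; other models
use arbitrary inverse-time units.  Frequencies are angular (rad/time).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .datatypes import FrequencySpectrum, SpectrumKind, TrajectoryEnsemble
from .reaction_times import (
    DichotomousRate,
    EnzymeTurnover,
    GammaDist,
    ModulatedRate,
    MultiChannel,
    MultiStep,
    OnOffModel,
    ReactionTimeModel,
    SingleExponential,
)
from .simulate import GeneExpressionParams, KtlDistribution, SimRun

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_spectrum",
    "read_spectrum",
    "RunConfig",
    "load_config",
    "reaction_time_from_dict",
    "promoter_from_dict",
    "modulated_rate_from_dict",
    "gene_params_from_dict",
]

_GRID_RTOL = 1e-9


def _fmt_meta_value(v: Any) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _parse_meta_value(s: str) -> Any:
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble in the long TSV dialect (round-trip safe)."""
    path = Path(path)
    lines = [
        f"#species={ensemble.species_label}",
        f"#dt={float(ensemble.dt)!r}",
        f"#t0={float(ensemble.t0)!r}",
    ]
    for k, v in ensemble.provenance.items():
        if isinstance(v, (str, int, float, np.integer, np.floating)):
            lines.append(f"#{k}={_fmt_meta_value(v)}")
    lines.append("trajectory\ttime\tcount")
    times = ensemble.times
    for i in range(ensemble.n_traj):
        row = ensemble.counts[i]
        for t, c in zip(times, row):
            lines.append(f"{i}\t{float(t)!r}\t{int(c)}")
    path.write_text("\n".join(lines) + "\n")


def read_trajectories(path) -> TrajectoryEnsemble:
    """Read the long TSV dialect back into an ensemble.

    Rejects ragged trajectories, non-integer or negative counts, missing
    ``dt`` metadata, and non-uniform time grids, naming the offending line.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    traj: dict[int, list[tuple[float, int]]] = {}
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = _parse_meta_value(v.strip())
                continue
            if not header_seen:
                if line.split("\t") != ["trajectory", "time", "count"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        "'trajectory\\ttime\\tcount'"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                idx = int(parts[0])
                t = float(parts[1])
                c_float = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row") from exc
            if c_float != int(c_float):
                raise ValueError(f"{path}:{lineno}: non-integer count {parts[2]}")
            c = int(c_float)
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            traj.setdefault(idx, []).append((t, c))
    if not traj:
        raise ValueError(f"{path}: no trajectory rows found")
    if "dt" not in meta:
        raise ValueError(f"{path}: missing required '#dt=' metadata line")
    dt = float(meta.pop("dt"))
    t0 = float(meta.pop("t0", traj[min(traj)][0][0]))
    species = str(meta.pop("species", "product"))
    lengths = {k: len(v) for k, v in traj.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(
            f"{path}: trajectories have different lengths: {sorted(set(lengths.values()))}"
        )
    keys = sorted(traj)
    counts = np.array([[c for _, c in traj[k]] for k in keys], dtype=np.int64)
    times = np.array([t for t, _ in traj[keys[0]]])
    expected = t0 + dt * np.arange(times.size)
    scale = max(abs(t0) + dt * times.size, dt)
    if not np.allclose(times, expected, rtol=0, atol=_GRID_RTOL * scale):
        raise ValueError(f"{path}: time grid is not uniform with step dt={dt}")
    return TrajectoryEnsemble(
        counts=counts, dt=dt, t0=t0, species_label=species, provenance=meta
    )


def write_spectrum(spectrum: FrequencySpectrum, path) -> None:
    """Write a spectrum in the TSV dialect (kind and scalars as comments)."""
    path = Path(path)
    lines = [f"#kind={spectrum.kind.value}"]
    if spectrum.mean_level is not None:
        lines.append(f"#mean_level={spectrum.mean_level!r}")
    for k, v in spectrum.meta.items():
        if isinstance(v, (str, int, float, np.integer, np.floating, bool)):
            lines.append(f"#{k}={_fmt_meta_value(v)}")
    lines.append("omega\tdensity")
    for w, v in zip(spectrum.omegas, spectrum.values):
        lines.append(f"{float(w)!r}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> FrequencySpectrum:
    path = Path(path)
    meta: dict[str, Any] = {}
    omegas: list[float] = []
    values: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = _parse_meta_value(v.strip())
                continue
            if not header_seen:
                if line.split("\t") != ["omega", "density"]:
                    raise ValueError(f"{path}:{lineno}: expected header 'omega\\tdensity'")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            omegas.append(float(parts[0]))
            values.append(float(parts[1]))
    if "kind" not in meta:
        raise ValueError(f"{path}: missing required '#kind=' metadata line")
    kind = SpectrumKind(meta.pop("kind"))
    mean_level = meta.pop("mean_level", None)
    w = np.asarray(omegas)
    if w.size > 1 and not (np.diff(w) > 0).all():
        raise ValueError(f"{path}: omegas must be strictly ascending")
    return FrequencySpectrum(
        omegas=w, values=np.asarray(values), kind=kind,
        mean_level=mean_level, meta=meta,
    )


# ---------------------------------------------------------------------------
# configuration


def _require_keys(block: dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        raise ValueError(f"missing keys in {where}: {sorted(missing)}")


def reaction_time_from_dict(d: dict) -> ReactionTimeModel:
    """Build a reaction-time model from a ``{variant: ..., ...}`` block."""
    d = dict(d)
    variant = d.pop("variant", None)
    if variant == "single_exponential":
        _require_keys(d, {"k"}, {"k"}, "single_exponential")
        return SingleExponential(k=float(d["k"]))
    if variant == "multi_step":
        _require_keys(d, {"rates"}, {"rates"}, "multi_step")
        return MultiStep(rates=[float(k) for k in d["rates"]])
    if variant == "multi_channel":
        _require_keys(d, {"probs", "rates"}, {"probs", "rates"}, "multi_channel")
        return MultiChannel(probs=d["probs"], rates=d["rates"])
    if variant == "gamma":
        _require_keys(d, {"a", "b"}, {"a", "b"}, "gamma")
        return GammaDist(a=float(d["a"]), b=float(d["b"]))
    if variant == "enzyme_turnover":
        _require_keys(d, {"k1S", "p2", "es"}, {"k1S", "p2", "es"}, "enzyme_turnover")
        es = reaction_time_from_dict(d["es"])
        return EnzymeTurnover(k1S=float(d["k1S"]), es_lifetime=es, p2=float(d["p2"]))
    raise ValueError(f"unknown reaction-time variant: {variant!r}")


def promoter_from_dict(d: dict) -> OnOffModel:
    # YAML 1.1 parses bare `on:` / `off:` keys as booleans; accept both
    d = {("on" if k is True else "off" if k is False else k): v for k, v in d.items()}
    _require_keys(d, {"on", "off"}, {"on", "off"}, "promoter")
    return OnOffModel(
        on_lifetime=reaction_time_from_dict(d["on"]),
        off_lifetime=reaction_time_from_dict(d["off"]),
    )


def modulated_rate_from_dict(d: dict):
    d = dict(d)
    if d.get("kind") == "dichotomous":
        _require_keys(d, {"kind", "mean_rate", "eta2", "lam"},
                      {"mean_rate", "eta2", "lam"}, "dichotomous rate")
        return DichotomousRate.from_moments(
            mean_rate=float(d["mean_rate"]), eta2=float(d["eta2"]), lam=float(d["lam"])
        )
    if {"mean_rate", "eta2"} <= set(d):
        _require_keys(d, {"mean_rate", "eta2", "lam"}, {"mean_rate", "eta2", "lam"},
                      "modulated rate")
        return ModulatedRate.from_moments(
            mean_rate=float(d["mean_rate"]), eta2=float(d["eta2"]), lam=float(d["lam"])
        )
    _require_keys(d, {"k0", "alpha", "lam", "gamma_var"}, {"k0", "alpha", "lam"},
                  "modulated rate")
    return ModulatedRate(
        k0=float(d["k0"]), alpha=float(d["alpha"]), lam=float(d["lam"]),
        gamma_var=float(d.get("gamma_var", 1.0)),
    )


def gene_params_from_dict(d: dict) -> GeneExpressionParams:
    _require_keys(
        d,
        {"promoter", "k_TX", "modulated_k_TX", "gamma_m", "k_TL", "gamma_p",
         "thinning_dt"},
        {"promoter", "gamma_m", "k_TL", "gamma_p"},
        "gene_expression params",
    )
    if ("k_TX" in d) == ("modulated_k_TX" in d):
        raise ValueError("specify exactly one of k_TX and modulated_k_TX")
    transcription: Any
    if "k_TX" in d:
        transcription = float(d["k_TX"])
    else:
        transcription = modulated_rate_from_dict(d["modulated_k_TX"])
    k_tl = d["k_TL"]
    if isinstance(k_tl, dict):
        k_tl = KtlDistribution(
            mean=float(k_tl["mean"]), eta2=float(k_tl.get("eta2", 0.0)),
            kind=str(k_tl.get("kind", "two_point")),
        )
    else:
        k_tl = float(k_tl)
    return GeneExpressionParams(
        promoter=promoter_from_dict(d["promoter"]),
        transcription=transcription,
        gamma_m=float(d["gamma_m"]),
        k_TL=k_tl,
        gamma_p=float(d["gamma_p"]),
        thinning_dt=float(d["thinning_dt"]) if "thinning_dt" in d else None,
    )


@dataclass
class RunConfig:
    """A parsed simulation/analytic configuration."""

    model: str
    params: dict
    run: SimRun | None
    record: str = "product"

    _MODELS = ("renewal_birth_death", "enzyme_network", "modulated_rate",
               "gene_expression")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _require_keys(raw, {"model", "params", "run", "record"}, {"model", "params"},
                  "config")
    model = str(raw["model"])
    if model not in RunConfig._MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {RunConfig._MODELS}")
    params = raw["params"]
    if not isinstance(params, dict):
        raise ValueError("params must be a mapping")
    run = None
    if "run" in raw:
        rb = dict(raw["run"])
        _require_keys(rb, {"seed", "n_traj", "t_total", "dt_record", "burn_in"},
                      {"seed", "n_traj", "t_total", "dt_record"}, "run block")
        run = SimRun(
            seed=int(rb["seed"]), n_traj=int(rb["n_traj"]),
            t_total=float(rb["t_total"]), dt_record=float(rb["dt_record"]),
            burn_in=float(rb.get("burn_in", 0.0)),
        )
    record = str(raw.get("record", "product"))
    # validate model-specific parameter blocks eagerly
    build_model_params(model, params)
    return RunConfig(model=model, params=params, run=run, record=record)


def build_model_params(model: str, params: dict) -> dict:
    """Validate a model parameter block and build the typed objects."""
    if model == "renewal_birth_death":
        _require_keys(params, {"reaction_time", "gamma"}, {"reaction_time", "gamma"},
                      "renewal_birth_death params")
        return {
            "model": reaction_time_from_dict(params["reaction_time"]),
            "gamma": float(params["gamma"]),
        }
    if model == "enzyme_network":
        _require_keys(
            params, {"k1S", "p2", "es", "n_enzymes", "gamma"},
            {"k1S", "p2", "es", "n_enzymes", "gamma"}, "enzyme_network params",
        )
        es = reaction_time_from_dict(params["es"])
        if not isinstance(es, GammaDist):
            raise ValueError("enzyme_network requires a gamma ES lifetime")
        return {
            "k1S": float(params["k1S"]), "p2": float(params["p2"]),
            "es_lifetime": es, "n_enzymes": int(params["n_enzymes"]),
            "gamma_z": float(params["gamma"]),
        }
    if model == "modulated_rate":
        _require_keys(params, {"rate", "gamma", "thinning_dt"},
                      {"rate", "gamma", "thinning_dt"}, "modulated_rate params")
        return {
            "rate": modulated_rate_from_dict(params["rate"]),
            "gamma_z": float(params["gamma"]),
            "thinning_dt": float(params["thinning_dt"]),
        }
    if model == "gene_expression":
        return {"params": gene_params_from_dict(params)}
    raise ValueError(f"unknown model {model!r}")
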