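"""Run configuration: YAML/JSON loading, strict validation, round-tripping.

A config file declares the objects a run needs — a prey community or
fixture recipe, kernels, a trait distribution, a genotype panel, a
resource environment, grids and thresholds.  Validation is strict by
default: unknown keys anywhere in the tree are rejected with their full
dotted path, so a typo in a parameter name fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import yaml

from .ecoevo import Genotype, ReactionNorm, ResourceEnvironment
from .errors import ConfigError
from .synthetic import FixtureSpec, NormSpec, make_mismatch_community
from .trait_intake import (
    AttackKernel,
    HandlingKernel,
    Prey,
    PreyCommunity,
    TraitDistribution,
    shared_kernels,
)

__all__ = ["RunConfig", "load_config", "save_config"]


_KERNEL_DEFAULTS = {"alpha_max": 1.0, "tau_alpha": 1.0, "eta_min": 1.0, "tau_eta": 1.0}
_DIST_DEFAULTS = {"mean": 0.0, "sigma2": 1.0}

_NORM_KEYS = {"value_at_ref", "slope", "form", "ref_temperature", "peak_temperature", "curvature"}
_NORMSPEC_KEYS = {"intercept", "intercept_sd", "mean_slope", "slope_sd"}

_SCHEMA: dict[str, set[str]] = {
    "": {
        "seed", "community", "fixture", "kernels", "distribution", "sweep",
        "panel", "environment", "temperature_grid", "simulate", "decompose",
        "compare",
    },
    "community": {"consumer_density", "prey"},
    "community.prey[]": {"id", "density", "optimum"},
    "fixture": {
        "n_prey", "mismatch_max", "density", "consumer_density", "predator_mean",
        "seed", "density_cv",
    },
    "kernels": set(_KERNEL_DEFAULTS),
    "distribution": set(_DIST_DEFAULTS),
    "sweep": {"sigma2_grid", "epsilon"},
    "panel": {"genotypes", "spec"},
    "panel.genotypes[]": {"id", "a", "m", "e"},
    "panel.spec": {"seed", "n_genotypes", "a", "m", "e", "T_ref"},
    "environment": {"r", "K", "valid_range"},
    "simulate": {"params", "initial", "horizon", "n_points"},
    "simulate.params": {"r", "K", "a", "e", "m"},
    "decompose": {"parameter"},
    "compare": {"sigma2_a", "sigma2_b"},
}


def _check_keys(mapping: dict, path: str, allowed: set[str], strict: bool) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(mapping).__name__}")
    unknown = sorted(set(mapping) - allowed)
    if unknown and strict:
        where = path or "top level"
        raise ConfigError(f"unknown key(s) at {where}: {', '.join(unknown)}")


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {message}")


def _validate(data: dict, strict: bool) -> dict:
    """Validate, fill defaults, and return a normalized copy."""
    _check_keys(data, "", _SCHEMA[""], strict)
    out: dict[str, Any] = {}

    if "seed" in data:
        _require(isinstance(data["seed"], int), "seed", "must be an integer")
        out["seed"] = data["seed"]

    if "community" in data:
        c = data["community"]
        _check_keys(c, "community", _SCHEMA["community"], strict)
        _require("prey" in c and isinstance(c["prey"], list) and c["prey"],
                 "community.prey", "must be a nonempty list")
        prey_out = []
        for k, p in enumerate(c["prey"]):
            _check_keys(p, f"community.prey[{k}]", _SCHEMA["community.prey[]"], strict)
            for req in ("id", "density", "optimum"):
                _require(req in p, f"community.prey[{k}].{req}", "is required")
            _require(p["density"] > 0, f"community.prey[{k}].density", "must be > 0")
            prey_out.append({"id": str(p["id"]), "density": float(p["density"]),
                             "optimum": float(p["optimum"])})
        cd = float(c.get("consumer_density", 1.0))
        _require(cd > 0, "community.consumer_density", "must be > 0")
        out["community"] = {"consumer_density": cd, "prey": prey_out}

    if "fixture" in data:
        f = data["fixture"]
        _check_keys(f, "fixture", _SCHEMA["fixture"], strict)
        _require("n_prey" in f, "fixture.n_prey", "is required")
        _require(f["n_prey"] >= 1, "fixture.n_prey", "must be >= 1")
        mm = float(f.get("mismatch_max", 25.0))
        _require(mm >= 0, "fixture.mismatch_max", "must be >= 0")
        out["fixture"] = {
            "n_prey": int(f["n_prey"]), "mismatch_max": mm,
            "density": float(f.get("density", 1.0)),
            "consumer_density": float(f.get("consumer_density", 1.0)),
            "predator_mean": float(f.get("predator_mean", 0.0)),
            "seed": int(f.get("seed", 0)),
            "density_cv": float(f.get("density_cv", 0.0)),
        }

    kern = dict(_KERNEL_DEFAULTS)
    if "kernels" in data:
        _check_keys(data["kernels"], "kernels", _SCHEMA["kernels"], strict)
        kern.update({k: float(v) for k, v in data["kernels"].items() if k in kern})
    for key in ("alpha_max", "tau_alpha", "eta_min", "tau_eta"):
        _require(kern[key] > 0, f"kernels.{key}", "must be > 0")
    out["kernels"] = kern

    dist = dict(_DIST_DEFAULTS)
    if "distribution" in data:
        _check_keys(data["distribution"], "distribution", _SCHEMA["distribution"], strict)
        dist.update({k: float(v) for k, v in data["distribution"].items() if k in dist})
    _require(dist["sigma2"] >= 0, "distribution.sigma2", "must be >= 0")
    out["distribution"] = dist

    if "sweep" in data:
        s = data["sweep"]
        _check_keys(s, "sweep", _SCHEMA["sweep"], strict)
        grid = [float(v) for v in s.get("sigma2_grid", [])]
        _require(bool(grid), "sweep.sigma2_grid", "must be a nonempty list")
        for k, v in enumerate(grid):
            _require(v >= 0, f"sweep.sigma2_grid[{k}]", "must be >= 0")
        eps = s.get("epsilon")
        if eps is not None:
            _require(eps >= 0, "sweep.epsilon", "must be >= 0")
            eps = float(eps)
        out["sweep"] = {"sigma2_grid": grid, "epsilon": eps}

    if "panel" in data:
        p = data["panel"]
        _check_keys(p, "panel", _SCHEMA["panel"], strict)
        _require(("genotypes" in p) != ("spec" in p), "panel",
                 "declare exactly one of 'genotypes' or 'spec'")
        if "genotypes" in p:
            genos = []
            for k, g in enumerate(p["genotypes"]):
                _check_keys(g, f"panel.genotypes[{k}]", _SCHEMA["panel.genotypes[]"], strict)
                for req in ("id", "a", "m", "e"):
                    _require(req in g, f"panel.genotypes[{k}].{req}", "is required")
                entry = {"id": str(g["id"])}
                for pname in ("a", "m", "e"):
                    nd = g[pname]
                    _check_keys(nd, f"panel.genotypes[{k}].{pname}", _NORM_KEYS, strict)
                    _require("value_at_ref" in nd,
                             f"panel.genotypes[{k}].{pname}.value_at_ref", "is required")
                    entry[pname] = dict(nd)
                genos.append(entry)
            out["panel"] = {"genotypes": genos}
        else:
            sp = p["spec"]
            _check_keys(sp, "panel.spec", _SCHEMA["panel.spec"], strict)
            _require("seed" in sp, "panel.spec.seed", "is required")
            spec_out: dict[str, Any] = {
                "seed": int(sp["seed"]),
                "n_genotypes": int(sp.get("n_genotypes", 2)),
                "T_ref": float(sp.get("T_ref", 15.0)),
            }
            for pname in ("a", "m", "e"):
                if pname in sp:
                    _check_keys(sp[pname], f"panel.spec.{pname}", _NORMSPEC_KEYS, strict)
                    spec_out[pname] = {k: float(v) for k, v in sp[pname].items()}
            out["panel"] = {"spec": spec_out}

    if "environment" in data:
        e = data["environment"]
        _check_keys(e, "environment", _SCHEMA["environment"], strict)
        env_out: dict[str, Any] = {}
        for nkey in ("r", "K"):
            if nkey in e:
                _check_keys(e[nkey], f"environment.{nkey}", _NORM_KEYS, strict)
                env_out[nkey] = dict(e[nkey])
        if "valid_range" in e:
            vr = e["valid_range"]
            _require(isinstance(vr, (list, tuple)) and len(vr) == 2,
                     "environment.valid_range", "must be [low, high]")
            env_out["valid_range"] = [float(vr[0]), float(vr[1])]
        out["environment"] = env_out

    if "temperature_grid" in data:
        tg = [float(v) for v in data["temperature_grid"]]
        _require(bool(tg), "temperature_grid", "must be a nonempty list")
        out["temperature_grid"] = tg

    if "simulate" in data:
        s = data["simulate"]
        _check_keys(s, "simulate", _SCHEMA["simulate"], strict)
        _require("params" in s, "simulate.params", "is required")
        _check_keys(s["params"], "simulate.params", _SCHEMA["simulate.params"], strict)
        for req in ("r", "K", "a", "e", "m"):
            _require(req in s["params"], f"simulate.params.{req}", "is required")
            _require(s["params"][req] > 0, f"simulate.params.{req}", "must be > 0")
        init = s.get("initial", [1.0, 1.0])
        _require(len(init) == 2 and all(v >= 0 for v in init),
                 "simulate.initial", "must be two nonnegative densities [R0, C0]")
        out["simulate"] = {
            "params": {k: float(v) for k, v in s["params"].items()},
            "initial": [float(init[0]), float(init[1])],
            "horizon": float(s.get("horizon", 100.0)),
            "n_points": int(s.get("n_points", 200)),
        }

    if "decompose" in data:
        d = data["decompose"]
        _check_keys(d, "decompose", _SCHEMA["decompose"], strict)
        _require(d.get("parameter") in ("a", "m", "e"),
                 "decompose.parameter", "must be one of 'a', 'm', 'e'")
        out["decompose"] = {"parameter": d["parameter"]}

    if "compare" in data:
        c = data["compare"]
        _check_keys(c, "compare", _SCHEMA["compare"], strict)
        for req in ("sigma2_a", "sigma2_b"):
            _require(req in c, f"compare.{req}", "is required")
            _require(c[req] >= 0, f"compare.{req}", "must be >= 0")
        out["compare"] = {"sigma2_a": float(c["sigma2_a"]), "sigma2_b": float(c["sigma2_b"])}

    return out


def _norm_from_dict(d: dict) -> ReactionNorm:
    return ReactionNorm(
        value_at_ref=float(d["value_at_ref"]),
        slope=float(d.get("slope", 0.0)),
        form=str(d.get("form", "linear")),
        ref_temperature=float(d.get("ref_temperature", 15.0)),
        peak_temperature=(None if d.get("peak_temperature") is None
                          else float(d["peak_temperature"])),
        curvature=None if d.get("curvature") is None else float(d["curvature"]),
    )


@dataclass(frozen=True)
class RunConfig:
    """Validated, defaulted run configuration.

    Wraps the normalized mapping and builds the domain objects on demand.
    Two configs loaded from the same file compare equal, and
    ``save_config`` followed by ``load_config`` round-trips exactly.
    """

    data: dict

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.data))  # deep copy via JSON

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RunConfig) and self.data == other.data

    # -- builders -----------------------------------------------------------

    def build_community(self) -> tuple[PreyCommunity, list[tuple[AttackKernel, HandlingKernel]]]:
        """Community + kernels from either an explicit prey list or a fixture recipe."""
        k = self.data["kernels"]
        if "community" in self.data:
            c = self.data["community"]
            comm = PreyCommunity(
                prey=tuple(Prey(**p) for p in c["prey"]),
                consumer_density=c["consumer_density"],
            )
            kernels = shared_kernels(
                comm, alpha_max=k["alpha_max"], tau_alpha=k["tau_alpha"],
                eta_min=k["eta_min"], tau_eta=k["tau_eta"],
            )
            return comm, kernels
        if "fixture" in self.data:
            f = self.data["fixture"]
            return make_mismatch_community(
                f["n_prey"], f["mismatch_max"], density=f["density"],
                consumer_density=f["consumer_density"],
                predator_mean=f["predator_mean"], seed=f["seed"],
                density_cv=f["density_cv"], alpha_max=k["alpha_max"],
                tau_alpha=k["tau_alpha"], eta_min=k["eta_min"], tau_eta=k["tau_eta"],
            )
        raise ConfigError("config declares neither 'community' nor 'fixture'")

    def build_distribution(self) -> TraitDistribution:
        d = self.data["distribution"]
        return TraitDistribution(mean=d["mean"], variance=d["sigma2"])

    def build_panel(self) -> list[Genotype]:
        if "panel" not in self.data:
            raise ConfigError("config declares no 'panel'")
        p = self.data["panel"]
        if "genotypes" in p:
            return [
                Genotype(
                    id=g["id"],
                    norm_a=_norm_from_dict(g["a"]),
                    norm_m=_norm_from_dict(g["m"]),
                    norm_e=_norm_from_dict(g["e"]),
                )
                for g in p["genotypes"]
            ]
        from .synthetic import make_genotype_panel

        sp = p["spec"]
        kwargs: dict[str, Any] = {
            "seed": sp["seed"], "n_genotypes": sp["n_genotypes"], "T_ref": sp["T_ref"],
        }
        for pname in ("a", "m", "e"):
            if pname in sp:
                kwargs[pname] = NormSpec(**sp[pname])
        panel, _ = make_genotype_panel(FixtureSpec(**kwargs))
        return panel

    def build_environment(self) -> ResourceEnvironment:
        e = self.data.get("environment", {})
        kwargs: dict[str, Any] = {}
        if "r" in e:
            kwargs["norm_r"] = _norm_from_dict(e["r"])
        if "K" in e:
            kwargs["norm_K"] = _norm_from_dict(e["K"])
        if "valid_range" in e:
            kwargs["valid_range"] = tuple(e["valid_range"])
        return ResourceEnvironment(**kwargs)


def load_config(path: str | Path, *, strict: bool = True) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return RunConfig(data=_validate(raw, strict))


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config so that loading it back yields an equal object."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
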