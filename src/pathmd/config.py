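"""Run configuration: schema, defaults, resolution and snapshotting.

Configs are TOML with sections ``[system]``, ``[integrator]``,
``[bias]``, ``[restraints]``, ``[output]`` plus top-level ``seed`` and
``n_steps``.  Every run writes its fully resolved config next to its
outputs so that config + seed + package version reproduce it exactly.

The bias defaults follow the published parameterization (N_R = 5,
tau1 = 1 ps, tau2 = 2.5 ps, beta' = beta_md' = 1e-4, gamma'' = 1e-4,
W = 0.1 kJ/mol, delta_E = 1000 kJ/mol).  For the built-in toy systems
the default eta' is raised to 2000 so that the renormalized bias-to-
gradient ratio alpha' ~ 0.1 matches the regime the method operates in
for macromolecules, where the global gradient norm (dominated by stiff
bonded terms across thousands of atoms) exceeds the force along any
slow mode by three to four orders of magnitude; a single-particle toy
surface has no such separation, so the ratio is restored through eta'.
"""

from __future__ import annotations

import copy
import tomllib

from pathmd.action_bias import build_bias_schedule
from pathmd.engine import IntegratorConfig
from pathmd.hybrid_coupling import BiasStack, CouplingParams
from pathmd.model_systems import _SYSTEM_DEFAULTS, make_system


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


#: toy-system default for eta' (see module docstring)
TOY_ETA_PRIME = 2000.0

_BIAS_DEFAULTS = {
    "enabled": True,
    "n_r": 5,
    "tau1_ps": 1.0,
    "tau2_ps": 2.5,
    "beta_md": 1e-4,
    "beta_prime": 1e-4,
    "eta_md": 1.0,
    "eta_prime": TOY_ETA_PRIME,
    "gamma_pp": 1e-4,
    "hill_w": 0.1,
    "hill_dsigma": "auto",
    "dsigma_floor": 1e-4,
    "delta_e": 1000.0,
    "well_tempered": False,
    "use_pca": False,
    "pca_window_ps": "auto",
    "per_atom_norm": False,
}

_INTEGRATOR_DEFAULTS = {
    "dt_ps": 0.005,
    "temperature_k": 300.0,
    "friction": 1.0,
}

_OUTPUT_DEFAULTS = {
    "directory": "pathmd_out",
    "stride": 10,
    "write_xyz": False,
    "write_hill_log": True,
}

_SYSTEM_KEYS = {
    "double_well_1d": {"a", "b", "mass", "n_particles"},
    "double_well_2d": {"a", "b", "mass", "n_particles"},
    "muller_brown": {"scale", "mass"},
    "torsion_surface": {"a", "b", "mass"},
    "bead_chain": {"n", "bond_k", "bond_r0", "repulsion_eps", "repulsion_sigma", "mass"},
}


def default_config(system: str = "double_well_1d") -> dict:
    if system not in _SYSTEM_DEFAULTS:
        raise ConfigError(f"[system].name: unknown system {system!r}")
    return {
        "seed": 0,
        "n_steps": 10000,
        "system": {"name": system, **copy.deepcopy(_SYSTEM_DEFAULTS[system])},
        "integrator": dict(_INTEGRATOR_DEFAULTS),
        "bias": dict(_BIAS_DEFAULTS),
        "restraints": {"file": ""},
        "output": dict(_OUTPUT_DEFAULTS),
    }


def _merge(base: dict, update: dict, path: str = "") -> dict:
    for key, value in update.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where!r} must be a table")
            _merge(base[key], value, where)
        else:
            base[key] = value
    return base


def resolve_config(raw: dict | None = None, system: str | None = None) -> dict:
    """Merge user values over the defaults and validate the schema."""
    raw = copy.deepcopy(raw or {})
    name = system or raw.get("system", {}).get("name", "double_well_1d")
    cfg = default_config(name)
    raw.get("system", {}).pop("name", None)
    extra = set(raw.get("system", {})) - _SYSTEM_KEYS[name]
    if extra:
        raise ConfigError(f"[system] keys {sorted(extra)} invalid for {name!r}")
    _merge(cfg, raw)
    if cfg["n_steps"] < 0:
        raise ConfigError("n_steps must be >= 0")
    if cfg["seed"] < 0:
        raise ConfigError("seed must be >= 0")
    return cfg


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return resolve_config(raw)


def build_run(cfg: dict):
    """Instantiate (system, integrator config, bias stack, restraints).

    The bias stack is None when the bias section is disabled.
    """
    sys_cfg = dict(cfg["system"])
    name = sys_cfg.pop("name")
    system = make_system(name, **sys_cfg)
    integ = IntegratorConfig(
        dt=cfg["integrator"]["dt_ps"],
        temperature=cfg["integrator"]["temperature_k"],
        friction=cfg["integrator"]["friction"],
        seed=cfg["seed"],
    )
    restraints = None
    if cfg["restraints"]["file"]:
        from pathmd.restraints_io import parse_restraint_table

        restraints = parse_restraint_table(cfg["restraints"]["file"])
    bias = None
    b = cfg["bias"]
    if b["enabled"]:
        schedule = build_bias_schedule(b["n_r"], b["tau1_ps"], b["tau2_ps"], integ.dt)
        coupling = CouplingParams(
            beta_md=b["beta_md"], beta_prime=b["beta_prime"],
            eta_md=b["eta_md"], eta_prime=b["eta_prime"],
        )
        dsig = None if b["hill_dsigma"] == "auto" else float(b["hill_dsigma"])
        pca_steps = (
            None if b["pca_window_ps"] == "auto"
            else max(1, int(round(float(b["pca_window_ps"]) / integ.dt)))
        )
        bias = BiasStack(
            schedule=schedule,
            coupling=coupling,
            n_atoms=system.n_particles,
            dim=system.dimension,
            gamma_pp=b["gamma_pp"],
            hill_w=b["hill_w"],
            hill_dsigma=dsig,
            dsigma_floor=b["dsigma_floor"],
            delta_e=b["delta_e"],
            well_tempered=b["well_tempered"],
            use_pca=b["use_pca"],
            pca_window_steps=pca_steps,
            per_atom_norm=b["per_atom_norm"],
            periodic=getattr(system, "periodic", False),
            period=getattr(system, "period", None) or 6.283185307179586,
        )
    return system, integ, bias, restraints


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_toml(cfg: dict) -> str:
    """Serialize a resolved (two-level) config back to TOML."""
    lines = []
    for key, value in cfg.items():
        if not isinstance(value, dict):
            lines.append(f"{key} = {_toml_value(value)}")
    for section, table in cfg.items():
        if isinstance(table, dict):
            lines.append(f"\n[{section}]")
            for key, value in table.items():
                lines.append(f"{key} = {_toml_value(value)}")
    return "\n".join(lines) + "\n"
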