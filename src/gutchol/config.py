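"""Run configuration, validated loading and tabular result writing.

A run configuration is a nested mapping with four sections mirroring the
pipeline stages (kinetics, upscaling, whole_body, exploration) plus global
keys (seed, out_dir, tolerances). Loading resolves every missing key to
its documented default, records the provenance of each value (default vs
user) and rejects unknown keys outright.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .wholebody import (DEFAULT_LITERATURE_FLUXES, DEFAULT_POOLS,
                        DEFAULT_VOLUMES, DEFAULT_MICROBIAL)


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


def _default_tree() -> dict:
    return {
        "seed": 0,
        "out_dir": "results",
        "kinetics": {
            "n_iter": 50_000,
            "burn_frac": 0.5,
            "adapt_start_frac": 0.1,
            "dr_scale": 5.0,
            "sigma2_init": 4e-4,
            "noise": {"density_sd": 0.02, "metabolite_sd": 0.02,
                      "n_replicates": 3, "n_timepoints": 20},
        },
        "upscaling": {
            "b_gut_max": 5.0e9,
            "w_pbs": 467.847,
            "a_bsh_mic": 0.0033,
            "a_bsh_invitro": 19.2466,
            "d8_max": 2.0e9,
            "bxyl_max": 4.0e9,
            "q_col_cop": 0.1,
            "invert_density_ratio": False,
        },
        "whole_body": {
            "fluxes": dict(DEFAULT_LITERATURE_FLUXES),
            "pools": dict(DEFAULT_POOLS),
            "volumes": dict(DEFAULT_VOLUMES),
            "microbial": dict(DEFAULT_MICROBIAL),
            "sbs_share": 1e-4,
            "bs_recycling": 0.95,
            "hill_sensitivity": 5.0,
            "hbs_feedback": "as_printed",
            "steady_tol": 1e-8,
            "t_max": 2000.0,
        },
        "tracer": {"dose_mg": 0.6, "days": 3.0, "pulse_days": 0.1,
                   "include_bs_pools": False},
        "exploration": {"n_samples": 10_000, "n_pcc": 2_000, "span": 0.5,
                        "cap_lo": 0.01, "cap_hi": 100.0,
                        "capacity_log": True},
    }


@dataclass
class RunConfig:
    """Validated configuration with all defaults resolved."""

    tree: dict
    provenance: dict = field(default_factory=dict)  # dotted key -> source
    path: str | None = None

    def __getitem__(self, section: str):
        return self.tree[section]

    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    def ledger(self):
        from .wholebody import CalibrationLedger
        wb = self.tree["whole_body"]
        return CalibrationLedger(fluxes=dict(wb["fluxes"]),
                                 pools=dict(wb["pools"]),
                                 volumes=dict(wb["volumes"]),
                                 microbial=dict(wb["microbial"]),
                                 sbs_share=float(wb["sbs_share"]),
                                 bs_recycling=float(wb["bs_recycling"]),
                                 hill_sensitivity=float(wb["hill_sensitivity"]))

    @property
    def hbs_feedback(self) -> str:
        return str(self.tree["whole_body"]["hbs_feedback"])

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.tree, sort_keys=True))


def _merge(defaults: dict, user: dict, prov: dict, prefix: str = "") -> dict:
    out = {}
    unknown = [k for k in user if k not in defaults]
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) {sorted(prefix + k for k in unknown)}")
    for key, dval in defaults.items():
        dotted = f"{prefix}{key}"
        if key not in user:
            out[key] = dval
            prov[dotted] = "default"
        elif isinstance(dval, dict):
            if not isinstance(user[key], dict):
                raise ConfigError(f"{dotted} must be a mapping")
            out[key] = _merge(dval, user[key], prov, dotted + ".")
        else:
            out[key] = user[key]
            prov[dotted] = "user"
    return out


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``path=None`` or an empty file yields the full-default configuration.
    Unknown keys raise :class:`ConfigError` listing the offending names.
    """
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"configuration file {path} does not exist")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        user = loaded
    if overrides:
        user = _deep_update(dict(user), overrides)
    prov: dict = {}
    tree = _merge(_default_tree(), user, prov)
    return RunConfig(tree=tree, provenance=prov,
                     path=str(path) if path else None)


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            base[k] = _deep_update(dict(base[k]), v)
        else:
            base[k] = v
    return base


# --------------------------------------------------------------------------
# result writing
# --------------------------------------------------------------------------

def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  seed: int | None = None,
                  extra: dict | None = None) -> dict:
    """Write each table as CSV plus a JSON manifest and return the manifest.

    The manifest lists every written file with its SHA-256 content hash,
    the seed, package versions and the wall-clock runtime stamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "files": files,
        "seed": seed,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "written_at_unix": time.time(),
    }
    if extra:
        manifest["extra"] = _jsonable(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def flux_table_frame(flux_table) -> pd.DataFrame:
    """Sankey-ready long frame: source, target, value (mg/day), cycle."""
    return pd.DataFrame(
        [{"name": e.name, "source": e.source, "target": e.target,
          "value": e.value, "cycle": e.cycle} for e in flux_table.edges])


def assays_frame(assays) -> pd.DataFrame:
    rows = []
    for a in assays:
        for i in range(len(a.times)):
            rows.append({"time_h": a.times[i], "density": a.density[i],
                         "metab_a": a.metabolite_a[i],
                         "metab_b": a.metabolite_b[i],
                         "bs0": a.initial_bs, "replicate": a.replicate_id})
    return pd.DataFrame(rows)


def assays_from_frame(df: pd.DataFrame):
    from .kinetics import GrowthAssay
    assays = []
    for (rep, bs0), g in df.groupby(["replicate", "bs0"], sort=False):
        g = g.sort_values("time_h")
        assays.append(GrowthAssay(times=g["time_h"].to_numpy(),
                                  density=g["density"].to_numpy(),
                                  metabolite_a=g["metab_a"].to_numpy(),
                                  metabolite_b=g["metab_b"].to_numpy(),
                                  initial_bs=float(bs0),
                                  replicate_id=str(rep)))
    return assays
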