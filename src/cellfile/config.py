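"""Parameter presets, configuration loading and result serialization.

Presets store the *dimensional* primaries (Table-style chemistry and
geometry for gibberellin in the Arabidopsis root); every dimensionless
quantity is derived at load time so there is a single source of truth for
the chemistry -> transport propagation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .geometry import (
    CellFileGeometry,
    DivisionSchedule,
    ExponentialDivisionProfile,
    LengthProfile,
    LinearGrowthProfile,
    LinearSpatialProfile,
    StaticUniformProfile,
    fit_linear_file,
)
from .membrane import (
    MUTANTS,
    WILD_TYPE,
    DimensionlessParameters,
    HormonePhysiology,
    nondimensionalize,
)

__all__ = ["PRESETS", "RunConfig", "load_config", "resolve", "write_results"]

# GA chemistry shared by all presets (dimensional primaries)
_GA_CHEMISTRY = dict(
    pK=4.2,
    pH_apo=5.3,
    pH_cyt=7.0,
    pH_vac=5.5,
    V_mem=-0.120,
    V_ton=-0.030,
    T_abs=300.0,
    F_D=96500.0,
    R_gas=8.31,
    P_pass=0.333,
    P_imp=0.017,
    P_exp=0.556,
    P_plas=0.81,
    D_apo=32.0,
    C_up=1.0,
)

PRESETS: dict[str, dict] = {
    # meristem-like short cells with small vacuoles
    "ga_short": {
        "physiology": dict(_GA_CHEMISTRY),
        "geometry": dict(n_cells=20, length_um=20.0, width_um=10.0, apoplast_um=0.5, phi=0.1),
    },
    # mature-zone long cells; phi chosen so the cytoplasmic area matches
    # the short cells (elongation by vacuolar expansion)
    "ga_long": {
        "physiology": dict(_GA_CHEMISTRY),
        "geometry": dict(n_cells=20, length_um=200.0, width_um=10.0, apoplast_um=0.5, phi=0.91),
    },
}

_PHYS_KEYS = set(_GA_CHEMISTRY)
_GEOM_KEYS = {"n_cells", "length_um", "width_um", "apoplast_um", "phi"}
_PROFILE_KINDS = {"static_uniform", "linear_time", "linear_space", "exponential_division"}
_TOP_KEYS = {
    "preset", "mutant", "plasmodesmata", "physiology", "geometry",
    "length_profile", "solver", "output",
}


@dataclass
class RunConfig:
    """Fully resolved model configuration.

    ``provenance`` records, per parameter, whether it came from the preset
    or an explicit override.
    """

    physiology: HormonePhysiology
    geometry: CellFileGeometry
    profile: LengthProfile
    params: DimensionlessParameters
    mutant: str = WILD_TYPE
    plasmodesmata: bool = True
    solver: dict = dataclasses.field(default_factory=dict)
    output: dict = dataclasses.field(default_factory=dict)
    provenance: dict = dataclasses.field(default_factory=dict)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "physiology": dataclasses.asdict(self.physiology),
                "geometry": {
                    "n_cells": self.geometry.n_cells,
                    "width_um": self.geometry.width_um,
                    "apoplast_um": self.geometry.apoplast_um,
                    "lengths_um": self.geometry.lengths_um.tolist(),
                    "fractions": self.geometry.fractions.tolist(),
                },
                "profile": repr(self.profile),
                "mutant": self.mutant,
                "plasmodesmata": self.plasmodesmata,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_profile(spec: Optional[dict], geometry_phi: float) -> LengthProfile:
    if spec is None:
        return StaticUniformProfile(phi0=geometry_phi)
    kind = spec.get("kind")
    if kind not in _PROFILE_KINDS:
        raise ValueError(f"unknown length_profile kind {kind!r}; expected {_PROFILE_KINDS}")
    pars = {k: v for k, v in spec.items() if k != "kind"}
    if kind == "static_uniform":
        return StaticUniformProfile(phi0=pars.get("phi0", geometry_phi))
    if kind == "linear_time":
        return LinearGrowthProfile(
            kappa=pars["kappa"],
            phi0=pars.get("phi0", geometry_phi),
            vacuolar_expansion=pars.get("vacuolar_expansion", True),
        )
    if kind == "linear_space":
        return LinearSpatialProfile(
            alpha=pars["alpha"],
            nu=pars["nu"],
            phi1=pars.get("phi1", 0.1),
            phiN1=pars.get("phiN1", 0.9),
        )
    sched = DivisionSchedule(T_div=pars["T_div"], lam=pars.get("lam", 0.0))
    return ExponentialDivisionProfile(sched=sched, phi0=pars.get("phi0", geometry_phi))


def resolve(
    preset: Optional[str] = None,
    mutant: str = WILD_TYPE,
    plasmodesmata: bool = True,
    physiology: Optional[dict] = None,
    geometry: Optional[dict] = None,
    length_profile: Optional[dict] = None,
    solver: Optional[dict] = None,
    output: Optional[dict] = None,
) -> RunConfig:
    """Merge a preset with overrides into a fully specified configuration."""
    if mutant not in MUTANTS:
        raise ValueError(f"unknown mutant {mutant!r}; expected one of {MUTANTS}")
    phys_kw: dict[str, Any] = {}
    geom_kw: dict[str, Any] = {}
    provenance: dict[str, str] = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
        phys_kw.update(PRESETS[preset]["physiology"])
        geom_kw.update(PRESETS[preset]["geometry"])
        provenance.update({k: f"preset:{preset}" for k in (*phys_kw, *geom_kw)})
    for source, keys, target in (
        (physiology or {}, _PHYS_KEYS, phys_kw),
        (geometry or {}, _GEOM_KEYS, geom_kw),
    ):
        unknown = set(source) - keys
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        target.update(source)
        provenance.update({k: "override" for k in source})
    missing = (_PHYS_KEYS - set(phys_kw)) | (_GEOM_KEYS - set(geom_kw))
    if missing:
        raise ValueError(f"missing required configuration keys: {sorted(missing)}")

    phys = HormonePhysiology(**phys_kw)
    if not plasmodesmata:
        phys = dataclasses.replace(phys, P_plas=0.0)
    profile_spec = length_profile
    if profile_spec is not None and profile_spec.get("kind") == "linear_space" and "alpha" not in profile_spec:
        # fit the per-cell discretisation from end-cell lengths
        fitted = fit_linear_file(
            l1_um=profile_spec["l1_um"],
            lN1_um=profile_spec["lN1_um"],
            phi1=profile_spec.get("phi1", 0.1),
            phiN1=profile_spec.get("phiN1", 0.9),
            n_cells=geom_kw["n_cells"],
            apoplast_um=geom_kw["apoplast_um"],
        )
        geom = fitted.geometry(width_um=geom_kw["width_um"])
        profile_spec = dict(
            kind="linear_space",
            alpha=fitted.alpha,
            nu=fitted.nu,
            phi1=profile_spec.get("phi1", 0.1),
            phiN1=profile_spec.get("phiN1", 0.9),
        )
    else:
        geom = CellFileGeometry.uniform(
            n_cells=geom_kw["n_cells"],
            length_um=geom_kw["length_um"],
            width_um=geom_kw["width_um"],
            apoplast_um=geom_kw["apoplast_um"],
            phi=geom_kw["phi"],
        )
    profile = _build_profile(profile_spec, geom_kw.get("phi", 0.1))
    params = nondimensionalize(phys, geom, mutant=mutant)
    return RunConfig(
        physiology=phys.with_mutant(mutant),
        geometry=geom,
        profile=profile,
        params=params,
        mutant=mutant,
        plasmodesmata=plasmodesmata,
        solver=solver or {},
        output=output or {},
        provenance=provenance,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ValueError(
            "empty configuration; required keys: preset, or physiology "
            f"({sorted(_PHYS_KEYS)}) and geometry ({sorted(_GEOM_KEYS)})"
        )
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return resolve(
        preset=data.get("preset"),
        mutant=data.get("mutant", WILD_TYPE),
        plasmodesmata=data.get("plasmodesmata", True),
        physiology=data.get("physiology"),
        geometry=data.get("geometry"),
        length_profile=data.get("length_profile"),
        solver=data.get("solver"),
        output=data.get("output"),
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not callable(v)
        }
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    return obj


def write_results(result, path, fmt: Optional[str] = None):
    """Serialize a trajectory, solution or coefficient set.

    CSV output is long-format; JSON output nests the arrays.  Floats are
    written at 12 significant digits with a deterministic column order.
    """
    import pandas as pd

    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "json")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        if hasattr(result, "to_frame"):
            frame = result.to_frame()
        elif hasattr(result, "C"):
            rows = []
            for k, t in enumerate(result.t):
                rows.append(
                    pd.DataFrame(
                        {"time": t, "position": result.grid, "concentration": result.C[k]}
                    )
                )
            frame = pd.concat(rows, ignore_index=True)
        elif isinstance(result, pd.DataFrame):
            frame = result
        else:
            frame = pd.DataFrame(_jsonable(result))
        frame.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        payload = _jsonable(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path
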