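"""Parameter-file handling, trajectory serialization, and test fixtures.

Parameter files are YAML with the same nested structure as
:class:`~colicarb.params.ParameterSet` (sections ``globals``, ``tfs``,
``reactions``, ``regulation``, ``anabolic``; each entry a
``{value, provenance, unit}`` mapping or a bare number, which is treated as
provenance=fallback). Trajectories are written as three RFC-4180 CSV tables
(states, fluxes, scalars) plus a JSON metadata sidecar carrying units, the
parameter-set hash, solver settings and the scenario, enough to reproduce
the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ParameterError, ParameterSet, _e
from .simulate import CultureScenario, Trajectory

logger = logging.getLogger("colicarb")

__all__ = [
    "read_parameters",
    "write_parameters",
    "write_trajectory",
    "read_trajectory_tables",
    "write_measured_flux_fixture",
    "read_measured_fluxes",
]


def _normalize_entry(path: str, raw) -> dict:
    if isinstance(raw, (int, float)):
        return _e(float(raw))
    if isinstance(raw, dict) and "value" in raw:
        entry = {"value": raw["value"],
                 "provenance": raw.get("provenance", "fallback"),
                 "unit": raw.get("unit", "")}
        if not isinstance(entry["value"], str):
            entry["value"] = float(entry["value"])
        return entry
    raise ParameterError(f"malformed parameter entry at {path}: {raw!r}")


def read_parameters(path: str | Path) -> ParameterSet:
    """Read a YAML parameter file into a validated :class:`ParameterSet`.

    Fallback-provenance entries are logged prominently so calibration gaps
    are never silent.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ParameterError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")

    data: dict = {"globals": {}, "tfs": {}, "reactions": {},
                  "regulation": raw.get("regulation", []), "anabolic": {}}
    for section in ("globals", "anabolic"):
        for name, entry in (raw.get(section) or {}).items():
            data[section][name] = _normalize_entry(f"{section}.{name}", entry)
    for section in ("tfs", "reactions"):
        for group, sub in (raw.get(section) or {}).items():
            data[section][group] = {
                name: _normalize_entry(f"{section}.{group}.{name}", entry)
                for name, entry in (sub or {}).items()
            }
    ps = ParameterSet(data)
    ps.validate()
    fallbacks = ps.fallback_entries()
    if fallbacks:
        logger.warning(
            "parameter file %s: %d entries use fallback (package-calibrated) "
            "values, e.g. %s", path, len(fallbacks), ", ".join(fallbacks[:5])
        )
    return ps


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a :class:`ParameterSet` to YAML (round-trips losslessly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory(trajectory: Trajectory, outdir: str | Path,
                     params: ParameterSet | None = None,
                     seed: int | None = None) -> dict[str, Path]:
    """Write a trajectory as states/fluxes/scalars CSVs plus metadata JSON.

    Time is in hours; intracellular states in mM, extracellular in g/l,
    biomass in gDCW/l, fluxes in mmol/gDCW/h. Values round-trip at double
    precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    states = pd.DataFrame(trajectory.states, columns=list(trajectory.species_names))
    states.insert(0, "time_h", trajectory.t)
    fluxes = pd.DataFrame(trajectory.fluxes, columns=list(trajectory.flux_names))
    fluxes.insert(0, "time_h", trajectory.t)
    scalars = pd.DataFrame({
        "time_h": trajectory.t,
        "mu": trajectory.mu,
        "v_NADPH": trajectory.v_nadph,
        "EIIA_P_fraction": trajectory.eiia_p,
    })
    for i, tf in enumerate(trajectory.tf_names):
        scalars[f"TF_{tf}"] = trajectory.tf_activities[:, i]

    paths = {}
    for name, frame in (("states", states), ("fluxes", fluxes), ("scalars", scalars)):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.17g")
        paths[name] = p

    meta = {
        "units": {
            "time": "h", "intracellular": "mM", "extracellular": "g/l",
            "biomass": "gDCW/l", "flux": "mmol/gDCW/h", "mu": "1/h",
        },
        "scenario": dataclasses.asdict(trajectory.scenario),
        "genotype": {
            "knockouts": sorted(trajectory.genotype.knockouts),
            "tf_overrides": dict(trajectory.genotype.tf_overrides),
            "mva_pathway": trajectory.genotype.mva_pathway,
        },
        "cultivation_time_h": trajectory.cultivation_time,
        "flags": trajectory.flags,
        "solver": {
            "method": trajectory.scenario.method,
            "rtol": trajectory.scenario.rtol,
            "atol": trajectory.scenario.atol,
        },
        "parameter_hash": params.content_hash() if params is not None else None,
        "seed": seed,
    }
    meta_path = outdir / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    paths["metadata"] = meta_path
    return paths


def read_trajectory_tables(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_trajectory`."""
    outdir = Path(outdir)
    return {name: pd.read_csv(outdir / f"{name}.csv", float_precision="round_trip")
            for name in ("states", "fluxes", "scalars")}


# ---------------------------------------------------------------------------
# measured-flux fixtures for the correlation utility
# ---------------------------------------------------------------------------


def write_measured_flux_fixture(
    fluxes: dict[str, float],
    path: str | Path,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Perturb simulated fluxes with Gaussian noise and write them as a
    two-column delimited table (reaction, flux), emulating a measured-flux
    dataset for testing :func:`~colicarb.analysis.flux_correlation`."""
    rng = np.random.default_rng(seed)
    values = np.array(list(fluxes.values()), dtype=float)
    span = float(values.max() - values.min()) or 1.0
    noisy = {
        name: float(v + rng.normal(0.0, noise_sd_fraction * span))
        for name, v in fluxes.items()
    }
    with open(path, "w") as fh:
        fh.write("reaction\tflux_mmol_gDCW_h\n")
        for name, v in noisy.items():
            fh.write(f"{name}\t{v:.6f}\n")
    return noisy


def read_measured_fluxes(path: str | Path) -> dict[str, float]:
    """Read a two-column (reaction, flux) delimited text table."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (reaction, flux)")
    return {str(k): float(v) for k, v in zip(frame.iloc[:, 0], frame.iloc[:, 1])}
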