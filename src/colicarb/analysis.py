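"""NADPH and mevalonate performance metrics and xylose-content design scans.

Total NADPH produced over a batch (mmol per liter of culture) integrates
the specific NADPH production rate times biomass over the cultivation time;
subtracting the anabolic demand (k_Anabolism per unit final biomass) and
dividing by the cultivation time gives the NADPH productivity used to rank
strains and media.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import Genotype
from .params import ParameterSet, default_parameters
from .simulate import CultureScenario, Trajectory, simulate_batch

__all__ = [
    "total_nadph",
    "anabolic_demand",
    "nadph_productivity",
    "exponential_phase_mu",
    "ScanResult",
    "xylose_scan",
    "flux_correlation",
]


def _cultivation_mask(trajectory: Trajectory) -> np.ndarray:
    return trajectory.t <= trajectory.cultivation_time + 1e-12


def total_nadph(trajectory: Trajectory) -> float:
    """Total NADPH produced during the batch (mmol/l of culture).

    Trapezoidal quadrature of v_NADPH(t) * X(t) on the trajectory's dense
    output grid over [0, T].
    """
    m = _cultivation_mask(trajectory)
    integrand = trajectory.v_nadph[m] * trajectory.series("X")[m]
    return float(np.trapezoid(integrand, trajectory.t[m]))


def anabolic_demand(final_biomass: float, params: ParameterSet) -> float:
    """NADPH consumed for cell synthesis: k_Anabolism * X(T) (mmol/l)."""
    if final_biomass < 0:
        raise ValueError("final biomass must be >= 0")
    return params.g("k_Anabolism") * final_biomass


def nadph_productivity(trajectory: Trajectory, params: ParameterSet) -> float:
    """(total NADPH - anabolic demand) / cultivation time (mmol/l/h).

    Negative when anabolic demand exceeds production (the deficit the cell
    would have to cover by transhydrogenase); not clamped.
    """
    t_cult = trajectory.cultivation_time
    if t_cult <= 0:
        raise ValueError("cultivation time must be > 0")
    m = _cultivation_mask(trajectory)
    x_final = float(trajectory.series("X")[m][-1])
    return (total_nadph(trajectory) - anabolic_demand(x_final, params)) / t_cult


def exponential_phase_mu(trajectory: Trajectory, t_min: float = 0.5) -> float:
    """Exponential-phase specific growth rate: the maximum of mu(t) after a
    short adaptation window (the seed intracellular state relaxes within
    the first fraction of an hour)."""
    m = trajectory.t >= min(t_min, trajectory.t[-1] * 0.5)
    return float(np.max(trajectory.mu[m]))


@dataclass
class ScanResult:
    """Per-xylose-content metrics of a batch design scan."""

    table: pd.DataFrame
    preset_name: str
    total_substrate: float
    failures: dict[float, str] = field(default_factory=dict)

    def argmax(self, metric: str) -> float:
        """Xylose content (%) maximizing ``metric``; ties break low."""
        col = self.table[metric]
        ok = col.notna()
        if not ok.any():
            raise ValueError(f"no successful scan points for metric {metric!r}")
        best = col[ok].max()
        return float(self.table.loc[ok & (col >= best - 1e-12), "content"].iloc[0])

    def at(self, content: float) -> pd.Series:
        row = self.table[np.isclose(self.table["content"], content)]
        if row.empty:
            raise KeyError(f"content {content} not in scan grid")
        return row.iloc[0]


def xylose_scan(
    genotype: Genotype,
    total_substrate: float,
    grid: Sequence[float] | None = None,
    params: ParameterSet | None = None,
    scenario_kwargs: Mapping | None = None,
    preset_name: str = "",
) -> ScanResult:
    """Batch-simulate a strain across xylose contents of a fixed-total
    glucose+xylose mixture and tabulate the performance metrics.

    For content c (%), the medium holds (1-c/100)*total glucose and
    (c/100)*total xylose (g/l). The returned table has one row per grid
    point with total NADPH, anabolic demand, NADPH productivity,
    exponential-phase growth rate, final biomass, final mevalonate and
    cultivation time; failed points are recorded and skipped.
    """
    params = params if params is not None else default_parameters()
    if not total_substrate > 0:
        raise ValueError("total substrate must be > 0")
    if grid is None:
        grid = np.arange(0.0, 101.0, 1.0)
    grid = np.asarray(list(grid), dtype=float)
    if np.any((grid < 0) | (grid > 100)):
        raise ValueError("xylose contents must lie in [0, 100] %")

    kwargs = dict(scenario_kwargs or {})
    rows = []
    failures: dict[float, str] = {}
    for content in grid:
        scenario = CultureScenario(
            mode="batch",
            glucose=(1.0 - content / 100.0) * total_substrate,
            xylose=(content / 100.0) * total_substrate,
            **kwargs,
        )
        try:
            traj = simulate_batch(scenario, genotype, params)
            x_final = traj.final_biomass
            tot = total_nadph(traj)
            demand = anabolic_demand(x_final, params)
            rows.append({
                "content": content,
                "total_nadph": tot,
                "anabolic_demand": demand,
                "nadph_productivity": nadph_productivity(traj, params),
                "mu_exp": exponential_phase_mu(traj),
                "final_biomass": x_final,
                "final_mva": float(traj.series("MVA")[-1]),
                "cultivation_time": traj.cultivation_time,
            })
        except Exception as exc:  # record and continue scanning
            failures[float(content)] = f"{type(exc).__name__}: {exc}"
            rows.append({"content": content, "total_nadph": np.nan,
                         "anabolic_demand": np.nan, "nadph_productivity": np.nan,
                         "mu_exp": np.nan, "final_biomass": np.nan,
                         "final_mva": np.nan, "cultivation_time": np.nan})
    table = pd.DataFrame(rows)
    return ScanResult(table=table, preset_name=preset_name,
                      total_substrate=total_substrate, failures=failures)


def flux_correlation(
    simulated: Mapping[str, float],
    measured: Mapping[str, float],
) -> tuple[float, float, list[str]]:
    """Pearson correlation between simulated and measured fluxes.

    Reaction names are matched case-insensitively; returns (r, p-value,
    matched names). Requires at least three shared reactions.
    """
    sim_lower = {k.lower(): float(v) for k, v in simulated.items()}
    pairs = []
    matched = []
    for name, value in measured.items():
        key = name.lower()
        if key in sim_lower:
            pairs.append((sim_lower[key], float(value)))
            matched.append(name)
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 shared reaction names, matched only {len(pairs)}: {matched}"
        )
    sim_v, meas_v = map(np.array, zip(*pairs))
    r, p = stats.pearsonr(sim_v, meas_v)
    return float(r), float(p), matched
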