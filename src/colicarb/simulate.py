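"""Batch and chemostat culture simulation of the kinetic network.

The ODE state is the full :data:`~colicarb.network.SPECIES` vector:
intracellular metabolites (mM, growth-diluted), conserved cofactor pools
(mM, not diluted so that moiety totals are invariant), extracellular
substrates/products (g/l), and biomass (gDCW/l). Specific fluxes
(mmol/gDCW/h) convert to intracellular concentration changes through the
cytoplasmic volume ``V_cyto`` (l/gDCW) and to extracellular changes through
biomass and molar mass.

Integration uses a stiff solver (BDF by default) with event-based detection
of substrate depletion in batch mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import (
    COFACTORS,
    EXTRACELLULAR,
    INTRACELLULAR,
    REACTIONS,
    SPECIES,
    STOICHIOMETRY,
    FluxVector,
    Genotype,
    NetworkState,
    RegulationMap,
    atp_rate,
    compute_fluxes,
    compute_tf_activities,
    eiia_phosphorylated_fraction,
    growth_rate,
    nadph_rate,
)
from .params import ParameterSet, default_parameters

__all__ = [
    "CultureScenario",
    "Trajectory",
    "SimulationError",
    "assemble_rhs",
    "simulate_batch",
    "simulate_chemostat",
    "cultivation_time",
    "default_initial_state",
]

_IDX = {name: i for i, name in enumerate(SPECIES)}
_FLUX_NAMES = tuple(REACTIONS) + ("Resp", "Udh")


class SimulationError(RuntimeError):
    """Solver failure, carrying the last valid state for diagnosis."""

    def __init__(self, message: str, last_state: NetworkState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class CultureScenario:
    """Culture mode, medium, and solver settings for one simulation.

    ``glucose``/``xylose``/``acetate`` are initial (batch) or feed-tank
    (chemostat, via ``feed``) concentrations. ``unit`` declares whether
    substrate concentrations are given in g/l or mM; mM inputs are converted
    with the molar masses in the parameter set.
    """

    mode: str = "batch"  # "batch" | "chemostat"
    glucose: float = 4.0
    xylose: float = 0.0
    acetate: float = 0.0
    unit: str = "g/l"  # "g/l" | "mM"
    biomass0: float = 0.01  # gDCW/l
    aerobic: bool = True
    horizon: float = 40.0  # h
    dilution_rate: float = 0.0  # 1/h, chemostat only
    feed: Mapping[str, float] | None = None  # g/l (or `unit`) in chemostat
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    method: str = "BDF"
    n_output: int = 600

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "chemostat"):
            raise ValueError(f"unknown culture mode {self.mode!r}")
        if self.mode == "chemostat" and not self.dilution_rate > 0:
            raise ValueError("chemostat mode requires dilution_rate > 0")
        if self.mode == "batch" and self.dilution_rate:
            raise ValueError("dilution_rate must be 0 in batch mode")
        if self.unit not in ("g/l", "mM"):
            raise ValueError(f"unknown concentration unit {self.unit!r}")
        for name in ("glucose", "xylose", "acetate", "biomass0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.horizon > 0:
            raise ValueError("horizon must be > 0")

    def initial_extracellular(self, params: ParameterSet) -> dict[str, float]:
        conv = _unit_conversion(self.unit, params)
        return {
            "GLC": self.glucose * conv["GLC"],
            "XYL": self.xylose * conv["XYL"],
            "ACE": self.acetate * conv["ACE"],
            "MVA": 0.0,
        }

    def feed_concentrations(self, params: ParameterSet) -> dict[str, float]:
        conv = _unit_conversion(self.unit, params)
        feed = dict(self.feed or {})
        out = {"GLC": 0.0, "XYL": 0.0, "ACE": 0.0, "MVA": 0.0}
        for key, val in feed.items():
            k = key.upper()
            if k not in out:
                raise KeyError(f"unknown feed species {key!r}")
            out[k] = val * conv[k]
        return out


def _unit_conversion(unit: str, params: ParameterSet) -> dict[str, float]:
    """Factor turning scenario concentrations into g/l."""
    if unit == "g/l":
        return {k: 1.0 for k in EXTRACELLULAR}
    return {k: params.g(f"M_{k}") / 1000.0 for k in EXTRACELLULAR}


#: physiological seed values for the intracellular pools (mM); the fast
#: metabolite dynamics forget these within minutes of simulated time
_SEED_INTRACELLULAR = {
    "G6P": 1.0, "F6P": 0.4, "FBP": 1.0, "GAP": 0.2, "PEP": 1.0, "PYR": 1.0,
    "ACCOA": 0.3, "P6G": 0.1, "RU5P": 0.1, "X5P": 0.1, "R5P": 0.1,
    "S7P": 0.05, "E4P": 0.05, "ICIT": 0.1, "AKG": 0.3, "SUC": 0.3,
    "FUM": 0.2, "MAL": 0.5, "OAA": 0.05, "GLX": 0.01,
    "XYLIN": 0.0, "XYLU": 0.0, "AACOA": 0.0, "HMGCOA": 0.0,
}


def default_initial_state(scenario: CultureScenario, params: ParameterSet) -> NetworkState:
    state = NetworkState(_SEED_INTRACELLULAR)
    for name in ("ATP", "ADP", "AMP", "NAD", "NADH", "NADP", "NADPH"):
        state[name] = params.g(f"{name}0")
    state.update(scenario.initial_extracellular(params))
    state["X"] = scenario.biomass0
    return state


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def _rhs_vector(
    y: np.ndarray,
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet,
    reg: RegulationMap,
    feed: Mapping[str, float],
) -> tuple[np.ndarray, FluxVector, float]:
    """Time derivative of the raw state vector, plus fluxes and mu."""
    state = dict(zip(SPECIES, y))
    tfs = compute_tf_activities(state, genotype, params, aerobic=scenario.aerobic)
    v = compute_fluxes(state, genotype, params, tfs=tfs, reg=reg,
                       aerobic=scenario.aerobic)
    v_atp = atp_rate(v, params)
    mu = growth_rate(v_atp, max(state["ACE"], 0.0), params)

    vc = params.g("V_cyto")
    dy = np.zeros_like(y)

    # reaction stoichiometry -> net specific production per species
    net = {s: 0.0 for s in INTRACELLULAR + COFACTORS}
    for rxn, stoich in STOICHIOMETRY.items():
        flux = v[rxn] if rxn != "Resp" else v["Resp"]
        if flux == 0.0:
            continue
        for sp, coeff in stoich.items():
            net[sp] += coeff * flux

    # anabolic precursor drains (mmol/gDCW per unit biomass formed),
    # saturable so an empty pool cannot be driven negative
    k_anab = params.g("K_anabolic_sat")
    for sp in INTRACELLULAR:
        coeff = params.anabolic_coeff(sp)
        if coeff:
            c = max(state[sp], 0.0)
            net[sp] -= coeff * mu * c / (k_anab + c)

    # lumped anabolic + maintenance ATP demand, first-order in [ATP] so the
    # adenylate pool settles mid-range (production saturates through ADP);
    # mirrored onto ADP to conserve the moiety
    # the extra ATP/(kd+ATP) factor lets demand fall off faster than
    # ATP-coupled production at low energy charge, so transient dips recover
    atp = max(state["ATP"], 0.0)
    kd = params.g("K_ATP_demand")
    sat = atp / (kd + atp)
    atp_demand = params.g("k_ATP_drain") * atp * sat + params.g("m_ATP") * sat
    net["ATP"] -= atp_demand
    net["ADP"] += atp_demand

    # anabolic NADPH demand (k_Anabolism per unit biomass), saturable
    nadph = max(state["NADPH"], 0.0)
    kn = params.g("K_NADPH_demand")
    nsat = (nadph / (kn + nadph)) / (
        params.g("NADPH_ref") / (kn + params.g("NADPH_ref"))
    )
    nadph_demand = params.g("k_Anabolism") * mu * nsat
    net["NADPH"] -= nadph_demand
    net["NADP"] += nadph_demand

    for sp in INTRACELLULAR:
        dy[_IDX[sp]] = net[sp] / vc - mu * max(state[sp], 0.0)
    for sp in COFACTORS:
        dy[_IDX[sp]] = net[sp] / vc

    # extracellular balances (g/l/h)
    x = max(state["X"], 0.0)
    d = scenario.dilution_rate
    ext_rate = {
        "GLC": -(v["PTS"] + v["NPTS"]) * params.g("M_GLC") / 1000.0,
        "XYL": -v["XT"] * params.g("M_XYL") / 1000.0,
        "ACE": (v["PTACK"] - v["Acs"]) * params.g("M_ACE") / 1000.0,
        "MVA": v["HMGR"] * params.g("M_MVA") / 1000.0,
    }
    for sp in EXTRACELLULAR:
        dy[_IDX[sp]] = ext_rate[sp] * x + d * (feed.get(sp, 0.0) - state[sp])
    dy[_IDX["X"]] = (mu - d) * x

    return dy, v, mu


def assemble_rhs(
    state: NetworkState | Mapping[str, float],
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet,
) -> NetworkState:
    """Evaluate the mass-balance right-hand side at one state.

    Each intracellular species obeys dc/dt = (production - consumption -
    anabolic drain)/V_cyto - mu*c; extracellular species follow uptake/
    secretion scaled by biomass (plus dilution terms in chemostat mode).
    Returns the derivative keyed like a :class:`NetworkState`.
    """
    if not isinstance(state, NetworkState):
        state = NetworkState(state)
    for sp, val in state.items():
        if val < -1e-6:
            raise SimulationError(
                f"negative concentration beyond tolerance for {sp}: {val}", state
            )
    reg = RegulationMap.from_parameters(params)
    feed = scenario.feed_concentrations(params) if scenario.mode == "chemostat" else {}
    dy, _, _ = _rhs_vector(state.to_vector(), scenario, genotype, params, reg, feed)
    return NetworkState.from_vector(dy)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-indexed result of one culture simulation."""

    t: np.ndarray  # h
    states: np.ndarray  # (n_t, n_species)
    fluxes: np.ndarray  # (n_t, n_fluxes)
    mu: np.ndarray  # 1/h
    tf_activities: np.ndarray  # (n_t, 4): Crp, Cra, ArcA, XylR
    eiia_p: np.ndarray  # phosphorylated EIIA fraction
    v_nadph: np.ndarray  # mmol/gDCW/h
    scenario: CultureScenario
    genotype: Genotype
    cultivation_time: float
    flags: dict = field(default_factory=dict)
    species_names: tuple = SPECIES
    flux_names: tuple = _FLUX_NAMES
    tf_names: tuple = ("Crp", "Cra", "ArcA", "XylR")

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def series(self, name: str) -> np.ndarray:
        if name in self.species_names:
            return self.states[:, self.species_names.index(name)]
        if name in self.flux_names:
            return self.fluxes[:, self.flux_names.index(name)]
        if name in self.tf_names:
            return self.tf_activities[:, self.tf_names.index(name)]
        raise KeyError(name)

    def state_at(self, i: int) -> NetworkState:
        return NetworkState.from_vector(self.states[i])

    def flux_at(self, i: int) -> FluxVector:
        return FluxVector(dict(zip(self.flux_names, self.fluxes[i])))

    @property
    def final_state(self) -> NetworkState:
        return self.state_at(-1)

    @property
    def final_biomass(self) -> float:
        return float(self.series("X")[-1])


def _postprocess(
    t: np.ndarray,
    ys: np.ndarray,
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet,
    reg: RegulationMap,
    flags: dict,
) -> Trajectory:
    n = len(t)
    fluxes = np.zeros((n, len(_FLUX_NAMES)))
    mu = np.zeros(n)
    tfa = np.zeros((n, 4))
    eiia = np.zeros(n)
    vnadph = np.zeros(n)
    for i in range(n):
        state = dict(zip(SPECIES, np.maximum(ys[i], 0.0)))
        tfs = compute_tf_activities(state, genotype, params, aerobic=scenario.aerobic)
        v = compute_fluxes(state, genotype, params, tfs=tfs, reg=reg,
                           aerobic=scenario.aerobic)
        fluxes[i] = [v[name] for name in _FLUX_NAMES]
        mu[i] = growth_rate(atp_rate(v, params), state["ACE"], params)
        tfa[i] = [tfs.crp, tfs.cra, tfs.arca, tfs.xylr]
        eiia[i] = eiia_phosphorylated_fraction(state, params)
        vnadph[i] = nadph_rate(v, params)

    thr = params.g("depletion_threshold")
    glc = ys[:, _IDX["GLC"]]
    xyl = ys[:, _IDX["XYL"]]
    depleted = (glc < thr) & (xyl < thr)
    if flags.get("substrate_depleted"):
        t_cult = float(t[-1])
    elif depleted.any():
        t_cult = float(t[int(np.argmax(depleted))])
    else:
        t_cult = float(scenario.horizon)

    return Trajectory(
        t=t,
        states=np.maximum(ys, 0.0),
        fluxes=fluxes,
        mu=mu,
        tf_activities=tfa,
        eiia_p=eiia,
        v_nadph=vnadph,
        scenario=scenario,
        genotype=genotype,
        cultivation_time=t_cult,
        flags=flags,
    )


def _integrate(
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet,
    y0: np.ndarray,
    events=None,
):
    reg = RegulationMap.from_parameters(params)
    feed = scenario.feed_concentrations(params) if scenario.mode == "chemostat" else {}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy, _, _ = _rhs_vector(y, scenario, genotype, params, reg, feed)
        return dy

    sol = solve_ivp(
        rhs,
        (0.0, scenario.horizon),
        y0,
        method=scenario.method,
        rtol=scenario.rtol,
        atol=scenario.atol,
        max_step=scenario.max_step,
        dense_output=True,
        events=events,
    )
    if not sol.success:
        last = NetworkState.from_vector(sol.y[:, -1]) if sol.y.size else None
        raise SimulationError(f"ODE solver failed: {sol.message}", last)
    return sol, reg


def simulate_batch(
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet | None = None,
    initial_state: NetworkState | None = None,
) -> Trajectory:
    """Integrate an aerobic/anaerobic batch culture until substrate
    depletion (both glucose and xylose below the depletion threshold) or the
    scenario horizon."""
    params = params if params is not None else default_parameters()
    if scenario.mode != "batch":
        raise ValueError("simulate_batch requires a batch scenario")
    state0 = initial_state or default_initial_state(scenario, params)
    y0 = state0.to_vector()

    if state0["X"] == 0.0:
        # no cells: nothing changes
        t = np.linspace(0.0, scenario.horizon, 11)
        ys = np.tile(y0, (len(t), 1))
        reg = RegulationMap.from_parameters(params)
        return _postprocess(t, ys, scenario, genotype, params, reg,
                            {"substrate_depleted": False, "horizon_reached": True})

    thr = params.g("depletion_threshold")

    def depleted(t: float, y: np.ndarray) -> float:
        return max(y[_IDX["GLC"]], y[_IDX["XYL"]]) - thr

    depleted.terminal = True
    depleted.direction = -1.0

    sol, reg = _integrate(scenario, genotype, params, y0, events=[depleted])
    t_end = float(sol.t[-1])
    hit = bool(sol.t_events and len(sol.t_events[0]))
    flags = {"substrate_depleted": hit, "horizon_reached": not hit}

    t = np.unique(np.concatenate([np.linspace(0.0, t_end, scenario.n_output), sol.t]))
    ys = sol.sol(t).T
    return _postprocess(t, ys, scenario, genotype, params, reg, flags)


def cultivation_time(trajectory: Trajectory, threshold: float | None = None) -> float:
    """Earliest time at which glucose and xylose are both below
    ``threshold`` (g/l); the horizon if they never are."""
    if threshold is None:
        return trajectory.cultivation_time
    glc = trajectory.series("GLC")
    xyl = trajectory.series("XYL")
    below = (glc < threshold) & (xyl < threshold)
    if below.any():
        return float(trajectory.t[int(np.argmax(below))])
    return float(trajectory.scenario.horizon)


# ---------------------------------------------------------------------------
# chemostat
# ---------------------------------------------------------------------------

_CONSERVED_DROP = ("ADP", "NAD", "NADP", "AMP")


def simulate_chemostat(
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet | None = None,
    initial_state: NetworkState | None = None,
) -> tuple[Trajectory, NetworkState | None]:
    """Integrate a chemostat to steady state and refine it with a root solve.

    Returns the trajectory and the refined steady state (``None`` on
    washout, which is flagged in ``trajectory.flags['washout']``).
    """
    params = params if params is not None else default_parameters()
    if scenario.mode != "chemostat":
        raise ValueError("simulate_chemostat requires a chemostat scenario")
    state0 = initial_state or _chemostat_seed(scenario, params)
    y0 = state0.to_vector()

    sol, reg = _integrate(scenario, genotype, params, y0)
    t = np.unique(np.concatenate(
        [np.linspace(0.0, sol.t[-1], scenario.n_output), sol.t]))
    ys = sol.sol(t).T

    y_end = sol.y[:, -1]
    washout = y_end[_IDX["X"]] < 1e-4
    flags = {"washout": bool(washout), "horizon_reached": True,
             "substrate_depleted": False}
    steady: NetworkState | None = None
    if not washout:
        y_ss = _refine_steady_state(y_end, scenario, genotype, params, reg)
        if y_ss is not None:
            steady = NetworkState.from_vector(y_ss)
            flags["steady_state"] = True
        else:
            steady = NetworkState.from_vector(y_end)
            flags["steady_state"] = False
    traj = _postprocess(t, ys, scenario, genotype, params, reg, flags)
    return traj, steady


def _chemostat_seed(scenario: CultureScenario, params: ParameterSet) -> NetworkState:
    feed = scenario.feed_concentrations(params)
    state = NetworkState(_SEED_INTRACELLULAR)
    for name in ("ATP", "ADP", "AMP", "NAD", "NADH", "NADP", "NADPH"):
        state[name] = params.g(f"{name}0")
    state["GLC"] = max(0.25 * feed["GLC"], 1e-3)
    state["XYL"] = 0.25 * feed["XYL"]
    state["ACE"] = 0.0
    state["X"] = max(scenario.biomass0, 0.1)
    return state


def _refine_steady_state(
    y_end: np.ndarray,
    scenario: CultureScenario,
    genotype: Genotype,
    params: ParameterSet,
    reg: RegulationMap,
) -> np.ndarray | None:
    """Newton-refine the integration endpoint on the conservation-reduced
    system (ADP/NAD/NADP/AMP follow from their moiety totals)."""
    feed = scenario.feed_concentrations(params)
    free = [i for i, s in enumerate(SPECIES) if s not in _CONSERVED_DROP]
    totals = {
        "ADP": y_end[_IDX["ATP"]] + y_end[_IDX["ADP"]],
        "NAD": y_end[_IDX["NAD"]] + y_end[_IDX["NADH"]],
        "NADP": y_end[_IDX["NADP"]] + y_end[_IDX["NADPH"]],
        "AMP": y_end[_IDX["AMP"]],
    }

    def expand(z: np.ndarray) -> np.ndarray:
        y = np.empty(len(SPECIES))
        y[free] = z
        y[_IDX["ADP"]] = totals["ADP"] - y[_IDX["ATP"]]
        y[_IDX["NAD"]] = totals["NAD"] - y[_IDX["NADH"]]
        y[_IDX["NADP"]] = totals["NADP"] - y[_IDX["NADPH"]]
        y[_IDX["AMP"]] = totals["AMP"]
        return y

    def fun(z: np.ndarray) -> np.ndarray:
        dy, _, _ = _rhs_vector(expand(z), scenario, genotype, params, reg, feed)
        return dy[free]

    res = root(fun, y_end[free], method="hybr", tol=1e-12)
    if not res.success:
        return None
    y_ss = expand(res.x)
    if np.any(y_ss < -1e-9) or y_ss[_IDX["X"]] < 1e-4:
        return None
    return np.maximum(y_ss, 0.0)
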