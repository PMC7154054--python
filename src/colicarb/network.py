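"""Reaction network, rate laws, TF activity functions and scalar observables.

The network covers glycolysis, the pentose phosphate pathway, the TCA cycle
and glyoxylate shunt, anaplerosis, fermentative and acetate pathways,
oxidative phosphorylation, glucose transport (PTS and non-PTS), the xylose
assimilation subsystem (transport XT, isomerase Xyi, xylulokinase Xyk), and
an optional three-step heterologous mevalonate pathway (AtoB, HMGS, HMGR).

Regulation is two-layered: allosteric effectors sit inside individual rate
laws (FBP activates Pyk, NADPH inhibits G6PDH, G6P throttles the PTS as a
proxy for ptsG-mRNA destabilization), and transcription-factor activities
(cAMP-Crp, Cra, ArcA, XylR) scale maximum rates through
``vmax = vmax' * f(TF)`` with ``f = a + b*TF`` for activation and
``f = a + b*(1 - TF)`` for repression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .params import ParameterSet, ParameterError

__all__ = [
    "SPECIES",
    "REACTIONS",
    "NetworkState",
    "TFActivities",
    "Genotype",
    "RegulationMap",
    "FluxVector",
    "FluxError",
    "GENE_REACTION_MAP",
    "compute_tf_activities",
    "regulated_vmax",
    "regulation_factor",
    "compute_fluxes",
    "atp_rate",
    "growth_rate",
    "nadph_rate",
    "eiia_phosphorylated_fraction",
    "STOICHIOMETRY",
]

# ---------------------------------------------------------------------------
# species layout
# ---------------------------------------------------------------------------

#: intracellular metabolites (mM), diluted by growth
INTRACELLULAR = (
    "G6P", "F6P", "FBP", "GAP", "PEP", "PYR", "ACCOA",
    "P6G", "RU5P", "X5P", "R5P", "S7P", "E4P",
    "ICIT", "AKG", "SUC", "FUM", "MAL", "OAA", "GLX",
    "XYLIN", "XYLU",
    "AACOA", "HMGCOA",
)

#: conserved cofactor pools (mM), not growth-diluted
COFACTORS = ("ATP", "ADP", "AMP", "NADH", "NAD", "NADPH", "NADP")

#: extracellular species (g/l) and biomass (gDCW/l)
EXTRACELLULAR = ("GLC", "XYL", "ACE", "MVA")
BIOMASS = ("X",)

SPECIES: tuple[str, ...] = INTRACELLULAR + COFACTORS + EXTRACELLULAR + BIOMASS
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: canonical reaction order of the flux vector
REACTIONS: tuple[str, ...] = (
    "PTS", "NPTS", "Glk",
    "Pgi", "Pfk", "Fbp", "Fba", "L_Emp", "Pyk", "Pps",
    "PDH", "Pfl",
    "G6PDH", "PGDH", "Rpe", "Rpi", "TktA", "TktB", "Tal",
    "CS", "ICDH", "aKGDH", "SFM", "Fum", "MDH", "Icl", "MS",
    "Ppc", "Pck", "Mez",
    "PTACK", "Acs", "LDH", "ADH",
    "XT", "Xyi", "Xyk",
    "OP",
    "AtoB", "HMGS", "HMGR",
)

#: gene -> network reaction map used by knockouts (lumped reactions disable
#: the whole lump)
GENE_REACTION_MAP: dict[str, str] = {
    "pgi": "Pgi",
    "ptsG": "PTS",
    "pfl": "Pfl",
    "ackA": "PTACK",
    "pta": "PTACK",
    "zwf": "G6PDH",
    "pykF": "Pyk",
    "ppc": "Ppc",
    "aceA": "Icl",
    "ldhA": "LDH",
    "adhE": "ADH",
}

# stoichiometry of intracellular species and cofactors per unit flux
# (extracellular balances are handled by the culture simulator);
# OP carries its ATP yield in the flux value itself, with the underlying
# NADH oxidation reported as the auxiliary flux "Resp"
STOICHIOMETRY: dict[str, dict[str, float]] = {
    "PTS": {"G6P": 1, "PEP": -1, "PYR": 1},
    "Glk": {"G6P": 1, "ATP": -1, "ADP": 1},
    "Pgi": {"G6P": -1, "F6P": 1},
    "Pfk": {"F6P": -1, "FBP": 1, "ATP": -1, "ADP": 1},
    "Fbp": {"FBP": -1, "F6P": 1},
    "Fba": {"FBP": -1, "GAP": 2},
    "L_Emp": {"GAP": -1, "PEP": 1, "NAD": -1, "NADH": 1, "ADP": -1, "ATP": 1},
    "Pyk": {"PEP": -1, "PYR": 1, "ADP": -1, "ATP": 1},
    "Pps": {"PYR": -1, "PEP": 1, "ATP": -1, "ADP": 1},
    "PDH": {"PYR": -1, "ACCOA": 1, "NAD": -1, "NADH": 1},
    "Pfl": {"PYR": -1, "ACCOA": 1},
    "G6PDH": {"G6P": -1, "P6G": 1, "NADP": -1, "NADPH": 1},
    "PGDH": {"P6G": -1, "RU5P": 1, "NADP": -1, "NADPH": 1},
    "Rpe": {"RU5P": -1, "X5P": 1},
    "Rpi": {"RU5P": -1, "R5P": 1},
    "TktA": {"X5P": -1, "R5P": -1, "S7P": 1, "GAP": 1},
    "Tal": {"S7P": -1, "GAP": -1, "E4P": 1, "F6P": 1},
    "TktB": {"X5P": -1, "E4P": -1, "F6P": 1, "GAP": 1},
    "CS": {"ACCOA": -1, "OAA": -1, "ICIT": 1},
    "ICDH": {"ICIT": -1, "AKG": 1, "NADP": -1, "NADPH": 1},
    "aKGDH": {"AKG": -1, "SUC": 1, "NAD": -1, "NADH": 1, "ADP": -1, "ATP": 1},
    "SFM": {"SUC": -1, "FUM": 1},
    "Fum": {"FUM": -1, "MAL": 1},
    "MDH": {"MAL": -1, "OAA": 1, "NAD": -1, "NADH": 1},
    "Icl": {"ICIT": -1, "SUC": 1, "GLX": 1},
    "MS": {"GLX": -1, "ACCOA": -1, "MAL": 1},
    "Ppc": {"PEP": -1, "OAA": 1},
    "Pck": {"OAA": -1, "PEP": 1, "ATP": -1, "ADP": 1},
    "Mez": {"MAL": -1, "PYR": 1, "NADP": -1, "NADPH": 1},
    "PTACK": {"ACCOA": -1, "ADP": -1, "ATP": 1},
    "Acs": {"ACCOA": 1, "ATP": -1, "ADP": 1},
    "LDH": {"PYR": -1, "NADH": -1, "NAD": 1},
    "ADH": {"ACCOA": -1, "NADH": -2, "NAD": 2},
    "XT": {"XYLIN": 1, "ATP": -1, "ADP": 1},
    "Xyi": {"XYLIN": -1, "XYLU": 1},
    "Xyk": {"XYLU": -1, "X5P": 1, "ATP": -1, "ADP": 1},
    "OP": {"ATP": 1, "ADP": -1},
    "Resp": {"NADH": -1, "NAD": 1},
    "Udh": {"NADPH": -1, "NADP": 1, "NAD": -1, "NADH": 1},
    "AtoB": {"ACCOA": -2, "AACOA": 1},
    "HMGS": {"AACOA": -1, "ACCOA": -1, "HMGCOA": 1},
    "HMGR": {"HMGCOA": -1, "NADPH": -2, "NADP": 2},
    "NPTS": {},
}


class FluxError(ArithmeticError):
    """A rate law evaluated to NaN/Inf, with the offending reaction named."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class NetworkState(dict):
    """Concentrations at one time point, keyed by species name.

    Intracellular species and cofactors are in mM, extracellular species in
    g/l, biomass ``X`` in gDCW/l. Missing species default to 0.
    """

    def __init__(self, values: Mapping[str, float] | None = None, **kw: float):
        super().__init__({s: 0.0 for s in SPECIES})
        if values:
            self.update(values)
        self.update(kw)
        unknown = set(self) - set(SPECIES)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")

    def to_vector(self) -> np.ndarray:
        return np.array([self[s] for s in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, y: Iterable[float]) -> "NetworkState":
        y = list(y)
        if len(y) != len(SPECIES):
            raise ValueError(f"expected {len(SPECIES)} entries, got {len(y)}")
        return cls(dict(zip(SPECIES, map(float, y))))

    def validate(self) -> None:
        for s, v in self.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite concentration for {s}: {v}")
            if v < -1e-9:
                raise ValueError(f"negative concentration for {s}: {v}")


@dataclass(frozen=True)
class TFActivities:
    """Activities (each in [0, 1]) of the four modeled transcription factors."""

    crp: float
    cra: float
    arca: float
    xylr: float
    overridden: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("crp", "cra", "arca", "xylr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"TF activity {name} out of [0,1]: {v}")

    def get(self, tf: str) -> float:
        return getattr(self, tf.lower().replace("camp-crp", "crp"))

    def as_dict(self) -> dict[str, float]:
        return {"Crp": self.crp, "Cra": self.cra, "ArcA": self.arca, "XylR": self.xylr}


@dataclass(frozen=True)
class Genotype:
    """A strain: knocked-out genes, pinned TF activities, MVA-pathway flag."""

    knockouts: frozenset[str] = frozenset()
    tf_overrides: Mapping[str, float] = field(default_factory=dict)
    mva_pathway: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "tf_overrides", dict(self.tf_overrides))
        unknown = self.knockouts - set(GENE_REACTION_MAP)
        if unknown:
            raise KeyError(
                f"unknown knockout gene(s) {sorted(unknown)}; "
                f"supported: {sorted(GENE_REACTION_MAP)}"
            )
        for tf, level in self.tf_overrides.items():
            if not (0.0 <= level <= 1.0):
                raise ValueError(f"TF override for {tf} out of [0,1]: {level}")

    @property
    def disabled_reactions(self) -> frozenset[str]:
        return frozenset(GENE_REACTION_MAP[g] for g in self.knockouts)


@dataclass(frozen=True)
class RegulationEdge:
    tf: str
    target: str
    sign: str
    a: float
    b: float

    def factor(self, activity: float) -> float:
        g = activity if self.sign == "+" else 1.0 - activity
        return max(self.a + self.b * g, 0.0)


class RegulationMap:
    """TF -> reaction regulation edges with per-edge linear f(TF) constants."""

    def __init__(self, edges: Iterable[RegulationEdge]):
        self.edges = list(edges)
        by_target: dict[str, list[RegulationEdge]] = {}
        for e in self.edges:
            if e.sign not in ("+", "-"):
                raise ValueError(f"bad regulation sign {e.sign!r}")
            by_target.setdefault(e.target, []).append(e)
        self._by_target = by_target

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "RegulationMap":
        return cls(
            RegulationEdge(d["tf"], d["target"], d["sign"], d["a"], d["b"])
            for d in params.regulation
        )

    def edges_for(self, reaction: str) -> list[RegulationEdge]:
        return self._by_target.get(reaction, [])


class FluxVector(dict):
    """Named specific reaction rates (mmol/gDCW/h)."""

    def __init__(self, values: Mapping[str, float] | None = None, **kw: float):
        super().__init__({r: 0.0 for r in REACTIONS})
        if values:
            self.update(values)
        self.update(kw)

    def to_series(self):
        import pandas as pd

        return pd.Series(self, dtype=float)


# ---------------------------------------------------------------------------
# TF activities
# ---------------------------------------------------------------------------

_EPS = 1e-12


def eiia_phosphorylated_fraction(state: Mapping[str, float], params: ParameterSet) -> float:
    """Quasi-steady-state phosphorylated fraction of PTS protein EIIA.

    The PTS phosphorelay equilibrates much faster than metabolism, leaving
    the EIIA~P fraction a saturating, monotone increasing function of the
    PEP/PYR ratio that drives it.
    """
    r = state["PEP"] / max(state["PYR"], _EPS)
    n = params.g("n_EIIA")
    return r**n / (params.g("K_EIIA") ** n + r**n)


def compute_tf_activities(
    state: Mapping[str, float],
    genotype: Genotype,
    params: ParameterSet,
    aerobic: bool = True,
) -> TFActivities:
    """Evaluate cAMP-Crp, Cra, ArcA and XylR activities for one state.

    cAMP-Crp rises with the PEP/PYR ratio (through EIIA~P and adenylate
    cyclase), Cra falls with FBP, XylR rises with intracellular xylose, and
    ArcA follows the NADH/NAD redox ratio (floored near 1 anaerobically).
    Genotype overrides pin a TF to a fixed activity.
    """
    try:
        r = state["PEP"] / max(state["PYR"], _EPS)
        k, n = params.tf("Crp", "K"), params.tf("Crp", "n")
        crp = r**n / (k**n + r**n)

        fbp = max(state["FBP"], 0.0)
        k, n = params.tf("Cra", "K"), params.tf("Cra", "n")
        cra = 1.0 / (1.0 + (fbp / k) ** n)

        xylin = max(state["XYLIN"], 0.0)
        xylr = xylin / (params.tf("XylR", "K") + xylin)

        ratio = max(state["NADH"], 0.0) / max(state["NAD"], _EPS)
        k, n = params.tf("ArcA", "K"), params.tf("ArcA", "n")
        arca = ratio**n / (k**n + ratio**n)
        if not aerobic:
            arca = max(arca, params.tf("ArcA", "anaerobic_floor"))
    except ParameterError as exc:
        raise ParameterError(f"TF activity function misconfigured: {exc}") from exc

    acts = {"Crp": crp, "Cra": cra, "ArcA": arca, "XylR": xylr}
    overridden = []
    for tf, level in genotype.tf_overrides.items():
        key = {"crp": "Crp", "camp-crp": "Crp", "cra": "Cra",
               "arca": "ArcA", "xylr": "XylR"}.get(tf.lower())
        if key is None:
            raise KeyError(f"unknown transcription factor {tf!r}")
        acts[key] = float(level)
        overridden.append(key)
    return TFActivities(
        crp=min(max(acts["Crp"], 0.0), 1.0),
        cra=min(max(acts["Cra"], 0.0), 1.0),
        arca=min(max(acts["ArcA"], 0.0), 1.0),
        xylr=min(max(acts["XylR"], 0.0), 1.0),
        overridden=frozenset(overridden),
    )


def regulation_factor(reaction: str, tfs: TFActivities, reg: RegulationMap) -> float:
    """Product of per-edge f(TF) factors for one reaction (1 if unregulated)."""
    f = 1.0
    for edge in reg.edges_for(reaction):
        f *= edge.factor(tfs.get(edge.tf))
    return f


def regulated_vmax(
    reaction: str,
    tfs: TFActivities,
    reg: RegulationMap,
    params: ParameterSet,
) -> float:
    """TF-modulated rate capacity vmax' * f(TF_i, ...) for one reaction."""
    if reaction not in params.data["reactions"]:
        raise KeyError(f"unknown reaction {reaction!r}")
    return params.vmax(reaction) * regulation_factor(reaction, tfs, reg)


# ---------------------------------------------------------------------------
# explicit xylose-subsystem rate laws
# ---------------------------------------------------------------------------


def rate_xt(state: Mapping[str, float], tfs: TFActivities, params: ParameterSet,
            reg: RegulationMap | None = None) -> float:
    """Xylose transport with inducer exclusion by unphosphorylated EIIA.

    v = vmax' * f(Crp, XylR) * [XYL] / (K_XYL + (1 + [EIIA]/K_I) * [XYL])
    """
    reg = reg if reg is not None else RegulationMap.from_parameters(params)
    vmax = regulated_vmax("XT", tfs, reg, params)
    xyl = max(state["XYL"], 0.0)
    eiia = max(state.get("EIIA", _unphosphorylated_eiia(state, params)), 0.0)
    return vmax * xyl / (params.rx("XT", "K_XYL") + (1.0 + eiia / params.rx("XT", "K_I")) * xyl)


def _unphosphorylated_eiia(state: Mapping[str, float], params: ParameterSet) -> float:
    return params.g("EIIA_total") * (1.0 - eiia_phosphorylated_fraction(state, params))


def rate_xyi(state: Mapping[str, float], tfs: TFActivities, params: ParameterSet,
             reg: RegulationMap | None = None) -> float:
    """Xylose isomerase, Michaelis--Menten in intracellular xylose."""
    reg = reg if reg is not None else RegulationMap.from_parameters(params)
    vmax = regulated_vmax("Xyi", tfs, reg, params)
    xylin = max(state["XYLIN"], 0.0)
    return vmax * xylin / (params.rx("Xyi", "K_XYLIN") + xylin)


def rate_xyk(state: Mapping[str, float], tfs: TFActivities, params: ParameterSet,
             reg: RegulationMap | None = None) -> float:
    """Xylulokinase, two-substrate (xylulose, ATP) rate law."""
    reg = reg if reg is not None else RegulationMap.from_parameters(params)
    vmax = regulated_vmax("Xyk", tfs, reg, params)
    xu = max(state["XYLU"], 0.0)
    atp = max(state["ATP"], 0.0)
    ku, ka = params.rx("Xyk", "K_XYLU"), params.rx("Xyk", "K_ATP")
    return vmax * xu * atp / (ku * ka + ka * xu + ku * atp + xu * atp)


# ---------------------------------------------------------------------------
# full flux computation
# ---------------------------------------------------------------------------


def _mm(c: float, k: float) -> float:
    c = max(c, 0.0)
    return c / (k + c)


def compute_fluxes(
    state: Mapping[str, float],
    genotype: Genotype,
    params: ParameterSet,
    tfs: TFActivities | None = None,
    reg: RegulationMap | None = None,
    aerobic: bool = True,
) -> FluxVector:
    """Evaluate every rate law at one state; knocked-out reactions are 0.

    Returns a :class:`FluxVector` with the canonical reactions plus the
    auxiliary entry ``Resp`` (NADH oxidation by the respiratory chain, whose
    ATP yield is the ``OP`` entry).
    """
    reg = reg if reg is not None else RegulationMap.from_parameters(params)
    if tfs is None:
        tfs = compute_tf_activities(state, genotype, params, aerobic=aerobic)

    c = {s: max(state[s], 0.0) for s in SPECIES}
    rv = lambda r: regulated_vmax(r, tfs, reg, params)  # noqa: E731
    p = params.rx
    v = FluxVector()
    aero = 1.0 if aerobic else 0.0

    # substrate transport
    rpp = c["PEP"] / max(c["PYR"], _EPS)
    v["PTS"] = (
        rv("PTS")
        * (c["GLC"] / (p("PTS", "K_GLC") + c["GLC"]))
        * (rpp / (p("PTS", "K_pp") + rpp))
        / (1.0 + (c["G6P"] / p("PTS", "Ki_G6P")) ** p("PTS", "n_G6P"))
    )
    # non-PTS transporters + glucokinase are lumped: one rate, with Glk
    # reporting the same value and carrying the ATP cost; glucokinase is
    # product-inhibited by G6P
    v["NPTS"] = (
        rv("NPTS") * c["GLC"] / (p("NPTS", "K_GLC") + c["GLC"])
        * _mm(c["ATP"], p("NPTS", "K_ATP"))
        / (1.0 + (c["G6P"] / p("NPTS", "Ki_G6P")) ** p("NPTS", "n_G6P"))
    )
    v["Glk"] = v["NPTS"]

    # glycolysis / gluconeogenesis
    v["Pgi"] = (
        rv("Pgi")
        * (c["G6P"] - c["F6P"] / p("Pgi", "Keq"))
        / (p("Pgi", "K_G6P") + c["G6P"] + c["F6P"] * p("Pgi", "K_G6P") / p("Pgi", "K_F6P"))
    )
    v["Pfk"] = (
        rv("Pfk") * _mm(c["F6P"], p("Pfk", "K_F6P")) * _mm(c["ATP"], p("Pfk", "K_ATP"))
        / (1.0 + c["PEP"] / p("Pfk", "Ki_PEP"))
    )
    v["Fbp"] = rv("Fbp") * _mm(c["FBP"], p("Fbp", "K_FBP"))
    v["Fba"] = rv("Fba") * _mm(c["FBP"], p("Fba", "K_FBP"))
    v["L_Emp"] = (
        rv("L_Emp") * _mm(c["GAP"], p("L_Emp", "K_GAP"))
        * _mm(c["NAD"], p("L_Emp", "K_NAD")) * _mm(c["ADP"], p("L_Emp", "K_ADP"))
    )
    fbp_act = p("Pyk", "basal") + (1.0 - p("Pyk", "basal")) * (
        c["FBP"] ** p("Pyk", "n_FBP")
        / (p("Pyk", "Ka_FBP") ** p("Pyk", "n_FBP") + c["FBP"] ** p("Pyk", "n_FBP"))
    )
    v["Pyk"] = (
        rv("Pyk") * _mm(c["PEP"], p("Pyk", "K_PEP")) * _mm(c["ADP"], p("Pyk", "K_ADP")) * fbp_act
    )
    v["Pps"] = rv("Pps") * _mm(c["PYR"], p("Pps", "K_PYR")) * _mm(c["ATP"], p("Pps", "K_ATP"))
    v["PDH"] = (
        rv("PDH") * _mm(c["PYR"], p("PDH", "K_PYR")) * _mm(c["NAD"], p("PDH", "K_NAD"))
        / (1.0 + c["NADH"] / p("PDH", "Ki_NADH"))
    )
    v["Pfl"] = rv("Pfl") * _mm(c["PYR"], p("Pfl", "K_PYR"))

    # pentose phosphate pathway
    v["G6PDH"] = (
        rv("G6PDH") * _mm(c["G6P"], p("G6PDH", "K_G6P")) * _mm(c["NADP"], p("G6PDH", "K_NADP"))
        / (1.0 + (c["NADPH"] / p("G6PDH", "Ki_NADPH")) ** p("G6PDH", "n_NADPH"))
    )
    v["PGDH"] = (
        rv("PGDH") * _mm(c["P6G"], p("PGDH", "K_6PG")) * _mm(c["NADP"], p("PGDH", "K_NADP"))
        / (1.0 + c["NADPH"] / p("PGDH", "Ki_NADPH"))
    )
    v["Rpe"] = (
        rv("Rpe") * (c["RU5P"] - c["X5P"] / p("Rpe", "Keq"))
        / (p("Rpe", "K_RU5P") + c["RU5P"] + c["X5P"])
    )
    v["Rpi"] = (
        rv("Rpi") * (c["RU5P"] - c["R5P"] / p("Rpi", "Keq"))
        / (p("Rpi", "K_RU5P") + c["RU5P"] + c["R5P"])
    )
    for name, (a, b, cc, d) in {
        "TktA": ("X5P", "R5P", "S7P", "GAP"),
        "Tal": ("S7P", "GAP", "E4P", "F6P"),
        "TktB": ("X5P", "E4P", "F6P", "GAP"),
    }.items():
        ab, cd = c[a] * c[b], c[cc] * c[d]
        v[name] = rv(name) * (ab - cd / p(name, "Keq")) / (p(name, "K") + ab + cd)

    # TCA cycle and glyoxylate shunt
    v["CS"] = rv("CS") * _mm(c["ACCOA"], p("CS", "K_ACCOA")) * _mm(c["OAA"], p("CS", "K_OAA"))
    v["ICDH"] = (
        rv("ICDH") * _mm(c["ICIT"], p("ICDH", "K_ICIT")) * _mm(c["NADP"], p("ICDH", "K_NADP"))
        / (1.0 + c["NADPH"] / p("ICDH", "Ki_NADPH"))
    )
    v["aKGDH"] = (
        rv("aKGDH") * _mm(c["AKG"], p("aKGDH", "K_AKG")) * _mm(c["NAD"], p("aKGDH", "K_NAD"))
        * _mm(c["ADP"], p("aKGDH", "K_ADP")) / (1.0 + c["NADH"] / p("aKGDH", "Ki_NADH"))
    )
    v["SFM"] = rv("SFM") * _mm(c["SUC"], p("SFM", "K_SUC")) * aero
    v["Fum"] = (
        rv("Fum") * (c["FUM"] - c["MAL"] / p("Fum", "Keq"))
        / (p("Fum", "K_FUM") + c["FUM"] + c["MAL"])
    )
    v["MDH"] = (
        rv("MDH") * _mm(c["MAL"], p("MDH", "K_MAL")) * _mm(c["NAD"], p("MDH", "K_NAD"))
        / (1.0 + c["NADH"] / p("MDH", "Ki_NADH"))
    )
    v["Icl"] = rv("Icl") * _mm(c["ICIT"], p("Icl", "K_ICIT"))
    v["MS"] = rv("MS") * _mm(c["GLX"], p("MS", "K_GLX")) * _mm(c["ACCOA"], p("MS", "K_ACCOA"))

    # anaplerosis (Ppc is allosterically activated by FBP)
    ppc_act = p("Ppc", "basal") + (1.0 - p("Ppc", "basal")) * (
        c["FBP"] ** p("Ppc", "n_FBP")
        / (p("Ppc", "Ka_FBP") ** p("Ppc", "n_FBP") + c["FBP"] ** p("Ppc", "n_FBP"))
    )
    v["Ppc"] = rv("Ppc") * _mm(c["PEP"], p("Ppc", "K_PEP")) * ppc_act
    v["Pck"] = rv("Pck") * _mm(c["OAA"], p("Pck", "K_OAA")) * _mm(c["ATP"], p("Pck", "K_ATP"))
    v["Mez"] = rv("Mez") * _mm(c["MAL"], p("Mez", "K_MAL")) * _mm(c["NADP"], p("Mez", "K_NADP"))

    # overflow / fermentative / acetate
    v["PTACK"] = rv("PTACK") * _mm(c["ACCOA"], p("PTACK", "K_ACCOA")) * _mm(c["ADP"], p("PTACK", "K_ADP"))
    v["Acs"] = rv("Acs") * _mm(c["ACE"], p("Acs", "K_ACE")) * _mm(c["ATP"], p("Acs", "K_ATP"))
    v["LDH"] = rv("LDH") * _mm(c["PYR"], p("LDH", "K_PYR")) * _mm(c["NADH"], p("LDH", "K_NADH"))
    v["ADH"] = rv("ADH") * _mm(c["ACCOA"], p("ADH", "K_ACCOA")) * _mm(c["NADH"], p("ADH", "K_NADH"))

    # xylose subsystem; in the assembled network the ABC transporter XT is
    # additionally coupled to ATP availability (it stalls when the ATP pool
    # empties), on top of its regulatory/substrate form
    xstate = dict(state)
    xstate["EIIA"] = _unphosphorylated_eiia(state, params)
    v["XT"] = rate_xt(xstate, tfs, params, reg) * _mm(c["ATP"], p("XT", "K_ATP"))
    v["Xyi"] = rate_xyi(xstate, tfs, params, reg)
    v["Xyk"] = rate_xyk(xstate, tfs, params, reg)

    # soluble transhydrogenase (UdhA): relieves NADPH overflow toward NADH;
    # engaged only at high NADPH so it never covers an NADPH deficit
    v["Udh"] = (
        rv("Udh")
        * (c["NADPH"] ** 2 / (p("Udh", "K_NADPH") ** 2 + c["NADPH"] ** 2))
        * _mm(c["NAD"], p("Udh", "K_NAD"))
    )

    # respiration and oxidative phosphorylation
    resp = (
        rv("OP") * _mm(c["NADH"], p("OP", "K_NADH")) * _mm(c["ADP"], p("OP", "K_ADP")) * aero
    )
    v["Resp"] = resp
    v["OP"] = params.g("PO_NADH") * resp + params.g("PO_FADH") * v["SFM"]

    # heterologous mevalonate pathway
    if genotype.mva_pathway:
        v["AtoB"] = rv("AtoB") * _mm(c["ACCOA"], p("AtoB", "K_ACCOA")) ** 2
        v["HMGS"] = (
            rv("HMGS") * _mm(c["AACOA"], p("HMGS", "K_AACOA")) * _mm(c["ACCOA"], p("HMGS", "K_ACCOA"))
        )
        v["HMGR"] = (
            rv("HMGR") * _mm(c["HMGCOA"], p("HMGR", "K_HMGCOA")) * _mm(c["NADPH"], p("HMGR", "K_NADPH"))
        )
    else:
        v["AtoB"] = v["HMGS"] = v["HMGR"] = 0.0

    # knockouts zero the mapped reaction exactly (NPTS remains under dptsG)
    for reaction in genotype.disabled_reactions:
        v[reaction] = 0.0

    for name, val in v.items():
        if not math.isfinite(val):
            raise FluxError(f"rate law {name!r} evaluated to {val} at state {dict(state)}")
    return v


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------


def atp_rate(fluxes: Mapping[str, float], params: ParameterSet | None = None) -> float:
    """Specific ATP production rate (mmol/gDCW/h).

    v_ATP = OP + v_L_Emp + v_Pyk + v_PTACK + v_aKGDH
            - v_Glk - v_Pfk - v_Pps - v_Pck - v_Acs - v_XT - v_Xyk
    """
    return (
        fluxes["OP"] + fluxes["L_Emp"] + fluxes["Pyk"] + fluxes["PTACK"] + fluxes["aKGDH"]
        - fluxes["Glk"] - fluxes["Pfk"] - fluxes["Pps"] - fluxes["Pck"]
        - fluxes["Acs"] - fluxes["XT"] - fluxes["Xyk"]
    )


def growth_rate(v_atp: float, ace: float, params: ParameterSet) -> float:
    """Specific growth rate mu = k_ATP * v_ATP * k_ACE/(k_ACE + [ACE]).

    Linearly coupled to the specific ATP production rate, inhibited by
    extracellular acetate, and clamped at zero from below.
    """
    if ace < 0:
        raise ValueError(f"acetate concentration must be >= 0, got {ace}")
    k_ace = params.g("k_ACE")
    mu = params.g("k_ATP") * v_atp * k_ace / (k_ace + ace)
    return max(mu, 0.0)


def nadph_rate(fluxes: Mapping[str, float], params: ParameterSet | None = None) -> float:
    """Specific NADPH production rate: G6PDH + 6PGDH + ICDH + Mez fluxes.

    The first site is configurable (``nadph_first_site``); the default reads
    the oxidative-PP entry G6PDH, the alternative reads the glycolytic lump.
    """
    first = "G6PDH"
    if params is not None:
        first = params.data["globals"].get("nadph_first_site", {}).get("value", "G6PDH")
        if first in ("GAPDH", "L_Emp"):
            first = "L_Emp"
    return fluxes[first] + fluxes["PGDH"] + fluxes["ICDH"] + fluxes["Mez"]
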