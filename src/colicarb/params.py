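"""Kinetic, regulatory, and global constants for the central-carbon model.

Every entry carries a provenance flag: ``supplementary`` for values printed
in the primary literature (currently only the anabolic NADPH demand
k_Anabolism = 14.849 mmol/gDCW), ``fallback`` for values belonging to this
package's own Michaelis--Menten parameterization, calibrated so that the
model reproduces the documented physiology of glucose/xylose co-metabolism
(diauxie in the wild type, co-consumption and slow growth in the pgi and
ptsG mutants, chemostat growth up to D = 0.5 1/h on glucose).

Units
-----
* maximum rates (``vmax``): mmol/gDCW/h
* intracellular Michaelis / inhibition constants: mM
* extracellular half-saturation constants (glucose, xylose, acetate): g/l
* k_ATP: gDCW/mmol; k_Anabolism: mmol/gDCW; k_ACE: g/l
* cytoplasmic volume ``V_cyto``: l/gDCW
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from typing import Iterator

PROVENANCES = ("supplementary", "fallback")

#: globals that must be present in any usable parameter file
REQUIRED_GLOBALS = ("k_ATP", "k_Anabolism", "k_ACE", "V_cyto")

#: Eq-5 constants that the xylose subsystem cannot run without
REQUIRED_XYLOSE = {
    "XT": ("vmax", "K_XYL", "K_I"),
    "Xyi": ("vmax", "K_XYLIN"),
    "Xyk": ("vmax", "K_XYLU", "K_ATP"),
}


class ParameterError(ValueError):
    """Raised for missing, malformed, or invariant-violating parameters."""


def _e(value: float, provenance: str = "fallback", unit: str = "") -> dict:
    return {"value": float(value), "provenance": provenance, "unit": unit}


def _section(unit: str, **kw: float) -> dict:
    return {k: _e(v, unit=unit) for k, v in kw.items()}


def _rx(vmax: float, **kw: float) -> dict:
    d = {"vmax": _e(vmax, unit="mmol/gDCW/h")}
    d.update({k: _e(v, unit="mM") for k, v in kw.items()})
    return d


def _default_data() -> dict:
    """Build the nested default parameter dictionary."""
    glob = {
        # growth coupling: mu = k_ATP * v_ATP * k_ACE/(k_ACE+[ACE])
        "k_ATP": _e(0.0122, unit="gDCW/mmol"),
        "k_Anabolism": _e(14.849, "supplementary", "mmol/gDCW"),
        "k_ACE": _e(5.0, unit="g/l"),
        # cytoplasmic volume converting specific flux to concentration change
        "V_cyto": _e(2.47e-3, unit="l/gDCW"),
        # PTS phosphorelay quasi-steady state: phosphorylated EIIA fraction
        # = r/(K_EIIA + r) with r = [PEP]/[PYR]
        "EIIA_total": _e(0.04, unit="mM"),
        "K_EIIA": _e(2.0, unit="-"),
        "n_EIIA": _e(2.0, unit="-"),
        # oxidative phosphorylation P/O-type yields
        "PO_NADH": _e(2.0, unit="mol ATP/mol NADH"),
        "PO_FADH": _e(1.0, unit="mol ATP/mol FADH2"),
        # lumped anabolic+maintenance ATP drain: k_ATP_drain*[ATP] plus a
        # saturable maintenance term
        "K_ATP_demand": _e(0.5, unit="mM"),
        "k_ATP_drain": _e(25.0, unit="mmol/gDCW/h/mM"),
        "m_ATP": _e(2.0, unit="mmol/gDCW/h"),
        # precursor-availability saturation of the anabolic drains
        "K_anabolic_sat": _e(0.02, unit="mM"),
        # anabolic NADPH drain saturation
        "K_NADPH_demand": _e(0.02, unit="mM"),
        "NADPH_ref": _e(0.12, unit="mM"),
        # conserved cofactor pool initial partitioning (mM)
        "ATP0": _e(3.0, unit="mM"),
        "ADP0": _e(1.0, unit="mM"),
        "AMP0": _e(0.3, unit="mM"),
        "NAD0": _e(1.8, unit="mM"),
        "NADH0": _e(0.15, unit="mM"),
        "NADP0": _e(0.38, unit="mM"),
        "NADPH0": _e(0.12, unit="mM"),
        # which flux the first NADPH term uses (the printed symbol is
        # ambiguous; the enumerated production sites name G6PDH)
        "nadph_first_site": {"value": "G6PDH", "provenance": "fallback", "unit": ""},
        # molar masses for extracellular unit conversion (g/mol)
        "M_GLC": _e(180.16, unit="g/mol"),
        "M_XYL": _e(150.13, unit="g/mol"),
        "M_ACE": _e(60.05, unit="g/mol"),
        "M_MVA": _e(148.16, unit="g/mol"),
        # batch substrate-depletion threshold
        "depletion_threshold": _e(0.01, unit="g/l"),
    }

    tfs = {
        # cAMP-Crp: Hill in the PEP/PYR ratio (EIIA-P -> adenylate cyclase)
        "Crp": _section("-", K=1.2, n=2.0),
        # Cra: repressed (sequestered) by FBP
        "Cra": _section("mM", K=0.6, n=2.0),
        # XylR: activated by intracellular xylose
        "XylR": _section("mM", K=0.02, n=1.0),
        # ArcA: responds to the NADH/NAD redox ratio; anaerobically floored
        "ArcA": _section("-", K=0.45, n=2.0, anaerobic_floor=0.9),
    }

    reactions = {
        # -- substrate transport ------------------------------------------
        "PTS": _rx(26.0, K_pp=1.0, Ki_G6P=15.0, n_G6P=2.0)
        | {"K_GLC": _e(0.04, unit="g/l")},
        "NPTS": {
            "vmax": _e(5.0, unit="mmol/gDCW/h"),
            "K_GLC": _e(0.03, unit="g/l"),
            "K_ATP": _e(0.4, unit="mM"),
            "Ki_G6P": _e(20.0, unit="mM"),
            "n_G6P": _e(2.0, unit="-"),
        },
        # Eq-5 xylose subsystem (explicit forms)
        "XT": {
            "vmax": _e(22.0, unit="mmol/gDCW/h"),
            "K_XYL": _e(1.0, unit="g/l"),
            "K_I": _e(4.0e-3, unit="mM"),
            "K_ATP": _e(0.1, unit="mM"),
        },
        "Xyi": _rx(20.0, K_XYLIN=1.0),
        "Xyk": _rx(20.0, K_XYLU=0.5, K_ATP=0.3),
        # -- glycolysis / gluconeogenesis ---------------------------------
        "Pgi": _rx(60.0, Keq=0.4, K_G6P=1.0, K_F6P=1.0),
        "Pfk": _rx(16.0, K_F6P=0.3, K_ATP=0.4, Ki_PEP=30.0),
        "Fbp": _rx(1.5, K_FBP=0.5),
        "Fba": _rx(16.0, K_FBP=0.4),
        "L_Emp": _rx(55.0, K_GAP=0.4, K_NAD=0.15, K_ADP=0.25),
        "Pyk": _rx(70.0, K_PEP=3.0, K_ADP=0.25, Ka_FBP=0.3, n_FBP=2.0, basal=0.3),
        "Pps": _rx(1.2, K_PYR=1.0, K_ATP=0.4),
        "PDH": _rx(14.0, K_PYR=0.5, K_NAD=0.15, Ki_NADH=0.4),
        "Pfl": _rx(10.0, K_PYR=0.5),
        # -- pentose phosphate pathway ------------------------------------
        "G6PDH": _rx(7.0, K_G6P=3.0, K_NADP=0.04, Ki_NADPH=0.25, n_NADPH=2.0),
        "PGDH": _rx(11.0, K_6PG=0.3, K_NADP=0.04, Ki_NADPH=0.3),
        "Rpe": _rx(30.0, Keq=1.4, K_RU5P=0.5, K_X5P=0.5),
        "Rpi": _rx(30.0, Keq=1.0, K_RU5P=0.5, K_R5P=0.5),
        "TktA": _rx(18.0, Keq=1.2, K=0.2),
        "Tal": _rx(18.0, Keq=1.05, K=0.2),
        "TktB": _rx(18.0, Keq=8.0, K=0.2),
        # -- TCA cycle and glyoxylate shunt -------------------------------
        "CS": _rx(14.0, K_ACCOA=0.3, K_OAA=0.04),
        "ICDH": _rx(14.0, K_ICIT=0.3, K_NADP=0.04, Ki_NADPH=1.0),
        "aKGDH": _rx(10.0, K_AKG=0.5, K_NAD=0.15, Ki_NADH=0.4, K_ADP=0.25),
        "SFM": _rx(12.0, K_SUC=0.5),
        "Fum": _rx(25.0, Keq=4.4, K_FUM=1.0, K_MAL=1.0),
        "MDH": _rx(25.0, K_MAL=0.5, K_NAD=0.15, Ki_NADH=1.0),
        "Icl": _rx(1.2, K_ICIT=0.6),
        "MS": _rx(1.2, K_GLX=0.2, K_ACCOA=0.3),
        # -- anaplerosis ---------------------------------------------------
        "Ppc": _rx(6.0, K_PEP=0.4, Ka_FBP=0.5, n_FBP=2.0, basal=0.25),
        "Pck": _rx(1.2, K_OAA=0.6, K_ATP=0.4),
        "Mez": _rx(0.8, K_MAL=0.5, K_NADP=0.04),
        # -- fermentative / acetate ---------------------------------------
        "PTACK": _rx(9.0, K_ACCOA=2.0, K_ADP=0.25),
        "Acs": {
            "vmax": _e(1.0, unit="mmol/gDCW/h"),
            "K_ACE": _e(0.2, unit="g/l"),
            "K_ATP": _e(0.4, unit="mM"),
        },
        "LDH": _rx(10.0, K_PYR=1.5, K_NADH=0.3),
        "ADH": _rx(8.0, K_ACCOA=1.0, K_NADH=0.3),
        # -- transhydrogenase and respiration -----------------------------
        "Udh": _rx(2.5, K_NADPH=0.3, K_NAD=0.3),
        "OP": _rx(50.0, K_NADH=0.12, K_ADP=0.25),
        # -- heterologous mevalonate pathway ------------------------------
        "AtoB": _rx(3.0, K_ACCOA=0.15),
        "HMGS": _rx(3.0, K_AACOA=0.1, K_ACCOA=0.15),
        "HMGR": _rx(8.0, K_HMGCOA=0.1, K_NADPH=0.05),
    }

    # transcription-factor regulation map: f = a + b*TF (activation, "+")
    # or a + b*(1-TF) (repression, "-"); one row per (TF, target)
    regulation = [
        {"tf": "Crp", "target": "XT", "sign": "+", "a": 0.02, "b": 0.98},
        {"tf": "XylR", "target": "XT", "sign": "+", "a": 0.15, "b": 0.85},
        {"tf": "Crp", "target": "Xyi", "sign": "+", "a": 0.05, "b": 0.95},
        {"tf": "XylR", "target": "Xyi", "sign": "+", "a": 0.15, "b": 0.85},
        {"tf": "Crp", "target": "Xyk", "sign": "+", "a": 0.05, "b": 0.95},
        {"tf": "XylR", "target": "Xyk", "sign": "+", "a": 0.15, "b": 0.85},
        {"tf": "Crp", "target": "NPTS", "sign": "+", "a": 0.12, "b": 0.88},
        {"tf": "Cra", "target": "Pyk", "sign": "-", "a": 0.5, "b": 0.5},
        {"tf": "Crp", "target": "CS", "sign": "+", "a": 0.5, "b": 0.5},
        {"tf": "ArcA", "target": "CS", "sign": "-", "a": 0.1, "b": 0.9},
        {"tf": "ArcA", "target": "ICDH", "sign": "-", "a": 0.1, "b": 0.9},
        {"tf": "ArcA", "target": "aKGDH", "sign": "-", "a": 0.1, "b": 0.9},
        {"tf": "ArcA", "target": "SFM", "sign": "-", "a": 0.1, "b": 0.9},
        {"tf": "ArcA", "target": "OP", "sign": "-", "a": 0.5, "b": 0.5},
        {"tf": "ArcA", "target": "Pfl", "sign": "+", "a": 0.02, "b": 0.98},
        {"tf": "Cra", "target": "Icl", "sign": "+", "a": 0.1, "b": 0.9},
        {"tf": "Cra", "target": "Fbp", "sign": "+", "a": 0.2, "b": 0.8},
        {"tf": "Cra", "target": "Pps", "sign": "+", "a": 0.2, "b": 0.8},
        {"tf": "Cra", "target": "Pck", "sign": "+", "a": 0.2, "b": 0.8},
        {"tf": "Crp", "target": "Acs", "sign": "+", "a": 0.05, "b": 0.95},
    ]

    # biomass precursor demands (mmol/gDCW), classic E. coli composition
    anabolic = _section(
        "mmol/gDCW",
        G6P=0.205,
        F6P=0.071,
        GAP=0.129,
        PEP=2.015,
        PYR=2.833,
        ACCOA=3.748,
        AKG=1.079,
        OAA=1.787,
        R5P=0.898,
        E4P=0.361,
    )

    return {
        "globals": glob,
        "tfs": tfs,
        "reactions": reactions,
        "regulation": regulation,
        "anabolic": anabolic,
    }


@dataclass
class ParameterSet:
    """All kinetic, regulatory and global constants, with provenance.

    Thin wrapper around a nested dict; values are reached through
    :meth:`g` (globals), :meth:`rx` (per-reaction constants) and
    :meth:`tf` (TF-function constants).
    """

    data: dict

    # -- accessors -----------------------------------------------------
    def g(self, name: str) -> float:
        try:
            return self.data["globals"][name]["value"]
        except KeyError:
            raise ParameterError(f"missing global parameter {name!r}") from None

    def rx(self, reaction: str, name: str) -> float:
        try:
            return self.data["reactions"][reaction][name]["value"]
        except KeyError:
            raise ParameterError(
                f"missing constant {name!r} for reaction {reaction!r}"
            ) from None

    def tf(self, tf: str, name: str) -> float:
        try:
            return self.data["tfs"][tf][name]["value"]
        except KeyError:
            raise ParameterError(
                f"missing TF-function constant {name!r} for TF {tf!r}"
            ) from None

    def vmax(self, reaction: str) -> float:
        return self.rx(reaction, "vmax")

    def anabolic_coeff(self, species: str) -> float:
        return self.data["anabolic"].get(species, {"value": 0.0})["value"]

    @property
    def regulation(self) -> list[dict]:
        return self.data["regulation"]

    @property
    def reactions(self) -> list[str]:
        return list(self.data["reactions"])

    # -- editing -------------------------------------------------------
    def copy(self) -> "ParameterSet":
        return ParameterSet(copy.deepcopy(self.data))

    def set_global(self, name: str, value: float) -> None:
        self.data["globals"].setdefault(name, _e(0.0))["value"] = value

    def set_rx(self, reaction: str, name: str, value: float) -> None:
        self.data["reactions"][reaction].setdefault(name, _e(0.0))["value"] = value

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check structural completeness and the parameter invariants."""
        for name in REQUIRED_GLOBALS:
            if name not in self.data.get("globals", {}):
                raise ParameterError(f"missing required global {name!r}")
        for reaction, names in REQUIRED_XYLOSE.items():
            sec = self.data.get("reactions", {}).get(reaction, {})
            for name in names:
                if name not in sec:
                    raise ParameterError(
                        f"missing xylose-subsystem constant {name!r} "
                        f"for reaction {reaction!r}"
                    )
        for path, entry in self.walk():
            value = entry.get("value")
            prov = entry.get("provenance")
            if prov not in PROVENANCES:
                raise ParameterError(f"{path}: bad provenance {prov!r}")
            if isinstance(value, str):
                continue
            leaf = path.rsplit(".", 1)[-1]
            if leaf.startswith(("K", "vmax", "Ki", "Ka")) and not value > 0:
                raise ParameterError(f"{path}: must be strictly positive, got {value}")
            if leaf.startswith("n") and leaf != "nadph_first_site" and value < 1:
                raise ParameterError(f"{path}: Hill coefficient must be >= 1")
        kan = self.data["globals"]["k_Anabolism"]
        if kan["provenance"] == "supplementary" and abs(kan["value"] - 14.849) > 1e-9:
            raise ParameterError(
                "k_Anabolism flagged 'supplementary' must equal 14.849 mmol/gDCW"
            )
        for edge in self.regulation:
            if edge["sign"] not in ("+", "-"):
                raise ParameterError(f"regulation sign must be '+' or '-': {edge}")
            if edge["target"] not in self.data["reactions"]:
                raise ParameterError(
                    f"regulation target {edge['target']!r} is not a network reaction"
                )

    def walk(self) -> Iterator[tuple[str, dict]]:
        """Yield (dotted path, entry dict) for every parameter entry."""
        for section in ("globals", "anabolic"):
            for name, entry in self.data.get(section, {}).items():
                yield f"{section}.{name}", entry
        for tf, sec in self.data.get("tfs", {}).items():
            for name, entry in sec.items():
                yield f"tfs.{tf}.{name}", entry
        for reaction, sec in self.data.get("reactions", {}).items():
            for name, entry in sec.items():
                yield f"reactions.{reaction}.{name}", entry

    def fallback_entries(self) -> list[str]:
        return [p for p, e in self.walk() if e.get("provenance") == "fallback"]

    def content_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_parameters() -> ParameterSet:
    """The package's calibrated default :class:`ParameterSet`."""
    ps = ParameterSet(_default_data())
    ps.validate()
    return ps
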