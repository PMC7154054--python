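"""Strain presets and genotype-building operators.

Knockouts zero the mapped reaction's capacity (lumped reactions disable the
whole lump), TF overexpression pins a transcription-factor activity, and
the mevalonate extension enables the three-step AtoB/HMGS/HMGR pathway from
acetyl-CoA with HMGR consuming 2 NADPH per mevalonate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from types import MappingProxyType

from .network import GENE_REACTION_MAP, Genotype
from .params import ParameterSet, ParameterError

__all__ = [
    "StrainPreset",
    "STRAIN_PRESETS",
    "MEDIA_PRESETS",
    "get_preset",
    "knockout",
    "overexpress_tf",
    "add_mva_pathway",
]

_MVA_REQUIRED = {
    "AtoB": ("vmax", "K_ACCOA"),
    "HMGS": ("vmax", "K_AACOA", "K_ACCOA"),
    "HMGR": ("vmax", "K_HMGCOA", "K_NADPH"),
}


def knockout(genotype: Genotype, gene: str) -> Genotype:
    """Return a genotype with ``gene`` knocked out (idempotent)."""
    if gene not in GENE_REACTION_MAP:
        raise KeyError(
            f"unknown gene {gene!r}; supported: {sorted(GENE_REACTION_MAP)}"
        )
    return replace(genotype, knockouts=genotype.knockouts | {gene})


def overexpress_tf(genotype: Genotype, tf: str, level: float) -> Genotype:
    """Pin a transcription factor's activity to ``level`` in [0, 1]."""
    if not (0.0 <= level <= 1.0):
        raise ValueError(f"TF activity must lie in [0, 1], got {level}")
    overrides = dict(genotype.tf_overrides)
    overrides[tf] = float(level)
    return replace(genotype, tf_overrides=overrides)


def add_mva_pathway(genotype: Genotype, params: ParameterSet) -> Genotype:
    """Enable the heterologous mevalonate pathway (AtoB, HMGS, HMGR).

    Requires the three reactions' kinetic constants to be present in the
    parameter set; raises :class:`ParameterError` naming anything missing.
    """
    missing = [
        f"{rxn}.{name}"
        for rxn, names in _MVA_REQUIRED.items()
        for name in names
        if name not in params.data.get("reactions", {}).get(rxn, {})
    ]
    if missing:
        raise ParameterError(f"missing MVA-pathway constants: {missing}")
    return replace(genotype, mva_pathway=True)


@dataclass(frozen=True)
class StrainPreset:
    """A named strain with an immutable genotype."""

    name: str
    genotype: Genotype
    notes: str = ""


def _build_presets() -> MappingProxyType:
    wt = Genotype()
    dpgi = Genotype(knockouts=frozenset({"pgi"}))
    presets = {
        "WT": StrainPreset("WT", wt, "wild type"),
        "dpgi": StrainPreset("dpgi", dpgi, "pgi knockout: OPP-forced NADPH overproducer"),
        "dptsG": StrainPreset(
            "dptsG", Genotype(knockouts=frozenset({"ptsG"})),
            "ptsG knockout: relaxed carbon catabolite repression",
        ),
        "dpfl": StrainPreset("dpfl", Genotype(knockouts=frozenset({"pfl"})),
                             "pyruvate formate-lyase knockout"),
        "dack": StrainPreset("dack", Genotype(knockouts=frozenset({"ackA"})),
                             "acetate kinase knockout (disables the PTACK lump)"),
        "MVA_WT": StrainPreset(
            "MVA_WT", Genotype(mva_pathway=True),
            "wild type + E. faecalis mevalonate pathway",
        ),
        "MVA_dpgi": StrainPreset(
            "MVA_dpgi", Genotype(knockouts=frozenset({"pgi"}), mva_pathway=True),
            "pgi knockout + mevalonate pathway",
        ),
        "MVA_dpgi_arcA": StrainPreset(
            "MVA_dpgi_arcA",
            Genotype(knockouts=frozenset({"pgi"}), tf_overrides={"ArcA": 0.95},
                     mva_pathway=True),
            "pgi knockout + mevalonate pathway + ArcA overexpression "
            "(activity pinned to 0.95 to repress the TCA cycle)",
        ),
    }
    return MappingProxyType(presets)


STRAIN_PRESETS = _build_presets()

#: media/cultivation presets mirroring the studied conditions
MEDIA_PRESETS = MappingProxyType({
    "glc4": {"glucose": 4.0, "xylose": 0.0, "unit": "g/l", "aerobic": True},
    "glc5xyl5": {"glucose": 5.0, "xylose": 5.0, "unit": "g/l", "aerobic": True},
    "glc3xyl3": {"glucose": 3.0, "xylose": 3.0, "unit": "g/l", "aerobic": True},
    "glc40mM_xyl40mM": {"glucose": 40.0, "xylose": 40.0, "unit": "mM", "aerobic": True},
    "glc10xyl10_ace1_anaerobic": {
        "glucose": 10.0, "xylose": 10.0, "acetate": 1.0, "unit": "g/l",
        "aerobic": False,
    },
    "chemostat_glc4": {
        "mode": "chemostat", "glucose": 1.0, "xylose": 0.0, "unit": "g/l",
        "aerobic": True, "feed": {"GLC": 4.0}, "dilution_rate": 0.2,
    },
})


def get_preset(name: str) -> StrainPreset:
    try:
        return STRAIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown strain preset {name!r}; available: {sorted(STRAIN_PRESETS)}"
        ) from None
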