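"""Built-in model variants of the exocytosis reaction network.

The fusion machinery is modeled in blocks that compose freely:

* fundamental subsystem — SNAP25 + syntaxin <-> tSNARE, tSNARE + VAMP2 <-> FHC.
  Formation of the four-helical core complex (FHC) is the fusion readout.
* complexin clamp — FHC + complexin <-> FC; the clamped complex FC is terminal.
* Ca2+/synaptotagmin — four sequential single-ion binding steps up to Ca4S,
  which activates either free tSNARE (-> Tsc) or assembled FHC (-> FHC*);
  Tsc + VAMP2 -> FHC* closes the triangle.  Ca2+ itself can be clamped at a
  constant level or driven by a recruitment source (rectangular pulse).
* MUNC18 — binds FHC to form the fusion-competent FHC**, and irreversibly
  sequesters closed-conformation syntaxin as Smc.

The fusion readout species set is {FHC, FHC*, FHC**}.  Default initial
concentrations follow the physiological presets: vesicle/VAMP2 0.2-30 µM,
SNAP25/syntaxin 0.1-100 µM, MUNC18 1-30 µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .network import NetworkError, Reaction, ReactionNetwork, Species

__all__ = [
    "ModelVariant",
    "FUSION_READOUT",
    "fundamental_subsystem",
    "full_system",
    "with_self_association",
    "munc18_subsystem",
    "rectangular_pulse",
]

#: species whose summed concentration is the fusion readout
FUSION_READOUT = ("FHC", "FHC*", "FHC**")

#: physiological concentration ranges (µM) for preset validation
PHYSIOLOGICAL_RANGES = {
    "VAMP2": (0.2, 30.0),
    "SNAP25": (0.1, 100.0),
    "syntaxin": (0.1, 100.0),
    "MUNC18": (1.0, 30.0),
}


@dataclass
class ModelVariant:
    """A named reaction network with default initials, rates and options."""

    name: str
    network: ReactionNetwork
    options: dict = field(default_factory=dict)

    @property
    def default_initials(self) -> dict[str, float]:
        return {s.name: s.initial_concentration for s in self.network.species}

    @property
    def default_rates(self) -> dict[str, float]:
        return dict(
            zip(self.network.rate_names, self.network.default_rates())
        )

    def readout_indices(self) -> list[int]:
        return [
            self.network.index[s]
            for s in FUSION_READOUT
            if s in self.network.index
        ]

    def fusion_readout(self, states: np.ndarray) -> np.ndarray:
        """Sum of core-complex concentrations for a state or trajectory."""
        idx = self.readout_indices()
        if not idx:
            raise NetworkError(f"variant {self.name!r} has no fusion readout species")
        return np.asarray(states)[..., idx].sum(axis=-1)


def rectangular_pulse(
    amplitude: float = 10.0, onset: float = 0.0, duration: float = 1.0
) -> Callable[[float], float]:
    """Rectangular Ca2+ recruitment source s(t), µM/s."""

    def source(t: float) -> float:
        return amplitude if onset <= t < onset + duration else 0.0

    return source


def _fundamental_parts(
    initials: Mapping[str, float],
) -> tuple[list[Species], list[Reaction]]:
    species = [
        Species("SNAP25", initials.get("SNAP25", 1.5), "protein"),
        Species("syntaxin", initials.get("syntaxin", 2.0), "protein"),
        Species("VAMP2", initials.get("VAMP2", 1.0), "protein"),
        Species("tSNARE", initials.get("tSNARE", 0.0), "complex"),
        Species("FHC", initials.get("FHC", 0.0), "complex"),
    ]
    reactions = [
        Reaction(
            {"SNAP25": 1, "syntaxin": 1}, {"tSNARE": 1},
            k_forward=0.7, k_reverse=0.1, label="tsnare_assembly",
        ),
        Reaction(
            {"tSNARE": 1, "VAMP2": 1}, {"FHC": 1},
            k_forward=0.4, k_reverse=0.05, label="fhc_assembly",
        ),
    ]
    return species, reactions


def fundamental_subsystem(
    initials: Mapping[str, float] | None = None,
) -> ModelVariant:
    """The two-reaction core of SNARE assembly (5 species, 2 reactions)."""
    species, reactions = _fundamental_parts(initials or {})
    return ModelVariant(
        "fundamental",
        ReactionNetwork(species, reactions),
        options={"complexin": False, "ca_mode": "off", "munc18": False},
    )


def full_system(
    complexin: bool = False,
    ca_mode: str = "off",
    munc18: bool = False,
    self_association: bool = False,
    n_max: int = 5,
    ca_coop: float = 1.0,
    ca_pulse: tuple[float, float, float] = (10.0, 0.0, 1.0),
    initials: Mapping[str, float] | None = None,
) -> ModelVariant:
    """The regulated system: fundamental core plus optional blocks.

    Parameters
    ----------
    complexin : add the FHC + complexin <-> FC clamp.
    ca_mode : "off", "clamped" (constant [Ca]) or "dynamic" (Ca balance with
        a rectangular recruitment source ``ca_pulse``).
    munc18 : add MUNC18 + FHC <-> FHC** and the irreversible
        MUNC18 + syntaxin -> Smc sequestration.
    self_association : add syntaxin oligomers up to ``n_max``.
    ca_coop : factor multiplying successive Ca-binding forward rates
        (1.0 = shared rates, the minimal sequential-binding scheme).
    """
    if ca_mode not in ("off", "clamped", "dynamic"):
        raise NetworkError(f"unknown ca_mode {ca_mode!r}")
    init = dict(initials or {})
    species, reactions = _fundamental_parts(
        {**{"SNAP25": 5.0, "syntaxin": 5.0, "VAMP2": 2.0}, **init}
    )
    clamped: list[str] = []
    inflows: dict[str, Callable[[float], float]] = {}

    if complexin:
        species += [
            Species("complexin", init.get("complexin", 2.0), "protein"),
            Species("FC", init.get("FC", 0.0), "complex"),
        ]
        reactions.append(
            Reaction(
                {"FHC": 1, "complexin": 1}, {"FC": 1},
                k_forward=0.5, k_reverse=0.1, label="complexin_clamp",
            )
        )

    if ca_mode != "off":
        species += [
            Species("Ca", init.get("Ca", 10.0), "ion"),
            Species("Syt", init.get("Syt", 2.0), "protein"),
            Species("CaS", init.get("CaS", 0.0), "complex"),
            Species("Ca2S", init.get("Ca2S", 0.0), "complex"),
            Species("Ca3S", init.get("Ca3S", 0.0), "complex"),
            Species("Ca4S", init.get("Ca4S", 0.0), "complex"),
            Species("Tsc", init.get("Tsc", 0.0), "complex"),
            Species("FHC*", init.get("FHC*", 0.0), "complex"),
        ]
        chain = ["Syt", "CaS", "Ca2S", "Ca3S", "Ca4S"]
        for i in range(4):
            reactions.append(
                Reaction(
                    {"Ca": 1, chain[i]: 1}, {chain[i + 1]: 1},
                    k_forward=1.0 * ca_coop**i, k_reverse=1.0,
                    label=f"ca_binding_{i + 1}",
                )
            )
        reactions += [
            Reaction(
                {"Ca4S": 1, "tSNARE": 1}, {"Tsc": 1},
                k_forward=0.5, k_reverse=0.1, label="tsc_formation",
            ),
            Reaction(
                {"Ca4S": 1, "FHC": 1}, {"FHC*": 1},
                k_forward=0.5, k_reverse=0.1, label="fhc_activation",
            ),
            Reaction(
                {"Tsc": 1, "VAMP2": 1}, {"FHC*": 1},
                k_forward=0.4, k_reverse=0.05, label="tsc_fusion",
            ),
        ]
        if ca_mode == "clamped":
            clamped.append("Ca")
        else:
            inflows["Ca"] = rectangular_pulse(*ca_pulse)

    if munc18:
        species += [
            Species("MUNC18", init.get("MUNC18", 3.0), "protein"),
            Species("Smc", init.get("Smc", 0.0), "complex"),
            Species("FHC**", init.get("FHC**", 0.0), "complex"),
        ]
        reactions += [
            Reaction(
                {"MUNC18": 1, "FHC": 1}, {"FHC**": 1},
                k_forward=0.5, k_reverse=0.05, label="munc18_fhc",
            ),
            Reaction(
                {"MUNC18": 1, "syntaxin": 1}, {"Smc": 1},
                k_forward=0.5, k_reverse=None, label="munc18_sequestration",
            ),
        ]

    variant = ModelVariant(
        "full",
        ReactionNetwork(species, reactions, clamped=clamped, inflows=inflows),
        options={
            "complexin": complexin,
            "ca_mode": ca_mode,
            "munc18": munc18,
            "self_association": self_association,
        },
    )
    if self_association:
        variant = with_self_association(variant, n_max=n_max)
        variant.name = "full"
    if not (complexin or munc18 or self_association) and ca_mode == "off":
        variant.name = "fundamental"
    return variant


def with_self_association(variant: ModelVariant, n_max: int = 5) -> ModelVariant:
    """Add syntaxin oligomers syntaxin2..syntaxin{n_max} with stepwise
    association syntaxin_n + syntaxin <-> syntaxin_{n+1}.

    The default n_max=5 adds exactly four oligomer species (and equations).
    """
    if n_max < 2:
        raise NetworkError("n_max must be >= 2")
    net = variant.network
    if "syntaxin" not in net.index:
        raise NetworkError("variant has no syntaxin species")
    species = list(net.species)
    reactions = list(net.reactions)
    for n in range(2, n_max + 1):
        species.append(Species(f"syntaxin{n}", 0.0, "complex"))
        prev = "syntaxin" if n == 2 else f"syntaxin{n - 1}"
        reactants = {"syntaxin": 2} if n == 2 else {prev: 1, "syntaxin": 1}
        reactions.append(
            Reaction(
                reactants, {f"syntaxin{n}": 1},
                k_forward=0.1, k_reverse=0.1, label=f"syntaxin_oligomer_{n}",
            )
        )
    return ModelVariant(
        f"{variant.name}+self_association",
        ReactionNetwork(
            species, reactions, clamped=net.clamped, inflows=net.inflows
        ),
        options={**variant.options, "self_association": True, "n_max": n_max},
    )


def munc18_subsystem(
    initials: Mapping[str, float] | None = None,
) -> ModelVariant:
    """Reduced MUNC18 subsystem with tSNARE preformed.

    Species {tSNARE, VAMP2, FHC, MUNC18, Smc, FHC**}; in this reduction the
    preformed tSNARE pool carries the closed-conformation syntaxin that
    MUNC18 sequesters, so the Smc-forming step reads
    MUNC18 + tSNARE -> Smc (no reverse rate: dissociation is negligible
    compared to binding).  The MUNC18 moiety MUNC18 + Smc + FHC** is
    conserved, which reduces the dynamics to five independent variables.
    """
    init = dict(initials or {})
    species = [
        Species("tSNARE", init.get("tSNARE", 20.0), "complex"),
        Species("VAMP2", init.get("VAMP2", 8.0), "protein"),
        Species("FHC", init.get("FHC", 0.0), "complex"),
        Species("MUNC18", init.get("MUNC18", 16.0), "protein"),
        Species("Smc", init.get("Smc", 0.0), "complex"),
        Species("FHC**", init.get("FHC**", 0.0), "complex"),
    ]
    reactions = [
        Reaction(
            {"tSNARE": 1, "VAMP2": 1}, {"FHC": 1},
            k_forward=0.5, k_reverse=0.0, label="fhc_assembly",
        ),
        Reaction(
            {"MUNC18": 1, "FHC": 1}, {"FHC**": 1},
            k_forward=0.5, k_reverse=0.0, label="munc18_fhc",
        ),
        Reaction(
            {"MUNC18": 1, "tSNARE": 1}, {"Smc": 1},
            k_forward=0.5, k_reverse=None, label="munc18_sequestration",
        ),
    ]
    return ModelVariant(
        "munc18_subsystem",
        ReactionNetwork(species, reactions),
        options={"munc18": True},
    )
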