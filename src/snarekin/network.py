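"""Generic mass-action reaction networks.

A :class:`ReactionNetwork` is an ordered list of species together with
(reversible) mass-action reactions.  The net stoichiometry matrix ``N``
(n_species x n_reactions) determines the dynamics

    dx/dt = N @ v(x),    v_j = k_f,j * prod_r x_r^a_rj  -  k_r,j * prod_p x_p^b_pj,

where ``a``/``b`` are reactant/product stoichiometries.  Conserved moieties
are the left null vectors of ``N``; they are computed exactly over the
rationals and returned in a canonical reduced integer form.

Species may be *clamped* (held constant, e.g. buffered Ca2+) or carry a
time-dependent zeroth-order inflow (e.g. a Ca2+ recruitment source).  Both
break the conservation laws that involve them, so such species are excluded
from the conserved-moiety computation.

Units are µM and seconds throughout; a rate constant for a reaction of
molecularity m carries units µM^(1-m) s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "Species",
    "Reaction",
    "ConservationLaw",
    "ReactionNetwork",
    "build_network",
    "mass_action_rhs",
    "conservation_laws",
    "jacobian",
    "parse_reaction",
    "format_reaction",
]


class NetworkError(ValueError):
    """Raised for ill-formed network definitions."""


@dataclass(frozen=True)
class Species:
    """A chemical species (protein, complex or ion)."""

    name: str
    initial_concentration: float = 0.0  # µM
    role: str = "protein"  # protein | complex | ion

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise NetworkError("species name must be a non-empty string")
        if self.initial_concentration < 0:
            raise NetworkError(
                f"initial concentration of {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )
        if self.role not in ("protein", "complex", "ion"):
            raise NetworkError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A reversible (or irreversible) elementary mass-action reaction.

    ``k_reverse=None`` marks an irreversible reaction.  Stoichiometries are
    positive integers keyed by species name.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    k_forward: float
    k_reverse: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise NetworkError(
                f"reaction {self.label!r} needs at least one reactant and one product"
            )
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if int(coeff) != coeff or coeff <= 0:
                    raise NetworkError(
                        f"stoichiometric coefficient of {name!r} in {self.label!r} "
                        f"must be a positive integer, got {coeff}"
                    )
        if self.k_forward < 0:
            raise NetworkError(f"k_forward of {self.label!r} must be >= 0")
        if self.k_reverse is not None and self.k_reverse < 0:
            raise NetworkError(f"k_reverse of {self.label!r} must be >= 0")

    @property
    def reversible(self) -> bool:
        return self.k_reverse is not None


@dataclass(frozen=True)
class ConservationLaw:
    """An exactly conserved linear combination of concentrations (a moiety).

    ``coefficients`` are primitive integers over the network's species order;
    ``total`` is the value implied by the initial concentrations.
    """

    coefficients: tuple[int, ...]
    species: tuple[str, ...]
    total: float

    def evaluate(self, state: np.ndarray) -> np.ndarray:
        """Value of the conserved combination for one state or a trajectory."""
        c = np.asarray(self.coefficients, dtype=float)
        return np.asarray(state) @ c

    def __str__(self) -> str:
        terms = [
            (f"{c}*" if c != 1 else "") + s
            for c, s in zip(self.coefficients, self.species)
            if c != 0
        ]
        return " + ".join(terms) + f" = {self.total:g}"


class ReactionNetwork:
    """Validated species + reactions with a populated stoichiometry matrix."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        clamped: Sequence[str] = (),
        inflows: Mapping[str, Callable[[float], float]] | None = None,
    ):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise NetworkError(f"duplicate species names: {sorted(dupes)}")
        self.species: tuple[Species, ...] = tuple(species)
        self.species_names: tuple[str, ...] = tuple(names)
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for rxn in reactions:
            for name in set(rxn.reactants) | set(rxn.products):
                if name not in self.index:
                    raise NetworkError(
                        f"reaction {rxn.label!r} references unknown species {name!r}"
                    )
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        for name in clamped:
            if name not in self.index:
                raise NetworkError(f"clamped species {name!r} not in network")
        self.clamped: frozenset[str] = frozenset(clamped)
        self.inflows: dict[str, Callable[[float], float]] = dict(inflows or {})
        for name in self.inflows:
            if name not in self.index:
                raise NetworkError(f"inflow species {name!r} not in network")

        n, m = len(self.species), len(self.reactions)
        # reactant / product stoichiometry matrices and the net matrix
        self._A = np.zeros((n, m), dtype=int)
        self._B = np.zeros((n, m), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.reactants.items():
                self._A[self.index[name], j] = int(coeff)
            for name, coeff in rxn.products.items():
                self._B[self.index[name], j] = int(coeff)
        self.stoichiometry: np.ndarray = self._B - self._A

        # ordered rate slots: k{i}f and, for reversible reactions, k{i}r
        slots: list[tuple[str, int, bool]] = []  # (name, reaction index, is_forward)
        for j, rxn in enumerate(self.reactions, start=1):
            slots.append((f"k{j}f", j - 1, True))
            if rxn.reversible:
                slots.append((f"k{j}r", j - 1, False))
        self.rate_names: tuple[str, ...] = tuple(s[0] for s in slots)
        self._slots = slots
        self._laws: list[ConservationLaw] | None = None

    # -- parameters ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_rates(self) -> int:
        return len(self.rate_names)

    def default_rates(self) -> np.ndarray:
        """Rate vector assembled from the reactions' own constants."""
        vals = []
        for name, j, fwd in self._slots:
            rxn = self.reactions[j]
            vals.append(rxn.k_forward if fwd else rxn.k_reverse)
        return np.array(vals, dtype=float)

    def rates_from_mapping(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Rate vector from a {slot name: value} mapping (missing -> default)."""
        base = self.default_rates()
        for key, val in mapping.items():
            if key not in self.rate_names:
                raise NetworkError(f"unknown rate name {key!r}")
            base[self.rate_names.index(key)] = float(val)
        return base

    def _split_rates(self, params: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """(kf, kr) per reaction; kr = 0 for irreversible reactions."""
        if params is None:
            params = self.default_rates()
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_rates,):
            raise NetworkError(
                f"expected {self.n_rates} rate values, got shape {params.shape}"
            )
        kf = np.zeros(self.n_reactions)
        kr = np.zeros(self.n_reactions)
        for val, (name, j, fwd) in zip(params, self._slots):
            if fwd:
                kf[j] = val
            else:
                kr[j] = val
        return kf, kr

    def initial_state(
        self, overrides: Mapping[str, float] | None = None
    ) -> np.ndarray:
        x0 = np.array([s.initial_concentration for s in self.species], dtype=float)
        for name, val in (overrides or {}).items():
            if name not in self.index:
                raise NetworkError(f"unknown species {name!r} in initial overrides")
            if val < 0:
                raise NetworkError(f"initial concentration of {name!r} must be >= 0")
            x0[self.index[name]] = float(val)
        return x0

    # -- dynamics -----------------------------------------------------------

    def fluxes(self, state: np.ndarray, params: np.ndarray | None = None) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise NetworkError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        kf, kr = self._split_rates(params)
        # prod x^A per reaction; 0**0 == 1 handles absent species
        fwd = np.prod(state[:, None] ** self._A, axis=0)
        rev = np.prod(state[:, None] ** self._B, axis=0)
        return kf * fwd - kr * rev

    def rhs(
        self, state: np.ndarray, params: np.ndarray | None = None, t: float = 0.0
    ) -> np.ndarray:
        """Time derivative dx/dt (µM/s) at ``state``."""
        dx = self.stoichiometry @ self.fluxes(state, params)
        for name, source in self.inflows.items():
            dx[self.index[name]] += source(t)
        for name in self.clamped:
            dx[self.index[name]] = 0.0
        return dx

    def jacobian(
        self, state: np.ndarray, params: np.ndarray | None = None
    ) -> np.ndarray:
        """Analytic Jacobian d(rhs)/d(state), clamping respected."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise NetworkError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        kf, kr = self._split_rates(params)
        n, m = self.n_species, self.n_reactions
        dv = np.zeros((m, n))
        for j in range(m):
            for s in np.nonzero(self._A[:, j])[0]:
                a = self._A[:, j].astype(float).copy()
                a[s] -= 1.0
                dv[j, s] += kf[j] * self._A[s, j] * np.prod(state**a)
            for s in np.nonzero(self._B[:, j])[0]:
                b = self._B[:, j].astype(float).copy()
                b[s] -= 1.0
                dv[j, s] -= kr[j] * self._B[s, j] * np.prod(state**b)
        J = self.stoichiometry @ dv
        for name in self.clamped:
            J[self.index[name], :] = 0.0
        return J

    # -- conservation -------------------------------------------------------

    def conservation_laws(self) -> list[ConservationLaw]:
        """Basis of conserved moieties, canonical reduced integer form.

        Clamped species and species with inflows cannot take part in a
        conserved combination; the basis is the left null space of the
        stoichiometry matrix restricted to the remaining species, computed
        exactly over the rationals and canonicalized by row reduction.
        """
        if self._laws is not None:
            return self._laws
        excluded = self.clamped | set(self.inflows)
        keep = [i for i, n in enumerate(self.species_names) if n not in excluded]
        sub = sympy.Matrix(self.stoichiometry[keep, :])
        null = sub.T.nullspace()
        laws: list[ConservationLaw] = []
        if null:
            basis = sympy.Matrix.hstack(*null).T  # rows are null vectors
            basis = basis.rref()[0]
            x0 = self.initial_state()
            for r in range(basis.rows):
                row = basis.row(r)
                if all(v == 0 for v in row):
                    continue
                denom = sympy.lcm([sympy.fraction(sympy.Rational(v))[1] for v in row])
                ints = [int(v * denom) for v in row]
                g = int(sympy.gcd(ints))
                ints = [v // g for v in ints]
                lead = next(v for v in ints if v != 0)
                if lead < 0:
                    ints = [-v for v in ints]
                full = [0] * self.n_species
                for i, v in zip(keep, ints):
                    full[i] = v
                total = float(np.dot(full, x0))
                laws.append(
                    ConservationLaw(tuple(full), self.species_names, total)
                )
        self._laws = laws
        return laws

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "name": s.name,
                    "initial_concentration": s.initial_concentration,
                    "role": s.role,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "equation": format_reaction(r),
                    "k_forward": r.k_forward,
                    **({"k_reverse": r.k_reverse} if r.reversible else {}),
                    "label": r.label,
                }
                for r in self.reactions
            ],
            "clamped": sorted(self.clamped),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReactionNetwork":
        species = [Species(**s) for s in data["species"]]
        reactions = []
        for r in data["reactions"]:
            reactants, products, reversible = parse_reaction(r["equation"])
            k_rev = r.get("k_reverse")
            if reversible and k_rev is None:
                raise NetworkError(
                    f"reversible reaction {r['equation']!r} needs k_reverse"
                )
            if not reversible and k_rev is not None:
                raise NetworkError(
                    f"irreversible reaction {r['equation']!r} cannot have k_reverse"
                )
            reactions.append(
                Reaction(
                    reactants,
                    products,
                    float(r["k_forward"]),
                    None if k_rev is None else float(k_rev),
                    r.get("label", ""),
                )
            )
        return cls(species, reactions, clamped=data.get("clamped", ()))

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, "
            f"{self.n_reactions} reactions)"
        )


# -- reaction-string parsing ------------------------------------------------


def parse_reaction(text: str) -> tuple[dict[str, int], dict[str, int], bool]:
    """Parse ``"A + 2 B <-> C"`` into (reactants, products, reversible)."""
    if "<->" in text:
        lhs, rhs = text.split("<->")
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->")
        reversible = False
    else:
        raise NetworkError(f"reaction string {text!r} has no '->' or '<->'")

    def side(s: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for term in s.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in reaction {text!r}")
            parts = term.split()
            if len(parts) == 2 and parts[0].isdigit():
                coeff, name = int(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, name = 1, parts[0]
            else:
                raise NetworkError(f"cannot parse term {term!r} in {text!r}")
            out[name] = out.get(name, 0) + coeff
        return out

    return side(lhs), side(rhs), reversible


def format_reaction(rxn: Reaction) -> str:
    def side(d: Mapping[str, int]) -> str:
        return " + ".join(
            (f"{c} " if c != 1 else "") + n for n, c in d.items()
        )

    arrow = "<->" if rxn.reversible else "->"
    return f"{side(rxn.reactants)} {arrow} {side(rxn.products)}"


# -- module-level functional surface ---------------------------------------


def build_network(
    species_defs: Sequence[Species | Mapping],
    reaction_defs: Sequence[Reaction | Mapping],
    clamped: Sequence[str] = (),
    inflows: Mapping[str, Callable[[float], float]] | None = None,
) -> ReactionNetwork:
    """Build and validate a :class:`ReactionNetwork`.

    Species may be given as :class:`Species` or mappings; reactions as
    :class:`Reaction` or mappings with an ``equation`` string.
    """
    species = [s if isinstance(s, Species) else Species(**s) for s in species_defs]
    reactions = []
    for r in reaction_defs:
        if isinstance(r, Reaction):
            reactions.append(r)
        else:
            r = dict(r)
            if "equation" in r:
                reactants, products, reversible = parse_reaction(r.pop("equation"))
                k_rev = r.pop("k_reverse", None)
                if reversible and k_rev is None:
                    raise NetworkError("reversible reaction needs k_reverse")
                reactions.append(
                    Reaction(reactants, products, k_reverse=k_rev, **r)
                )
            else:
                reactions.append(Reaction(**r))
    return ReactionNetwork(species, reactions, clamped=clamped, inflows=inflows)


def mass_action_rhs(
    network: ReactionNetwork,
    state: np.ndarray,
    params: np.ndarray | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """dx/dt = N @ v(x) with mass-action fluxes (µM/s)."""
    return network.rhs(state, params, t)


def conservation_laws(network: ReactionNetwork) -> list[ConservationLaw]:
    return network.conservation_laws()


def jacobian(
    network: ReactionNetwork, state: np.ndarray, params: np.ndarray | None = None
) -> np.ndarray:
    return network.jacobian(state, params)
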