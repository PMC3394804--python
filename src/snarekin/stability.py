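"""Steady states, local stability and MUNC18 bistability.

Steady states of the fundamental SNARE subsystem are obtained from the
case analysis of the near-irreversible regime (dissociation rates small
against association rates).  The closed forms of that limit — terminal
fusion equal to the least available moiety — seed an exact root solve of
the steady-state algebraic system (vanishing fluxes + moiety totals), so
every returned state satisfies the substitution residual at the actual
rate constants, not just at leading order.

Stability is classified from the Jacobian restricted to the stoichiometric
compatibility class: directions along conservation laws always carry zero
eigenvalues and are excluded before reading off signs.

MUNC18 turns the terminal fusion level bistable at intermediate initial
MUNC18: steady states are enumerated by basin sampling over admissible
partitions of the conserved moieties and labeled by the depletion
signatures of the two branches (high fusion: free MUNC18 and free VAMP2
essentially zero; low fusion: free MUNC18 and free tSNARE essentially
zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import orth
from scipy.optimize import root

from .models import ModelVariant, fundamental_subsystem, munc18_subsystem
from .network import NetworkError
from .simulate import (
    SimulationConfig,
    SimulationError,
    steady_state_by_integration,
)

__all__ = [
    "SteadyState",
    "FusionPrediction",
    "BistabilityScan",
    "analytic_steady_states",
    "numeric_steady_states",
    "classify_steady_state",
    "fusion_level_predictor",
    "munc18_steady_states",
    "bistability_scan",
]

#: free-species depletion threshold relative to the moiety total
DEPLETION_FRACTION = 1e-3
#: pairwise sup-distance below which steady states are merged (µM)
MERGE_TOL = 1e-5


@dataclass
class SteadyState:
    """A stationary concentration vector with optional classification."""

    state: np.ndarray
    species: tuple[str, ...]
    residual: float
    source: str  # analytic-case-A|B|C | numeric | munc18-analytic
    eigenvalues: np.ndarray | None = None
    classification: str | None = None  # stable-node | stable | saddle | non-hyperbolic
    label: str | None = None  # high-fusion | low-fusion for MUNC18 states

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.species.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(v) for s, v in zip(self.species, self.state)}


@dataclass(frozen=True)
class FusionPrediction:
    """Closed-form terminal fusion level in the near-irreversible regime."""

    predicted_fhc_infinity: float
    regime: str  # no-preformed | preformed
    initials: dict

@dataclass
class BistabilityScan:
    m0_grid: np.ndarray
    n_stable_states: np.ndarray
    state_signatures: list[tuple[str, ...]]
    window: tuple[float, float] | None


# -- classification ---------------------------------------------------------


def classify_steady_state(
    variant: ModelVariant,
    params: np.ndarray | Mapping[str, float] | None,
    state: np.ndarray | SteadyState,
    steady_tol: float = 1e-6,
    zero_tol: float = 1e-9,
    source: str = "numeric",
) -> SteadyState:
    """Eigenvalue classification on the stoichiometric compatibility class.

    Raises if the state is not stationary within ``steady_tol``.
    """
    net = variant.network
    if isinstance(params, Mapping):
        params = net.rates_from_mapping(params)
    if isinstance(state, SteadyState):
        x = np.asarray(state.state, dtype=float)
        source = state.source
        label = state.label
    else:
        x = np.asarray(state, dtype=float)
        label = None
    resid = float(np.max(np.abs(net.rhs(x, params))))
    if resid > steady_tol:
        raise SimulationError(
            f"state is not stationary: ||rhs|| = {resid:g} > {steady_tol:g}"
        )
    S = net.stoichiometry.astype(float).copy()
    for name in net.clamped:
        S[net.index[name], :] = 0.0
    Q = orth(S)
    J = net.jacobian(x, params)
    Jr = Q.T @ J @ Q
    eigs = np.linalg.eigvals(Jr)
    re = eigs.real
    scale = max(1.0, float(np.max(np.abs(eigs))) if eigs.size else 1.0)
    tol = zero_tol * scale
    if np.any(re > tol):
        cls = "saddle"
    elif np.any(np.abs(re) <= tol):
        cls = "non-hyperbolic"
    elif np.allclose(eigs.imag, 0.0, atol=tol):
        cls = "stable-node"
    else:
        cls = "stable"
    return SteadyState(
        state=x,
        species=net.species_names,
        residual=resid,
        source=source,
        eigenvalues=eigs,
        classification=cls,
        label=label,
    )


# -- analytic cases for the fundamental subsystem ---------------------------


def _totals(init: Mapping[str, float]) -> tuple[float, float, float]:
    s0 = init.get("SNAP25", 0.0)
    x0 = init.get("syntaxin", 0.0)
    v0 = init.get("VAMP2", 0.0)
    t0 = init.get("tSNARE", 0.0)
    f0 = init.get("FHC", 0.0)
    return s0 + t0 + f0, x0 + t0 + f0, v0 + f0


def _vertex_candidates(
    stot: float, xtot: float, vtot: float
) -> list[np.ndarray]:
    """Irreversible-limit steady states: one of {SNAP25, syntaxin} and one of
    {tSNARE, VAMP2} exhausted; nonnegative solutions only.

    State order (SNAP25, syntaxin, VAMP2, tSNARE, FHC).
    """
    out = []
    for limiting, ltot, otot in (("S", stot, xtot), ("X", xtot, stot)):
        # limiting free protein -> 0; other free protein = otot - ltot
        if otot < ltot:
            continue
        # (a) VAMP2 exhausted: F = vtot, T = ltot - vtot
        if ltot >= vtot:
            t, f = ltot - vtot, vtot
            st = (0.0, otot - ltot, 0.0, t, f)
            out.append(np.array(st if limiting == "S" else (st[1], st[0]) + st[2:]))
        # (b) tSNARE exhausted: F = ltot, V = vtot - ltot
        if vtot >= ltot:
            t, f = 0.0, ltot
            st = (0.0, otot - ltot, vtot - ltot, t, f)
            out.append(np.array(st if limiting == "S" else (st[1], st[0]) + st[2:]))
    # deduplicate exact coincidences (e.g. stot == xtot)
    uniq: list[np.ndarray] = []
    for c in out:
        if not any(np.allclose(c, u, atol=1e-12) for u in uniq):
            uniq.append(c)
    return uniq


def _corrected_seed(
    seed_state: np.ndarray, params: np.ndarray
) -> np.ndarray:
    """Add the leading-order reverse-rate corrections to a vertex state.

    The irreversible-limit vertices have exact zeros; the true root sits
    O(k_r/k_f) away, where Newton converges quadratically from the
    corrected point.
    """
    k1f, k1r, k2f, k2r = params[:4]
    s, x, v, t, f = seed_state
    tiny = 1e-30
    if t <= 0.0 and v > 0.0:  # tSNARE-exhausted branch
        t = k2r * f / max(k2f * v, tiny)
    elif v <= 0.0 and t > 0.0:  # VAMP2-exhausted branch
        v = k2r * f / max(k2f * t, tiny)
    if s <= 0.0 and x > 0.0:
        s = k1r * t / max(k1f * x, tiny)
    elif x <= 0.0 and s > 0.0:
        x = k1r * t / max(k1f * s, tiny)
    elif s <= 0.0 and x <= 0.0:  # equal totals: both vanish together
        s = x = np.sqrt(max(k1r * t / max(k1f, tiny), 0.0))
    return np.array([s, x, v, t, f])


def _polish(
    variant: ModelVariant,
    params: np.ndarray,
    seed_state: np.ndarray,
    totals: tuple[float, float, float],
) -> np.ndarray | None:
    """Newton-refine a candidate on {fluxes = 0, moiety totals fixed}."""
    net = variant.network
    stot, xtot, vtot = totals
    cons = np.array(
        [
            [1.0, 0.0, 0.0, 1.0, 1.0],  # SNAP25 moiety
            [0.0, 1.0, 0.0, 1.0, 1.0],  # syntaxin moiety
            [0.0, 0.0, 1.0, 0.0, 1.0],  # VAMP2 moiety
        ]
    )
    rhs_tot = np.array([stot, xtot, vtot])

    def g(x):
        fl = net.fluxes(x, params)
        return np.concatenate([fl, cons @ x - rhs_tot])

    def gjac(x):
        k1f, k1r, k2f, k2r = params[:4]
        s, xx, v, t, f = x
        dfl = np.array(
            [
                [k1f * xx, k1f * s, 0.0, -k1r, 0.0],
                [0.0, 0.0, k2f * t, k2f * v, -k2r],
            ]
        )
        return np.vstack([dfl, cons])

    scale = max(1.0, stot, xtot, vtot)
    x = _corrected_seed(np.asarray(seed_state, dtype=float), params)
    r = g(x)
    best = float(np.max(np.abs(r)))
    for _ in range(60):
        if best < 1e-12 * scale:
            break
        step, *_ = np.linalg.lstsq(gjac(x), -r, rcond=None)
        lam = 1.0
        improved = False
        for _ in range(40):
            cand = x + lam * step
            rc = g(cand)
            nc = float(np.max(np.abs(rc)))
            if nc < best:
                x, r, best = cand, rc, nc
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    if best < 1e-9 * scale and np.all(x > -1e-9 * scale):
        return np.clip(x, 0.0, None)
    sol = root(g, x, method="lm")  # rank-deficient-tolerant fallback
    if float(np.max(np.abs(g(np.clip(sol.x, 0.0, None))))) < 1e-9 * scale and np.all(
        sol.x > -1e-9 * scale
    ):
        return np.clip(sol.x, 0.0, None)
    return None


def analytic_steady_states(
    case: str,
    initials: Mapping[str, float],
    params: np.ndarray | Mapping[str, float],
    steady_tol: float = 1e-6,
) -> list[SteadyState]:
    """Steady states of the fundamental subsystem for case A, B or C.

    Case A requires equal SNAP25 and syntaxin initials; cases A and B assume
    the near-irreversible regime (k_r << k_f) that makes the closed forms
    exact at leading order; case C accepts comparable forward/backward
    rates and adds an integration-based interior seed.  Every returned
    state is refined to the exact root and verified by substitution.
    """
    case = case.upper()
    if case not in ("A", "B", "C"):
        raise ValueError(f"unknown case {case!r}")
    variant = fundamental_subsystem(initials)
    net = variant.network
    if isinstance(params, Mapping):
        params = net.rates_from_mapping(params)
    params = np.asarray(params, dtype=float)
    init = {**{s: 0.0 for s in net.species_names}, **dict(initials)}
    if case == "A":
        s0, x0 = init["SNAP25"], init["syntaxin"]
        if not np.isclose(s0, x0, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"case A requires equal SNAP25 and syntaxin initials "
                f"(got {s0} and {x0})"
            )
    if case in ("A", "B"):
        kvals = dict(zip(net.rate_names, params))
        if kvals["k1r"] > 0.1 * kvals["k1f"] or kvals["k2r"] > 0.1 * kvals["k2f"]:
            raise ValueError(
                "cases A/B assume the near-irreversible regime (k_r << k_f)"
            )

    totals = _totals(init)
    seeds = _vertex_candidates(*totals)
    if case == "C":
        cfg = SimulationConfig(t_end=200.0, n_points=50)
        try:
            interior = steady_state_by_integration(variant, params, init, cfg)
            seeds.append(interior.state)
        except SimulationError:
            pass

    states: list[SteadyState] = []
    for seed_state in seeds:
        x = _polish(variant, params, seed_state, totals)
        if x is None:
            continue
        resid = float(np.max(np.abs(net.rhs(x, params))))
        if resid > steady_tol:
            continue
        if any(
            np.max(np.abs(x - s.state)) < MERGE_TOL for s in states
        ):
            continue
        states.append(
            classify_steady_state(
                variant, params, x, steady_tol, source=f"analytic-case-{case}"
            )
        )
    return states


def numeric_steady_states(
    variant: ModelVariant,
    params: np.ndarray | Mapping[str, float] | None,
    initials_grid: Iterable[Mapping[str, float]],
    config: SimulationConfig | None = None,
    merge_tol: float = MERGE_TOL,
) -> list[SteadyState]:
    """Deduplicated, classified terminal states reached from a grid of
    initial conditions.  Non-converged grid points are skipped."""
    config = config or SimulationConfig()
    states: list[SteadyState] = []
    for init in initials_grid:
        try:
            ss = steady_state_by_integration(variant, params, init, config)
        except SimulationError:
            continue
        if any(np.max(np.abs(ss.state - s.state)) < merge_tol for s in states):
            continue
        states.append(
            classify_steady_state(
                variant, params, ss.state, steady_tol=10 * config.steady_tol
            )
        )
    return states


def fusion_level_predictor(initials: Mapping[str, float]) -> FusionPrediction:
    """Terminal [FHC] in the near-irreversible regime.

    Without preformed tSNARE the fusion level is the least of the three
    protein initials; with tSNARE0 > 0 it is min(T0 + min(S0, X0), V0).
    """
    s0 = initials.get("SNAP25", 0.0)
    x0 = initials.get("syntaxin", 0.0)
    v0 = initials.get("VAMP2", 0.0)
    t0 = initials.get("tSNARE", 0.0)
    if min(s0, x0, v0, t0) < 0:
        raise ValueError("initials must be nonnegative")
    if t0 > 0:
        pred = min(t0 + min(s0, x0), v0)
        regime = "preformed"
    else:
        pred = min(s0, x0, v0)
        regime = "no-preformed"
    return FusionPrediction(float(pred), regime, dict(initials))


# -- MUNC18 subsystem -------------------------------------------------------


def _munc18_partitions(
    t_tot: float, v_tot: float, m_tot: float, ic_samples: int, seed: int
) -> list[dict[str, float]]:
    """Latin grid over admissible partitions of the conserved moieties.

    phi = fraction of fusible material pre-assembled as FHC, psi = fraction
    of remaining binding capacity pre-sequestered as Smc; FHC**0 = 0
    throughout.  The corners of the (phi, psi) square — all free, fully
    preformed, fully pre-sequestered, both — are always included so every
    feasible basin is probed; Latin pairs fill the interior.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D756E63]))
    corners = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)][:ic_samples]
    n = max(ic_samples - len(corners), 0)
    phis = ((np.arange(n) + rng.random(n)) / n) if n else np.array([])
    psis = ((np.arange(n) + rng.random(n)) / n) if n else np.array([])
    rng.shuffle(psis)
    pairs = corners + list(zip(phis, psis))
    out = []
    for phi, psi in pairs:
        f = phi * min(t_tot, v_tot)
        smc = psi * min(m_tot, max(t_tot - f, 0.0))
        out.append(
            {
                "tSNARE": t_tot - f - smc,
                "VAMP2": v_tot - f,
                "FHC": f,
                "MUNC18": m_tot - smc,
                "Smc": smc,
                "FHC**": 0.0,
            }
        )
    return out


def _signature(state: SteadyState, totals: Mapping[str, float]) -> str:
    eps = DEPLETION_FRACTION
    m_dep = state["MUNC18"] < eps * max(totals["MUNC18"], 1e-12)
    v_dep = state["VAMP2"] < eps * max(totals["VAMP2"], 1e-12)
    t_dep = state["tSNARE"] < eps * max(totals["tSNARE"], 1e-12)
    if m_dep and v_dep:
        return "high-fusion"
    if m_dep and t_dep:
        return "low-fusion"
    return "other"


def munc18_steady_states(
    initials: Mapping[str, float] | None = None,
    params: np.ndarray | Mapping[str, float] | None = None,
    config: SimulationConfig | None = None,
    ic_samples: int = 8,
    seed: int = 0,
) -> list[SteadyState]:
    """Stable states of the MUNC18 subsystem by basin sampling.

    Requires FHC**0 = 0.  States are labeled high-fusion (free MUNC18 and
    free VAMP2 virtually zero) or low-fusion (free MUNC18 and free tSNARE
    virtually zero) when they match the depletion signatures.
    """
    variant = munc18_subsystem(initials)
    init = variant.default_initials
    if init.get("FHC**", 0.0) != 0.0:
        raise ValueError("the MUNC18 analysis assumes FHC**0 = 0")
    net = variant.network
    if isinstance(params, Mapping):
        params = net.rates_from_mapping(params)
    config = config or SimulationConfig(t_end=400.0, n_points=100)
    t_tot = init["tSNARE"] + init["FHC"] + init["Smc"] + init["FHC**"]
    v_tot = init["VAMP2"] + init["FHC"] + init["FHC**"]
    m_tot = init["MUNC18"] + init["Smc"] + init["FHC**"]
    totals = {"tSNARE": t_tot, "VAMP2": v_tot, "MUNC18": m_tot}

    found: dict[str, SteadyState] = {}
    for part in _munc18_partitions(t_tot, v_tot, m_tot, ic_samples, seed):
        try:
            ss = steady_state_by_integration(variant, params, part, config)
        except SimulationError:
            continue
        sig = _signature(ss, totals)
        if sig not in found:
            ss.label = sig
            ss.source = "munc18-analytic"
            found[sig] = ss
    return list(found.values())


def bistability_scan(
    m0_grid: Sequence[float],
    initials: Mapping[str, float] | None = None,
    params: np.ndarray | Mapping[str, float] | None = None,
    ic_samples: int = 6,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> BistabilityScan:
    """Count distinct stable branches of the MUNC18 subsystem per M0.

    Reports the contiguous M0 window where both the high-fusion and the
    low-fusion branch are reached (count 2); outside it a single branch
    remains.
    """
    m0_grid = np.asarray(m0_grid, dtype=float)
    if np.any(m0_grid <= 0):
        raise ValueError("m0_grid must be positive")
    if ic_samples < 2:
        raise ValueError("ic_samples must be >= 2")
    counts = np.zeros(len(m0_grid), dtype=int)
    sigs: list[tuple[str, ...]] = []
    for i, m0 in enumerate(m0_grid):
        init = {**(initials or {}), "MUNC18": float(m0)}
        states = munc18_steady_states(
            init, params, config, ic_samples=ic_samples, seed=seed
        )
        labels = tuple(sorted(s.label for s in states))
        counts[i] = len(labels)
        sigs.append(labels)
    window = None
    both = [s == ("high-fusion", "low-fusion") for s in sigs]
    if any(both):
        runs = []
        start = None
        for i, b in enumerate(both):
            if b and start is None:
                start = i
            elif not b and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(both) - 1))
        lo, hi = max(runs, key=lambda r: r[1] - r[0])
        window = (float(m0_grid[lo]), float(m0_grid[hi]))
    return BistabilityScan(m0_grid, counts, sigs, window)
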