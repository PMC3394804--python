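"""Synthetic ground truths and fluorescence traces.

No in-vitro fusion-assay data are deposited for this system, so fitting
and stability tests run against synthetic traces: the fundamental
subsystem is integrated from physiological initial concentrations
(VAMP2 0.2-30 µM, SNAP25/syntaxin 0.1-100 µM, MUNC18 1-30 µM), observed
through the linear intensity model, and corrupted with multiplicative
Gaussian noise (fluorescence noise scales with signal).

A trace's ``meta`` records the full provenance (regime, seed, noise,
grid), enough to regenerate it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inverse import FluorescenceTrace, ObservationModel, ParameterVector, observe
from .models import fundamental_subsystem, munc18_subsystem
from .simulate import SimulationConfig, integrate, steady_state_by_integration

__all__ = ["GroundTruth", "ground_truth", "generate_trace"]

REGIMES = ("default", "near-irreversible", "bistable-munc18")


@dataclass
class GroundTruth:
    """A documented parameter regime used as simulation ground truth."""

    regime: str
    params: ParameterVector
    initials: dict[str, float]
    obs: ObservationModel
    provenance: str = "synthetic-default"


def ground_truth(regime: str = "default", seed: int | None = None) -> GroundTruth:
    """Fixed, documented ground-truth regimes.

    * default — moderately reversible fundamental subsystem, the regime the
      recovery tests run in.
    * near-irreversible — dissociation rates 1e-4 of association rates;
      the terminal fusion obeys the min-rule exactly to that order.
    * bistable-munc18 — MUNC18 subsystem with an initial MUNC18 inside the
      verified two-state window (tSNARE 20, VAMP2 8, MUNC18 16 µM).

    The regimes are fixed by construction; ``seed`` is accepted for
    interface symmetry and recorded but does not alter them.
    """
    if regime == "default":
        # assembly rate-limiting, fusion pseudo-first-order (VAMP2 in
        # excess), a small preformed tSNARE pool as in binary t-SNARE
        # assays: this keeps both forward rates kinetically visible
        return GroundTruth(
            regime,
            ParameterVector(np.array([0.25, 0.05, 0.3, 0.05, 2.0])),
            {"SNAP25": 2.0, "syntaxin": 2.0, "VAMP2": 4.0,
             "tSNARE": 0.4, "FHC": 0.0},
            ObservationModel(gain=2.0),
        )
    if regime == "near-irreversible":
        return GroundTruth(
            regime,
            ParameterVector(np.array([0.7, 0.7e-4, 0.4, 0.4e-4, 2.0])),
            {"SNAP25": 1.5, "syntaxin": 2.0, "VAMP2": 1.0,
             "tSNARE": 0.0, "FHC": 0.0},
            ObservationModel(gain=2.0),
        )
    if regime == "bistable-munc18":
        return GroundTruth(
            regime,
            ParameterVector(
                np.array([0.5, 0.0, 0.5, 0.0, 0.5]),
                names=("k1f", "k1r", "k2f", "k2r", "k3f"),
            ),
            {"tSNARE": 20.0, "VAMP2": 8.0, "FHC": 0.0,
             "MUNC18": 16.0, "Smc": 0.0, "FHC**": 0.0},
            ObservationModel(gain=1.0),
        )
    raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")


def _auto_t_end(truth: GroundTruth, margin: float = 2.0) -> float:
    """Horizon = ``margin`` times the 95%-of-terminal crossing time, so the
    window shows the rise and an established plateau (deterministic,
    from a fixed fine grid)."""
    variant = fundamental_subsystem(truth.initials)
    cfg = SimulationConfig(t_end=50.0, n_points=400)
    terminal = float(
        variant.fusion_readout(
            steady_state_by_integration(
                variant, truth.params.values[:4], truth.initials, cfg
            ).state[None, :]
        )[0]
    )
    t_end = 50.0
    for _ in range(20):
        traj = integrate(
            variant, truth.params.values[:4], truth.initials,
            SimulationConfig(t_end=t_end, n_points=400),
        )
        read = variant.fusion_readout(traj.states)
        crossing = np.nonzero(read >= 0.95 * terminal)[0]
        if len(crossing):
            return margin * float(traj.times[crossing[0]])
        t_end *= 2.0
    raise RuntimeError("readout never reached 95% of its terminal value")


def generate_trace(
    truth: GroundTruth,
    n_points: int = 50,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
    t_end: float | None = None,
) -> FluorescenceTrace:
    """integrate -> observe -> multiply by (1 + eps), eps ~ N(0, sd^2).

    Times are uniform on [0, t_end]; by default t_end is chosen so the
    noiseless readout reaches at least 95% of its terminal value.
    """
    if truth.regime == "bistable-munc18":
        raise ValueError("trace generation uses the fundamental-subsystem regimes")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be >= 0")
    if t_end is None:
        t_end = _auto_t_end(truth)
    variant = fundamental_subsystem(truth.initials)
    cfg = SimulationConfig(t_end=float(t_end), n_points=n_points,
                           rel_tol=1e-10, abs_tol=1e-12)
    traj = integrate(variant, truth.params.values[:4], truth.initials, cfg)
    trace = observe(traj, truth.obs)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7ACE]))
        trace.intensities = trace.intensities * (
            1.0 + noise_sd_rel * rng.standard_normal(n_points)
        )
    trace.meta = {
        "provenance": "synthetic",
        "regime": truth.regime,
        "seed": int(seed),
        "noise_sd_rel": float(noise_sd_rel),
        "n_points": int(n_points),
        "t_end": float(t_end),
        "params": truth.params.as_dict(),
        "initials": dict(truth.initials),
        "gain": truth.obs.gain,
        "offset": truth.obs.offset,
        "background": truth.obs.background,
    }
    return trace
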