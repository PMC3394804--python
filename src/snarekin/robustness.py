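"""Latin Hypercube parameter designs and batch robustness scans.

Each parameter is varied uniformly within ±delta (relative) of its nominal
value, with exactly one draw per equal-width stratum.  Draws come from a
counter-based Philox generator keyed by (seed, parameter index, stratum),
so a design is reproducible bit-for-bit across platforms and independent
of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ModelVariant
from .simulate import (
    SimulationConfig,
    SimulationError,
    integrate,
    preformed_vs_sequential,
    steady_state_by_integration,
)
from .simulate import _t90

__all__ = ["LHSDesign", "lhs_sample", "robustness_scan"]

METRICS = ("final-fusion", "t90", "t90-paired", "n-stable-states")


@dataclass
class LHSDesign:
    n: int
    delta: float
    nominal: np.ndarray
    samples: np.ndarray  # (n, p)
    seed: int

    def to_frame(self, names=None) -> pd.DataFrame:
        p = self.samples.shape[1]
        names = list(names) if names is not None else [f"p{i}" for i in range(p)]
        return pd.DataFrame(self.samples, columns=names)

    def strata(self) -> np.ndarray:
        """Stratum index of each sample per parameter (occupancy check)."""
        lo = self.nominal * (1 - self.delta)
        width = 2 * self.delta * self.nominal / self.n
        idx = np.floor((self.samples - lo) / width).astype(int)
        return np.clip(idx, 0, self.n - 1)


def _u01(seed: int, param: int, stratum: int) -> float:
    """Platform-stable uniform draw keyed by (seed, parameter, stratum)."""
    bg = np.random.Philox(np.random.SeedSequence([seed, param, stratum]))
    return float(np.random.Generator(bg).random())


def lhs_sample(
    nominal: np.ndarray | Mapping[str, float],
    n: int,
    delta: float = 0.2,
    seed: int = 0,
) -> LHSDesign:
    """Stratified uniform design on [nominal(1-delta), nominal(1+delta)].

    delta must be < 1 so that all sampled rates stay positive.
    """
    names = None
    if isinstance(nominal, Mapping):
        names = list(nominal)
        nominal = np.array([nominal[k] for k in names], dtype=float)
    nominal = np.atleast_1d(np.asarray(nominal, dtype=float))
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= delta < 1:
        raise ValueError("delta must be in [0, 1) to keep rates positive")
    if np.any(nominal < 0):
        raise ValueError("nominal rates must be nonnegative")
    p = nominal.size
    samples = np.empty((n, p))
    for j in range(p):
        perm = np.random.Generator(
            np.random.Philox(np.random.SeedSequence([seed, j, n]))
        ).permutation(n)
        for i in range(n):
            s = int(perm[i])
            u = _u01(seed, j, s)
            frac = (s + u) / n  # position inside [0, 1)
            samples[i, j] = nominal[j] * (1 - delta + 2 * delta * frac)
    design = LHSDesign(n, delta, nominal, samples, seed)
    if names is not None:
        design.names = names  # type: ignore[attr-defined]
    return design


def robustness_scan(
    variant: ModelVariant,
    design: LHSDesign,
    initials: Mapping[str, float] | None = None,
    metric: str = "final-fusion",
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Evaluate an outcome metric for every design row.

    Returns one row per sample with the parameters, the metric value(s) and
    a convergence flag; per-row failures are recorded, not fatal.  Summary
    quantiles are attached as ``df.attrs["quantiles"]``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    config = config or SimulationConfig()
    net = variant.network
    if design.samples.shape[1] != net.n_rates:
        raise ValueError(
            f"design has {design.samples.shape[1]} parameters, variant needs "
            f"{net.n_rates} ({net.rate_names})"
        )
    rows = []
    for params in design.samples:
        rec: dict[str, float | bool] = dict(zip(net.rate_names, params))
        try:
            if metric == "final-fusion":
                ss = steady_state_by_integration(variant, params, initials, config)
                rec["final_fusion"] = float(
                    variant.fusion_readout(ss.state[None, :])[0]
                )
            elif metric == "t90":
                traj = integrate(variant, params, initials, config)
                read = variant.fusion_readout(traj.states)
                rec["t90"] = _t90(traj.times, read)
            elif metric == "t90-paired":
                comp = preformed_vs_sequential(
                    params, initials, config, variant=variant
                )
                rec["t90_preformed"] = comp.t90_preformed
                rec["t90_sequential"] = comp.t90_sequential
                rec["final_fusion_preformed"] = comp.final_fusion_preformed
                rec["final_fusion_sequential"] = comp.final_fusion_sequential
            elif metric == "n-stable-states":
                from .stability import munc18_steady_states

                states = munc18_steady_states(
                    initials, params, config, ic_samples=6, seed=design.seed
                )
                rec["n_stable_states"] = len(states)
            rec["converged"] = True
        except (SimulationError, ValueError) as exc:
            rec["converged"] = False
            rec["error"] = str(exc)
        rows.append(rec)
    df = pd.DataFrame(rows)
    value_cols = [
        c for c in df.columns
        if c not in net.rate_names and c not in ("converged", "error")
    ]
    if value_cols:
        df.attrs["quantiles"] = df[value_cols].quantile([0.05, 0.25, 0.5, 0.75, 0.95])
    return df
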