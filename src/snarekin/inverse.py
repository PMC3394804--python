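"""Rate-parameter recovery from fluorescence fusion traces.

The measured intensity is affine in the summed core-complex concentration
(linear far below detector saturation):

    I(t) = a * ([FHC] + [FHC*] + [FHC**])(t) + b + c,

with gain ``a``, instrument offset ``b`` and constant background supply
``c``.  For the fundamental subsystem the gain is absorbed into a single
fitted fusion-concentration constant K, so the recovered parameter vector
is q = (k1f, k1r, k2f, k2r, K); the offset b + c is treated as known.

Recovery minimizes the Tikhonov-regularized energy functional

    J(q) = ||F(q) - z||^2 + alpha * ||q||^2 + P(q),

where F maps parameters to the model intensity on the data's time grid, z
is the measured trace, and P is a quadratic hinge penalty keeping rates
positive.  The search runs on log-parameters (positivity is then automatic
and the penalty inactive) in two phases: steepest descent with a
forward-difference gradient, then a quasi-Newton phase whose Hessian
approximation H = 2 J^T J is assembled from the Jacobian of the
parameter-data map (Levenberg-damped Gauss-Newton), started from the
phase-1 point.  Confidence intervals come from a residual-resampling
parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .models import ModelVariant, fundamental_subsystem
from .network import NetworkError
from .simulate import SimulationConfig, SimulationError, Trajectory, integrate

__all__ = [
    "ObservationModel",
    "FluorescenceTrace",
    "ParameterVector",
    "RegularizationConfig",
    "FitResult",
    "observe",
    "objective",
    "fit",
    "confidence_intervals",
    "l_curve",
    "multistart_fit",
]

PARAM_NAMES = ("k1f", "k1r", "k2f", "k2r", "K")


@dataclass(frozen=True)
class ObservationModel:
    """Linear fluorescence readout: intensity = a * readout + b + c."""

    gain: float = 1.0  # a, intensity per µM
    offset: float = 0.0  # b, instrument offset
    background: float = 0.0  # c, constant supply

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain a must be > 0")


@dataclass
class FluorescenceTrace:
    """Observed intensity time series."""

    times: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ParameterVector:
    """Ordered positive rates (k1f, k1r, k2f, k2r) plus the constant K."""

    values: np.ndarray
    names: tuple[str, ...] = PARAM_NAMES
    bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} parameters {self.names}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass
class RegularizationConfig:
    """Objective and optimizer settings for the inverse problem."""

    alpha: float | None = None  # None -> 1e-6 * ||z||^2 at fit time
    penalty_weight: float = 1e3
    init_guess: np.ndarray | None = None
    phase1_iters: int = 25
    phase2_iters: int = 300
    grad_step: float = 1e-5  # forward-difference step on log-parameters
    grad_tol: float = 1e-8
    ftol: float = 1e-14  # relative cost-decrease stopping threshold
    offset: float = 0.0  # known b + c, subtracted from the data
    #: admissible parameter box Q_ad, one (lo, hi) per parameter; None = R+^5
    bounds: tuple[tuple[float, float], ...] | None = None
    rel_tol: float = 1e-10  # forward-solver tolerances
    abs_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")
        if self.grad_step <= 0:
            raise ValueError("grad_step must be > 0")


@dataclass
class FitResult:
    q_hat: ParameterVector
    objective: float
    grad_norm: float
    converged: bool
    n_iterations: int
    objective_history: np.ndarray
    intervals_95: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0


def observe(trajectory: Trajectory, model: ObservationModel) -> FluorescenceTrace:
    """Apply the linear observation model to a trajectory."""
    from .models import FUSION_READOUT

    present = [s for s in FUSION_READOUT if s in trajectory.species]
    if not present:
        raise NetworkError(
            f"trajectory lacks fusion readout species {FUSION_READOUT}"
        )
    idx = [trajectory.species.index(s) for s in present]
    readout = trajectory.states[:, idx].sum(axis=1)
    intensity = model.gain * readout + model.offset + model.background
    return FluorescenceTrace(
        trajectory.times.copy(),
        intensity,
        meta={"provenance": "model", "observation": {
            "gain": model.gain, "offset": model.offset,
            "background": model.background,
        }},
    )


def _forward(
    q: np.ndarray,
    initials: Mapping[str, float],
    times: np.ndarray,
    reg: RegularizationConfig,
) -> np.ndarray:
    """Model intensity K*[FHC](t) + offset on the data's time grid."""
    variant = fundamental_subsystem(initials)
    rates = np.array(q[:4], dtype=float)
    cfg = SimulationConfig(
        t_end=float(times[-1]),
        n_points=2,  # unused: we pass explicit t_eval via trace grid below
        rel_tol=reg.rel_tol,
        abs_tol=reg.abs_tol,
    )
    # integrate on exactly the observation grid (prepend t=0 if needed)
    from scipy.integrate import solve_ivp

    net = variant.network
    x0 = net.initial_state(initials)
    t_eval = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    sol = solve_ivp(
        lambda t, x: net.rhs(x, rates, t),
        (0.0, float(times[-1])),
        x0,
        method="LSODA",
        jac=lambda t, x: net.jacobian(x, rates),
        t_eval=t_eval,
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
    )
    if not sol.success:
        raise SimulationError(f"forward solve failed: {sol.message}")
    fhc = sol.y[net.index["FHC"], :]
    if times[0] != 0.0:
        fhc = fhc[1:]
    return q[4] * fhc + reg.offset


def objective(
    q: np.ndarray | ParameterVector,
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig,
) -> float:
    """Regularized energy J(q) = ||F(q) - z||^2 + alpha ||q||^2 + P(q)."""
    if isinstance(q, ParameterVector):
        q = q.values
    q = np.asarray(q, dtype=float)
    z = data.intensities
    alpha = reg.alpha if reg.alpha is not None else 1e-6 * float(z @ z)
    penalty = reg.penalty_weight * float(np.sum(np.clip(-q, 0.0, None) ** 2))
    q_eval = np.clip(q, 1e-12, None)  # mass action needs nonnegative rates
    model = _forward(q_eval, initials, data.times, reg)
    resid = model - z
    return float(resid @ resid + alpha * (q @ q) + penalty)


def _fd_grad(f, x: np.ndarray, h: float) -> tuple[float, np.ndarray]:
    """Forward-difference gradient; returns (f(x), grad)."""
    f0 = f(x)
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += h
        g[i] = (f(xp) - f0) / h
    return f0, g


def _aug_residual(
    theta: np.ndarray,
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig,
    alpha: float,
) -> np.ndarray:
    """Augmented residual [F(q) - z; sqrt(alpha) q]; its squared norm is J."""
    q = np.exp(theta)
    model = _forward(q, initials, data.times, reg)
    out = model - data.intensities
    if alpha > 0:
        out = np.concatenate([out, np.sqrt(alpha) * q])
    return out


def fit(
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """Two-phase recovery of q = (k1f, k1r, k2f, k2r, K).

    Phase 1 is steepest descent with a forward-difference gradient and
    Armijo backtracking.  Phase 2 is a quasi-Newton iteration whose Hessian
    approximation H = 2 J^T J comes from the forward-difference Jacobian of
    the parameter-data map, with Levenberg damping and a trust step cap.
    The search runs on log-parameters, so all iterates are positive and the
    objective decreases monotonically across accepted steps.
    """
    reg = reg or RegularizationConfig()
    if len(data) < len(PARAM_NAMES):
        raise ValueError(
            f"need at least {len(PARAM_NAMES)} time points, got {len(data)}"
        )
    q0 = (
        np.asarray(reg.init_guess, dtype=float)
        if reg.init_guess is not None
        else np.array([1.0, 0.1, 1.0, 0.1, 1.0])
    )
    if np.any(q0 <= 0):
        raise ValueError("init_guess must be positive")
    z = data.intensities
    alpha = reg.alpha if reg.alpha is not None else 1e-6 * float(z @ z)

    def J(theta: np.ndarray) -> float:
        return objective(np.exp(theta), data, initials, reg)

    if reg.bounds is not None:
        lo = np.log([b[0] for b in reg.bounds])
        hi = np.log([b[1] for b in reg.bounds])
        if np.any(lo >= hi):
            raise ValueError("each bound must satisfy lo < hi")
        project = lambda th: np.clip(th, lo, hi)  # noqa: E731
    else:
        project = lambda th: th  # noqa: E731

    theta = project(np.log(q0))
    h = reg.grad_step
    history = []
    f0, g = _fd_grad(J, theta, h)
    history.append(f0)
    n_iter = 0
    grad_norm = float(np.max(np.abs(g)))

    # phase 1: steepest descent with Armijo backtracking
    for _ in range(reg.phase1_iters):
        grad_norm = float(np.max(np.abs(g)))
        if grad_norm < reg.grad_tol:
            break
        step = 1.0 / max(grad_norm, 1.0)
        accepted = False
        for _ in range(30):
            cand = project(theta - step * g)
            fc = J(cand)
            if fc < f0 - 1e-4 * step * float(g @ g):
                theta, f0 = cand, fc
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        history.append(f0)
        n_iter += 1
        _, g = _fd_grad(J, theta, h)

    # phase 2: Levenberg-damped Gauss-Newton on the augmented residual,
    # with active-set reduction at the admissible-box faces
    f = _aug_residual(theta, data, initials, reg, alpha)
    cost = float(f @ f)
    lam = 1e-3
    converged = False
    at_lo = at_hi = None
    for _ in range(reg.phase2_iters):
        Jm = np.empty((f.size, theta.size))
        for i in range(theta.size):
            tp = theta.copy()
            tp[i] += h
            Jm[:, i] = (_aug_residual(tp, data, initials, reg, alpha) - f) / h
        g = 2.0 * Jm.T @ f
        if reg.bounds is not None:
            at_lo = theta <= lo + 1e-12
            at_hi = theta >= hi - 1e-12
            free = ~((at_lo & (g > 0)) | (at_hi & (g < 0)))
        else:
            free = np.ones(theta.size, dtype=bool)
        grad_norm = float(np.max(np.abs(g[free]))) if free.any() else 0.0
        if grad_norm < reg.grad_tol:
            converged = True
            break
        Jf = Jm[:, free]
        gf = g[free]
        H = 2.0 * Jf.T @ Jf
        accepted = False
        for _ in range(50):
            try:
                step_f = np.linalg.solve(
                    H + lam * np.diag(np.diag(H) + 1e-12), -gf
                )
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            step = np.zeros_like(theta)
            step[free] = step_f
            norm = float(np.linalg.norm(step))
            if norm > 1.0:  # trust cap: at most one e-fold per parameter
                step *= 1.0 / norm
            cand = project(theta + step)
            fc = _aug_residual(cand, data, initials, reg, alpha)
            cc = float(fc @ fc)
            if np.isfinite(cc) and cc < cost:
                rel_drop = (cost - cc) / max(cost, 1e-300)
                theta, f, cost = cand, fc, cc
                lam = max(lam / 3.0, 1e-14)
                accepted = True
                history.append(cost)
                n_iter += 1
                if rel_drop < reg.ftol:
                    converged = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not accepted or converged:
            # no further descent possible at numerical precision
            converged = converged or not accepted
            break
    f_final = float(cost)
    if not np.isfinite(f_final):
        raise SimulationError("objective became non-finite during the fit")
    return FitResult(
        q_hat=ParameterVector(np.exp(theta)),
        objective=f_final,
        grad_norm=grad_norm,
        converged=converged,
        n_iterations=n_iter,
        objective_history=np.asarray(history),
    )


def confidence_intervals(
    fit_result: FitResult,
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> FitResult:
    """95% parametric-bootstrap intervals by residual resampling.

    Refits n_boot residual-resampled traces from the point estimate; the
    point estimate itself is included in the percentile pool, so the
    intervals always contain it.
    """
    reg = reg or RegularizationConfig()
    if not fit_result.converged:
        raise ValueError("confidence intervals require a converged fit")
    q_hat = fit_result.q_hat.values
    model = _forward(np.clip(q_hat, 1e-12, None), initials, data.times, reg)
    residuals = data.intensities - model
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    # warm-started refits need only modest precision for percentile intervals
    warm = replace(
        reg,
        init_guess=q_hat,
        phase1_iters=0,
        phase2_iters=80,
        ftol=max(reg.ftol, 1e-9),
    )
    draws = [q_hat]
    failures = 0
    for _ in range(n_boot):
        resampled = rng.choice(residuals, size=len(residuals), replace=True)
        boot = FluorescenceTrace(data.times, model + resampled)
        try:
            r = fit(boot, initials, warm)
        except (SimulationError, ValueError):
            failures += 1
            continue
        if r.converged:
            draws.append(r.q_hat.values)
        else:
            failures += 1
    if n_boot > 0 and (n_boot - failures) / n_boot < 0.8:
        raise SimulationError(
            f"bootstrap convergence rate below 80% ({failures}/{n_boot} failed)"
        )
    arr = np.array(draws)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    intervals = {
        name: (float(l), float(h))
        for name, l, h in zip(fit_result.q_hat.names, lo, hi)
    }
    return replace(
        fit_result, intervals_95=intervals, n_boot=len(draws) - 1
    )


def l_curve(
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig | None = None,
    alphas: np.ndarray | None = None,
):
    """Residual norm vs parameter norm across alpha (L-curve diagnostic)."""
    import pandas as pd

    reg = reg or RegularizationConfig()
    if alphas is None:
        alphas = np.logspace(-10, -2, 9) * float(
            data.intensities @ data.intensities
        )
    rows = []
    for a in alphas:
        r = fit(data, initials, replace(reg, alpha=float(a)))
        q = r.q_hat.values
        model = _forward(q, initials, data.times, reg)
        resid = float(np.sum((model - data.intensities) ** 2))
        rows.append(
            {"alpha": float(a), "residual_norm2": resid,
             "param_norm2": float(q @ q), "converged": r.converged}
        )
    return pd.DataFrame(rows)


def multistart_fit(
    data: FluorescenceTrace,
    initials: Mapping[str, float],
    reg: RegularizationConfig | None = None,
    n_starts: int = 10,
    spread: float = 0.5,
    seed: int = 0,
) -> list[FitResult]:
    """Fits from ``n_starts`` initial guesses jittered within ±spread."""
    reg = reg or RegularizationConfig()
    base = (
        np.asarray(reg.init_guess, dtype=float)
        if reg.init_guess is not None
        else np.array([1.0, 0.1, 1.0, 0.1, 1.0])
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    results = []
    for _ in range(n_starts):
        factors = 1.0 + spread * (2 * rng.random(base.size) - 1)
        results.append(fit(data, initials, replace(reg, init_guess=base * factors)))
    return results
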