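"""Firing-rate dynamics: threshold-linear and supralinear (SSN) models.

Implements forward-Euler integration of

    tau * dr/dt = -r + f(s * (W r + X))

where ``W`` and ``X`` are the unnormalized effective matrices (mV/Hz and
mV) and ``s`` is an optional coupling rescaling used to probe the
strong-coupling limit: as the coupling scale grows, stable fixed points
approach the semi-balanced solution, with populations silenced by excess
inhibition converging to zero rate.

Supported f-I curves: rectified linear ``g*[I]^+``, rectified square
``k*([I]^+)^2`` (the stabilized supralinear network), and a saturating
sigmoid with ceiling ``M``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .meanfield import MeanFieldNetwork, _as_stim, semibalanced_rates

__all__ = [
    "RateModelConfig",
    "RateTrajectory",
    "ISNReport",
    "integrate_rate",
    "integrate_ssn",
    "rate_fixed_point",
    "classify_isn",
    "isn_sweep",
    "limit_convergence_study",
]

F_KINDS = ("rectified_linear", "rectified_square", "saturating")


@dataclass
class RateModelConfig:
    """Parameters of the rate model.

    ``JK_mVHz`` rescales coupling: the input becomes
    ``(JK_mVHz / net.JK) * (W r + X)``; leave None for the network's own
    scale.  ``gain_Hz_per_mV`` is the slope of the rectified-linear
    curve; ``k_Hz_per_mV2`` the supralinear gain; ``M_Hz`` the
    saturation ceiling; ``I0_mV`` the sigmoid width.  ``dt_auto`` shrinks
    the Euler step when coupling makes the system stiff.
    """

    tau_ms: float = 10.0
    dt_ms: float = 1.0
    T_ms: float = 5000.0
    f_kind: str = "rectified_linear"
    gain_Hz_per_mV: float = 1.0
    k_Hz_per_mV2: float = 10.0
    M_Hz: float = 100.0
    I0_mV: float = 1.0
    JK_mVHz: float | None = None
    rate_ceiling_Hz: float = 1e5
    record_stride: int = 10
    dt_auto: bool = True
    conv_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.f_kind not in F_KINDS:
            raise ValueError(f"f_kind must be one of {F_KINDS}")
        if self.tau_ms <= 0 or self.dt_ms <= 0 or self.T_ms <= 0:
            raise ValueError("tau, dt and T must be positive")


@dataclass
class RateTrajectory:
    times: np.ndarray
    rates: np.ndarray  # (n_times, n_pop)
    final_rates: np.ndarray
    converged: bool
    final_rel_change: float
    diverged: bool = False


def _coupling_scale(net: MeanFieldNetwork, cfg: RateModelConfig) -> float:
    if cfg.JK_mVHz is None:
        return 1.0
    if net.JK <= 0:
        raise ValueError("network JK is zero; cannot rescale coupling")
    return cfg.JK_mVHz / net.JK


def _f(u: np.ndarray, cfg: RateModelConfig) -> np.ndarray:
    if cfg.f_kind == "rectified_linear":
        return cfg.gain_Hz_per_mV * np.maximum(u, 0.0)
    if cfg.f_kind == "rectified_square":
        return cfg.k_Hz_per_mV2 * np.maximum(u, 0.0) ** 2
    # saturating sigmoid: 0 at -inf, M at +inf
    return cfg.M_Hz / (1.0 + np.exp(-np.clip(u / cfg.I0_mV, -500, 500)))


def _local_gain(u: np.ndarray, cfg: RateModelConfig) -> np.ndarray:
    """Elementwise derivative f'(u), for stiffness control and Jacobians."""
    if cfg.f_kind == "rectified_linear":
        return np.where(u > 0, cfg.gain_Hz_per_mV, 0.0)
    if cfg.f_kind == "rectified_square":
        return 2.0 * cfg.k_Hz_per_mV2 * np.maximum(u, 0.0)
    sig = 1.0 / (1.0 + np.exp(-np.clip(u / cfg.I0_mV, -500, 500)))
    return cfg.M_Hz / cfg.I0_mV * sig * (1.0 - sig)


def integrate_rate(net: MeanFieldNetwork, stim, cfg: RateModelConfig,
                   r0=None) -> RateTrajectory:
    """Forward-Euler integration of the rate model.

    Divergence (any rate above ``rate_ceiling_Hz``) stops integration
    early with ``diverged=True``.
    """
    X = _as_stim(stim, net.n)
    s = _coupling_scale(net, cfg)
    r = np.ones(net.n) if r0 is None else np.asarray(r0, dtype=float).copy()
    if np.any(r < 0):
        raise ValueError("initial rates must be nonnegative")
    tau, dt = cfg.tau_ms, cfg.dt_ms
    Wn = np.linalg.norm(net.W, np.inf)
    n_steps = int(round(cfg.T_ms / dt))
    times, rates = [0.0], [r.copy()]
    t = 0.0
    converged = False
    diverged = False
    rel_change = np.inf
    window_ms = 10 * tau
    t_check = 0.0
    r_prev_win = r.copy()
    k = 0
    max_steps = 5_000_000
    while t < cfg.T_ms - 1e-9 and k < max_steps:
        u = s * (net.W @ r + X)
        if cfg.dt_auto:
            rho = float(s * Wn * _local_gain(u, cfg).max(initial=0.0))
            dt_eff = min(dt, 0.5 * tau / max(1.0, rho))
        else:
            dt_eff = dt
        r = r + (dt_eff / tau) * (-r + _f(u, cfg))
        t += dt_eff
        k += 1
        if not np.all(np.isfinite(r)) or np.any(r > cfg.rate_ceiling_Hz):
            diverged = True
            break
        if k % cfg.record_stride == 0:
            times.append(t)
            rates.append(r.copy())
        if t - t_check >= window_ms:
            denom = max(1.0, float(np.abs(r).max()))
            rel_change = float(np.abs(r - r_prev_win).max()) / denom
            r_prev_win = r.copy()
            t_check = t
            if rel_change < cfg.conv_rtol:
                converged = True
                break
    if times[-1] != t:
        times.append(t)
        rates.append(r.copy())
    return RateTrajectory(times=np.asarray(times), rates=np.asarray(rates),
                          final_rates=r, converged=converged,
                          final_rel_change=rel_change, diverged=diverged)


def integrate_ssn(net: MeanFieldNetwork, stim, cfg: RateModelConfig,
                  r0=None) -> RateTrajectory:
    """Integrate the supralinear (squared-rectified) rate model."""
    if cfg.f_kind != "rectified_square":
        cfg = replace(cfg, f_kind="rectified_square")
    return integrate_rate(net, stim, cfg, r0=r0)


def _linear_fixed_points(net: MeanFieldNetwork, X: np.ndarray, g: float,
                         s: float) -> list[np.ndarray]:
    """Exact fixed points of r = g*s*[W r + X]^+ by support enumeration."""
    n = net.n
    out: list[np.ndarray] = []
    for size in range(n + 1):
        for S in itertools.combinations(range(n), size):
            r = np.zeros(n)
            if S:
                S = list(S)
                A = np.eye(len(S)) / (g * s) - net.W[np.ix_(S, S)]
                if np.linalg.cond(A) > 1e12:
                    continue
                rS = np.linalg.solve(A, X[S])
                if np.any(rS <= 0):
                    continue
                r[S] = rS
            u = net.W @ r + X
            off = [a for a in range(n) if a not in (S or [])]
            if off and np.any(u[off] > 1e-10 * max(1.0, np.abs(u).max())):
                continue
            if not any(np.allclose(r, q, atol=1e-8) for q in out):
                out.append(r)
    return out


def rate_fixed_point(net: MeanFieldNetwork, stim, cfg: RateModelConfig,
                     r0=None) -> tuple[np.ndarray, bool]:
    """Locate a stable fixed point of the rate model.

    Rectified-linear models are solved exactly by support enumeration
    when feasible (picking the dynamically reachable solution via a short
    integration); otherwise integration to tolerance is used.
    """
    X = _as_stim(stim, net.n)
    s = _coupling_scale(net, cfg)
    if cfg.f_kind == "rectified_linear" and net.n <= 12:
        cands = _linear_fixed_points(net, X, cfg.gain_Hz_per_mV, s)
        g = cfg.gain_Hz_per_mV

        def _stable(q):
            S = np.flatnonzero(q > 0)
            if S.size == 0:
                return True
            eig = np.linalg.eigvals(g * s * net.W[np.ix_(S, S)])
            return bool(np.max(eig.real) < 1.0)

        stable = [q for q in cands if _stable(q)]
        if len(stable) == 1:
            return stable[0], True
        traj = integrate_rate(net, stim,
                              replace(cfg, T_ms=min(cfg.T_ms, 500 * cfg.tau_ms)),
                              r0=r0)
        pool = stable or cands
        if pool:
            best = min(pool, key=lambda q: np.linalg.norm(q - traj.final_rates))
            if np.linalg.norm(best - traj.final_rates) <= 1e-3 * max(1.0, np.linalg.norm(best)):
                return best, True
        return traj.final_rates, traj.converged and not traj.diverged
    traj = integrate_rate(net, stim, cfg, r0=r0)
    r_est = traj.final_rates
    ok = traj.converged and not traj.diverged
    # Newton polish: stiff strongly-coupled systems leave forward Euler with
    # a tiny stable step; the smooth root problem is better conditioned.
    polished = _polish_root(net, X, s, cfg, r_est)
    if polished is not None:
        return polished, True
    return r_est, ok


def _f_inverse(r: np.ndarray, cfg: RateModelConfig) -> np.ndarray:
    """Inverse of the f-I curve on strictly positive rates."""
    if cfg.f_kind == "rectified_linear":
        return r / cfg.gain_Hz_per_mV
    if cfg.f_kind == "rectified_square":
        return np.sqrt(r / cfg.k_Hz_per_mV2)
    r = np.clip(r, 1e-12, cfg.M_Hz * (1 - 1e-12))
    return cfg.I0_mV * np.log(r / (cfg.M_Hz - r))


def _boundary_fixed_point(net: MeanFieldNetwork, X: np.ndarray, s: float,
                          cfg: RateModelConfig, r_init: np.ndarray,
                          tol: float = 1e-9) -> np.ndarray | None:
    """Active-set solve of r = f(s(Wr+X)) for strongly coupled systems.

    On the active set the fixed point satisfies
    ``(W r + X)_S = f^{-1}(r_S) / s`` — a well-conditioned equation even
    when direct iteration of the steep f is hopeless.  Off the set,
    rates follow explicitly.  The active set is taken from ``r_init``
    and the result is verified before being returned.
    """
    from scipy.optimize import root as _root
    n = net.n
    active = r_init > max(1e-6, 1e-6 * float(np.max(r_init, initial=0.0)))
    if not active.any():
        r = _f(s * X, cfg)
        return r if np.all(np.abs(r - _f(s * (net.W @ r + X), cfg))
                           <= 1e-6) else None
    S = np.flatnonzero(active)
    off = np.flatnonzero(~active)
    r = r_init.copy()
    for _ in range(8):
        def G(rS):
            rr = r.copy()
            rr[S] = rS
            return (net.W @ rr + X)[S] - _f_inverse(rS, cfg) / s
        sol = _root(G, r[S], method="hybr")
        if not sol.success or np.any(sol.x <= 0):
            return None
        r[S] = sol.x
        if off.size:
            r[off] = _f(s * (net.W @ r + X)[off], cfg)
    resid = np.abs(r - _f(s * (net.W @ r + X), cfg))
    if np.all(resid <= 1e-6 * max(1.0, float(np.abs(r).max()))):
        return r
    return None


def _polish_root(net: MeanFieldNetwork, X: np.ndarray, s: float,
                 cfg: RateModelConfig, r0: np.ndarray) -> np.ndarray | None:
    """Solve r = f(s(Wr+X)) by a root finder seeded at ``r0``; None on failure."""
    from scipy.optimize import root as _root

    def F(r):
        return r - _f(s * (net.W @ r + X), cfg)

    sol = _root(F, np.maximum(r0, 0.0), method="hybr")
    if sol.success and np.all(sol.x >= -1e-9) and \
            np.linalg.norm(F(sol.x)) <= 1e-8 * max(1.0, np.abs(sol.x).max()):
        return np.maximum(sol.x, 0.0)
    return None


@dataclass
class ISNReport:
    """Stability and inhibitory-stabilization classification.

    A network is an ISN when the full fixed point is stable but the
    excitatory sub-circuit alone (inhibitory rows and columns removed
    from the Jacobian) is unstable.
    """

    fixed_point: np.ndarray
    max_eig_full: float
    max_eig_exc: float
    stable: bool
    isn: bool | None
    converged: bool = True
    eig_threshold: float = 1e-8


def _jacobian(net: MeanFieldNetwork, r: np.ndarray, X: np.ndarray, s: float,
              cfg: RateModelConfig) -> np.ndarray:
    u = s * (net.W @ r + X)
    D = _local_gain(u, cfg)
    return (-np.eye(net.n) + D[:, None] * (s * net.W)) / cfg.tau_ms


def classify_isn(net: MeanFieldNetwork, stim, cfg: RateModelConfig,
                 exc_idx=None, r0=None) -> ISNReport:
    """Classify the SSN fixed point as ISN or non-ISN.

    ``exc_idx`` selects the excitatory rows/columns; defaults to the
    spec's excitatory populations or, absent a spec, all but the last.
    """
    X = _as_stim(stim, net.n)
    s = _coupling_scale(net, cfg)
    if cfg.f_kind != "rectified_square":
        cfg = replace(cfg, f_kind="rectified_square")
    r, ok = rate_fixed_point(net, stim, cfg, r0=r0)
    if exc_idx is None:
        if net.spec is not None:
            exc_idx = [k for k, i in enumerate(net.spec.recurrent)
                       if net.spec.signs[i] == "e"]
        else:
            exc_idx = list(range(net.n - 1))
    J = _jacobian(net, r, X, s, cfg)
    eig_full = float(np.max(np.linalg.eigvals(J).real))
    sub = J[np.ix_(exc_idx, exc_idx)]
    eig_exc = float(np.max(np.linalg.eigvals(sub).real)) if len(exc_idx) else -np.inf
    thr = 1e-8
    stable = eig_full < thr
    isn = (eig_exc > thr) if stable else None
    return ISNReport(fixed_point=r, max_eig_full=eig_full, max_eig_exc=eig_exc,
                     stable=stable, isn=isn, converged=ok, eig_threshold=thr)


def isn_sweep(net: MeanFieldNetwork, rx1: float, rx2_values, cfg: RateModelConfig):
    """Sweep the second external rate and classify ISN state at each point.

    The fixed point found at each sweep value seeds the next, following
    the branch continuously.
    """
    from .meanfield import external_drive
    reports = []
    r0 = None
    for rx2 in rx2_values:
        stim = external_drive(net, [rx1, rx2])
        rep = classify_isn(net, stim, cfg, r0=r0)
        r0 = np.maximum(rep.fixed_point, 0.0)
        reports.append(rep)
    return reports


def limit_convergence_study(net: MeanFieldNetwork, stim, cfg: RateModelConfig,
                            JK_list) -> dict:
    """Distance of rate-model fixed points to the semi-balanced solution.

    For each coupling scale in ``JK_list`` (mV/Hz), the fixed point of
    the rate model is computed and its Euclidean distance to the
    threshold-linear solution is recorded.  In the strong-coupling limit
    the distance shrinks; populations silenced in the limit solution
    converge to zero rate.
    """
    X = _as_stim(stim, net.n)
    target = semibalanced_rates(net, X)
    if not target.ok:
        raise ValueError("no semi-balanced solution exists for this stimulus")
    rows = []
    r_prev = None
    for JK in sorted(float(j) for j in JK_list):
        c = replace(cfg, JK_mVHz=JK)
        if r_prev is None or cfg.f_kind == "rectified_linear":
            r, ok = rate_fixed_point(net, stim, c)
        else:
            # continuation in the coupling scale: the previous fixed point
            # seeds an active-set boundary-layer solve, avoiding
            # ever-stiffer explicit integration
            r = _boundary_fixed_point(net, X, _coupling_scale(net, c), c,
                                      r_prev)
            ok = r is not None
            if r is None:
                r, ok = rate_fixed_point(net, stim, c, r0=r_prev)
        r_prev = r
        rows.append({"JK_mVHz": JK,
                     "rates_Hz": r,
                     "distance_Hz": float(np.linalg.norm(r - target.r)),
                     "converged": bool(ok)})
    return {"target_Hz": target.r, "rows": rows}
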