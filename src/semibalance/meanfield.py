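"""Mean-field construction and fixed-point solvers for balanced and
semi-balanced excitatory-inhibitory networks.

A network of ``n`` recurrent populations driven by external populations is
summarized by an effective connectivity matrix ``W`` whose entry ``(a, b)``
is the mean connection strength times the mean in-degree from population
``b`` to ``a``.  With strong coupling, population rates ``r`` settle into
one of two regimes:

* the *balanced* state, where excitation and inhibition cancel for every
  population and ``r = -W^{-1} X`` (valid only when all entries are
  positive), or
* the *semi-balanced* state, where populations may receive excess
  inhibition (and are silenced) but never excess excitation; rates then
  satisfy the threshold-linear fixed-point equation ``r = [W r + X + r]^+``.

Units convention: rates in Hz, ``W`` entries in mV/Hz, stimuli ``X`` in mV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSpec",
    "MeanFieldNetwork",
    "StimulusVector",
    "SemiBalancedSolution",
    "ConditionReport",
    "build_meanfield",
    "external_drive",
    "balanced_rates",
    "semibalanced_rates",
    "verify_semibalance",
    "scale_invariance_check",
    "breaking_stimulus",
]

#: Default boundary tolerance (mV) for support / residual tie-breaking.
DEFAULT_TOL = 1e-8

RECURRENT_SIGNS = ("e", "i")
ALL_SIGNS = ("e", "i", "x")


@dataclass
class PopulationSpec:
    """Block-random network specification.

    Parameters
    ----------
    names
        Labels for all populations, recurrent first, external last.
    sizes
        Neurons per population, same order as ``names``.
    signs
        One of ``'e'`` (excitatory), ``'i'`` (inhibitory), ``'x'``
        (external) per population.  External populations must come after
        all recurrent ones and receive no recurrent input.
    j
        ``(n_rec, n_pop)`` array of connection-strength coefficients
        ``j_ab`` in mV/Hz (signed; zero where the block is absent).  Rows
        index postsynaptic recurrent populations, columns presynaptic
        populations (recurrent then external).
    p
        ``(n_rec, n_pop)`` array of connection probabilities in [0, 1].
    """

    names: list[str]
    sizes: np.ndarray
    signs: list[str]
    j: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.j = np.asarray(self.j, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.validate()

    # -- derived layout -------------------------------------------------
    @property
    def n_pop(self) -> int:
        return len(self.names)

    @property
    def recurrent(self) -> list[int]:
        return [k for k, s in enumerate(self.signs) if s in RECURRENT_SIGNS]

    @property
    def external(self) -> list[int]:
        return [k for k, s in enumerate(self.signs) if s == "x"]

    @property
    def n_rec(self) -> int:
        return len(self.recurrent)

    @property
    def N(self) -> int:
        """Total recurrent neuron count."""
        return int(self.sizes[self.recurrent].sum())

    def validate(self) -> None:
        n_rec, n_pop = self.n_rec, self.n_pop
        if not (len(self.sizes) == len(self.signs) == n_pop):
            raise ValueError("names, sizes and signs must have equal length")
        for s in self.signs:
            if s not in ALL_SIGNS:
                raise ValueError(f"unknown population sign {s!r}")
        if self.signs != sorted(self.signs, key=lambda s: s == "x"):
            raise ValueError("external populations must come after recurrent ones")
        if np.any(self.sizes <= 0):
            raise ValueError("population sizes must be positive")
        if self.j.shape != (n_rec, n_pop) or self.p.shape != (n_rec, n_pop):
            raise ValueError(
                f"j and p must have shape ({n_rec}, {n_pop}); got "
                f"{self.j.shape} and {self.p.shape}"
            )
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        # Dale's law: each presynaptic column carries a single sign.
        for b in range(n_pop):
            col = self.j[:, b]
            sign = self.signs[b]
            if sign in ("e", "x") and np.any(col < 0):
                raise ValueError(
                    f"Dale violation: column {self.names[b]!r} is "
                    "excitatory/external but has negative entries"
                )
            if sign == "i" and np.any(col > 0):
                raise ValueError(
                    f"Dale violation: column {self.names[b]!r} is inhibitory "
                    "but has positive entries"
                )


@dataclass
class MeanFieldNetwork:
    """Effective mean-field matrices of a :class:`PopulationSpec`.

    ``W`` and ``Wx`` are the *unnormalized* effective matrices
    ``J_ab * K_ab = j_ab * p_ab * N_b / N**s`` (mV/Hz).  The coupling
    scale ``JK`` (mean magnitude over nonzero blocks) is reported for
    diagnostics; it cancels in the balanced and semi-balanced fixed-point
    equations, so rates computed from ``W`` do not depend on it.
    """

    W: np.ndarray
    Wx: np.ndarray
    JK: float
    spec: PopulationSpec | None = None
    rec_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        self.Wx = np.asarray(self.Wx, dtype=float)
        if not self.rec_names:
            self.rec_names = [f"p{k}" for k in range(self.W.shape[0])]

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class StimulusVector:
    """External drive ``X`` (mV) per recurrent population.

    Either ``X`` is given directly, or it is derived from external
    population rates ``rx`` (Hz) via ``X = Wx @ rx``.
    """

    X: np.ndarray
    rx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).ravel()


def external_drive(net: MeanFieldNetwork, rx) -> StimulusVector:
    """Stimulus vector ``X = Wx @ rx`` from external population rates."""
    rx = np.asarray(rx, dtype=float).ravel()
    if net.Wx.size == 0:
        raise ValueError("network has no external populations")
    if net.Wx.shape[1] != rx.size:
        raise ValueError(
            f"rx has length {rx.size}, expected {net.Wx.shape[1]}"
        )
    return StimulusVector(X=net.Wx @ rx, rx=rx)


def _as_stim(stim, n: int) -> np.ndarray:
    X = stim.X if isinstance(stim, StimulusVector) else np.asarray(stim, float).ravel()
    if X.size != n:
        raise ValueError(f"stimulus has length {X.size}, expected {n}")
    return X


def build_meanfield(spec: PopulationSpec, weight_scaling: float = 0.5) -> MeanFieldNetwork:
    """Construct mean-field matrices from a population specification.

    ``W[a, b] = j_ab * p_ab * N_b / N**weight_scaling``.  The default
    exponent 1/2 corresponds to the classical strong-coupling scaling
    ``J ~ 1/sqrt(K)`` and reproduces realistic postsynaptic-potential
    amplitudes for the bundled presets.
    """
    spec.validate()
    rec, ext = spec.recurrent, spec.external
    scale = float(spec.N) ** weight_scaling
    full = spec.j * spec.p * spec.sizes[None, :] / scale
    W = full[:, rec]
    Wx = full[:, ext] if ext else np.zeros((len(rec), 0))
    nz = np.abs(full) > 0
    JK = float(np.abs(full[nz]).mean()) if nz.any() else 0.0
    return MeanFieldNetwork(
        W=W, Wx=Wx, JK=JK, spec=spec,
        rec_names=[spec.names[k] for k in rec],
    )


class SingularNetworkError(np.linalg.LinAlgError):
    """Raised when the effective matrix is numerically singular."""

    def __init__(self, cond: float):
        self.cond = cond
        super().__init__(
            f"effective connectivity matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g})"
        )


def balanced_rates(net: MeanFieldNetwork, stim) -> np.ndarray:
    """Balanced-state rates ``r = -W^{-1} X``.

    No positivity is enforced; negative entries signal that the stimulus
    breaks the classical balanced state and the semi-balanced solver
    should be consulted instead.
    """
    X = _as_stim(stim, net.n)
    cond = np.linalg.cond(net.W)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularNetworkError(cond)
    return -np.linalg.solve(net.W, X)


@dataclass
class SemiBalancedSolution:
    """A solution of ``r = [W r + X + r]^+`` with bookkeeping.

    ``status`` is ``'unique'`` when exactly one support admits a valid
    solution, ``'multiple'`` when several do (all are kept in
    ``all_solutions``), and ``'none'`` when no support works.
    """

    r: np.ndarray
    support: tuple[int, ...]
    residual: np.ndarray
    status: str
    all_solutions: list[np.ndarray] = field(default_factory=list)
    tol: float = DEFAULT_TOL

    @property
    def ok(self) -> bool:
        return self.status in ("unique", "multiple")


@dataclass
class ConditionReport:
    """Per-population verdicts of the three semi-balance conditions.

    Condition 1: ``[W r + X]_a <= 0`` (no excess excitation).
    Condition 2: ``[W r + X]_a < 0  =>  r_a = 0`` (excess inhibition
    silences).  Condition 3: ``r_a >= 0``.
    """

    cond1: np.ndarray
    cond2: np.ndarray
    nonneg: np.ndarray
    residual: np.ndarray
    tol: float

    @property
    def verdict(self) -> bool:
        return bool(self.cond1.all() and self.cond2.all() and self.nonneg.all())


def verify_semibalance(net: MeanFieldNetwork, stim, r, tol: float = DEFAULT_TOL) -> ConditionReport:
    """Check the semi-balance conditions for a candidate rate vector.

    By the equivalence theorem, the verdict is true exactly when ``r``
    solves the threshold-linear fixed-point equation within ``tol``.
    """
    X = _as_stim(stim, net.n)
    r = np.asarray(r, dtype=float).ravel()
    if r.size != net.n:
        raise ValueError(f"rate vector has length {r.size}, expected {net.n}")
    resid = net.W @ r + X
    cond1 = resid <= tol
    cond2 = (resid >= -tol) | (np.abs(r) <= tol)
    nonneg = r >= -tol
    return ConditionReport(cond1=cond1, cond2=cond2, nonneg=nonneg,
                           residual=resid, tol=tol)


def _solve_support(W: np.ndarray, X: np.ndarray, S: tuple[int, ...]) -> np.ndarray | None:
    """Solve ``[W r + X]_S = 0`` with ``r = 0`` off ``S``; None if singular."""
    n = len(X)
    r = np.zeros(n)
    if S:
        sub = W[np.ix_(S, S)]
        cond = np.linalg.cond(sub)
        if not np.isfinite(cond) or cond > 1e12:
            return None
        r[list(S)] = -np.linalg.solve(sub, X[list(S)])
    return r


def semibalanced_rates(
    net: MeanFieldNetwork,
    stim,
    tol: float = DEFAULT_TOL,
    max_enumerate: int = 20,
) -> SemiBalancedSolution:
    """Solve the semi-balanced fixed-point equation ``r = [W r + X + r]^+``.

    For ``n <= max_enumerate`` populations, all ``2^n`` candidate supports
    are enumerated exactly: for each support ``S`` the linear subsystem
    ``[W r + X]_S = 0`` is solved with ``r = 0`` off ``S``, and the
    candidate is accepted when all three semi-balance conditions hold
    within ``tol``.  Larger systems fall back to damped fixed-point
    iteration, whose answer is verified before being accepted.
    """
    X = _as_stim(stim, net.n)
    n = net.n
    if n <= max_enumerate:
        solutions: list[np.ndarray] = []
        supports: list[tuple[int, ...]] = []
        # largest supports first: when the balanced solution is positive it
        # is found immediately and becomes the primary solution
        for size in range(n, -1, -1):
            for S in itertools.combinations(range(n), size):
                r = _solve_support(net.W, X, S)
                if r is None:
                    continue
                rep = verify_semibalance(net, X, r, tol)
                if rep.verdict:
                    # skip duplicates (boundary supports give the same r)
                    if any(np.allclose(r, q, atol=10 * tol) for q in solutions):
                        continue
                    solutions.append(np.maximum(r, 0.0))
                    supports.append(S)
        if not solutions:
            return SemiBalancedSolution(
                r=np.full(n, np.nan), support=(), residual=np.full(n, np.nan),
                status="none", tol=tol)
        status = "unique" if len(solutions) == 1 else "multiple"
        r = solutions[0]
        return SemiBalancedSolution(
            r=r, support=tuple(np.flatnonzero(r > tol)),
            residual=net.W @ r + X, status=status,
            all_solutions=solutions, tol=tol)
    # iterative scheme for large n
    r = np.maximum(-np.linalg.pinv(net.W) @ X, 0.0)
    damping, max_iter = 0.1, 100_000
    for _ in range(max_iter):
        r_new = r + damping * (np.maximum(net.W @ r + X + r, 0.0) - r)
        if np.linalg.norm(r_new - r) <= 1e-10 * max(1.0, np.linalg.norm(r)):
            r = r_new
            break
        r = r_new
    rep = verify_semibalance(net, X, r, max(tol, 1e-6))
    if not rep.verdict:
        return SemiBalancedSolution(
            r=np.full(n, np.nan), support=(), residual=np.full(n, np.nan),
            status="none", tol=tol)
    return SemiBalancedSolution(
        r=r, support=tuple(np.flatnonzero(r > tol)),
        residual=net.W @ r + X, status="unique",
        all_solutions=[r], tol=tol)


def scale_invariance_check(net: MeanFieldNetwork, stim, r, scales=(0.01, 1.0, 100.0),
                           tol: float = 1e-6) -> bool:
    """All-or-none scale invariance of the fixed-point equation.

    ``[W r + X + c r]^+ = c r`` holds either for every ``c > 0`` or for no
    ``c > 0``.  Returns True when the tested scales agree unanimously
    (all satisfied or none satisfied), False when they disagree — which
    would contradict the scale-invariance theorem.
    """
    X = _as_stim(stim, net.n)
    r = np.asarray(r, dtype=float).ravel()
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    results = []
    for c in scales:
        lhs = np.maximum(net.W @ r + X + c * r, 0.0)
        scale = max(1.0, float(np.abs(c * r).max(initial=0.0)))
        results.append(bool(np.all(np.abs(lhs - c * r) <= tol * scale)))
    return all(results) or not any(results)


def breaking_stimulus(net: MeanFieldNetwork, mix=None) -> StimulusVector:
    """Construct a strictly positive stimulus that breaks the balanced state.

    For any Dale-compliant nonsingular ``W`` with at least one excitatory
    column, choose ``v`` negative on excitatory indices and positive on
    inhibitory indices; then ``X = -W v`` is strictly positive and the
    balanced solution ``-W^{-1} X = v`` has a negative (excitatory) entry.

    Parameters
    ----------
    mix
        Optional positive magnitudes for ``v`` (length ``n``); defaults
        to all ones.
    """
    W = net.W
    n = net.n
    col_pos = np.array([np.all(W[:, b] >= 0) and np.any(W[:, b] > 0) for b in range(n)])
    col_neg = np.array([np.all(W[:, b] <= 0) and np.any(W[:, b] < 0) for b in range(n)])
    for b in range(n):
        if not (col_pos[b] or col_neg[b]):
            raise ValueError(
                f"column {b} is zero or violates Dale's law; the "
                "balance-breaking construction requires signed nonzero columns")
    if not col_pos.any():
        raise ValueError("construction requires at least one excitatory column")
    mag = np.ones(n) if mix is None else np.abs(np.asarray(mix, dtype=float).ravel())
    v = np.where(col_pos, -mag, mag)
    X = -W @ v
    bad = np.flatnonzero(X <= 0)
    if bad.size:
        raise ValueError(
            f"constructed stimulus non-positive at rows {bad.tolist()}; "
            "theorem hypotheses violated")
    out = StimulusVector(X=X)
    out.v = v  # the engineered balanced solution, for inspection
    return out
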