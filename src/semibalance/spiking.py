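"""Adaptive exponential integrate-and-fire network simulator.

Networks of adaptive EIF neurons with current-based or conductance-based
exponential synapses, Poisson external drive, per-neuron DC stimuli
(optionally on a piecewise-constant schedule), homeostatic inhibitory
spike-timing-dependent plasticity (iSTDP), and recording of spikes,
membrane traces and time-binned input-current decompositions.

Membrane dynamics (leak-normalized, everything in mV and ms):

    tau_m dV/dt = -(V - E_L) + D_T exp((V - V_T)/D_T) - w + I(t)
    tau_w dw/dt = -w

with reset to ``V_re`` and adaptation increment ``B`` on threshold
crossing at ``V_th``, and a hard floor at ``V_lb``.  Synaptic input is a
sum of exponential kernels ``exp(-t/tau_b)/tau_b`` weighted by the
per-pair weights ``j_ab / N**s`` (current model) or drives conductances
multiplying ``(V - E_e)`` / ``(V - E_i)`` (conductance model, with
weights rescaled by the reversal-potential distances from ``V_0``).

Update order within a step: synaptic/trace decay, membrane update,
threshold test and reset, spike propagation, plasticity.  Spike trains
are bit-exact reproducible under a fixed seed and step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .meanfield import PopulationSpec

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "IstdpConfig",
    "WeightRealization",
    "SimulationRecord",
    "sample_connectivity",
    "rheobase",
    "simulate",
    "estimate_rates",
    "decompose_currents",
    "psp_amplitudes",
]


@dataclass
class NeuronParams:
    """Adaptive EIF parameters (mV, ms)."""

    tau_m: float = 15.0
    E_L: float = -72.0
    D_T: float = 1.0
    V_T: float = -55.0
    V_th: float = 0.0
    V_re: float = -72.0
    V_lb: float = -85.0
    B: float = 0.75
    tau_w: float = 200.0

    def __post_init__(self) -> None:
        if not (self.V_lb < self.V_re <= self.E_L < self.V_T < self.V_th):
            raise ValueError("require V_lb < V_re <= E_L < V_T < V_th")


@dataclass
class SynapseParams:
    """Synapse model and kinetics.

    ``model`` is ``'current'`` or ``'conductance'``.  Time constants are
    per presynaptic class (excitatory / inhibitory / external).  For the
    conductance model, weights are rescaled by ``(E_e - V0)`` and
    ``(E_i - V0)`` so the same effective matrices predict rates.
    """

    model: str = "current"
    tau_e: float = 8.0
    tau_i: float = 4.0
    tau_x: float = 10.0
    E_e: float = 0.0
    E_i: float = -75.0
    V0: float = -55.0

    def __post_init__(self) -> None:
        if self.model not in ("current", "conductance"):
            raise ValueError("model must be 'current' or 'conductance'")
        if min(self.tau_e, self.tau_i, self.tau_x) <= 0:
            raise ValueError("synaptic time constants must be positive")
        if not (self.E_i < self.V0 < self.E_e):
            raise ValueError("require E_i < V0 < E_e")


@dataclass
class IstdpConfig:
    """Homeostatic inhibitory STDP.

    Spike traces ``x_j`` decay with ``tau_x`` and jump by one on the
    owner's spikes.  On each excitatory spike, incoming i->e weights
    change by ``-eta * x_i(pre)``; on each inhibitory spike, outgoing
    weights change by ``-eta * (x_e(post) - alpha)``.  The implied target
    excitatory rate is ``alpha / (2 * tau_x)`` (5 Hz at the defaults).
    Weights are clipped at zero so they cannot change sign.
    """

    tau_x: float = 200.0
    alpha: float = 2.0
    eta: float | None = None  # weight units (mV*ms) per event; see simulate()
    enabled: bool = True

    @property
    def target_rate_Hz(self) -> float:
        return self.alpha / (2.0 * self.tau_x / 1000.0)


@dataclass
class WeightRealization:
    """Sampled neuron-to-neuron connectivity in out-adjacency (CSR) form.

    Weights are stored in mV*ms (``1000 * j_ab / N**s``); recurrent and
    feedforward synapses are kept separately.  ``ie_*`` arrays index the
    i->e synapses both by presynaptic inhibitory neuron (implicitly, via
    the out-adjacency) and by postsynaptic excitatory neuron (explicitly)
    so plasticity can address them from either side.
    """

    spec: PopulationSpec
    seed: int
    weight_scaling: float
    pop_of: np.ndarray        # recurrent neuron -> recurrent population idx
    is_exc: np.ndarray        # recurrent neuron -> bool
    xpop_of: np.ndarray       # external neuron -> external population idx
    out_ptr: np.ndarray
    out_tgt: np.ndarray
    out_w: np.ndarray
    xout_ptr: np.ndarray
    xout_tgt: np.ndarray
    xout_w: np.ndarray
    ie_in_ptr: np.ndarray     # per recurrent neuron (nonempty only for e)
    ie_in_pos: np.ndarray     # positions into out_w
    ie_in_pre: np.ndarray     # presynaptic (inhibitory) neuron ids

    @property
    def n_rec(self) -> int:
        return self.pop_of.size

    @property
    def n_ext(self) -> int:
        return self.xpop_of.size

    @property
    def ie_weights(self) -> np.ndarray:
        """Current i->e weights (mV*ms), in the reverse-index order."""
        return self.out_w[self.ie_in_pos]

    def set_ie_weights(self, weights: np.ndarray) -> None:
        """Install i->e weights (e.g. the outcome of an iSTDP run)."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.ie_in_pos.size,):
            raise ValueError("weight vector must match the i->e synapse count")
        if np.any(weights > 0):
            raise ValueError("i->e weights must be nonpositive")
        self.out_w[self.ie_in_pos] = weights


def sample_connectivity(spec: PopulationSpec, seed: int = 0,
                        weight_scaling: float = 0.5) -> WeightRealization:
    """Draw a random weight matrix: Bernoulli(p_ab) per ordered pair.

    Present synapses have weight ``j_ab / N**s`` (stored in mV*ms).
    Reproducible under ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rec, ext = spec.recurrent, spec.external
    rec_sizes = spec.sizes[rec]
    ext_sizes = spec.sizes[ext]
    n_rec = int(rec_sizes.sum())
    scale = float(spec.N) ** weight_scaling

    pop_of = np.repeat(np.arange(len(rec)), rec_sizes).astype(np.int64)
    is_exc = np.array([spec.signs[rec[a]] == "e" for a in pop_of], dtype=bool)
    xpop_of = np.repeat(np.arange(len(ext)), ext_sizes).astype(np.int64)
    rec_start = np.concatenate([[0], np.cumsum(rec_sizes)])

    def _build(pre_sizes, pre_pops, col_offset):
        """Out-adjacency over all pre neurons of the given group."""
        ptr = [0]
        tgt_chunks, w_chunks = [], []
        for bi, nb in enumerate(pre_sizes):
            # per-(post block) parameters for this pre population
            blocks = []
            for ai in range(len(rec)):
                p = spec.p[ai, col_offset + bi]
                j = spec.j[ai, col_offset + bi]
                if p > 0 and j != 0:
                    blocks.append((ai, p, 1000.0 * j / scale))
            for _ in range(nb):
                t_parts, w_parts = [], []
                for ai, p, wgt in blocks:
                    na = rec_sizes[ai]
                    m = rng.binomial(na, p)
                    if m:
                        idx = rng.choice(na, size=m, replace=False)
                        t_parts.append(rec_start[ai] + np.sort(idx))
                        w_parts.append(np.full(m, wgt))
                if t_parts:
                    tgt_chunks.append(np.concatenate(t_parts))
                    w_chunks.append(np.concatenate(w_parts))
                    ptr.append(ptr[-1] + tgt_chunks[-1].size)
                else:
                    ptr.append(ptr[-1])
        tgt = (np.concatenate(tgt_chunks) if tgt_chunks else np.empty(0, int))
        w = (np.concatenate(w_chunks) if w_chunks else np.empty(0))
        return (np.asarray(ptr, dtype=np.int64), tgt.astype(np.int64),
                np.asarray(w, dtype=np.float64))

    out_ptr, out_tgt, out_w = _build(rec_sizes, rec, 0)
    xout_ptr, xout_tgt, xout_w = _build(ext_sizes, ext, len(rec))

    # reverse index of i->e synapses by postsynaptic excitatory neuron
    pre_of_syn = np.repeat(np.arange(n_rec), np.diff(out_ptr))
    mask = (~is_exc[pre_of_syn]) & is_exc[out_tgt]
    pos = np.flatnonzero(mask)
    order = np.argsort(out_tgt[pos], kind="stable")
    pos = pos[order]
    tgt_sorted = out_tgt[pos]
    ie_in_ptr = np.zeros(n_rec + 1, dtype=np.int64)
    np.add.at(ie_in_ptr, tgt_sorted + 1, 1)
    ie_in_ptr = np.cumsum(ie_in_ptr)
    return WeightRealization(
        spec=spec, seed=seed, weight_scaling=weight_scaling,
        pop_of=pop_of, is_exc=is_exc, xpop_of=xpop_of,
        out_ptr=out_ptr, out_tgt=out_tgt, out_w=out_w,
        xout_ptr=xout_ptr, xout_tgt=xout_tgt, xout_w=xout_w,
        ie_in_ptr=ie_in_ptr, ie_in_pos=pos.astype(np.int64),
        ie_in_pre=pre_of_syn[pos].astype(np.int64),
    )


def rheobase(params: NeuronParams | None = None) -> float:
    """Minimal constant input (mV) abolishing the EIF resting state.

    The resting nullcline ``I = (V - E_L) - D_T exp((V - V_T)/D_T)`` is
    maximized at ``V = V_T``, giving ``(V_T - E_L) - D_T``.
    """
    p = params or NeuronParams()
    return (p.V_T - p.E_L) - p.D_T


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_kernel(seed, n_steps, dt,
                # neuron params
                tau_m, E_L, D_T, V_T, V_th, V_re, V_lb, B, tau_w,
                # synapse params: model flag 0=current 1=conductance
                model, tau_e, tau_i, tau_x_syn, E_e, E_i,
                # connectivity
                is_exc, out_ptr, out_tgt, out_w,
                xout_ptr, xout_tgt, xout_w,
                # external drive
                x_rates_per_ms,  # per external neuron
                dc_times, dc_vals,  # schedule: epochs x n
                # plasticity
                plast_on, eta, alpha, tau_x_tr, ie_in_ptr, ie_in_pos, ie_in_pre,
                # recording
                trace_idx, trace_stride, bin_steps,
                spike_cap):
    n = is_exc.size
    nx = x_rates_per_ms.size
    V = np.full(n, E_L)
    w_ad = np.zeros(n)
    s_e = np.zeros(n)
    s_i = np.zeros(n)
    s_x = np.zeros(n)
    x_tr = np.zeros(n)  # plasticity traces (per recurrent neuron)

    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    dec_x = np.exp(-dt / tau_x_syn)
    dec_w = np.exp(-dt / tau_w)
    dec_tr = np.exp(-dt / tau_x_tr)

    spk_id = np.empty(spike_cap, dtype=np.int64)
    spk_t = np.empty(spike_cap, dtype=np.float64)
    n_spk = 0
    overflow = False

    n_tr = trace_idx.size
    n_tr_steps = n_steps // trace_stride + 1
    traces = np.zeros((n_tr, n_tr_steps))
    tr_k = 0

    n_bins = (n_steps + bin_steps - 1) // bin_steps
    Ebin = np.zeros((n, n_bins))
    Ibin = np.zeros((n, n_bins))
    Gebin = np.zeros((n, n_bins)) if model == 1 else np.zeros((1, 1))
    Gibin = np.zeros((n, n_bins)) if model == 1 else np.zeros((1, 1))
    cnt = np.zeros(n_bins)
    wie_mean = np.zeros(n_bins)

    spiked = np.empty(n, dtype=np.int64)
    np.random.seed(seed)

    epoch = 0
    n_epochs = dc_times.size

    for it in range(n_steps):
        t = it * dt
        while epoch + 1 < n_epochs and t >= dc_times[epoch + 1]:
            epoch += 1
        b = it // bin_steps

        # --- external Poisson spikes ---
        for k in range(nx):
            if np.random.random() < x_rates_per_ms[k]:
                for idx in range(xout_ptr[k], xout_ptr[k + 1]):
                    s_x[xout_tgt[idx]] += xout_w[idx] / tau_x_syn

        # --- decay ---
        for j in range(n):
            s_e[j] *= dec_e
            s_i[j] *= dec_i
            s_x[j] *= dec_x
            w_ad[j] *= dec_w
            if plast_on:
                x_tr[j] *= dec_tr

        # --- membrane update, threshold ---
        n_now = 0
        for j in range(n):
            if model == 0:
                I = s_e[j] + s_i[j] + s_x[j] + dc_vals[epoch, j]
                Ecur = s_e[j] + s_x[j] + max(dc_vals[epoch, j], 0.0)
                Icur = s_i[j] + min(dc_vals[epoch, j], 0.0)
            else:
                Ecur = -(s_e[j] + s_x[j]) * (V[j] - E_e) + max(dc_vals[epoch, j], 0.0)
                Icur = -s_i[j] * (V[j] - E_i) + min(dc_vals[epoch, j], 0.0)
                I = Ecur + Icur
                Gebin[j, b] += s_e[j] + s_x[j]
                Gibin[j, b] += s_i[j]
            Ebin[j, b] += Ecur
            Ibin[j, b] += Icur
            ex = (V[j] - V_T) / D_T
            if ex > 30.0:
                ex = 30.0
            V[j] += (dt / tau_m) * (-(V[j] - E_L) + D_T * np.exp(ex) - w_ad[j] + I)
            if V[j] < V_lb:
                V[j] = V_lb
            if V[j] >= V_th:
                V[j] = V_re
                w_ad[j] += B
                spiked[n_now] = j
                n_now += 1
                if n_spk < spike_cap:
                    spk_id[n_spk] = j
                    spk_t[n_spk] = t + dt
                    n_spk += 1
                else:
                    overflow = True
        cnt[b] += 1.0

        # --- propagate + plasticity ---
        for m in range(n_now):
            k = spiked[m]
            exc = is_exc[k]
            for idx in range(out_ptr[k], out_ptr[k + 1]):
                tgt = out_tgt[idx]
                if exc:
                    s_e[tgt] += out_w[idx] / tau_e
                else:
                    s_i[tgt] += out_w[idx] / tau_i
                    if plast_on and is_exc[tgt]:
                        # pre-inhibitory spike: dJ = -eta * (x_e(post) - alpha)
                        wnew = out_w[idx] - eta * (x_tr[tgt] - alpha)
                        out_w[idx] = wnew if wnew < 0.0 else 0.0
            if plast_on:
                x_tr[k] += 1.0
                if exc:
                    # post-excitatory spike: dJ = -eta * x_i(pre)
                    for q in range(ie_in_ptr[k], ie_in_ptr[k + 1]):
                        pos = ie_in_pos[q]
                        wnew = out_w[pos] - eta * x_tr[ie_in_pre[q]]
                        out_w[pos] = wnew if wnew < 0.0 else 0.0

        # --- traces & weight monitor ---
        if it % trace_stride == 0 and n_tr > 0:
            for q in range(n_tr):
                traces[q, tr_k] = V[trace_idx[q]]
            tr_k += 1
        if plast_on and it % bin_steps == 0 and ie_in_pos.size > 0:
            acc = 0.0
            for q in range(ie_in_pos.size):
                acc += out_w[ie_in_pos[q]]
            wie_mean[b] = acc / ie_in_pos.size

    if not overflow:
        if not np.all(np.isfinite(V)):
            overflow = True  # reuse flag channel; wrapper re-checks
    return (spk_id[:n_spk], spk_t[:n_spk], overflow, traces[:, :tr_k],
            Ebin, Ibin, Gebin, Gibin, cnt, wie_mean, V, out_w)


@dataclass
class SimulationRecord:
    """Spikes, traces, current decomposition and final weights."""

    spike_ids: np.ndarray
    spike_times: np.ndarray
    T_ms: float
    dt_ms: float
    pop_of: np.ndarray
    is_exc: np.ndarray
    pop_names: list[str]
    bin_edges_ms: np.ndarray
    E_currents: np.ndarray        # (n, n_bins) mean over each bin, mV
    I_currents: np.ndarray
    dc_mean: np.ndarray           # (n, n_bins) mean applied DC
    traces: np.ndarray | None = None
    trace_idx: np.ndarray | None = None
    trace_times: np.ndarray | None = None
    mean_ie_weight: np.ndarray | None = None
    final_V: np.ndarray | None = None
    final_ie_weights: np.ndarray | None = None
    model: str = "current"
    seed: int = 0
    g_e: np.ndarray | None = None  # binned conductances (conductance model)
    g_i: np.ndarray | None = None
    syn: "SynapseParams | None" = None

    @property
    def n_rec(self) -> int:
        return self.pop_of.size

    def total_currents(self) -> np.ndarray:
        return self.E_currents + self.I_currents


def simulate(realization: WeightRealization,
             neuron: NeuronParams | None = None,
             syn: SynapseParams | None = None,
             rx_Hz=None,
             dc_mV=None,
             dc_schedule=None,
             T_ms: float = 1000.0,
             dt_ms: float = 0.05,
             seed: int = 0,
             plasticity: IstdpConfig | None = None,
             record_traces=None,
             trace_stride: int = 20,
             current_bin_ms: float = 100.0,
             spike_cap: int | None = None) -> SimulationRecord:
    """Simulate the network.

    Parameters
    ----------
    rx_Hz
        External population rates (one per external population, or a
        per-external-neuron array).  External spikes are independent
        Poisson processes realized per external neuron.
    dc_mV
        Constant per-neuron DC input (length n) added to the synaptic
        input, e.g. a distributed stimulus Z.
    dc_schedule
        Alternative to ``dc_mV``: tuple ``(times_ms, values)`` with
        ``values`` of shape (n_epochs, n); epoch ``k`` applies from
        ``times_ms[k]`` until the next entry.
    plasticity
        Optional iSTDP configuration; when enabled, i->e weights evolve
        and their mean is recorded per current bin.  If ``eta`` is None a
        default of ``1e-3 * mean |initial i->e weight|`` is used.
    record_traces
        Neuron indices whose membrane potential is recorded.
    """
    neuron = neuron or NeuronParams()
    syn = syn or SynapseParams()
    r = realization
    n = r.n_rec
    if dt_ms <= 0 or T_ms <= 0:
        raise ValueError("T and dt must be positive")

    # external rates per neuron, per ms
    if rx_Hz is None:
        x_rates = np.zeros(r.n_ext)
    else:
        rx_Hz = np.asarray(rx_Hz, dtype=float).ravel()
        if rx_Hz.size == r.n_ext:
            x_rates = rx_Hz
        else:
            ext = r.spec.external
            if rx_Hz.size != len(ext):
                raise ValueError("rx_Hz length matches neither external "
                                 "neurons nor external populations")
            x_rates = rx_Hz[r.xpop_of]
    if np.any(x_rates < 0):
        raise ValueError("external rates must be nonnegative")
    x_rates_per_ms = x_rates * 1e-3 * dt_ms  # probability per step
    if np.any(x_rates_per_ms > 0.1):
        raise ValueError("rate*dt too large for per-step thinning; reduce dt")

    # DC schedule
    if dc_schedule is not None:
        dc_times = np.asarray(dc_schedule[0], dtype=float)
        dc_vals = np.asarray(dc_schedule[1], dtype=float)
        if dc_vals.ndim != 2 or dc_vals.shape != (dc_times.size, n):
            raise ValueError("dc_schedule values must have shape (n_epochs, n)")
    else:
        dc_times = np.zeros(1)
        base = np.zeros(n) if dc_mV is None else np.asarray(dc_mV, float).ravel()
        if base.size != n:
            raise ValueError(f"dc_mV has length {base.size}, expected {n}")
        dc_vals = base[None, :]

    # conductance rescaling
    out_w = r.out_w.copy()
    xout_w = r.xout_w.copy()
    model = 0 if syn.model == "current" else 1
    if model == 1:
        pre_of_syn = np.repeat(np.arange(n), np.diff(r.out_ptr))
        denom = np.where(r.is_exc[pre_of_syn], syn.E_e - syn.V0, syn.E_i - syn.V0)
        out_w = out_w / denom
        xout_w = xout_w / (syn.E_e - syn.V0)

    plast = plasticity or IstdpConfig(enabled=False)
    eta = plast.eta
    if eta is None:
        base_w = np.abs(out_w[r.ie_in_pos]).mean() if r.ie_in_pos.size else 0.0
        eta = 1e-3 * base_w
    trace_idx = (np.asarray(record_traces, dtype=np.int64)
                 if record_traces is not None else np.empty(0, dtype=np.int64))

    n_steps = int(round(T_ms / dt_ms))
    bin_steps = max(1, int(round(current_bin_ms / dt_ms)))
    if spike_cap is None:
        spike_cap = int(max(1_000_000, n * T_ms * 0.25))

    (spk_id, spk_t, overflow, traces, Ebin, Ibin, Gebin, Gibin, cnt,
     wie_mean, V_fin, out_w_fin) = _run_kernel(
        seed, n_steps, dt_ms,
        neuron.tau_m, neuron.E_L, neuron.D_T, neuron.V_T, neuron.V_th,
        neuron.V_re, neuron.V_lb, neuron.B, neuron.tau_w,
        model, syn.tau_e, syn.tau_i, syn.tau_x, syn.E_e, syn.E_i,
        r.is_exc, r.out_ptr, r.out_tgt, out_w,
        r.xout_ptr, r.xout_tgt, xout_w,
        x_rates_per_ms, dc_times, dc_vals,
        plast.enabled, eta, plast.alpha, plast.tau_x,
        r.ie_in_ptr, r.ie_in_pos, r.ie_in_pre,
        trace_idx, trace_stride, bin_steps, spike_cap)
    if overflow:
        if not np.all(np.isfinite(V_fin)):
            bad = int(np.flatnonzero(~np.isfinite(V_fin))[0])
            raise FloatingPointError(f"non-finite membrane state at neuron {bad}")
        raise RuntimeError("spike buffer overflow; raise spike_cap")

    n_bins = Ebin.shape[1]
    cnt = np.maximum(cnt, 1.0)
    edges = np.arange(n_bins + 1) * bin_steps * dt_ms
    edges[-1] = min(edges[-1], T_ms)
    # mean applied DC per bin
    dc_mean = np.zeros((n, n_bins))
    for bi in range(n_bins):
        tm = 0.5 * (edges[bi] + edges[bi + 1])
        ep = int(np.searchsorted(dc_times, tm, side="right") - 1)
        dc_mean[:, bi] = dc_vals[max(ep, 0)]

    rec_names = [r.spec.names[k] for k in r.spec.recurrent]
    return SimulationRecord(
        spike_ids=spk_id, spike_times=spk_t, T_ms=T_ms, dt_ms=dt_ms,
        pop_of=r.pop_of, is_exc=r.is_exc, pop_names=rec_names,
        bin_edges_ms=edges,
        E_currents=Ebin / cnt[None, :], I_currents=Ibin / cnt[None, :],
        dc_mean=dc_mean,
        traces=traces if trace_idx.size else None,
        trace_idx=trace_idx if trace_idx.size else None,
        trace_times=(np.arange(traces.shape[1]) * trace_stride * dt_ms
                     if trace_idx.size else None),
        mean_ie_weight=wie_mean if plast.enabled else None,
        final_V=V_fin,
        final_ie_weights=out_w_fin[r.ie_in_pos] if r.ie_in_pos.size else None,
        model=syn.model, seed=seed,
        g_e=Gebin / cnt[None, :] if model == 1 else None,
        g_i=Gibin / cnt[None, :] if model == 1 else None,
        syn=syn)


def estimate_rates(record: SimulationRecord, window_ms=None,
                   per: str = "population") -> np.ndarray:
    """Firing rates (Hz) from spike counts in a time window.

    ``window_ms`` is ``(t0, t1)``; defaults to the full simulation.
    ``per`` is ``'neuron'`` or ``'population'``.
    """
    t0, t1 = (0.0, record.T_ms) if window_ms is None else window_ms
    if not (0 <= t0 < t1 <= record.T_ms + record.dt_ms):
        raise ValueError("window must lie within the simulation span")
    dur_s = (t1 - t0) / 1000.0
    sel = (record.spike_times >= t0) & (record.spike_times < t1)
    ids = record.spike_ids[sel]
    counts = np.bincount(ids, minlength=record.n_rec)
    per_neuron = counts / dur_s
    if per == "neuron":
        return per_neuron
    n_pop = int(record.pop_of.max()) + 1
    out = np.zeros(n_pop)
    for a in range(n_pop):
        out[a] = per_neuron[record.pop_of == a].mean()
    return out


def decompose_currents(record: SimulationRecord, normalize: bool = False,
                       neuron_params: NeuronParams | None = None,
                       effective: bool = False):
    """Per-neuron binned E / I / total currents.

    Excitatory and external sources are pooled as E (plus any positive
    DC), inhibitory as I (plus negative DC); total = E + I.  With
    ``normalize=True`` everything is divided by the rheobase.  For the
    conductance model, ``effective=True`` returns the voltage-independent
    effective currents ``-g_a (V0 - E_a)`` instead of the actual ones.
    """
    if record.E_currents is None:
        raise ValueError("currents were not recorded")
    if effective:
        if record.model != "conductance" or record.g_e is None:
            raise ValueError("effective currents require the conductance model")
        syn = record.syn or SynapseParams(model="conductance")
        E = record.g_e * (syn.E_e - syn.V0) + np.maximum(record.dc_mean, 0.0)
        I = record.g_i * (syn.E_i - syn.V0) + np.minimum(record.dc_mean, 0.0)
        tot = E + I
        if normalize:
            rb = rheobase(neuron_params)
            E, I, tot = E / rb, I / rb, tot / rb
        return E, I, tot
    E = record.E_currents.copy()
    I = record.I_currents.copy()
    tot = E + I
    if normalize:
        rb = rheobase(neuron_params)
        E, I, tot = E / rb, I / rb, tot / rb
    return E, I, tot


def psp_amplitudes(spec: PopulationSpec, weight_scaling: float = 0.5,
                   neuron: NeuronParams | None = None,
                   syn: SynapseParams | None = None,
                   dt_ms: float = 0.01, T_ms: float = 300.0) -> dict:
    """Peak postsynaptic-potential amplitude (mV) for each nonzero block.

    A single presynaptic spike is injected into a neuron at rest and the
    peak deviation from ``E_L`` is recorded; used to calibrate the weight
    scaling against physiological PSP sizes.
    """
    neuron = neuron or NeuronParams()
    syn = syn or SynapseParams()
    taus = {"e": syn.tau_e, "i": syn.tau_i, "x": syn.tau_x}
    scale = float(spec.N) ** weight_scaling
    out = {}
    for ai, a in enumerate(spec.recurrent):
        for b in range(spec.n_pop):
            j = spec.j[ai, b]
            if j == 0 or spec.p[ai, b] == 0:
                continue
            J = 1000.0 * j / scale  # mV*ms
            tau_s = taus[spec.signs[b]]
            V = neuron.E_L
            s = J / tau_s
            peak = 0.0
            dec = np.exp(-dt_ms / tau_s)
            for _ in range(int(T_ms / dt_ms)):
                s *= dec
                ex = min((V - neuron.V_T) / neuron.D_T, 30.0)
                V += (dt_ms / neuron.tau_m) * (
                    -(V - neuron.E_L) + neuron.D_T * np.exp(ex) + s)
                peak = max(peak, abs(V - neuron.E_L))
            out[(spec.names[a], spec.names[b])] = peak
    return out
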