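"""Plasticity and readout rules.

Contains the event-level homeostatic inhibitory STDP rule (the same rule
the spiking kernel applies online, exposed here for direct use and
testing), the closed-form one-hot least-squares readout, the supervised
Hebbian interlayer rule with row/column normalization, and
winner-take-all evaluation of a competitive output layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spiking import IstdpConfig, SimulationRecord, estimate_rates

__all__ = [
    "IstdpConfig",
    "IstdpState",
    "ReadoutModel",
    "InterlayerWeights",
    "istdp_events",
    "train_linear_readout",
    "classify_readout",
    "train_interlayer_hebbian",
    "winner_take_all_eval",
]


@dataclass
class IstdpState:
    """Traces and i->e weights for the event-level iSTDP rule.

    ``weights`` has shape (n_e, n_i) with nonpositive entries; absent
    synapses are marked in ``mask`` and never updated.  ``x_e`` / ``x_i``
    are the spike traces, ``t`` the time of the last processed event.
    """

    weights: np.ndarray
    mask: np.ndarray
    x_e: np.ndarray
    x_i: np.ndarray
    t: float = 0.0
    clip_count: int = 0


def istdp_events(state: IstdpState, events, cfg: IstdpConfig) -> IstdpState:
    """Apply a chronological sequence of spike events to the iSTDP state.

    ``events`` is an iterable of ``(time_ms, pop, index)`` with ``pop``
    ``'e'`` or ``'i'``.  Traces decay exponentially between events and
    jump by one on the owner's spike; on an excitatory spike the incoming
    i->e weights move by ``-eta * x_i``, on an inhibitory spike the
    outgoing weights move by ``-eta * (x_e - alpha)``.  Weights are
    clipped at zero (sign crossings counted in ``clip_count``).
    """
    eta = cfg.eta if cfg.eta is not None else 1e-3
    for (t, pop, j) in events:
        dt = t - state.t
        if dt < 0:
            raise ValueError("events must be chronological")
        if dt > 0:
            dec = np.exp(-dt / cfg.tau_x)
            state.x_e *= dec
            state.x_i *= dec
            state.t = t
        if pop == "e":
            upd = -eta * state.x_i[None, :]
            row = state.weights[j] + upd[0]
            clip = (row > 0) & state.mask[j]
            state.clip_count += int(clip.sum())
            state.weights[j] = np.where(state.mask[j], np.minimum(row, 0.0),
                                        state.weights[j])
            state.x_e[j] += 1.0
        elif pop == "i":
            col = state.weights[:, j] - eta * (state.x_e - cfg.alpha)
            clip = (col > 0) & state.mask[:, j]
            state.clip_count += int(clip.sum())
            state.weights[:, j] = np.where(state.mask[:, j],
                                           np.minimum(col, 0.0),
                                           state.weights[:, j])
            state.x_i[j] += 1.0
        else:
            raise ValueError(f"unknown population {pop!r}")
    return state


@dataclass
class ReadoutModel:
    """Linear readout trained on one-hot targets by least squares."""

    weights: np.ndarray  # (n_labels, n_units)
    labels: np.ndarray
    loss: float
    ridge: float = 0.0
    warning: str | None = None

    def scores(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        return self.weights @ rates


def train_linear_readout(rates: np.ndarray, labels, ridge_rel: float = 1e-8,
                         classes=None) -> ReadoutModel:
    """Closed-form one-hot least-squares readout.

    ``rates`` has shape (n_units, n_samples).  The readout ``W`` solves
    ``min ||W R - H||_F^2`` (+ a small relative ridge for rank-deficient
    inputs) where ``H`` is the one-hot label matrix.  ``classes``
    optionally fixes the label set (rows of the readout) independently of
    which labels appear in this sample.
    """
    R = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    if R.ndim != 2 or R.shape[1] != labels.size:
        raise ValueError("rates must be (n_units, n_samples) matching labels")
    uniq = np.unique(labels) if classes is None else np.asarray(classes)
    H = (labels[None, :] == uniq[:, None]).astype(float)
    warning = None
    if R.shape[1] < uniq.size:
        warning = (f"fewer samples ({R.shape[1]}) than labels ({uniq.size}); "
                   "readout is underdetermined")
        warnings.warn(warning)
    G = R @ R.T
    lam = ridge_rel * (np.trace(G) / max(G.shape[0], 1) + 1e-300)
    W = np.linalg.solve(G + lam * np.eye(G.shape[0]), R @ H.T).T
    loss = float(np.sum((W @ R - H) ** 2))
    return ReadoutModel(weights=W, labels=uniq, loss=loss, ridge=lam,
                        warning=warning)


def classify_readout(model: ReadoutModel, rates: np.ndarray):
    """Predicted label per sample: argmax of the readout scores.

    Exact ties break to the lowest label index.
    """
    scores = model.scores(np.atleast_2d(np.asarray(rates, dtype=float).T).T
                          if np.asarray(rates).ndim == 1 else rates)
    if scores.ndim == 1:
        scores = scores[:, None]
    idx = np.argmax(scores, axis=0)  # argmax returns the first (lowest) maximum
    out = model.labels[idx]
    return out[0] if np.asarray(rates).ndim == 1 else out


@dataclass
class InterlayerWeights:
    """Nonnegative class-by-pixel interlayer matrix and its expansion."""

    U: np.ndarray                 # (n_classes, n_pixels)
    labels: np.ndarray
    normalization: str = "column_then_row"
    raw_U: np.ndarray | None = None

    def expand(self, pop_of_post: np.ndarray, pixel_of_pre: np.ndarray
               ) -> np.ndarray:
        """Neuron-level feedforward matrix ``J[j, k] = U[pop(j), pixel(k)]``."""
        return self.U[np.asarray(pop_of_post)[:, None],
                      np.asarray(pixel_of_pre)[None, :]]


def train_interlayer_hebbian(rates: np.ndarray, labels, pixel_of_neuron,
                             n_pixels: int | None = None, eta: float = 1.0,
                             order: str = "column_then_row") -> InterlayerWeights:
    """Supervised Hebbian interlayer rule.

    For each labeled sample, the row of ``U`` belonging to the sample's
    class accrues ``eta`` times the rates of layer-1 neurons pooled by
    the pixel they receive input from.  Afterwards each column and then
    each row of ``U`` is normalized to unit norm (order configurable via
    ``order='row_then_column'``), which makes ``eta`` immaterial.
    All entries stay nonnegative, respecting Dale's law for this
    excitatory pathway.
    """
    R = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    pixel_of_neuron = np.asarray(pixel_of_neuron)
    if np.any(R < 0):
        raise ValueError("rates must be nonnegative")
    if order not in ("column_then_row", "row_then_column"):
        raise ValueError("order must be 'column_then_row' or 'row_then_column'")
    uniq = np.unique(labels)
    if n_pixels is None:
        n_pixels = int(pixel_of_neuron.max()) + 1
    U = np.zeros((uniq.size, n_pixels))
    # pool rates by pixel: pooled[p, s] = sum of rates of neurons on pixel p
    pooled = np.zeros((n_pixels, R.shape[1]))
    np.add.at(pooled, pixel_of_neuron, R)
    for m, lab in enumerate(uniq):
        sel = labels == lab
        U[m] += eta * pooled[:, sel].sum(axis=1)
    raw = U.copy()

    def _norm_cols(M):
        nrm = np.linalg.norm(M, axis=0)
        return M / np.where(nrm > 0, nrm, 1.0)

    def _norm_rows(M):
        nrm = np.linalg.norm(M, axis=1)
        return M / np.where(nrm > 0, nrm, 1.0)[:, None]

    if order == "column_then_row":
        U = _norm_rows(_norm_cols(U))
    else:
        U = _norm_cols(_norm_rows(U))
    return InterlayerWeights(U=U, labels=uniq, normalization=order, raw_U=raw)


def winner_take_all_eval(record: SimulationRecord, windows_ms,
                         label_of_pop=None):
    """Predicted label per stimulus window: the most active e population.

    ``windows_ms`` is a sequence of ``(t0, t1)``.  Returns
    ``(labels, flags)`` where flags mark ties (broken to the lowest
    population index) and all-silent abstentions (label -1).
    """
    n_pop = int(record.pop_of.max()) + 1
    exc_pops = [a for a in range(n_pop)
                if record.is_exc[record.pop_of == a].all()]
    if label_of_pop is None:
        label_of_pop = {a: k for k, a in enumerate(exc_pops)}
    preds, flags = [], []
    for (t0, t1) in windows_ms:
        rates = estimate_rates(record, (t0, t1), per="population")
        er = rates[exc_pops]
        if np.all(er == 0):
            preds.append(-1)
            flags.append("silent")
            continue
        best = int(np.argmax(er))
        tie = np.sum(er == er[best]) > 1
        preds.append(label_of_pop[exc_pops[best]])
        flags.append("tie" if tie else "")
    return np.asarray(preds), flags
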