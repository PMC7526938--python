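"""Two-layer digit-classification pipeline.

Layer 1 is the one-population semi-balanced network driven by pixel
projections: each pixel feeds a fixed block of consecutive excitatory
neurons, and the external Poisson drive is replaced by its time-constant
mean (the stimulus of interest is the pixel projection; the background
drive only sets the operating point).  Inhibitory weights are trained by
homeostatic iSTDP on a subset of images, then frozen.

Readouts of the layer-1 rate representation use the closed-form one-hot
least-squares readout.  Layer 2 is a competitive winner-take-all spiking
network (one excitatory population per class, one shared inhibitory
population) driven through nonnegative interlayer weights trained with
the supervised Hebbian rule; its drive is the mean-input image of the
layer-1 rates through those weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import learning, meanfield as mf, spiking as sp, synthetic

__all__ = ["Layer1Result", "run_layer1", "ClassifyResult", "run_classification"]


@dataclass
class Layer1Result:
    """Trained layer-1 network and its rate representation of a digit set."""

    realization: sp.WeightRealization
    rates: np.ndarray          # (n_samples, n_e)
    labels: np.ndarray
    pixel_of_neuron: np.ndarray
    n_e: int
    baseline_mV: np.ndarray    # per-neuron background DC


def run_layer1(digits: synthetic.SyntheticDigitSet,
               neurons_per_pixel: int = 10,
               pixel_strength_mV: float = 20.0,
               rx_Hz: float = 10.0,
               n_train_istdp: int = 40,
               present_ms: float = 600.0,
               istdp_present_ms: float = 500.0,
               eta: float = 0.06,
               dt_ms: float = 0.05,
               seed: int = 0) -> Layer1Result:
    """Train layer 1 with iSTDP on digit drive, then record rate vectors.

    The network size follows the pixel count: ``n_e = n_pixels *
    neurons_per_pixel`` excitatory neurons, with inhibitory and external
    populations at a quarter of that, as in the one-population preset.
    """
    n_pix = digits.pixels.shape[1]
    n_e = n_pix * neurons_per_pixel
    N = int(n_e / 0.8)
    fx = synthetic.fixture("fig3_detailed", size_factor=N / 30000)
    spec = fx.spec
    real = sp.sample_connectivity(spec, seed=seed)
    n = real.n_rec
    n_e = int(real.is_exc.sum())
    Q = synthetic.pixel_projection(n_pix, neurons_per_pixel, pixel_strength_mV)
    Q = Q[:n_e]
    pixel_of_neuron = np.arange(n_e) // neurons_per_pixel

    # background drive: the mean input the external population would give
    net = mf.build_meanfield(spec)
    X = mf.external_drive(net, [rx_Hz]).X
    baseline = np.where(real.is_exc, X[0], X[1])

    rng = np.random.default_rng(seed + 1)
    cfg = sp.IstdpConfig(eta=eta)

    # --- iSTDP training on a random subset of images ---
    idx = rng.permutation(len(digits.labels))[:n_train_istdp]
    times = np.arange(idx.size) * istdp_present_ms
    vals = np.tile(baseline, (idx.size, 1))
    for k, i in enumerate(idx):
        vals[k, :n_e] += Q @ digits.pixels[i]
    rec = sp.simulate(real, T_ms=istdp_present_ms * idx.size, dt_ms=dt_ms,
                      seed=seed + 2, plasticity=cfg, dc_schedule=(times, vals),
                      current_bin_ms=1000.0)
    real.set_ie_weights(rec.final_ie_weights)

    # --- frozen-weight presentation of the full set ---
    m = len(digits.labels)
    times = np.arange(m) * present_ms
    vals = np.tile(baseline, (m, 1))
    for k in range(m):
        vals[k, :n_e] += Q @ digits.pixels[k]
    rec = sp.simulate(real, T_ms=present_ms * m, dt_ms=dt_ms, seed=seed + 3,
                      dc_schedule=(times, vals), current_bin_ms=1000.0)
    burn = min(200.0, present_ms / 3)
    R = np.array([sp.estimate_rates(rec, (t + burn, t + present_ms),
                                    per="neuron")[:n_e] for t in times])
    return Layer1Result(realization=real, rates=R, labels=digits.labels,
                        pixel_of_neuron=pixel_of_neuron, n_e=n_e,
                        baseline_mV=baseline)


@dataclass
class ClassifyResult:
    rate_readout_accuracy: float
    pixel_readout_accuracy: float
    wta_accuracy: float
    wta_predictions: np.ndarray
    wta_labels: np.ndarray
    n_classes: int

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


def _readout_accuracy(features: np.ndarray, labels, train_idx, test_idx) -> float:
    model = learning.train_linear_readout(features[:, train_idx], labels[train_idx])
    pred = learning.classify_readout(model, features[:, test_idx])
    return float(np.mean(pred == labels[test_idx]))


def run_classification(layer1: Layer1Result,
                       digits: synthetic.SyntheticDigitSet,
                       n_readout_dims: int | None = None,
                       train_frac: float = 0.75,
                       layer2_N: int | None = None,
                       wta_present_ms: float = 500.0,
                       drive_scale_mV: float = 20.0,
                       dt_ms: float = 0.05,
                       seed: int = 0) -> ClassifyResult:
    """Evaluate readouts of the layer-1 representation and the layer-2 WTA.

    The rate and pixel readouts are compared at matched dimension: a
    random subset of ``n_readout_dims`` excitatory neurons against the
    full pixel vector (``n_readout_dims`` defaults to the pixel count).
    The layer-2 drive is normalized so its largest entry is
    ``drive_scale_mV``.
    """
    rng = np.random.default_rng(seed)
    labels = layer1.labels
    m = labels.size
    n_pix = digits.pixels.shape[1]
    if n_readout_dims is None:
        n_readout_dims = n_pix
    split = int(round(train_frac * m))
    perm = rng.permutation(m)
    train_idx, test_idx = perm[:split], perm[split:]

    sub = rng.choice(layer1.n_e, size=min(n_readout_dims, layer1.n_e),
                     replace=False)
    acc_rate = _readout_accuracy(layer1.rates[:, sub].T, labels,
                                 train_idx, test_idx)
    acc_pix = _readout_accuracy(digits.pixels.T, labels, train_idx, test_idx)

    # --- interlayer Hebbian weights from the training split ---
    inter = learning.train_interlayer_hebbian(
        layer1.rates[train_idx].T, labels[train_idx],
        layer1.pixel_of_neuron, n_pixels=n_pix)
    n_classes = inter.labels.size
    if layer2_N is None:
        layer2_N = max(500, 125 * n_classes)
    spec2 = synthetic.layer2_fixture(n_classes, layer2_N)
    real2 = sp.sample_connectivity(spec2, seed=seed + 10)
    pop_of_post = real2.pop_of[real2.is_exc]
    J21 = inter.expand(pop_of_post, layer1.pixel_of_neuron)

    # drive each test image through the trained interlayer weights
    n2 = real2.n_rec
    n2e = int(real2.is_exc.sum())
    times = np.arange(test_idx.size) * wta_present_ms
    vals = np.zeros((test_idx.size, n2))
    drive = layer1.rates[test_idx] @ J21.T  # (n_test, n2e)
    drive *= drive_scale_mV / max(drive.max(), 1e-12)
    vals[:, :n2e] = drive
    rec2 = sp.simulate(real2, T_ms=wta_present_ms * test_idx.size, dt_ms=dt_ms,
                       seed=seed + 11, dc_schedule=(times, vals),
                       current_bin_ms=1000.0)
    burn = min(150.0, wta_present_ms / 3)
    windows = [(t + burn, t + wta_present_ms) for t in times]
    preds, _ = learning.winner_take_all_eval(rec2, windows)
    pred_labels = np.where(preds >= 0, inter.labels[np.maximum(preds, 0)], -1)
    acc_wta = float(np.mean(pred_labels == labels[test_idx]))
    return ClassifyResult(rate_readout_accuracy=acc_rate,
                          pixel_readout_accuracy=acc_pix,
                          wta_accuracy=acc_wta,
                          wta_predictions=pred_labels,
                          wta_labels=labels[test_idx],
                          n_classes=n_classes)
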