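"""Parameter presets and synthetic-data generators.

Every numeric value in the presets is either transcribed from the model
definitions the package implements (connection strengths ``j_ab`` in
mV/Hz, probabilities ``p_ab``, population sizes) or is a documented
default.  Generators are pure functions of their seeds.

Presets
-------
``fig1_linear``
    Three recurrent populations (e1, e2, i) and two external populations;
    feedforward probabilities chosen so the balanced solution is positive
    over the whole stimulus square, giving a linear (planar) manifold.
``fig1_competitive``
    Same network with competitive feedforward wiring (``p_e1x2 = p_e2x1 =
    0``), so unequal external rates silence one excitatory population and
    push the network into the semi-balanced state.
``fig2_ssn``
    The competitive network together with the supralinear rate-model gain
    ``k = 10 Hz/mV^2``.
``fig3_detailed``
    One excitatory / one inhibitory / one external population with a
    distributed two-dimensional stimulus; used for detailed (single
    neuron) balance studies and inhibitory plasticity.
``fig4_layers``
    The two-layer digit-classification architecture: layer 1 is the
    ``fig3_detailed`` network driven by pixel projections, layer 2 a
    competitive network with one excitatory population per class.
``contrast_demo``
    A four-population receptive-field model given directly as an
    effective matrix, with six printed stimulus vectors; low-contrast
    stimuli add linearly, high-contrast ones sub-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meanfield import MeanFieldNetwork, PopulationSpec

__all__ = [
    "FixtureConfig",
    "DistributedStimulus",
    "SyntheticDigitSet",
    "fixture",
    "distributed_stimulus",
    "stimulus_lattice",
    "synthetic_digits",
    "pixel_projection",
    "digit_template",
]

PRESETS = (
    "fig1_linear",
    "fig1_competitive",
    "fig2_ssn",
    "fig3_detailed",
    "fig4_layers",
    "contrast_demo",
)


@dataclass
class FixtureConfig:
    """A fully resolved preset: population spec plus protocol parameters."""

    name: str
    spec: PopulationSpec | None = None
    net: MeanFieldNetwork | None = None
    stimuli: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "params": dict(self.params)}
        if self.spec is not None:
            d["spec"] = {
                "names": list(self.spec.names),
                "sizes": self.spec.sizes.tolist(),
                "signs": list(self.spec.signs),
                "j": self.spec.j.tolist(),
                "p": self.spec.p.tolist(),
            }
        if self.net is not None and self.spec is None:
            d["net"] = {"W": self.net.W.tolist(), "Wx": self.net.Wx.tolist(),
                        "JK": self.net.JK, "rec_names": self.net.rec_names}
        if self.stimuli:
            d["stimuli"] = {k: np.asarray(v).tolist() for k, v in self.stimuli.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        spec = None
        net = None
        if "spec" in d:
            spec = PopulationSpec(**d["spec"])
        if "net" in d:
            net = MeanFieldNetwork(W=np.array(d["net"]["W"]),
                                   Wx=np.array(d["net"]["Wx"]),
                                   JK=d["net"]["JK"],
                                   rec_names=list(d["net"]["rec_names"]))
        stimuli = {k: np.array(v) for k, v in d.get("stimuli", {}).items()}
        return cls(name=d["name"], spec=spec, net=net, stimuli=stimuli,
                   params=dict(d.get("params", {})))


def _three_pop_spec(p_ffwd: np.ndarray, size_factor: float = 1.0,
                    j_ii: float = -3.75) -> PopulationSpec:
    """e1/e2/i network with two external populations (three-population family).

    ``j_ii`` defaults to -3.75 mV/Hz, the value consistent with the
    one-population weight set and the only one under which the balanced
    state is feasible for positive stimuli (a tenfold-weaker variant of
    the same coefficient appears in some tabulations and is selectable
    for single-synapse calibration purposes).
    """
    f = size_factor
    sizes = [int(round(12000 * f)), int(round(12000 * f)), int(round(6000 * f)),
             int(round(3000 * f)), int(round(3000 * f))]
    #            e1      e2      i      x1     x2
    j = [[0.375, 0.375, -2.25, 2.70, 2.70],   # -> e1
         [0.375, 0.375, -2.25, 2.70, 2.70],   # -> e2
         [1.70,  1.70,  j_ii,  2.025, 2.025]]  # -> i
    p_rec = np.array([[0.15, 0.05, 0.1],
                      [0.05, 0.15, 0.1],
                      [0.1, 0.1, 0.1]])
    p = np.hstack([p_rec, p_ffwd])
    return PopulationSpec(names=["e1", "e2", "i", "x1", "x2"], sizes=sizes,
                          signs=["e", "e", "i", "x", "x"], j=j, p=p)


def _one_pop_spec(N: int = 30000) -> PopulationSpec:
    """e/i/x network with a distributed stimulus (one-population family).

    Connection strengths follow the same weight set as the three-population
    network, with the e->i, i->i and feedforward coefficients specific to
    this architecture.
    """
    Ne, Ni, Nx = int(0.8 * N), int(0.2 * N), int(0.2 * N)
    #        e        i       x
    j = [[0.0375, -0.225, 2.7],      # -> e
         [0.16875, -0.375, 2.025]]   # -> i
    p = [[0.1, 0.1, 0.1],
         [0.1, 0.1, 0.1]]
    return PopulationSpec(names=["e", "i", "x"], sizes=[Ne, Ni, Nx],
                          signs=["e", "i", "x"], j=j, p=p)


def _layer2_spec(n_classes: int = 10, N: int = 5000) -> PopulationSpec:
    """Competitive winner-take-all network: one e population per class."""
    Ni = int(0.2 * N)
    Ne_each = (N - Ni) // n_classes
    names = [f"e{k}" for k in range(n_classes)] + ["i"]
    sizes = [Ne_each] * n_classes + [Ni]
    signs = ["e"] * n_classes + ["i"]
    n = n_classes + 1
    j = np.zeros((n, n))
    p = np.zeros((n, n))
    for a in range(n_classes):
        j[a, a] = 0.375
        p[a, a] = 0.1
        j[a, n_classes] = -2.25
        p[a, n_classes] = 0.1
        j[n_classes, a] = 1.70
        p[n_classes, a] = 0.1
    j[n_classes, n_classes] = -3.75
    p[n_classes, n_classes] = 0.1
    return PopulationSpec(names=names, sizes=sizes, signs=signs, j=j, p=p)


def contrast_demo_network() -> MeanFieldNetwork:
    """Four-population receptive-field model (e1, e2, i1, i2).

    The effective matrix is printed in mV*ms and converted to mV/Hz by
    1e-3; connectivity is twice as strong within a receptive field as
    between receptive fields.
    """
    W = np.array([[10.0, 5.0, -60.0, -30.0],
                  [5.0, 10.0, -30.0, -60.0],
                  [50.0, 25.0, -100.0, -50.0],
                  [25.0, 50.0, -50.0, -100.0]]) * 1e-3
    return MeanFieldNetwork(W=W, Wx=np.zeros((4, 0)), JK=float(np.abs(W).mean()),
                            rec_names=["e1", "e2", "i1", "i2"])


CONTRAST_STIMULI = {
    "X1low": np.array([0.4, 0.3, 0.15, 0.05]),
    "X2low": np.array([0.3, 0.4, 0.05, 0.15]),
    "X1+2low": np.array([0.7, 0.7, 0.2, 0.2]),
    "X1high": np.array([0.8, 0.3, 0.25, 0.1]),
    "X2high": np.array([0.3, 0.8, 0.1, 0.25]),
    "X1+2high": np.array([1.1, 1.1, 0.35, 0.35]),
}


def fixture(name: str, size_factor: float = 1.0,
            j_ii: float = -3.75) -> FixtureConfig:
    """Return a fully resolved named preset.

    ``size_factor`` rescales population sizes (for reduced-scale runs);
    mean-field rates are unaffected because effective weights rescale
    accordingly.  ``j_ii`` applies to the three-population presets only
    (see :func:`_three_pop_spec`).
    """
    if name == "fig1_linear":
        p_ffwd = np.array([[0.08, 0.1], [0.1, 0.1], [0.12, 0.12]])
        return FixtureConfig(name=name,
                             spec=_three_pop_spec(p_ffwd, size_factor, j_ii),
                             params={"rx_baseline_Hz": [15.0, 15.0],
                                     "j_ii_mV_per_Hz": j_ii})
    if name in ("fig1_competitive", "fig2_ssn"):
        p_ffwd = np.array([[0.15, 0.0], [0.0, 0.15], [0.15, 0.15]])
        params = {"rx_baseline_Hz": [15.0, 15.0], "j_ii_mV_per_Hz": j_ii}
        if name == "fig2_ssn":
            params.update({"k_Hz_per_mV2": 10.0, "rx1_Hz": 10.0,
                           "rx2_sweep_Hz": [0.0, 30.0],
                           # coupling scale at which the rx2 sweep shows the
                           # ISN <-> non-ISN transition (see docs/methods.md)
                           "sweep_JK_mVHz": 0.15})
        return FixtureConfig(name=name,
                             spec=_three_pop_spec(p_ffwd, size_factor, j_ii),
                             params=params)
    if name == "fig3_detailed":
        N = int(round(30000 * size_factor))
        return FixtureConfig(
            name=name, spec=_one_pop_spec(N),
            params={"rx_baseline_Hz": 10.0,
                    "sigma_fixed_mV": 22.5,
                    "sigma_resample_range_mV": [-30.0, 30.0],
                    "sigma_resample_period_ms": 2000.0,
                    "lattice_range_mV": [-18.0, 18.0],
                    "lattice_points": 17,
                    "istdp": {"tau_x_ms": 200.0, "alpha": 2.0}})
    if name == "fig4_layers":
        N1 = int(round(5000 * size_factor))
        N2 = int(round(5000 * size_factor))
        return FixtureConfig(
            name=name, spec=_one_pop_spec(N1),
            params={"layer2_spec": "competitive_10",
                    "n_classes": 10,
                    "layer2_N": N2,
                    "pixel_strength_mV": 20.0,
                    "neurons_per_pixel": 10,
                    "image_shape": [20, 20],
                    "istdp": {"tau_x_ms": 200.0, "alpha": 2.0}})
    if name == "contrast_demo":
        return FixtureConfig(name=name, net=contrast_demo_network(),
                             stimuli=dict(CONTRAST_STIMULI))
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")


def layer2_fixture(n_classes: int = 10, N: int = 5000) -> PopulationSpec:
    return _layer2_spec(n_classes, N)


# ---------------------------------------------------------------------------
# distributed two-dimensional stimulus
# ---------------------------------------------------------------------------

@dataclass
class DistributedStimulus:
    """Per-neuron stimulus ``Z = sigma1*Z1 + sigma2*Z2``.

    ``Z1`` and ``Z2`` are standard-normal component vectors drawn once per
    seed and held fixed while the scalar coefficients (mV) vary, so the
    stimulus lives on a fixed two-dimensional plane in neuron space.
    """

    Z1: np.ndarray
    Z2: np.ndarray
    sigma1: float = 0.0
    sigma2: float = 0.0

    @property
    def Z(self) -> np.ndarray:
        return self.sigma1 * self.Z1 + self.sigma2 * self.Z2

    def set_sigmas(self, sigma1: float, sigma2: float) -> "DistributedStimulus":
        self.sigma1 = float(sigma1)
        self.sigma2 = float(sigma2)
        return self


def distributed_stimulus(n_neurons: int, seed: int = 0) -> DistributedStimulus:
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    rng = np.random.default_rng(seed)
    return DistributedStimulus(Z1=rng.standard_normal(n_neurons),
                               Z2=rng.standard_normal(n_neurons))


def stimulus_lattice(lo: float = -18.0, hi: float = 18.0, n: int = 17) -> np.ndarray:
    """Uniform ``n x n`` lattice of (sigma1, sigma2) pairs, shape (n*n, 2)."""
    g = np.linspace(lo, hi, n)
    s1, s2 = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([s1.ravel(), s2.ravel()])


# ---------------------------------------------------------------------------
# synthetic digit-like images
# ---------------------------------------------------------------------------

# Seven-segment layout in unit coordinates: (x0, y0, x1, y1) per segment.
_SEGMENTS = {
    "top": (0.2, 0.1, 0.8, 0.1),
    "top_left": (0.2, 0.1, 0.2, 0.5),
    "top_right": (0.8, 0.1, 0.8, 0.5),
    "middle": (0.2, 0.5, 0.8, 0.5),
    "bot_left": (0.2, 0.5, 0.2, 0.9),
    "bot_right": (0.8, 0.5, 0.8, 0.9),
    "bottom": (0.2, 0.9, 0.8, 0.9),
}

_GLYPHS = {
    0: ("top", "top_left", "top_right", "bot_left", "bot_right", "bottom"),
    1: ("top_right", "bot_right"),
    2: ("top", "top_right", "middle", "bot_left", "bottom"),
    3: ("top", "top_right", "middle", "bot_right", "bottom"),
    4: ("top_left", "top_right", "middle", "bot_right"),
    5: ("top", "top_left", "middle", "bot_right", "bottom"),
    6: ("top", "top_left", "middle", "bot_left", "bot_right", "bottom"),
    7: ("top", "top_right", "bot_right"),
    8: ("top", "top_left", "top_right", "middle", "bot_left", "bot_right", "bottom"),
    9: ("top", "top_left", "top_right", "middle", "bot_right", "bottom"),
}


def digit_template(label: int, shape=(20, 20), thickness: float = 0.08) -> np.ndarray:
    """Stroke-glyph template for one class, pixel values in [0, 1]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    px = (xx + 0.5) / w
    py = (yy + 0.5) / h
    img = np.zeros(shape)
    for seg in _GLYPHS[label % 10]:
        x0, y0, x1, y1 = _SEGMENTS[seg]
        # distance from each pixel center to the segment
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        t = np.clip(((px - x0) * dx + (py - y0) * dy) / L2, 0.0, 1.0)
        dist = np.hypot(px - (x0 + t * dx), py - (y0 + t * dy))
        img = np.maximum(img, np.clip(1.0 - dist / thickness, 0.0, 1.0))
    return img


@dataclass
class SyntheticDigitSet:
    """Class-consistent stroke images plus labels.

    Images are ``template(label) + noise`` clipped to [0, 1]; at zero
    noise all images within a class are identical.
    """

    images: np.ndarray  # (n_samples, h, w)
    labels: np.ndarray  # (n_samples,)
    n_classes: int
    noise: float
    seed: int

    @property
    def pixels(self) -> np.ndarray:
        """Flattened (n_samples, h*w) pixel matrix."""
        return self.images.reshape(len(self.labels), -1)


def synthetic_digits(n_classes: int = 10, n_per_class: int = 20,
                     noise: float = 0.1, seed: int = 0,
                     shape=(20, 20)) -> SyntheticDigitSet:
    """Generate a deterministic digit-like image set.

    Pixel noise is additive Gaussian with standard deviation ``noise``;
    classes are linearly separable by construction at low noise.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    rng = np.random.default_rng(seed)
    templates = [digit_template(c, shape) for c in range(n_classes)]
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = templates[c] + noise * rng.standard_normal(shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(c)
    order = rng.permutation(n_classes * n_per_class)
    return SyntheticDigitSet(images=np.asarray(images)[order],
                             labels=np.asarray(labels)[order],
                             n_classes=n_classes, noise=noise, seed=seed)


def pixel_projection(n_pixels: int, neurons_per_pixel: int = 10,
                     strength_mV: float = 20.0) -> np.ndarray:
    """Projection matrix from pixel space to excitatory-neuron drive.

    Pixel ``k`` (0-based) projects with a fixed strength to the block of
    ``neurons_per_pixel`` consecutive neurons starting at index
    ``k * neurons_per_pixel``; the returned matrix has shape
    ``(n_pixels * neurons_per_pixel, n_pixels)``.
    """
    Ne = n_pixels * neurons_per_pixel
    Q = np.zeros((Ne, n_pixels))
    for k in range(n_pixels):
        Q[k * neurons_per_pixel:(k + 1) * neurons_per_pixel, k] = strength_mV
    return Q
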