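import numpy as np
import pytest

from semibalance import meanfield as mf, spiking as sp, synthetic


def random_dale_network(rng, n_max=5):
    """Random Dale-compliant effective matrix with all-nonzero entries.

    At least one excitatory and one inhibitory column; resampled until
    well-conditioned.
    """
    while True:
        n = rng.integers(2, n_max + 1)
        n_exc = rng.integers(1, n)
        signs = np.array([1.0] * n_exc + [-1.0] * (n - n_exc))
        W = np.abs(rng.uniform(0.2, 2.0, size=(n, n))) * signs[None, :]
        if np.linalg.cond(W) < 1e6:
            return mf.MeanFieldNetwork(W=W, Wx=np.zeros((n, 0)), JK=1.0)


def brute_force_semibalanced(W, X, tol=1e-8):
    """Independent exhaustive-support oracle for r = [W r + X + r]^+.

    Solves every one of the 2^n support subsystems directly and filters
    by literal evaluation of the fixed-point equation.
    """
    import itertools
    n = len(X)
    sols = []
    for S in itertools.chain.from_iterable(
            itertools.combinations(range(n), k) for k in range(n + 1)):
        r = np.zeros(n)
        S = list(S)
        if S:
            sub = W[np.ix_(S, S)]
            if np.linalg.cond(sub) > 1e10:
                continue
            r[S] = -np.linalg.solve(sub, X[S])
        if np.any(r < -tol):
            continue
        r = np.maximum(r, 0.0)
        lhs = np.maximum(W @ r + X + r, 0.0)
        if np.all(np.abs(lhs - r) <= 1e-6 * max(1.0, np.abs(r).max())):
            if not any(np.allclose(r, q, atol=1e-6) for q in sols):
                sols.append(r)
    return sols


@pytest.fixture(scope="session")
def contrast():
    return synthetic.fixture("contrast_demo")


@pytest.fixture(scope="session")
def trained_fig3_network():
    """N=2000 one-population network trained by iSTDP under a fixed
    distributed stimulus; shared by the homeostasis and manifold tests.

    Returns (realization, distributed stimulus, training record).
    """
    fx = synthetic.fixture("fig3_detailed", size_factor=2000 / 30000)
    real = sp.sample_connectivity(fx.spec, seed=3)
    n = real.n_rec
    ne = int(real.is_exc.sum())
    ds = synthetic.distributed_stimulus(ne, seed=7)
    dc = np.zeros(n)
    dc[:ne] = ds.set_sigmas(22.5, 22.5).Z
    rec = sp.simulate(real, rx_Hz=np.array([10.0]), T_ms=25000, dt_ms=0.05,
                      seed=4, plasticity=sp.IstdpConfig(eta=0.06), dc_mV=dc,
                      current_bin_ms=500.0)
    real.set_ie_weights(rec.final_ie_weights)
    return real, ds, rec
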