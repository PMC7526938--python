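"""Balance diagnostics, manifold dimensionality, and the SVD imbalance test.

* ``balance_metrics`` — tightness of balance ``beta = |E + I| / E`` and
  coupling-strength coefficient ``c = mean(E) / std(E)`` from recorded
  input-current decompositions.
* ``current_skewness`` — sample skewness of per-neuron total inputs; a
  left-skewed (negative) value is the signature of detailed semi-balance:
  excess inhibition to some neurons without matching excess excitation.
* ``pca_residual_variance`` / ``isomap_residual_variance`` — percent
  variance unexplained as a function of embedding dimension, linear
  (PCA) versus geodesic (Isomap); a curved low-dimensional manifold
  shows a lower Isomap residual at the intrinsic dimension.
* ``svd_imbalance_diagnostic`` — whether single-neuron balance is
  obstructed: if the stimulus has an O(1) fraction of its energy in the
  subspace spanned by the left singular vectors with small singular
  values, the recurrent input cannot cancel it and detailed balance is
  impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "BalanceMetrics",
    "ResidualVarianceCurve",
    "ImbalanceReport",
    "balance_metrics",
    "current_skewness",
    "pca_residual_variance",
    "isomap_residual_variance",
    "svd_imbalance_diagnostic",
    "dense_recurrent_matrix",
]


@dataclass
class BalanceMetrics:
    """Per-neuron balance tightness and coupling-strength metrics.

    ``beta`` uses time-averaged currents (ratio of means); entries where
    the mean excitatory current is not positive are flagged undefined
    rather than dropped.  ``c`` is the temporal mean over std of the
    excitatory current per neuron; undefined where the variance is zero.
    """

    beta: np.ndarray
    beta_defined: np.ndarray
    c: np.ndarray
    c_defined: np.ndarray
    window: tuple

    @property
    def beta_mean(self) -> float:
        return float(self.beta[self.beta_defined].mean())

    @property
    def c_mean(self) -> float:
        return float(self.c[self.c_defined].mean())


def balance_metrics(E: np.ndarray, I: np.ndarray, bins=None) -> BalanceMetrics:
    """Compute beta and c from binned E/I current series (n_neurons, n_bins).

    ``bins`` optionally selects a slice/index array of time bins.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    I = np.atleast_2d(np.asarray(I, dtype=float))
    if bins is not None:
        E, I = E[:, bins], I[:, bins]
    Em = E.mean(axis=1)
    Im = I.mean(axis=1)
    beta_def = Em > 0
    beta = np.where(beta_def, np.abs(Em + Im) / np.where(beta_def, Em, 1.0),
                    np.nan)
    Es = E.std(axis=1)
    c_def = Es > 0
    c = np.where(c_def, Em / np.where(c_def, Es, 1.0), np.nan)
    return BalanceMetrics(beta=beta, beta_defined=beta_def, c=c,
                          c_defined=c_def, window=(0, E.shape[1]))


def current_skewness(values: np.ndarray) -> float:
    """Adjusted (bias-corrected) sample skewness of per-neuron currents."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.std(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    return float(stats.skew(v, bias=False))


@dataclass
class ResidualVarianceCurve:
    """Percent variance unexplained per embedding dimension."""

    method: str
    dims: np.ndarray
    residual_percent: np.ndarray
    note: str = ""

    def at(self, dim: int) -> float:
        k = int(np.flatnonzero(self.dims == dim)[0])
        return float(self.residual_percent[k])


def pca_residual_variance(rates: np.ndarray, max_dim: int = 10
                          ) -> ResidualVarianceCurve:
    """PCA percent variance unexplained, ``100 * (1 - cum. explained)``."""
    X = np.asarray(rates, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rank = min(X.shape[0] - 1, X.shape[1])
    note = ""
    if max_dim > rank:
        note = f"max_dim truncated from {max_dim} to rank {rank}"
        max_dim = rank
    pca = PCA(n_components=max_dim).fit(X)
    resid = 100.0 * (1.0 - np.cumsum(pca.explained_variance_ratio_))
    return ResidualVarianceCurve(method="pca", dims=np.arange(1, max_dim + 1),
                                 residual_percent=np.maximum(resid, 0.0),
                                 note=note)


def isomap_residual_variance(rates: np.ndarray, max_dim: int = 10,
                             k_neighbors: int = 10) -> ResidualVarianceCurve:
    """Isomap percent residual variance per dimension.

    Residual variance at dimension d is ``100 * (1 - R^2)`` between the
    geodesic (graph shortest-path) distances and the Euclidean distances
    in the d-dimensional embedding.  A disconnected neighbor graph is
    handled by keeping the largest component (noted in the result).
    """
    X = np.asarray(rates, dtype=float)
    note = ""
    graph = kneighbors_graph(X, n_neighbors=min(k_neighbors, X.shape[0] - 1))
    n_comp, lab = connected_components(graph, directed=False)
    if n_comp > 1:
        keep = lab == np.bincount(lab).argmax()
        X = X[keep]
        note = f"kept largest of {n_comp} graph components ({keep.sum()} points)"
    max_dim = min(max_dim, X.shape[0] - 1, X.shape[1])
    iso = Isomap(n_neighbors=min(k_neighbors, X.shape[0] - 1),
                 n_components=max_dim).fit(X)
    geo = iso.dist_matrix_[np.triu_indices(X.shape[0], k=1)]
    resid = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        emb = pdist(iso.embedding_[:, :d])
        r = np.corrcoef(geo, emb)[0, 1]
        resid[d - 1] = 100.0 * (1.0 - r * r)
    return ResidualVarianceCurve(method="isomap",
                                 dims=np.arange(1, max_dim + 1),
                                 residual_percent=resid, note=note)


def dense_recurrent_matrix(realization) -> np.ndarray:
    """Dense neuron-level recurrent weight matrix (mV*ms), J[post, pre]."""
    n = realization.n_rec
    J = np.zeros((n, n))
    pre = np.repeat(np.arange(n), np.diff(realization.out_ptr))
    J[realization.out_tgt, pre] = realization.out_w
    return J


@dataclass
class ImbalanceReport:
    """Outcome of the small-singular-value stimulus-energy test."""

    singular_values: np.ndarray  # ascending
    rho0: float
    n_below: int
    stimulus_fraction: float
    threshold: float
    imbalance_forced: bool

    @property
    def verdict(self) -> str:
        return ("imbalance forced" if self.imbalance_forced
                else "balance not obstructed")


def svd_imbalance_diagnostic(J: np.ndarray, X: np.ndarray,
                             rho0: float | None = None,
                             threshold: float = 0.01) -> ImbalanceReport:
    """Detailed-balance obstruction test via the SVD of the connectivity.

    Computes the fraction of the squared stimulus norm lying in the span
    of left singular vectors whose singular values are at most ``rho0``
    (default: 3x the median singular value).  A fraction bounded away
    from zero means the recurrent input, which is strongly attenuated in
    that subspace, cannot cancel the stimulus there: single-neuron
    balance is impossible.
    """
    J = np.asarray(J, dtype=float)
    X = np.asarray(X, dtype=float).ravel()
    if J.shape[0] != X.size:
        raise ValueError("stimulus length must match matrix rows")
    nrm = np.linalg.norm(X)
    if nrm == 0:
        raise ValueError("stimulus must be nonzero")
    U, s, _ = np.linalg.svd(J)
    order = np.argsort(s)  # ascending
    s_asc = s[order]
    U_asc = U[:, order]
    if rho0 is None:
        rho0 = 3.0 * float(np.median(s_asc))
    n_below = int(np.sum(s_asc <= rho0))
    proj = U_asc[:, :n_below].T @ X
    frac = float(np.sum(proj ** 2) / nrm ** 2)
    return ImbalanceReport(singular_values=s_asc, rho0=float(rho0),
                           n_below=n_below, stimulus_fraction=frac,
                           threshold=threshold,
                           imbalance_forced=frac >= threshold)
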