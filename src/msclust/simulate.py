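"""Synthetic data generators with two-layer ground truth.

Two generators are provided:

* a hierarchical multivariate-Gaussian generator: cells carry a block
  correlation structure with an inner layer of tightly correlated seed
  clusters (rho_in) nested inside outer clusters of weaker correlation
  (rho_out), zero correlation elsewhere, plus i.i.d. Gaussian measurement
  noise of amplitude sigma added to every matrix entry;

* a Splatter-style count generator: gamma gene means, log-normal library
  sizes, per-group log-normal differential-expression factors, Poisson
  counts and an extra logistic-in-log-mean dropout mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import ExpressionMatrix

SCENARIO_REGULAR = "regular"
SCENARIO_IRREGULAR = "irregular"

# seed-cluster sizes and outer-layer composition (seeds per outer cluster)
_COMPOSITIONS = {
    # 21 seed clusters of 50 cells; six outer clusters of 3 seeds each and
    # three standalone seeds at the outer layer (1,050 cells)
    SCENARIO_REGULAR: ([50] * 21, [3, 3, 3, 3, 3, 3, 1, 1, 1]),
    # heterogeneous seeds (12x25, 6x50, 3x100 = 900 cells); each of three
    # outer clusters merges 4 small + 2 medium + 1 large seed
    SCENARIO_IRREGULAR: (
        [25] * 12 + [50] * 6 + [100] * 3,
        None,  # interleaved composition built in _irregular_outer
    ),
}


@dataclass
class GaussianSpec:
    """Parameters of the two-layer correlated Gaussian generator.

    ``delta_rho`` is the correlation gap rho_in - rho_out; by default
    rho_out = delta_rho and rho_in = 2 * delta_rho.  ``sigma`` is the SD of
    the additive noise; the pre-noise marginals are standard normal.
    """

    scenario: str = SCENARIO_REGULAR
    delta_rho: float = 0.125
    sigma: float = 0.5
    n_features: int = 500
    rho_in: float | None = None
    rho_out: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in _COMPOSITIONS:
            raise ValueError(f"unknown scenario: {self.scenario}")
        if self.rho_out is None:
            self.rho_out = self.delta_rho
        if self.rho_in is None:
            self.rho_in = self.rho_out + self.delta_rho
        if not 0 < self.rho_out < self.rho_in < 1:
            raise ValueError("need 0 < rho_out < rho_in < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class GaussianTruth:
    inner_labels: np.ndarray
    outer_labels: np.ndarray
    sigma_matrix: np.ndarray


def _irregular_outer() -> np.ndarray:
    """Outer-cluster id per seed for the irregular scenario: 3 outer
    clusters, each 4 small + 2 medium + 1 large seed."""
    out = np.empty(21, dtype=np.int64)
    out[:12] = np.repeat(np.arange(3), 4)  # small seeds
    out[12:18] = np.repeat(np.arange(3), 2)  # medium seeds
    out[18:] = np.arange(3)  # large seeds
    return out


def _layout(scenario: str) -> tuple[np.ndarray, np.ndarray]:
    sizes, comp = _COMPOSITIONS[scenario]
    inner = np.repeat(np.arange(len(sizes)), sizes)
    if scenario == SCENARIO_IRREGULAR:
        seed_outer = _irregular_outer()
    else:
        seed_outer = np.repeat(np.arange(len(comp)), comp)
    outer = seed_outer[inner]
    return inner, outer


def build_correlation(spec: GaussianSpec) -> tuple[np.ndarray, GaussianTruth]:
    """Cell-by-cell generating correlation matrix and ground-truth labels."""
    inner, outer = _layout(spec.scenario)
    same_outer = outer[:, None] == outer[None, :]
    same_inner = inner[:, None] == inner[None, :]
    C = np.where(same_outer, spec.rho_out, 0.0)
    C[same_inner] = spec.rho_in
    np.fill_diagonal(C, 1.0)
    # PSD check per outer block (blocks are independent)
    for o in np.unique(outer):
        ix = np.flatnonzero(outer == o)
        w = np.linalg.eigvalsh(C[np.ix_(ix, ix)])
        if w.min() < -1e-8:
            raise ValueError(f"correlation block {o} is not positive semidefinite")
    return C, GaussianTruth(inner, outer, C)


def gaussian_hierarchy(spec: GaussianSpec) -> tuple[ExpressionMatrix, GaussianTruth]:
    """Draw ``n_features`` i.i.d. feature vectors over cells from N(0, C)
    and add elementwise N(0, sigma^2) noise."""
    C, truth = build_correlation(spec)
    n = C.shape[0]
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    Z = rng.standard_normal((spec.n_features, n))
    X = Z @ L.T
    if spec.sigma > 0:
        X = X + spec.sigma * rng.standard_normal(X.shape)
    expr = ExpressionMatrix(
        X,
        [f"g{j}" for j in range(spec.n_features)],
        [f"cell{i}" for i in range(n)],
    )
    return expr, truth


def truth_cophenetic(truth: GaussianTruth, spec: GaussianSpec) -> np.ndarray:
    """Ground-truth cophenetic distances from the generating correlations
    via the correlation distance d = sqrt(2 (1 - rho))."""
    inner, outer = truth.inner_labels, truth.outer_labels
    same_inner = inner[:, None] == inner[None, :]
    same_outer = outer[:, None] == outer[None, :]
    D = np.full(same_inner.shape, np.sqrt(2.0))
    D[same_outer] = np.sqrt(2.0 * (1.0 - spec.rho_out))
    D[same_inner] = np.sqrt(2.0 * (1.0 - spec.rho_in))
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class SplatterSpec:
    """Parameters of the Splatter-style count generator.

    Library sizes are log-normal with location ``lib_loc`` and scale
    ``lib_scale``; dropout probability is logistic in the log expected
    count: pi = 1 / (1 + exp(-k (ln lambda - x0))) with shape k = -1, so
    low-expression entries drop out more often.  Gene-level defaults follow
    the simulation framework's standard parameterization.
    """

    group_sizes: tuple = (50, 35, 15)
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    dropout_mid: float = 0.0  # x0
    dropout_shape: float = -1.0  # k
    n_genes: int = 10000
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    de_prob: float = 0.1
    de_loc: float = 0.1
    de_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.lib_scale <= 0:
            raise ValueError("lib_scale must be positive")


def dropout_probability(lam: np.ndarray, x0: float, k: float) -> np.ndarray:
    """Logistic dropout probability in ln(lambda)."""
    with np.errstate(divide="ignore"):
        loglam = np.log(lam)
    return 1.0 / (1.0 + np.exp(-k * (loglam - x0)))


def splatter_like(spec: SplatterSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a counts matrix (genes x cells) with group structure,
    log-normal library sizes, Poisson sampling and logistic dropout.
    Returns the counts and the per-cell group labels."""
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    n_groups = len(spec.group_sizes)
    labels = np.repeat(np.arange(n_groups), spec.group_sizes)
    n_cells = labels.size

    base = rng.gamma(spec.mean_shape, 1.0 / spec.mean_rate, size=n_genes)
    group_means = np.tile(base, (n_groups, 1))  # groups x genes
    for gidx in range(n_groups):
        de = rng.random(n_genes) < spec.de_prob
        factors = np.exp(rng.normal(spec.de_loc, spec.de_scale, size=int(de.sum())))
        flip = rng.random(int(de.sum())) < 0.5
        factors[flip] = 1.0 / factors[flip]
        group_means[gidx, de] *= factors
    props = group_means / group_means.sum(axis=1, keepdims=True)

    lib = rng.lognormal(spec.lib_loc, spec.lib_scale, size=n_cells)
    lam = props[labels].T * lib[None, :]  # genes x cells expected counts
    counts = rng.poisson(lam).astype(float)
    pi = dropout_probability(lam, spec.dropout_mid, spec.dropout_shape)
    keep = rng.random(lam.shape) >= pi
    counts *= keep
    expr = ExpressionMatrix(
        counts,
        [f"g{j}" for j in range(n_genes)],
        [f"cell{i}" for i in range(n_cells)],
    )
    return expr, labels
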