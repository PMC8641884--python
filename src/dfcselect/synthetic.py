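"""Synthetic expression designs used to probe discriminative gene selection.

Two four-gene Gaussian designs construct *DE-equivalent* genes: every gene
has the same within-group variance and the same absolute difference of group
means, so a per-gene two-sample test cannot distinguish them.  What differs
is the joint structure:

* **Case I (correlated expression)** - all genes have variance 1 and a mean
  gap of magnitude 2 between groups A and B; the pair (X3, X4) is correlated
  (r = 0.7) within both groups, with the pair's mean displacement oriented
  against the correlation axis, while every other pair is independent.
* **Case II (heterogeneous population)** - group B is a mixture of three
  equal subpopulations: B1 expresses X1, B2 expresses X2, B3 expresses
  neither, so X1 and X2 are mutually exclusive within B.  Component means
  and mixing weight are chosen so that the marginal mean and variance of
  every gene match between groups (mu_B = 5/3, sigma^2 = 59/9 with the
  default parameters, mu_A = 5).

A third generator produces a simplified two-population correlated count
matrix with dropout, emulating marker genes drawn from two gene
co-expression networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, LabeledDataset

__all__ = [
    "Case1Design",
    "Case2Design",
    "mixture_moments",
    "generate_case1",
    "generate_case2",
    "generate_two_population_counts",
]


@dataclass(frozen=True)
class Case1Design:
    """Parameters of the correlated-pair design (case I).

    ``mean_gap`` is the absolute difference of group means shared by all
    four genes; ``rho`` is the within-group correlation of (X3, X4).
    """

    n_per_group: int = 1000
    sigma2: float = 1.0
    mean_gap: float = 2.0
    rho: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")


@dataclass(frozen=True)
class Case2Design:
    """Parameters of the exclusive-subpopulation design (case II).

    Group B splits into three subgroups of ``n_per_subgroup_b`` cells each;
    the marginal distribution of X1 and X2 within B is the two-component
    mixture ``p * g(mu1, sigma1_2) + (1 - p) * g(mu2, sigma2_2)``.  All
    non-mixture variables are single Gaussians with the matching group mean
    and the common mixture variance, so all four genes are DE-equivalent.
    """

    n_group_a: int = 1000
    n_per_subgroup_b: int = 333
    mu1: float = 0.0
    mu2: float = 5.0
    sigma1_2: float = 1.0
    sigma2_2: float = 1.0
    p: float = 2.0 / 3.0
    mu_a: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_per_subgroup_b < 1:
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("mixing proportion p must lie strictly inside (0, 1)")
        if self.sigma1_2 <= 0 or self.sigma2_2 <= 0:
            raise ValueError("component variances must be positive")

    @property
    def mu_b(self) -> float:
        return mixture_moments(self.mu1, self.mu2, self.sigma1_2, self.sigma2_2, self.p)[0]

    @property
    def sigma2(self) -> float:
        return mixture_moments(self.mu1, self.mu2, self.sigma1_2, self.sigma2_2, self.p)[1]


def mixture_moments(mu1, mu2, sigma1_2, sigma2_2, p):
    """Mean and variance of a two-component Gaussian mixture.

    mu = p*mu1 + (1-p)*mu2
    sigma^2 = p*sigma1^2 + (1-p)*sigma2^2 + p*(1-p)*(mu1 - mu2)^2
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if sigma1_2 < 0 or sigma2_2 < 0:
        raise ValueError("variances must be nonnegative")
    mu = p * mu1 + (1.0 - p) * mu2
    sigma2 = p * sigma1_2 + (1.0 - p) * sigma2_2 + p * (1.0 - p) * (mu1 - mu2) ** 2
    return mu, sigma2


_GENES4 = np.array(["X1", "X2", "X3", "X4"], dtype=object)


def _cells(prefix: str, n: int) -> np.ndarray:
    return np.array([f"{prefix}{i + 1:04d}" for i in range(n)], dtype=object)


def generate_case1(design: Case1Design | None = None, **kwargs) -> LabeledDataset:
    """Draw the case I dataset: four DE-equivalent genes, one correlated pair.

    Within each group (X3, X4) follow a bivariate Gaussian with correlation
    ``rho``; all other pairs are independent.  Group means are placed
    symmetrically about zero with gap ``mean_gap`` per gene; the gap of X4
    has the opposite sign so that the group displacement of the correlated
    pair is orthogonal to its correlation axis - the configuration in which
    the pair carries far more joint discriminative information than any
    independent gene despite identical marginal statistics.
    """
    if design is None:
        design = Case1Design(**kwargs)
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    sd = math.sqrt(design.sigma2)
    half = design.mean_gap / 2.0
    # mu_A - mu_B = (+gap, +gap, +gap, -gap)
    mu_a = np.array([half, half, half, -half])
    cov = np.eye(4) * design.sigma2
    cov[2, 3] = cov[3, 2] = design.rho * design.sigma2

    blocks = []
    for mu in (mu_a, -mu_a):
        x12 = rng.normal(loc=mu[:2], scale=sd, size=(n, 2))
        chol = np.linalg.cholesky(cov[2:, 2:])
        x34 = rng.standard_normal((n, 2)) @ chol.T + mu[2:]
        blocks.append(np.hstack([x12, x34]))
    values = np.vstack(blocks)
    cell_ids = np.concatenate([_cells("A", n), _cells("B", n)])
    group = np.array(["A"] * n + ["B"] * n, dtype=object)
    matrix = ExpressionMatrix(values, _GENES4, cell_ids)
    return LabeledDataset(matrix, group)


def generate_case2(design: Case2Design | None = None, **kwargs) -> LabeledDataset:
    """Draw the case II dataset: exclusive subpopulations inside group B.

    Group A cells draw all four genes from ``N(mu_a, sigma^2)`` with the
    common mixture variance.  Group B cells draw X3 and X4 from
    ``N(mu_b, sigma^2)``; X1 and X2 follow the exclusive assignment: B1
    draws X1 from the high component ``g(mu2, sigma2_2)`` and X2 from the
    low component ``g(mu1, sigma1_2)``, B2 the reverse, B3 both from the
    low component.
    """
    if design is None:
        design = Case2Design(**kwargs)
    rng = np.random.default_rng(design.seed)
    n_a = design.n_group_a
    n_sub = design.n_per_subgroup_b
    n_b = 3 * n_sub
    mu_b, sigma2 = mixture_moments(
        design.mu1, design.mu2, design.sigma1_2, design.sigma2_2, design.p
    )
    sd = math.sqrt(sigma2)
    lo_mu, lo_sd = design.mu1, math.sqrt(design.sigma1_2)
    hi_mu, hi_sd = design.mu2, math.sqrt(design.sigma2_2)

    a_vals = rng.normal(loc=design.mu_a, scale=sd, size=(n_a, 4))

    b_vals = np.empty((n_b, 4))
    sub = np.repeat(["B1", "B2", "B3"], n_sub)
    # exclusive mixture for X1/X2 by subgroup
    x1_mu = np.where(sub == "B1", hi_mu, lo_mu)
    x1_sd = np.where(sub == "B1", hi_sd, lo_sd)
    x2_mu = np.where(sub == "B2", hi_mu, lo_mu)
    x2_sd = np.where(sub == "B2", hi_sd, lo_sd)
    b_vals[:, 0] = rng.normal(x1_mu, x1_sd)
    b_vals[:, 1] = rng.normal(x2_mu, x2_sd)
    b_vals[:, 2:] = rng.normal(loc=mu_b, scale=sd, size=(n_b, 2))

    values = np.vstack([a_vals, b_vals])
    cell_ids = np.concatenate([_cells("A", n_a), _cells("B", n_b)])
    group = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    subgroup = np.concatenate([np.array([""] * n_a, dtype=object), sub.astype(object)])
    matrix = ExpressionMatrix(values, _GENES4, cell_ids)
    return LabeledDataset(matrix, group, subgroup)


def generate_two_population_counts(
    n_a: int = 500,
    n_b: int = 493,
    n_genes: int = 15,
    n_markers_per_network: int = 4,
    dropout_rate: float = 0.3,
    seed: int | None = None,
    base_rate: float = 5.0,
    marker_fold: float = 6.0,
    factor_scale: float = 0.8,
) -> LabeledDataset:
    """Simplified two-population count matrix with correlated marker modules.

    Two marker modules (``Gene1_1 .. GeneK_1`` and ``Gene1_2 .. GeneK_2``)
    emulate genes drawn from two co-expression networks: markers within a
    module share a per-cell latent factor (log-normal Poisson), so they are
    correlated within a cell population, while markers of different modules
    share nothing and are only weakly correlated.  Module-1 markers are
    up-regulated in group A and module-2 markers in group B; remaining
    genes are unstructured background.  Dropout is independent Bernoulli
    zeroing of the latent counts with probability ``dropout_rate``.

    The latent counts and the dropout mask use independent RNG streams
    spawned from ``seed``, so changing ``dropout_rate`` alone never changes
    the underlying counts.
    """
    if min(n_a, n_b, n_genes, n_markers_per_network) < 1:
        raise ValueError("all counts must be positive")
    if 2 * n_markers_per_network > n_genes:
        raise ValueError("marker genes cannot exceed the gene universe")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")

    ss = np.random.SeedSequence(seed)
    latent_rng, dropout_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = n_a + n_b
    k = n_markers_per_network
    group = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    is_a = (group == "A").astype(float)

    log_mu = np.full((n, n_genes), math.log(base_rate))
    # per-cell shared factor per module -> within-module correlation
    f1 = latent_rng.normal(0.0, factor_scale, size=n)
    f2 = latent_rng.normal(0.0, factor_scale, size=n)
    lf = math.log(marker_fold)
    log_mu[:, :k] += f1[:, None] + lf * is_a[:, None]
    log_mu[:, k : 2 * k] += f2[:, None] + lf * (1.0 - is_a)[:, None]

    latent = latent_rng.poisson(np.exp(log_mu)).astype(float)
    if dropout_rate > 0.0:
        keep = dropout_rng.random(latent.shape) >= dropout_rate
        counts = latent * keep
    else:
        counts = latent

    gene_ids = np.array(
        [f"Gene{i + 1}_1" for i in range(k)]
        + [f"Gene{i + 1}_2" for i in range(k)]
        + [f"Bg{i + 1}" for i in range(n_genes - 2 * k)],
        dtype=object,
    )
    cell_ids = np.concatenate([_cells("A", n_a), _cells("B", n_b)])
    matrix = ExpressionMatrix(counts, gene_ids, cell_ids)
    return LabeledDataset(matrix, group)
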