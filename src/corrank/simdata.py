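"""Synthetic expression matrices with known differential-expression truth.

Two generation routes are provided:

* **template route** — start from a real (or surrogate) expression matrix,
  standardize each gene within the template's own groups (mean 0, mean
  square 1), randomly re-split the columns into two new treatment groups,
  and spike known offsets into group 2 of randomly chosen genes.  The
  standardization preserves the intergene correlation of the template while
  equalizing gene energy, and the random re-split guarantees that, before
  spiking, no gene carries a genuine group difference beyond sampling noise.
* **simulation route** — draw columns i.i.d. from a zero-mean multivariate
  Gaussian with a parametric covariance (identity, block, AR(1), latent
  factors, or a user-supplied dense matrix), then spike.

Every operation is reproducible bit-exactly from its seed.
"""

from __future__ import annotations

import abc
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
import scipy.linalg
from numpy.random import SeedSequence, default_rng

from .errors import ValidationError
from .stats_core import ExpressionMatrix, GroupLabels

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeParams",
    "ExperimentParams",
    "TrialData",
    "CovarianceSpec",
    "IdentityCov",
    "BlockCov",
    "AR1Cov",
    "FactorCov",
    "DenseCov",
    "as_cov_spec",
    "brca_like_cov",
    "row_standardize",
    "random_split",
    "spike_in",
    "simulate_gaussian",
    "make_trial",
]


@dataclass(frozen=True)
class SpikeParams:
    """Spike-in parameters: how many genes are regulated and by how much."""

    G_plus: int
    G_minus: int
    x_plus: float
    x_minus: float
    p_delta: Optional[float] = None

    def __post_init__(self):
        if self.G_plus < 0 or self.G_minus < 0:
            raise ValidationError("G_plus and G_minus must be non-negative")
        if self.x_plus < 0 or self.x_minus > 0:
            raise ValidationError(
                f"offsets must satisfy x_plus >= 0 >= x_minus "
                f"(got x_plus={self.x_plus}, x_minus={self.x_minus})"
            )

    @property
    def G_delta(self) -> int:
        """Total number of truly differential genes."""
        return self.G_plus + self.G_minus


@dataclass(frozen=True)
class ExperimentParams:
    """Gene-discovery experiment parameters."""

    p0: float
    G: int
    G_star: int
    M1: int
    M2: int

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValidationError(f"p0 must lie in (0, 1), got {self.p0}")
        if self.M1 < 2 or self.M2 < 2:
            raise ValidationError("each group needs at least 2 samples")
        G0 = int(np.floor(self.p0 * self.G + 0.5))
        if self.G_star > self.G - G0:
            raise ValidationError(
                f"G_star={self.G_star} exceeds candidate set size {self.G - G0}"
            )
        if self.G_star < 1:
            raise ValidationError("G_star must be >= 1")


@dataclass
class TrialData:
    """A generated trial: data, labels, and the ground-truth gene set."""

    X: ExpressionMatrix
    labels: GroupLabels
    truth: Dict[str, int]  # gene id -> +1 (up) or -1 (down)
    seed: Optional[int] = None

    @property
    def truth_set(self) -> set:
        return set(self.truth)


# ---------------------------------------------------------------------------
# covariance specifications
# ---------------------------------------------------------------------------


class CovarianceSpec(abc.ABC):
    """A gene-gene covariance family with an exact sampler."""

    @abc.abstractmethod
    def sample(self, G: int, M: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (G, M) matrix whose columns are i.i.d. N(0, Lambda)."""

    @abc.abstractmethod
    def matrix(self, G: int) -> np.ndarray:
        """The dense G x G covariance matrix (tests / small problems only)."""


class IdentityCov(CovarianceSpec):
    def sample(self, G, M, rng):
        return rng.standard_normal((G, M))

    def matrix(self, G):
        return np.eye(G)


class BlockCov(CovarianceSpec):
    """Equicorrelated blocks: correlation ``rho`` inside consecutive blocks."""

    def __init__(self, rho: float, block_size: int):
        if not 0.0 <= rho < 1.0:
            raise ValidationError(f"block rho must lie in [0, 1), got {rho}")
        if block_size < 1:
            raise ValidationError("block_size must be >= 1")
        self.rho = float(rho)
        self.block_size = int(block_size)

    def sample(self, G, M, rng):
        n_blocks = -(-G // self.block_size)
        shared = rng.standard_normal((n_blocks, M))
        eps = rng.standard_normal((G, M))
        block_of = np.arange(G) // self.block_size
        return np.sqrt(self.rho) * shared[block_of] + np.sqrt(1.0 - self.rho) * eps

    def matrix(self, G):
        block_of = np.arange(G) // self.block_size
        R = np.where(block_of[:, None] == block_of[None, :], self.rho, 0.0)
        np.fill_diagonal(R, 1.0)
        return R


class AR1Cov(CovarianceSpec):
    """First-order autoregressive correlation along the gene index."""

    def __init__(self, rho: float):
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"AR(1) rho must lie in (-1, 1), got {rho}")
        self.rho = float(rho)

    def sample(self, G, M, rng):
        z = rng.standard_normal((G, M))
        out = np.empty((G, M))
        out[0] = z[0]
        c = np.sqrt(1.0 - self.rho**2)
        for g in range(1, G):
            out[g] = self.rho * out[g - 1] + c * z[g]
        return out

    def matrix(self, G):
        return scipy.linalg.toeplitz(self.rho ** np.arange(G))


class FactorCov(CovarianceSpec):
    """Latent-factor covariance with unit diagonal.

    ``Lambda = (1 - w) I + w U U^T`` where the rows of U are unit-norm
    loadings on ``n_factors`` latent factors and ``w`` is the fraction of
    each gene's variance shared through the factors.  The root-mean-square
    intergene correlation is approximately ``w / sqrt(n_factors)``.
    """

    def __init__(self, n_factors: int, shared_frac: float, loading_seed: int = 0):
        if n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        if not 0.0 <= shared_frac < 1.0:
            raise ValidationError(
                f"shared_frac must lie in [0, 1), got {shared_frac}"
            )
        self.n_factors = int(n_factors)
        self.shared_frac = float(shared_frac)
        self.loading_seed = int(loading_seed)

    def loadings(self, G: int) -> np.ndarray:
        L = default_rng(self.loading_seed).standard_normal((G, self.n_factors))
        return L / np.linalg.norm(L, axis=1, keepdims=True)

    def sample(self, G, M, rng):
        U = self.loadings(G)
        F = rng.standard_normal((self.n_factors, M))
        E = rng.standard_normal((G, M))
        w = self.shared_frac
        return np.sqrt(w) * (U @ F) + np.sqrt(1.0 - w) * E

    def matrix(self, G):
        U = self.loadings(G)
        w = self.shared_frac
        Lam = w * (U @ U.T)
        Lam += (1.0 - w) * np.eye(G)
        return Lam


class DenseCov(CovarianceSpec):
    """User-supplied dense positive semi-definite covariance matrix."""

    def __init__(self, matrix: np.ndarray):
        A = np.asarray(matrix, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("covariance matrix must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValidationError("covariance matrix must be symmetric")
        w, V = np.linalg.eigh(A)
        scale = max(abs(w[0]), abs(w[-1]), 1.0)
        if w[0] < -1e-8 * scale:
            raise ValidationError(
                f"covariance matrix is not positive semi-definite "
                f"(smallest eigenvalue {w[0]:.3e})"
            )
        self._A = A
        self._root = V * np.sqrt(np.clip(w, 0.0, None))

    def sample(self, G, M, rng):
        if G != self._A.shape[0]:
            raise ValidationError(
                f"covariance matrix is {self._A.shape[0]}x{self._A.shape[0]} "
                f"but G={G} was requested"
            )
        return self._root @ rng.standard_normal((G, M))

    def matrix(self, G):
        if G != self._A.shape[0]:
            raise ValidationError("dimension mismatch for dense covariance")
        return self._A.copy()


def as_cov_spec(obj) -> CovarianceSpec:
    """Coerce a covariance specification: spec object, array, or 'identity'."""
    if isinstance(obj, CovarianceSpec):
        return obj
    if isinstance(obj, str):
        if obj == "identity":
            return IdentityCov()
        raise ValidationError(f"unknown covariance spec {obj!r}")
    if isinstance(obj, np.ndarray):
        return DenseCov(obj)
    raise ValidationError(f"cannot interpret covariance spec of type {type(obj).__name__}")


def brca_like_cov() -> FactorCov:
    """Surrogate for a microarray-strength covariance (unit variances).

    Ten latent factors carrying half of each gene's variance give a
    root-mean-square intergene correlation of about 0.16, in the range
    reported for strongly correlated breast-cancer microarray panels.
    """
    return FactorCov(n_factors=10, shared_frac=0.5, loading_seed=56)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def row_standardize(X: ExpressionMatrix, labels: GroupLabels) -> ExpressionMatrix:
    """Force each (gene, group) block to mean 0 and mean square 1.

    Intergene correlation within each group is preserved (the transform is
    affine per gene per group).  Genes that are constant within either group
    are dropped; the number dropped is logged as a warning.
    """
    groups = labels.groups_for(X.sample_ids)
    out = X.values.copy()
    keep = np.ones(X.n_genes, dtype=bool)
    for k in (1, 2):
        cols = np.flatnonzero(groups == k)
        if cols.size < 2:
            raise ValidationError(f"group {k} has fewer than 2 samples")
        block = out[:, cols]
        block = block - block.mean(axis=1, keepdims=True)
        ms = np.einsum("ij,ij->i", block, block) / cols.size
        zero = ms == 0.0
        keep &= ~zero
        with np.errstate(divide="ignore", invalid="ignore"):
            block /= np.sqrt(ms)[:, None]
        out[:, cols] = block
    if not keep.all():
        logger.warning(
            "row_standardize dropped %d constant gene(s)", int((~keep).sum())
        )
        out = out[keep]
    return ExpressionMatrix(out, X.gene_ids[keep], X.sample_ids.copy())


def random_split(
    M: int, M1: int, M2: int, seed, sample_ids=None
) -> GroupLabels:
    """Uniformly random partition of M samples into groups of M1 and M2."""
    if M1 + M2 != M:
        raise ValidationError(f"M1 + M2 = {M1 + M2} does not equal M = {M}")
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(M)]
    else:
        sample_ids = list(sample_ids)
        if len(sample_ids) != M:
            raise ValidationError("sample_ids length does not match M")
    perm = default_rng(seed).permutation(M)
    groups = np.empty(M, dtype=np.int64)
    groups[perm[:M1]] = 1
    groups[perm[M1:]] = 2
    return GroupLabels.from_arrays(sample_ids, groups)


def spike_in(
    Xs: ExpressionMatrix,
    labels: GroupLabels,
    sp: SpikeParams,
    seed,
    pool: Optional[np.ndarray] = None,
) -> TrialData:
    """Add known offsets to group-2 entries of randomly chosen genes.

    ``G_plus`` genes receive ``x_plus`` and ``G_minus`` genes receive
    ``x_minus`` in every group-2 column; the (disjoint) gene sets are drawn
    uniformly without replacement from ``pool`` (default: all genes).
    """
    G = Xs.n_genes
    if sp.G_delta > G:
        raise ValidationError(
            f"cannot spike {sp.G_delta} genes into a matrix of {G} genes"
        )
    if pool is None:
        pool = np.arange(G)
    else:
        pool = np.asarray(pool, dtype=np.int64)
        if sp.G_delta > pool.size:
            raise ValidationError("spike pool is smaller than G_delta")
    rng = default_rng(seed)
    chosen = rng.choice(pool, size=sp.G_delta, replace=False)
    up, down = chosen[: sp.G_plus], chosen[sp.G_plus :]
    cols2 = np.flatnonzero(labels.groups_for(Xs.sample_ids) == 2)
    values = Xs.values.copy()
    if up.size:
        values[np.ix_(up, cols2)] += sp.x_plus
    if down.size:
        values[np.ix_(down, cols2)] += sp.x_minus
    truth: Dict[str, int] = {}
    for g in up:
        truth[str(Xs.gene_ids[g])] = +1
    for g in down:
        truth[str(Xs.gene_ids[g])] = -1
    X = ExpressionMatrix(values, Xs.gene_ids.copy(), Xs.sample_ids.copy())
    return TrialData(X=X, labels=labels, truth=truth)


def simulate_gaussian(
    G: int, M1: int, M2: int, cov_spec, seed
) -> ExpressionMatrix:
    """Null matrix with i.i.d. N(0, Lambda) columns, M = M1 + M2 of them."""
    if G < 2:
        raise ValidationError("need at least 2 genes")
    if M1 < 2 or M2 < 2:
        raise ValidationError("each group needs at least 2 samples")
    cov = as_cov_spec(cov_spec)
    rng = default_rng(seed)
    values = cov.sample(G, M1 + M2, rng)
    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    sample_ids = [f"s{j + 1:03d}" for j in range(M1 + M2)]
    return ExpressionMatrix(values, gene_ids, sample_ids)


def _nominal_labels(sample_ids) -> GroupLabels:
    """Fallback template grouping: first half group 1, second half group 2."""
    M = len(sample_ids)
    n1 = M // 2
    groups = [1] * n1 + [2] * (M - n1)
    return GroupLabels.from_arrays(sample_ids, groups)


def make_trial(
    source: Union[ExpressionMatrix, CovarianceSpec, np.ndarray, str],
    sp: SpikeParams,
    ep: ExperimentParams,
    seed: int,
    template_labels: Optional[GroupLabels] = None,
) -> TrialData:
    """Generate one trial with known truth from a template or a covariance.

    Template route: optionally subsample ``M1 + M2`` columns (small-sample
    robustness trials), standardize each gene within the *template's* groups
    (``template_labels``; defaults to a nominal half split), randomly
    re-split the columns into the trial's two groups, then spike.  The
    standardization grouping is deliberately distinct from the trial split:
    standardizing within the trial groups would zero every null t-statistic
    exactly and trivialize the problem.

    Simulation route: draw the null matrix from the covariance spec, split
    the (exchangeable) columns at random, then spike.
    """
    child = SeedSequence(seed).spawn(3)
    if isinstance(source, ExpressionMatrix):
        if source.n_genes != ep.G:
            raise ValidationError(
                f"template has {source.n_genes} genes but experiment expects {ep.G}"
            )
        M = ep.M1 + ep.M2
        X = source
        if source.n_samples > M:
            cols = np.sort(
                default_rng(child[0]).choice(source.n_samples, size=M, replace=False)
            )
            X = ExpressionMatrix(
                source.values[:, cols], source.gene_ids.copy(), source.sample_ids[cols]
            )
        elif source.n_samples < M:
            raise ValidationError(
                f"template has {source.n_samples} samples; experiment needs {M}"
            )
        tlabels = template_labels if template_labels is not None else _nominal_labels(X.sample_ids)
        Xs = row_standardize(X, tlabels)
        labels = random_split(M, ep.M1, ep.M2, child[1], sample_ids=Xs.sample_ids)
        trial = spike_in(Xs, labels, sp, child[2])
    else:
        X = simulate_gaussian(ep.G, ep.M1, ep.M2, source, child[0])
        labels = random_split(
            X.n_samples, ep.M1, ep.M2, child[1], sample_ids=X.sample_ids
        )
        trial = spike_in(X, labels, sp, child[2])
    trial.seed = int(seed)
    return trial


# Parameter presets for the benchmark scenarios exercised in the test suite.
CASE1_SPIKE = SpikeParams(G_plus=200, G_minus=100, x_plus=0.1, x_minus=-0.1, p_delta=0.025)
CASE2_SPIKE = SpikeParams(G_plus=600, G_minus=600, x_plus=0.02, x_minus=-0.02, p_delta=0.1)
GAUSSIAN_SPIKE = SpikeParams(G_plus=50, G_minus=50, x_plus=1.0, x_minus=-1.0, p_delta=0.031)
GAUSSIAN_EXPERIMENT = ExperimentParams(p0=0.5, G=3226, G_star=100, M1=10, M2=10)
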