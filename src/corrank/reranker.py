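"""Decorrelating rerank of candidate t-scores against an identified null set.

Pipeline: partition genes by |t| into an identified (assumed-null) set of
``G0 = round(p0 * G)`` genes and a candidate set of ``G1 = G - G0`` genes;
estimate the correlation partitions ``R00`` (identified x identified) and
``R10`` (candidate x identified) from the treatment-effect-removed data;
subtract from each candidate score the component linearly predictable from
the identified scores::

    tau = t1 - R10 @ solve(R00 + eps*I, t0)

The solve uses a Cholesky factorization; the explicit inverse is never
formed.  ``R10`` is only ever materialized in blocks of candidate rows, so
the full genes-by-genes correlation matrix is never held in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

import numpy as np
import scipy.linalg

from .errors import (
    FactorizationError,
    NonFiniteResultError,
    ValidationError,
)
from .stats_core import (
    ExpressionMatrix,
    GroupLabels,
    pooled_t,
    remove_treatment_effects,
    unit_energy_rows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionedScores",
    "CorrelationModel",
    "RerankResult",
    "za_partition",
    "build_correlation_model",
    "decorrelate",
    "decorrelate_scores",
    "rank_by_abs_desc",
    "rerank",
]

#: Default diagonal regularizer added to R00 before factorization.
DEFAULT_EPSILON = 1e-10

#: Warn when the smallest Cholesky pivot (squared diagonal entry of the
#: factor) falls below this value.
PIVOT_WARN_THRESHOLD = 1e-8

#: Candidate-row block size used when R10 is materialized blockwise.
DEFAULT_BLOCK_SIZE = 1024

#: Keep a dense R10 only when it has at most this many entries.
DENSE_R10_LIMIT = 4_000_000


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PartitionedScores:
    """t-scores split into identified (t0) and candidate (t1) blocks.

    ``perm`` sorts genes by ascending ``|t|`` (ties broken by ascending
    original index); the first ``G0`` sorted genes form the identified set.
    """

    perm: np.ndarray
    t0: np.ndarray
    t1: np.ndarray
    G0: int
    p0: float

    @property
    def G(self) -> int:
        return len(self.perm)

    @property
    def G1(self) -> int:
        return self.G - self.G0

    @property
    def idx0(self) -> np.ndarray:
        """Original gene indices of the identified set."""
        return self.perm[: self.G0]

    @property
    def idx1(self) -> np.ndarray:
        """Original gene indices of the candidate set."""
        return self.perm[self.G0:]


def za_partition(t: np.ndarray, p0: float) -> PartitionedScores:
    """Split genes into identified and candidate sets by |t| magnitude.

    ``G0 = round(p0 * G)`` genes with the smallest ``|t|`` are declared
    null a priori; ties are broken by ascending original gene index.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.ndim != 1:
        raise ValidationError("t must be a one-dimensional vector")
    if not np.all(np.isfinite(t)):
        raise ValidationError("t contains non-finite entries")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must lie strictly in (0, 1), got {p0}")
    G = t.size
    G0 = _round_half_up(p0 * G)
    if G0 < 2:
        raise ValidationError(
            f"identified set of size {G0} is too small to estimate R00 (need >= 2)"
        )
    if G - G0 < 1:
        raise ValidationError(f"candidate set is empty (G={G}, G0={G0})")
    perm = np.argsort(np.abs(t), kind="stable")
    return PartitionedScores(
        perm=perm, t0=t[perm[:G0]].copy(), t1=t[perm[G0:]].copy(), G0=G0, p0=float(p0)
    )


class CorrelationModel:
    """Correlation partitions of the treatment-effect-removed data.

    ``R00`` is stored with ``epsilon`` already added to its diagonal (the
    only matrix that is factorized).  ``R10`` is either a dense array (small
    problems) or represented implicitly by the unit-energy identified and
    candidate rows, from which blocks of R10 are materialized on demand.
    """

    def __init__(
        self,
        R00: np.ndarray,
        epsilon: float,
        R10: Optional[np.ndarray] = None,
        identified_rows: Optional[np.ndarray] = None,
        candidate_rows: Optional[np.ndarray] = None,
        block_size: int = DEFAULT_BLOCK_SIZE,
    ):
        self.R00 = np.asarray(R00, dtype=np.float64)
        if self.R00.ndim != 2 or self.R00.shape[0] != self.R00.shape[1]:
            raise ValidationError("R00 must be square")
        if epsilon < 0:
            raise ValidationError(f"epsilon must be >= 0, got {epsilon}")
        self.epsilon = float(epsilon)
        self.R10 = None if R10 is None else np.asarray(R10, dtype=np.float64)
        self._u0 = identified_rows
        self._u1 = candidate_rows
        if self.R10 is None and (self._u0 is None or self._u1 is None):
            raise ValidationError(
                "need either a dense R10 or identified/candidate row factors"
            )
        if self.R10 is not None and self.R10.shape[1] != self.R00.shape[0]:
            raise ValidationError("R10 column count must match R00")
        self.block_size = int(block_size)
        self._cho: Optional[Tuple[np.ndarray, bool]] = None

    @property
    def G0(self) -> int:
        return self.R00.shape[0]

    @property
    def G1(self) -> int:
        if self.R10 is not None:
            return self.R10.shape[0]
        return self._u1.shape[0]

    def cholesky(self) -> Tuple[np.ndarray, bool]:
        """Cached Cholesky factorization of the regularized R00."""
        if self._cho is None:
            try:
                self._cho = scipy.linalg.cho_factor(self.R00, lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise FactorizationError(
                    "Cholesky factorization of R00 failed even with "
                    f"epsilon={self.epsilon:g}; rerun with a larger epsilon"
                ) from exc
            pivot_min = float(np.min(np.diag(self._cho[0])) ** 2)
            if pivot_min < PIVOT_WARN_THRESHOLD:
                logger.warning(
                    "R00 is ill-conditioned (smallest Cholesky pivot %.3e); "
                    "results may be sensitive to epsilon",
                    pivot_min,
                )
        return self._cho

    def solve_identified(self, rhs: np.ndarray) -> np.ndarray:
        """Solve (R00 + eps*I) s0 = rhs without forming the inverse."""
        return scipy.linalg.cho_solve(self.cholesky(), rhs)

    def iter_r10_blocks(self) -> Iterator[Tuple[int, np.ndarray]]:
        """Yield ``(row_start, block)`` pairs covering R10 in candidate-row blocks."""
        if self.R10 is not None:
            for start in range(0, self.R10.shape[0], self.block_size):
                yield start, self.R10[start : start + self.block_size]
        else:
            for start in range(0, self._u1.shape[0], self.block_size):
                block = self._u1[start : start + self.block_size] @ self._u0.T
                np.clip(block, -1.0, 1.0, out=block)
                yield start, block

    def r10_matvec(self, v: np.ndarray) -> np.ndarray:
        """Compute ``R10 @ v`` blockwise (v may be a vector or a matrix)."""
        parts = [block @ v for _, block in self.iter_r10_blocks()]
        return np.concatenate(parts, axis=0)

    def materialize_r10(self) -> np.ndarray:
        """Dense R10 (intended for small problems and tests)."""
        if self.R10 is not None:
            return self.R10.copy()
        return np.concatenate([b for _, b in self.iter_r10_blocks()], axis=0)


def build_correlation_model(
    Xc: np.ndarray,
    part: PartitionedScores,
    epsilon: float = DEFAULT_EPSILON,
    gene_ids=None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    dense_limit: int = DENSE_R10_LIMIT,
) -> CorrelationModel:
    """Extract the R00 / R10 correlation partitions for a given ZA partition.

    ``Xc`` must be the treatment-effect-removed matrix in the original gene
    order.  ``epsilon`` is added to the diagonal of R00, and feasibility of
    its Cholesky factorization is verified before returning.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    if Xc.ndim != 2 or Xc.shape[0] != part.G:
        raise ValidationError(
            f"centered matrix has {Xc.shape[0]} rows but the partition covers {part.G} genes"
        )
    if epsilon < 0:
        raise ValidationError(f"epsilon must be >= 0, got {epsilon}")
    U = unit_energy_rows(Xc, gene_ids)
    u0 = np.ascontiguousarray(U[part.idx0])
    u1 = np.ascontiguousarray(U[part.idx1])
    R00 = u0 @ u0.T
    np.clip(R00, -1.0, 1.0, out=R00)
    np.fill_diagonal(R00, 1.0 + epsilon)
    dense = part.G0 * part.G1 <= dense_limit
    R10 = None
    if dense:
        R10 = np.clip(u1 @ u0.T, -1.0, 1.0)
    cm = CorrelationModel(
        R00,
        epsilon,
        R10=R10,
        identified_rows=None if dense else u0,
        candidate_rows=None if dense else u1,
        block_size=block_size,
    )
    cm.cholesky()  # verify feasibility up front
    return cm


def decorrelate_scores(t0: np.ndarray, t1: np.ndarray, cm: CorrelationModel) -> np.ndarray:
    """Low-level projection: ``t1 - R10 @ solve(R00 + eps*I, t0)``.

    Accepts vectors or matrices whose columns are independent replicates.
    """
    s0 = cm.solve_identified(np.asarray(t0, dtype=np.float64))
    return np.asarray(t1, dtype=np.float64) - cm.r10_matvec(s0)


@dataclass
class RerankResult:
    """Adjusted candidate scores and the resulting gene ranking."""

    tau: np.ndarray
    raw_t: np.ndarray
    candidate_indices: np.ndarray
    candidate_ids: np.ndarray
    order: np.ndarray
    raw_rank: Optional[np.ndarray] = None

    @property
    def ranking(self) -> np.ndarray:
        """Candidate gene ids ordered by decreasing |tau|."""
        return self.candidate_ids[self.order]

    def top(self, G_star: int) -> list:
        """The first ``G_star`` gene ids of the reranked list."""
        if not 1 <= G_star <= len(self.order):
            raise ValidationError(
                f"G_star={G_star} must lie in [1, {len(self.order)}] "
                "(cannot report more genes than there are candidates)"
            )
        return list(self.ranking[:G_star])


def decorrelate(
    part: PartitionedScores, cm: CorrelationModel, gene_ids=None
) -> RerankResult:
    """Apply the decorrelating projection and rank candidates by |tau|.

    Ties in |tau| are broken by ascending original gene index, which keeps
    the output equivariant under gene-row permutations.
    """
    if cm.G0 != part.G0 or cm.G1 != part.G1:
        raise ValidationError(
            f"correlation model dimensions ({cm.G1}x{cm.G0}) do not match the "
            f"partition ({part.G1}x{part.G0})"
        )
    tau = decorrelate_scores(part.t0, part.t1, cm)
    if not np.all(np.isfinite(tau)):
        raise NonFiniteResultError(
            "decorrelated scores are not finite; the correlation model is "
            "pathologically conditioned (try a larger epsilon)"
        )
    order = np.lexsort((part.idx1, -np.abs(tau)))
    if gene_ids is None:
        ids = np.asarray([str(i) for i in range(part.G)], dtype=object)
    else:
        ids = np.asarray(gene_ids, dtype=object)
    return RerankResult(
        tau=tau,
        raw_t=part.t1.copy(),
        candidate_indices=part.idx1.copy(),
        candidate_ids=ids[part.idx1],
        order=order,
    )


def rank_by_abs_desc(t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """1-based ranks by decreasing |t| (ties: ascending index) and the order."""
    t = np.asarray(t, dtype=np.float64)
    order = np.lexsort((np.arange(t.size), -np.abs(t)))
    ranks = np.empty(t.size, dtype=np.int64)
    ranks[order] = np.arange(1, t.size + 1)
    return ranks, order


def rerank(
    X: ExpressionMatrix,
    labels: GroupLabels,
    p0: float = 0.5,
    G_star: Optional[int] = None,
    epsilon: float = DEFAULT_EPSILON,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> Tuple[list, RerankResult]:
    """End-to-end reranking; returns the top-``G_star`` list and full result.

    Steps: pooled t-scores -> ZA partition at ``p0`` -> within-group mean
    removal -> correlation partitions with diagonal regularizer ``epsilon``
    -> decorrelating projection -> candidates ranked by decreasing |tau|.
    Identified genes never appear in the reported list.
    """
    t = pooled_t(X, labels)
    part = za_partition(t, p0)
    if G_star is not None and G_star > part.G1:
        raise ValidationError(
            f"G_star={G_star} exceeds the candidate set size G1={part.G1}"
        )
    Xc = remove_treatment_effects(X, labels)
    cm = build_correlation_model(
        Xc, part, epsilon=epsilon, gene_ids=X.gene_ids, block_size=block_size
    )
    result = decorrelate(part, cm, gene_ids=X.gene_ids)
    ranks, _ = rank_by_abs_desc(t)
    result.raw_rank = ranks[result.candidate_indices]
    top = result.top(G_star) if G_star is not None else list(result.ranking)
    return top, result
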