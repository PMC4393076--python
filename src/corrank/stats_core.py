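"""Per-gene two-sample summary statistics and residual correlation estimates.

The functions here operate on a genes-by-samples :class:`ExpressionMatrix`
(values on a log scale) together with a two-group :class:`GroupLabels`
assignment.  They provide:

* group means and the pooled (equal-variance, unpaired) t-statistic per gene,
* the SAM-style variant with an additive exchangeability factor ``s0``,
* removal of the per-group treatment effect (within-group mean subtraction),
* the sample correlation matrix of the treatment-effect-removed data.

The pooled standard error ``s_g`` includes the ``sqrt(1/M1 + 1/M2)`` factor,
so ``pooled_t`` is the textbook unpaired equal-variance t-statistic; under
the null its variance is ``nu / (nu - 2)`` with ``nu = M1 + M2 - 2``.  The
factor is a per-experiment constant and does not affect any gene ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    DuplicateGeneError,
    UnlabeledSampleError,
    ValidationError,
    ZeroEnergyGeneError,
)

__all__ = [
    "ExpressionMatrix",
    "GroupLabels",
    "group_means",
    "pooled_t",
    "pooled_sd",
    "sam_t",
    "remove_treatment_effects",
    "sample_correlation",
    "unit_energy_rows",
    "degrees_of_freedom",
]


def _as_id_array(ids: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be a one-dimensional sequence")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix of (log-scale) expression values.

    Parameters
    ----------
    values : array-like, shape (G, M)
        Real-valued expression matrix; no missing values allowed.
    gene_ids : sequence of str, length G
        Unique gene identifiers (row names).
    sample_ids : sequence of str, length M
        Unique sample identifiers (column names).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D matrix")
        self.gene_ids = _as_id_array(self.gene_ids, "gene_ids")
        self.sample_ids = _as_id_array(self.sample_ids, "sample_ids")
        G, M = self.values.shape
        if len(self.gene_ids) != G:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != number of rows {G}"
            )
        if len(self.sample_ids) != M:
            raise ValidationError(
                f"sample_ids length {len(self.sample_ids)} != number of columns {M}"
            )
        if G < 2:
            raise ValidationError(f"need at least 2 genes, got {G}")
        if M < 4:
            raise ValidationError(f"need at least 4 samples, got {M}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "expression matrix contains a missing or non-finite value at "
                f"gene {self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise DuplicateGeneError(f"duplicate gene ids: {', '.join(map(str, dup))}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {', '.join(map(str, dup))}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def overall_means(self) -> np.ndarray:
        """Per-gene mean over all samples (loader-level summary only)."""
        return self.values.mean(axis=1)


def _duplicates(ids: np.ndarray) -> list:
    uniq, counts = np.unique(ids.astype(str), return_counts=True)
    return list(uniq[counts > 1])


class GroupLabels:
    """Assignment of samples to the two treatment groups (1 and 2)."""

    def __init__(self, group_of: Mapping[str, int]):
        mapping = {}
        for sid, grp in group_of.items():
            g = int(grp)
            if g not in (1, 2):
                raise ValidationError(
                    f"sample {sid!r} has group {grp!r}; groups must be 1 or 2"
                )
            mapping[str(sid)] = g
        self._group_of = mapping
        counts = {1: 0, 2: 0}
        for g in mapping.values():
            counts[g] += 1
        if counts[1] < 2 or counts[2] < 2:
            raise ValidationError(
                f"each group needs at least 2 samples (got M1={counts[1]}, M2={counts[2]})"
            )
        self._m1, self._m2 = counts[1], counts[2]

    @classmethod
    def from_arrays(cls, sample_ids: Iterable[str], groups: Iterable[int]) -> "GroupLabels":
        sample_ids = list(sample_ids)
        groups = list(groups)
        if len(sample_ids) != len(groups):
            raise ValidationError("sample_ids and groups differ in length")
        if len(set(map(str, sample_ids))) != len(sample_ids):
            raise ValidationError("duplicate sample ids in label assignment")
        return cls(dict(zip(sample_ids, groups)))

    @property
    def group_of(self) -> Mapping[str, int]:
        return dict(self._group_of)

    @property
    def M1(self) -> int:
        return self._m1

    @property
    def M2(self) -> int:
        return self._m2

    @property
    def M(self) -> int:
        return self._m1 + self._m2

    def groups_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Group (1 or 2) for each requested sample, in order.

        Raises :class:`UnlabeledSampleError` naming the first sample without
        an assignment.
        """
        sids = list(sample_ids)
        out = np.empty(len(sids), dtype=np.int64)
        for i, sid in enumerate(sids):
            try:
                out[i] = self._group_of[str(sid)]
            except KeyError:
                raise UnlabeledSampleError(f"sample {sid!r} has no group label") from None
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupLabels) and self._group_of == other._group_of

    def __repr__(self) -> str:
        return f"GroupLabels(M1={self._m1}, M2={self._m2})"


def _group_masks(X: ExpressionMatrix, labels: GroupLabels):
    groups = labels.groups_for(X.sample_ids)
    m1 = groups == 1
    m2 = groups == 2
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError(
            "each group needs at least 2 samples among the matrix columns "
            f"(got {int(m1.sum())} and {int(m2.sum())})"
        )
    return m1, m2


def degrees_of_freedom(labels: GroupLabels) -> int:
    """Pooled-variance degrees of freedom, ``M1 + M2 - 2``."""
    return labels.M1 + labels.M2 - 2


def group_means(X: ExpressionMatrix, labels: GroupLabels) -> np.ndarray:
    """Per-gene group means, returned as an array of shape (G, 2).

    Column 0 holds the mean over group-1 samples, column 1 over group-2.
    """
    m1, m2 = _group_masks(X, labels)
    return np.column_stack(
        [X.values[:, m1].mean(axis=1), X.values[:, m2].mean(axis=1)]
    )


def _pooled_pieces(X: ExpressionMatrix, labels: GroupLabels):
    m1, m2 = _group_masks(X, labels)
    x1 = X.values[:, m1]
    x2 = X.values[:, m2]
    n1, n2 = x1.shape[1], x2.shape[1]
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1)
    ss += ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    nu = n1 + n2 - 2
    s = np.sqrt(ss / nu * (1.0 / n1 + 1.0 / n2))
    return mean2 - mean1, s


def pooled_sd(X: ExpressionMatrix, labels: GroupLabels) -> np.ndarray:
    """Per-gene pooled standard error ``s_g`` (includes sqrt(1/M1 + 1/M2))."""
    return _pooled_pieces(X, labels)[1]


def pooled_t(X: ExpressionMatrix, labels: GroupLabels) -> np.ndarray:
    """Unpaired equal-variance t-statistic per gene: (mean2 - mean1) / s_g.

    Genes with zero within-group variance in both groups cannot be ranked;
    their statistic is set to 0 and a ``RuntimeWarning`` is emitted.  A zero
    score keeps such genes deep in the identified (assumed-null) set.
    """
    diff, s = _pooled_pieces(X, labels)
    zero = s == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, diff / np.where(zero, 1.0, s))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) have zero pooled variance; "
            "their t-statistic was set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return t


def sam_t(X: ExpressionMatrix, labels: GroupLabels, s0: float) -> np.ndarray:
    """SAM-style statistic (mean2 - mean1) / (s_g + s0) with s0 >= 0."""
    if s0 < 0:
        raise ValidationError(f"exchangeability factor s0 must be >= 0, got {s0}")
    diff, s = _pooled_pieces(X, labels)
    denom = s + s0
    if np.any(denom == 0.0):
        # s0 == 0 and zero-variance genes: fall back to the pooled_t rule.
        return pooled_t(X, labels)
    return diff / denom


def remove_treatment_effects(X: ExpressionMatrix, labels: GroupLabels) -> np.ndarray:
    """Subtract each gene's within-group mean; returns the centered matrix.

    Nullifies genuine group differences so that only null correlation
    structure remains.  No variance scaling is applied.
    """
    m1, m2 = _group_masks(X, labels)
    out = X.values.copy()
    for mask in (m1, m2):
        out[:, mask] -= out[:, mask].mean(axis=1, keepdims=True)
    return out


def unit_energy_rows(Xc: np.ndarray, gene_ids=None) -> np.ndarray:
    """Scale each row of a centered matrix to unit sum of squares.

    Raises :class:`ZeroEnergyGeneError` naming the first zero-energy row;
    constant genes must be filtered before correlation estimation.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    zero = ss == 0.0
    if zero.any():
        i = int(np.flatnonzero(zero)[0])
        name = gene_ids[i] if gene_ids is not None else f"row {i}"
        raise ZeroEnergyGeneError(
            f"gene {name!r} has zero energy after centering; "
            "filter constant genes before estimating correlation"
        )
    return Xc / np.sqrt(ss)[:, None]


def sample_correlation(Xc: np.ndarray, gene_ids=None) -> np.ndarray:
    """Sample correlation matrix of a treatment-effect-removed matrix.

    ``R[g, g'] = sum_m x_gm x_g'm / sqrt(sum_m x_gm^2 * sum_m x_g'm^2)``
    computed across all columns (both groups pooled).  Any scalar factor
    common to all entries cancels downstream, so none is applied.
    """
    U = unit_energy_rows(Xc, gene_ids)
    R = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R
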