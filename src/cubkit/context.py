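"""Codon-pair context analysis on the 64 x 64 contingency table.

Adjacent in-frame codon pairs (5' codon in rows, 3' codon in columns)
are pooled over the gene set and compared against the independence
model E_ij = row_i * col_j / N.  Departures are expressed as adjusted
Pearson residuals,

    d_ij = (O_ij - E_ij) / sqrt(E_ij (1 - row_i/N) (1 - col_j/N)),

which have unit asymptotic variance under independence, so large |d|
marks preferred (positive) or avoided (negative) codon neighbourhoods.
A hierarchical clustering of the residual rows/columns supplies the
leaf order used for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genetic_code import ALL_CODONS
from .sequence_io import CodingSequence


@dataclass
class ContextMatrix:
    """Observed / expected / adjusted-residual codon-pair matrices.

    All three are 64 x 64 DataFrames in fixed alphabetical codon order;
    ``expected`` and ``residuals`` are None until
    :func:`context_residuals` fills them.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame | None = None
    residuals: pd.DataFrame | None = None

    @property
    def n_pairs(self) -> int:
        return int(self.observed.to_numpy().sum())


def pair_counts(genes: list[CodingSequence]) -> ContextMatrix:
    """Count adjacent in-frame codon pairs, pooled across genes.

    The start codon opens the first pair and the terminal stop closes
    the last, so each gene contributes n_codons - 1 pairs; validated
    input guarantees stops never appear as 5' members.
    """
    if not genes:
        raise ValueError("pair_counts requires at least one gene")
    idx = {c: i for i, c in enumerate(ALL_CODONS)}
    observed = np.zeros((64, 64), dtype=np.int64)
    for gene in genes:
        codons = gene.codons
        for a, b in zip(codons, codons[1:]):
            observed[idx[a], idx[b]] += 1
    frame = pd.DataFrame(observed, index=list(ALL_CODONS), columns=list(ALL_CODONS))
    return ContextMatrix(observed=frame)


def context_residuals(matrix: ContextMatrix) -> ContextMatrix:
    """Fill the independence expectation and adjusted Pearson residuals."""
    O = matrix.observed.to_numpy(dtype=float)
    N = O.sum()
    if N <= 0:
        raise ValueError("context matrix has no pairs")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(E * np.outer(1.0 - row / N, 1.0 - col / N))
        D = np.where(denom > 0, (O - E) / denom, 0.0)
    codons = list(ALL_CODONS)
    return ContextMatrix(
        observed=matrix.observed,
        expected=pd.DataFrame(E, index=codons, columns=codons),
        residuals=pd.DataFrame(D, index=codons, columns=codons),
    )


def mean_residual_matrix(genes: list[CodingSequence]) -> pd.DataFrame:
    """Mean over genes of each gene's own adjusted-residual matrix.

    The per-gene alternative to the pooled table: every gene's context
    matrix is residualized separately and the residuals averaged, so
    long genes do not dominate.
    """
    total = np.zeros((64, 64))
    for gene in genes:
        filled = context_residuals(pair_counts([gene]))
        total += filled.residuals.to_numpy()
    codons = list(ALL_CODONS)
    return pd.DataFrame(total / len(genes), index=codons, columns=codons)


def cluster_order(matrix: ContextMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Leaf orderings for heatmap display of the residual matrix.

    Average-linkage hierarchical clustering with Euclidean distance,
    applied separately to residual rows (5' codons) and columns
    (3' codons); returns the two permutations of 0..63.
    """
    if matrix.residuals is None:
        raise ValueError("residuals not filled; call context_residuals first")
    D = matrix.residuals.to_numpy()
    orders = []
    for data in (D, D.T):
        link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        orders.append(np.asarray(hierarchy.leaves_list(link), dtype=int))
    return orders[0], orders[1]


def chi_square(matrix: ContextMatrix) -> float:
    """Chi-square statistic = sum of squared unadjusted Pearson residuals."""
    if matrix.expected is None:
        raise ValueError("expected not filled; call context_residuals first")
    O = matrix.observed.to_numpy(dtype=float)
    E = matrix.expected.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(E > 0, (O - E) ** 2 / E, 0.0)
    return float(cells.sum())
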