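"""Correspondence analysis (CoA) of the gene x 59-codon RSCU matrix.

Classical correspondence analysis: the non-negative matrix is scaled
to proportions P (grand total 1), row and column masses r and c are
its margins, and the standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is decomposed by SVD.  Principal coordinates are the mass-rescaled
singular vectors times the singular values; the share of total inertia
(chi-square / grand total) carried by axis a is sigma_a^2 / sum sigma^2.
Genes that use similar codon repertoires land close together; codons
load the axes that separate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class CoaResult:
    gene_coords: pd.DataFrame  # genes x k principal coordinates
    codon_coords: pd.DataFrame  # columns x k principal coordinates
    inertia_fraction: np.ndarray  # per-axis, non-increasing, sums to 1
    singular_values: np.ndarray
    total_inertia: float
    k: int


def coa_fit(rscu_matrix: pd.DataFrame) -> CoaResult:
    """Fit classical CA to a non-negative gene x codon matrix.

    NaN entries (codons of amino acids absent from a gene) are imputed
    as 0 with a logged count.  Zero-mass rows are invalid (every gene
    must use at least one codon); zero-mass columns are kept in the
    output with coordinates 0.
    """
    X = rscu_matrix.to_numpy(dtype=float).copy()
    n_na = int(np.isnan(X).sum())
    if n_na:
        logger.warning("CoA input: %d NaN entries imputed as 0", n_na)
        X[np.isnan(X)] = 0.0
    if X.shape[0] < 3:
        raise ValueError("CoA needs at least 3 rows (genes)")
    if np.any(X < 0):
        raise ValueError("CoA input must be non-negative")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("CoA input is all zero")
    if np.any(X.sum(axis=1) <= 0):
        raise ValueError("CoA input has all-zero rows")

    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    col_ok = c > 0
    if not col_ok.all():
        logger.warning("CoA input: %d all-zero columns excluded", int((~col_ok).sum()))

    Pm = P[:, col_ok]
    cm = c[col_ok]
    S = (Pm - np.outer(r, cm)) / np.sqrt(np.outer(r, cm))
    U, sing, Vt = np.linalg.svd(S, full_matrices=False)

    keep = sing > np.sqrt(_EPS) * max(1.0, sing[0] if sing.size else 1.0)
    sing = sing[keep]
    U = U[:, keep]
    V = Vt[keep].T
    k = int(sing.size)
    if k == 0:  # identical rows: no variation, everything at the origin
        sing = np.zeros(1)
        U = np.zeros((X.shape[0], 1))
        V = np.zeros((int(col_ok.sum()), 1))
        k = 1

    total_inertia = float((sing**2).sum())
    if total_inertia > _EPS:
        inertia_fraction = sing**2 / total_inertia
    else:  # identical rows: no variation, everything at the origin
        inertia_fraction = np.zeros_like(sing)

    # principal coordinates: F = D_r^{-1/2} U Sigma, G = D_c^{-1/2} V Sigma
    F = (U / np.sqrt(r)[:, None]) * sing
    G_main = (V / np.sqrt(cm)[:, None]) * sing
    G = np.zeros((X.shape[1], k))
    G[col_ok] = G_main

    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        gene_coords=pd.DataFrame(F, index=rscu_matrix.index, columns=axes),
        codon_coords=pd.DataFrame(G, index=rscu_matrix.columns, columns=axes),
        inertia_fraction=inertia_fraction,
        singular_values=sing,
        total_inertia=total_inertia,
        k=k,
    )


def inertia_frame(result: CoaResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "axis": [f"axis{i + 1}" for i in range(result.k)],
            "singular_value": result.singular_values,
            "inertia_fraction": result.inertia_fraction,
            "inertia_percent": 100.0 * result.inertia_fraction,
        }
    )
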