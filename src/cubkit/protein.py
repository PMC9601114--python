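"""Physicochemical properties of the encoded proteins.

Length, GRAVY (grand average of hydropathicity: the mean Kyte &
Doolittle hydropathy over residues), aromaticity (fraction of F/W/Y),
and the isoelectric point.  pI is the pH at which the
Henderson-Hasselbalch net charge over the termini and the ionizable
side chains (D, E, C, Y, H, K, R) vanishes, found by bisection on
[0, 14] with the EMBOSS pKa set (echoed in output metadata).  Learned
pI predictors will differ in absolute value; what the downstream
correlation analysis uses is the ordering, which any classical pKa set
preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .genetic_code import (
    ACIDIC_SIDE_CHAINS,
    AROMATIC_AAS,
    BASIC_SIDE_CHAINS,
    EMBOSS_PKA,
    KYTE_DOOLITTLE,
)
from .sequence_io import CodingSequence

PI_TOLERANCE = 0.001


@dataclass
class ProteinProfile:
    id: str
    length_aa: int
    gravy: float
    aromo: float
    pI: float


def translate(gene: CodingSequence) -> str:
    """Standard-code translation of a validated CDS, stop dropped."""
    return str(Seq(gene.seq).translate(table=1)).rstrip("*")


def gravy(protein: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the protein's residues."""
    if not protein:
        raise ValueError("gravy undefined for an empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid letter {exc.args[0]!r}") from None


def aromaticity(protein: str) -> float:
    """Fraction of residues that are Phe, Trp or Tyr."""
    if not protein:
        raise ValueError("aromaticity undefined for an empty protein")
    return sum(aa in AROMATIC_AAS for aa in protein) / len(protein)


def net_charge(protein: str, ph: float, pka: dict[str, float] = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of the protein at a given pH."""
    positive = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    negative = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in protein:
        if aa in BASIC_SIDE_CHAINS:
            positive += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in ACIDIC_SIDE_CHAINS:
            negative += 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return positive - negative


def isoelectric_point(
    protein: str, pka: dict[str, float] = EMBOSS_PKA, tol: float = PI_TOLERANCE
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the bracket [0, 14]
    always contains exactly one root for any peptide with termini.
    """
    if not protein:
        raise ValueError("pI undefined for an empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_profile(gene: CodingSequence) -> ProteinProfile:
    protein = translate(gene)
    return ProteinProfile(
        id=gene.id,
        length_aa=len(protein),
        gravy=gravy(protein),
        aromo=aromaticity(protein),
        pI=isoelectric_point(protein),
    )


def protein_frame(profiles: list[ProteinProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in profiles],
            "length_aa": [p.length_aa for p in profiles],
            "gravy": [p.gravy for p in profiles],
            "aromo": [p.aromo for p in profiles],
            "pI": [p.pI for p in profiles],
        }
    )
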