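"""Nucleotide composition of coding sequences.

Per-gene percentages of A/T/G/C overall and at third codon positions,
plus GC content overall and at each codon position (GC1, GC2, GC3) and
their first/second-position mean GC12 — the quantities the parity and
neutrality analyses are built on.

The terminal stop codon is included by default: composition describes
the CDS as retrieved.  Pass ``exclude_stop=True`` for sensitivity
checks; this only ever moves percentages by one codon's worth.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .genetic_code import GC_BASES
from .sequence_io import CodingSequence

_FIELDS = (
    "A", "T", "G", "C",
    "A3", "T3", "G3", "C3",
    "GC", "AT", "GC1", "GC2", "GC3", "GC12",
)


@dataclass
class CompositionProfile:
    """Base composition of one gene (or dataset means), in percent."""

    id: str
    A: float
    T: float
    G: float
    C: float
    A3: float
    T3: float
    G3: float
    C3: float
    GC: float
    AT: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float
    n_codons: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def composition_profile(
    gene: CodingSequence, *, exclude_stop: bool = False
) -> CompositionProfile:
    """Compute the full composition profile of one validated CDS."""
    codons = gene.codons
    if exclude_stop:
        codons = codons[:-1]
    n = len(codons)
    seq = "".join(codons)
    total = len(seq)

    def pct(count: int, denom: int) -> float:
        return 100.0 * count / denom

    base_counts = {b: seq.count(b) for b in "ATGC"}
    pos = [[c[k] for c in codons] for k in range(3)]
    third = pos[2]
    third_counts = {b: third.count(b) for b in "ATGC"}
    gc_pos = [pct(sum(b in GC_BASES for b in p), n) for p in pos]
    gc = pct(sum(base_counts[b] for b in "GC"), total)
    return CompositionProfile(
        id=gene.id,
        A=pct(base_counts["A"], total),
        T=pct(base_counts["T"], total),
        G=pct(base_counts["G"], total),
        C=pct(base_counts["C"], total),
        A3=pct(third_counts["A"], n),
        T3=pct(third_counts["T"], n),
        G3=pct(third_counts["G"], n),
        C3=pct(third_counts["C"], n),
        GC=gc,
        AT=100.0 - gc,
        GC1=gc_pos[0],
        GC2=gc_pos[1],
        GC3=gc_pos[2],
        GC12=(gc_pos[0] + gc_pos[1]) / 2.0,
        n_codons=n,
    )


def dataset_composition(profiles: list[CompositionProfile]) -> CompositionProfile:
    """Unweighted per-gene mean of every composition field.

    Each gene contributes equally regardless of length, matching the
    per-gene averaging used for the reported dataset means.
    """
    if not profiles:
        raise ValueError("dataset_composition requires at least one profile")
    n = len(profiles)
    means = {
        name: sum(getattr(p, name) for p in profiles) / n
        for name in (*_FIELDS, "n_codons")
    }
    return CompositionProfile(id="MEAN", **means)


def composition_frame(
    profiles: list[CompositionProfile], *, with_mean: bool = True
) -> pd.DataFrame:
    """Tabulate profiles (one row per gene, optional trailing MEAN row)."""
    rows = [p.as_dict() for p in profiles]
    if with_mean and profiles:
        rows.append(dataset_composition(profiles).as_dict())
    return pd.DataFrame(rows)
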