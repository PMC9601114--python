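"""Codon counts, relative synonymous codon usage (RSCU) and Wright's
effective number of codons (ENC).

RSCU of codon *j* for amino acid *i* is the observed count divided by
the count expected if all of the amino acid's n_i synonymous codons
were used equally:

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)

A zero count for a codon of an amino acid that is otherwise present is
replaced by 0.5 before the ratio, so that rarely-used codons still get
a finite (small) RSCU.  Codons of an amino acid absent from the gene
are undefined (NaN).  The replacement applies only inside the RSCU
computation — never to ENC or composition.

ENC follows Wright (1990).  For each amino acid with total count
n >= 2, the codon homozygosity is estimated as

    F_hat = (n * sum_i p_i^2 - 1) / (n - 1)

with p_i the within-amino-acid codon frequencies.  Class means F̄k
average F_hat over amino acids of degeneracy k (excluding F_hat <= 0),
and

    ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

capped into [20, 61]: 20 means one codon per amino acid (maximal
bias), 61 uniform synonymous usage (no bias).  If Ile (the only 3-fold
amino acid) is absent, F̄3 is imputed as (F̄2 + F̄4)/2; a missing F̄2,
F̄4 or F̄6 makes ENC undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    ALL_CODONS,
    DEGENERACY_CLASSES,
    DEGENERATE_CODONS,
)
from .sequence_io import CodingSequence

OVER = "over"
MORE_FREQUENT = "more_frequent"
LESS_FREQUENT = "less_frequent"
UNDER = "under"

ENC_MIN = 20.0
ENC_MAX = 61.0


@dataclass
class CodonCounts:
    id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RscuProfile:
    """Per-gene (or mean) RSCU over the 59 degenerate sense codons."""

    id: str
    rscu: dict[str, float]  # NaN where the amino acid is absent
    categories: dict[str, str] = field(default_factory=dict)


@dataclass
class EncScore:
    id: str
    enc: float  # NaN when undefined
    class_means: dict[int, float]  # k -> F̄k (NaN when undefined)
    reason: str = ""


def count_codons(gene: CodingSequence) -> CodonCounts:
    """Tally every in-frame codon, terminal stop included."""
    counts = dict.fromkeys(ALL_CODONS, 0)
    for codon in gene.codons:
        counts[codon] += 1
    return CodonCounts(id=gene.id, counts=counts)


def categorize(value: float) -> str:
    """Four-way RSCU classification (over / more / less / under)."""
    if value > 1.6:
        return OVER
    if value < 0.6:
        return UNDER
    if value >= 1.0:
        return MORE_FREQUENT
    return LESS_FREQUENT


def rscu(counts: CodonCounts) -> RscuProfile:
    values: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        n_i = len(codons)
        if n_i == 1:
            continue  # Met, Trp carry no synonymous choice
        raw = [counts.counts[c] for c in codons]
        if sum(raw) == 0:
            for c in codons:
                values[c] = math.nan
            continue
        adjusted = [x if x > 0 else 0.5 for x in raw]
        total = sum(adjusted)
        for c, x in zip(codons, adjusted):
            values[c] = x / (total / n_i)
    values = {c: values[c] for c in DEGENERATE_CODONS}
    cats = {c: categorize(v) for c, v in values.items() if not math.isnan(v)}
    return RscuProfile(id=counts.id, rscu=values, categories=cats)


def mean_rscu(profiles: list[RscuProfile]) -> RscuProfile:
    """Per-codon unweighted mean over genes; NaN entries are ignored.

    Categories are re-derived from the means — this is what the
    over-/under-represented codon lists are read from.
    """
    if not profiles:
        raise ValueError("mean_rscu requires at least one profile")
    means: dict[str, float] = {}
    for codon in DEGENERATE_CODONS:
        vals = [p.rscu[codon] for p in profiles if not math.isnan(p.rscu[codon])]
        means[codon] = sum(vals) / len(vals) if vals else math.nan
    cats = {c: categorize(v) for c, v in means.items() if not math.isnan(v)}
    return RscuProfile(id="MEAN", rscu=means, categories=cats)


def pooled_rscu(counts_list: list[CodonCounts]) -> RscuProfile:
    """RSCU of the dataset-pooled codon counts (alternative to mean_rscu)."""
    pooled = dict.fromkeys(ALL_CODONS, 0)
    for cc in counts_list:
        for codon, x in cc.counts.items():
            pooled[codon] += x
    return rscu(CodonCounts(id="POOLED", counts=pooled))


def rscu_matrix(profiles: list[RscuProfile]) -> pd.DataFrame:
    """Genes x 59-codon RSCU matrix (heatmap- and CoA-ready)."""
    return pd.DataFrame(
        [[p.rscu[c] for c in DEGENERATE_CODONS] for p in profiles],
        index=[p.id for p in profiles],
        columns=list(DEGENERATE_CODONS),
    )


def _f_hat(raw: list[int]) -> float | None:
    """Wright's homozygosity estimator for one amino acid; None if out
    of the estimator's domain (n < 2 or F_hat <= 0)."""
    n = sum(raw)
    if n < 2:
        return None
    p_sq = sum((x / n) ** 2 for x in raw)
    f = (n * p_sq - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(counts: CodonCounts) -> EncScore:
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            f = _f_hat([counts.counts[c] for c in AA_TO_CODONS[aa]])
            if f is not None:
                fs.append(f)
        class_means[k] = sum(fs) / len(fs) if fs else math.nan
    missing = [k for k in (2, 4, 6) if math.isnan(class_means[k])]
    if missing:
        return EncScore(
            id=counts.id,
            enc=math.nan,
            class_means=class_means,
            reason=f"no usable amino acids in degeneracy class(es) {missing}",
        )
    if math.isnan(class_means[3]):
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    raw = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    return EncScore(
        id=counts.id,
        enc=float(np.clip(raw, ENC_MIN, ENC_MAX)),
        class_means=class_means,
    )


def enc_frame(scores: list[EncScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in scores],
            "enc": [s.enc for s in scores],
            "F2": [s.class_means.get(2) for s in scores],
            "F3": [s.class_means.get(3) for s in scores],
            "F4": [s.class_means.get(4) for s in scores],
            "F6": [s.class_means.get(6) for s in scores],
            "reason": [s.reason for s in scores],
        }
    )
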