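"""Mutation-vs-selection diagnostics: parity rule 2, the neutrality
plot, and the Pearson correlation / OLS regression suite.

Parity rule 2 (PR2) says that under pure, strand-symmetric mutation
pressure, A ~= T and G ~= C at third codon positions.  Each gene is
placed at (G3/(G3+C3), A3/(A3+T3)); 0.5 on both axes means no bias,
and systematic displacement implicates selection.

The neutrality plot regresses GC12 (mean GC at codon positions 1 and
2) on GC3.  A slope near 1 means mutation pressure moves all positions
together; a slope near 0 means selection holds positions 1-2 in place
while position 3 drifts.

All correlations are Karl Pearson product-moment coefficients with
two-sided p-values from the t transform (n-2 df); regressions are
ordinary least squares with intercept.  Significance is conventionally
flagged at p < 0.01; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import EncScore, RscuProfile
from .composition import CompositionProfile
from .genetic_code import DEGENERATE_CODONS, ends_gc
from .sequence_io import CodingSequence

logger = logging.getLogger(__name__)

#: the 12 composition features regressed against ENC
ENC_FEATURES = ("A", "T", "G", "C", "A3", "T3", "G3", "C3", "GC", "GC1", "GC2", "GC3")


@dataclass
class ParityPoint:
    id: str
    at_bias: float  # A3/(A3+T3); NaN if A3+T3 == 0
    gc_bias: float  # G3/(G3+C3); NaN if G3+C3 == 0


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    residuals: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class CorrelationReport:
    """Long-format collection of (x, y, r, p, n) correlation results."""

    pairs: list[tuple[str, str, float, float, int]] = field(default_factory=list)

    def add(self, x_name: str, y_name: str, r: float, p: float, n: int) -> None:
        self.pairs.append((x_name, y_name, r, p, n))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["x", "y", "r", "p_value", "n"])
        df["significant_p01"] = df["p_value"] < 0.01
        return df


@dataclass
class MfeRecord:
    """Minimum free energy of a gene's mRNA fold, kcal/mol (<= 0)."""

    id: str
    mfe_kcal_mol: float

    @property
    def abs_mfe(self) -> float:
        return -self.mfe_kcal_mol


def third_position_counts(
    gene: CodingSequence, *, include_stop: bool = False
) -> dict[str, int]:
    """Counts of A/T/G/C at third codon positions.

    The terminal stop is excluded by default: its third base is fixed
    by the stop-codon alphabet, and on short sequences it would distort
    the parity ratios.
    """
    codons = gene.codons if include_stop else gene.codons[:-1]
    third = [c[2] for c in codons]
    return {b: third.count(b) for b in "ATGC"}


def parity_point(gene: CodingSequence, *, include_stop: bool = False) -> ParityPoint:
    counts = third_position_counts(gene, include_stop=include_stop)
    return parity_point_from_counts(gene.id, counts)


def parity_point_from_counts(name: str, counts: dict[str, int]) -> ParityPoint:
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    if at == 0:
        logger.warning("gene %s: A3+T3 == 0, AT bias undefined", name)
    if gc == 0:
        logger.warning("gene %s: G3+C3 == 0, GC bias undefined", name)
    return ParityPoint(
        id=name,
        at_bias=counts["A"] / at if at else math.nan,
        gc_bias=counts["G"] / gc if gc else math.nan,
    )


def parity_frame(points: list[ParityPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in points],
            "gc_bias": [p.gc_bias for p in points],
            "at_bias": [p.at_bias for p in points],
        }
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a two-sided p (t transform, n-2 df).

    NA pairs are dropped pairwise; zero variance in either variable
    yields (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"pearson needs >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y) -> RegressionFit:
    """Ordinary least squares of y on x (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"regression needs >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: predictor has zero variance")
    res = stats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
        residuals=residuals,
    )


def neutrality_fit(profiles: list[CompositionProfile]) -> RegressionFit:
    """OLS of GC12 on GC3 across genes (the neutrality plot fit)."""
    gc3 = [p.GC3 for p in profiles]
    gc12 = [p.GC12 for p in profiles]
    return ols_fit(gc3, gc12)


def enc_composition_suite(
    profiles: list[CompositionProfile], enc_scores: list[EncScore]
) -> tuple[CorrelationReport, dict[str, RegressionFit]]:
    """ENC against each of the 12 composition features (A..GC3).

    Gene sets are matched on id; genes with undefined ENC are dropped.
    """
    comp = {p.id: p for p in profiles}
    shared = [s for s in enc_scores if s.id in comp and not math.isnan(s.enc)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared between ENC and composition")
    enc_vals = np.array([s.enc for s in shared])
    report = CorrelationReport()
    fits: dict[str, RegressionFit] = {}
    for feature in ENC_FEATURES:
        x = np.array([getattr(comp[s.id], feature) for s in shared])
        r, p = pearson(x, enc_vals)
        report.add(feature, "ENC", r, p, len(shared))
        fits[feature] = ols_fit(x, enc_vals)
    return report, fits


def codon_vs_gc3(
    rscu_profiles: list[RscuProfile], profiles: list[CompositionProfile]
) -> pd.DataFrame:
    """Per-codon correlation of RSCU with GC3 across genes.

    Each of the 59 codons is labelled GC-ending or AT-ending; under GC
    bias, GC-ending codons should correlate positively with GC3 and
    AT-ending ones negatively.
    """
    comp = {p.id: p for p in profiles}
    shared = [rp for rp in rscu_profiles if rp.id in comp]
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared between RSCU and composition")
    gc3 = np.array([comp[rp.id].GC3 for rp in shared])
    rows = []
    for codon in DEGENERATE_CODONS:
        vals = np.array([rp.rscu[codon] for rp in shared])
        if np.all(np.isnan(vals)):
            logger.warning("codon %s has no defined RSCU in any gene; dropped", codon)
            continue
        mask = ~np.isnan(vals)
        if mask.sum() < 3 or np.ptp(vals[mask]) == 0 or np.ptp(gc3[mask]) == 0:
            r, p = math.nan, math.nan
        else:
            r, p = pearson(gc3, vals)
        rows.append(
            {
                "codon": codon,
                "ending": "GC" if ends_gc(codon) else "AT",
                "r": r,
                "p_value": p,
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def base_vs_base3(profiles: list[CompositionProfile]) -> CorrelationReport:
    """The 4x4 grid of overall-base vs third-position-base correlations."""
    if len(profiles) < 3:
        raise ValueError("base_vs_base3 needs >= 3 genes")
    report = CorrelationReport()
    for overall in ("A", "T", "G", "C"):
        x = [getattr(p, overall) for p in profiles]
        for third in ("A3", "T3", "G3", "C3"):
            y = [getattr(p, third) for p in profiles]
            r, p = pearson(x, y)
            report.add(overall, third, r, p, len(profiles))
    return report


def load_mfe_table(path: str | Path) -> list[MfeRecord]:
    """Read a two-column TSV of (gene id, mFE in kcal/mol), header optional.

    mFE values must be <= 0 (folding releases energy); rows with a
    positive value are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("mFE table must have two columns: id, mfe_kcal_mol")
    records: list[MfeRecord] = []
    for _, row in df.iterrows():
        name, raw = str(row[0]), str(row[1]).replace("−", "-")
        try:
            value = float(raw)
        except ValueError:
            continue  # header or malformed row
        if value > 0:
            logger.warning("mFE row %s has positive value %s; rejected", name, value)
            continue
        records.append(MfeRecord(id=name, mfe_kcal_mol=value))
    return records


def correlate_mfe(
    records: list[MfeRecord],
    enc_scores: list[EncScore],
    profiles: list[CompositionProfile],
) -> CorrelationReport:
    """|mFE| against ENC and GC/GC1/GC2/GC3; genes without mFE are skipped."""
    mfe = {m.id: m.abs_mfe for m in records}
    enc_map = {s.id: s.enc for s in enc_scores if not math.isnan(s.enc)}
    comp = {p.id: p for p in profiles}
    shared = [i for i in mfe if i in enc_map and i in comp]
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared between mFE table and analysis")
    abs_mfe = np.array([mfe[i] for i in shared])
    report = CorrelationReport()
    r, p = pearson(np.array([enc_map[i] for i in shared]), abs_mfe)
    report.add("ENC", "abs_mfe", r, p, len(shared))
    for feature in ("GC", "GC1", "GC2", "GC3"):
        x = np.array([getattr(comp[i], feature) for i in shared])
        r, p = pearson(x, abs_mfe)
        report.add(feature, "abs_mfe", r, p, len(shared))
    return report
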