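"""The top-level modelling interface.

:class:`CodonUsageModel` is built from validated coding sequences (or
straight from a FASTA path) and its :meth:`~CodonUsageModel.fit` runs
every stage of the codon-usage-bias analysis — composition, RSCU/ENC,
parity and neutrality diagnostics, the correlation/regression suite,
correspondence analysis, codon-pair context, protein properties and
(when a table is supplied) mFE correlations — returning a
:class:`CodonUsageResults` that carries all estimates, exposes a
``summary()`` table, writes the TSV/JSON report bundle, and hosts the
diagnostic plots.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_usage, coa, composition, context, evolutionary, protein
from .codon_usage import EncScore, RscuProfile
from .composition import CompositionProfile
from .evolutionary import CorrelationReport, MfeRecord, ParityPoint, RegressionFit
from .sequence_io import CodingSequence, QcReport, read_fasta, validate_cds

logger = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    """Switches for the deliberately configurable conventions."""

    exclude_stop_composition: bool = False
    parity_include_stop: bool = False
    pooled_rscu: bool = False
    pooled_context: bool = True
    allow_alt_starts: bool = False


class CodonUsageModel:
    """Codon-usage-bias analysis of a set of coding sequences."""

    def __init__(
        self,
        genes: list[CodingSequence],
        mfe_records: list[MfeRecord] | None = None,
        options: AnalysisOptions | None = None,
        qc_report: QcReport | None = None,
    ):
        if not genes:
            raise ValueError("CodonUsageModel needs at least one validated gene")
        self.genes = genes
        self.mfe_records = mfe_records
        self.options = options or AnalysisOptions()
        self.qc_report = qc_report

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        mfe_table: str | Path | None = None,
        options: AnalysisOptions | None = None,
    ) -> "CodonUsageModel":
        """Read and validate a FASTA of CDS (and optionally an mFE TSV)."""
        options = options or AnalysisOptions()
        records = read_fasta(path)
        genes, report = validate_cds(records, allow_alt_starts=options.allow_alt_starts)
        if not genes:
            raise ValueError(f"no sequences in {path} passed CDS validation")
        mfe = evolutionary.load_mfe_table(mfe_table) if mfe_table else None
        return cls(genes, mfe_records=mfe, options=options, qc_report=report)

    def fit(self) -> "CodonUsageResults":
        opts = self.options
        genes = self.genes

        comp_profiles = [
            composition.composition_profile(g, exclude_stop=opts.exclude_stop_composition)
            for g in genes
        ]
        comp_mean = composition.dataset_composition(comp_profiles)

        counts = [codon_usage.count_codons(g) for g in genes]
        rscu_profiles = [codon_usage.rscu(c) for c in counts]
        rscu_mean = (
            codon_usage.pooled_rscu(counts)
            if opts.pooled_rscu
            else codon_usage.mean_rscu(rscu_profiles)
        )
        enc_scores = [codon_usage.enc(c) for c in counts]

        parity_points = [
            evolutionary.parity_point(g, include_stop=opts.parity_include_stop)
            for g in genes
        ]
        n = len(genes)
        neutrality = (
            evolutionary.neutrality_fit(comp_profiles) if n >= 3 else None
        )
        enc_corr, enc_fits = (
            evolutionary.enc_composition_suite(comp_profiles, enc_scores)
            if n >= 3
            else (None, None)
        )
        codon_gc3 = (
            evolutionary.codon_vs_gc3(rscu_profiles, comp_profiles) if n >= 3 else None
        )
        base_corr = evolutionary.base_vs_base3(comp_profiles) if n >= 3 else None

        rscu_mat = codon_usage.rscu_matrix(rscu_profiles)
        coa_result = coa.coa_fit(rscu_mat) if n >= 3 else None

        ctx = context.context_residuals(context.pair_counts(genes))
        ctx_order = context.cluster_order(ctx)
        ctx_mean_residuals = (
            None if opts.pooled_context else context.mean_residual_matrix(genes)
        )

        prot_profiles = [protein.protein_profile(g) for g in genes]
        prot_fits = None
        if n >= 3:
            enc_map = {s.id: s.enc for s in enc_scores if not math.isnan(s.enc)}
            shared = [p for p in prot_profiles if p.id in enc_map]
            if len(shared) >= 3:
                enc_vals = [enc_map[p.id] for p in shared]
                prot_fits = {
                    name: evolutionary.ols_fit(enc_vals, [getattr(p, name) for p in shared])
                    for name in ("length_aa", "pI", "gravy", "aromo")
                }

        mfe_corr = None
        if self.mfe_records:
            mfe_corr = evolutionary.correlate_mfe(
                self.mfe_records, enc_scores, comp_profiles
            )
        elif self.mfe_records is None:
            logger.info("no mFE table supplied; mFE stage skipped")

        return CodonUsageResults(
            model=self,
            composition_profiles=comp_profiles,
            composition_mean=comp_mean,
            rscu_profiles=rscu_profiles,
            rscu_mean=rscu_mean,
            rscu_matrix=rscu_mat,
            enc_scores=enc_scores,
            parity_points=parity_points,
            neutrality=neutrality,
            enc_composition_corr=enc_corr,
            enc_composition_fits=enc_fits,
            codon_gc3=codon_gc3,
            base_corr=base_corr,
            coa_result=coa_result,
            context_matrix=ctx,
            context_order=ctx_order,
            context_mean_residuals=ctx_mean_residuals,
            protein_profiles=prot_profiles,
            protein_enc_fits=prot_fits,
            mfe_corr=mfe_corr,
        )


@dataclass
class CodonUsageResults:
    """Everything the fitted analysis produced."""

    model: CodonUsageModel
    composition_profiles: list[CompositionProfile]
    composition_mean: CompositionProfile
    rscu_profiles: list[RscuProfile]
    rscu_mean: RscuProfile
    rscu_matrix: pd.DataFrame
    enc_scores: list[EncScore]
    parity_points: list[ParityPoint]
    neutrality: RegressionFit | None
    enc_composition_corr: CorrelationReport | None
    enc_composition_fits: dict[str, RegressionFit] | None
    codon_gc3: pd.DataFrame | None
    base_corr: CorrelationReport | None
    coa_result: coa.CoaResult | None
    context_matrix: context.ContextMatrix
    context_order: tuple[np.ndarray, np.ndarray]
    context_mean_residuals: pd.DataFrame | None
    protein_profiles: list[protein.ProteinProfile]
    protein_enc_fits: dict[str, RegressionFit] | None
    mfe_corr: CorrelationReport | None
    warnings: list[str] = field(default_factory=list)

    # -- headline quantities -------------------------------------------------

    @property
    def mean_enc(self) -> float:
        vals = [s.enc for s in self.enc_scores if not math.isnan(s.enc)]
        return sum(vals) / len(vals) if vals else math.nan

    @property
    def over_represented(self) -> list[str]:
        return sorted(
            c for c, cat in self.rscu_mean.categories.items()
            if cat == codon_usage.OVER
        )

    @property
    def under_represented(self) -> list[str]:
        return sorted(
            c for c, cat in self.rscu_mean.categories.items()
            if cat == codon_usage.UNDER
        )

    def headline(self) -> dict:
        """The dataset-level summary quantities, JSON-serializable."""
        out = {
            "n_genes": len(self.model.genes),
            "mean_enc": self.mean_enc,
            "mean_gc": self.composition_mean.GC,
            "mean_gc3": self.composition_mean.GC3,
            "mean_gc12": self.composition_mean.GC12,
            "over_represented_codons": self.over_represented,
            "under_represented_codons": self.under_represented,
            "mean_at_bias": float(np.nanmean([p.at_bias for p in self.parity_points])),
            "mean_gc_bias": float(np.nanmean([p.gc_bias for p in self.parity_points])),
        }
        if self.neutrality is not None:
            out["neutrality_slope"] = self.neutrality.slope
            out["neutrality_r"] = self.neutrality.r
            out["neutrality_p"] = self.neutrality.p_value
        if self.coa_result is not None:
            frac = self.coa_result.inertia_fraction
            out["coa_axis1_inertia_pct"] = float(100 * frac[0]) if len(frac) else 0.0
            out["coa_axis2_inertia_pct"] = float(100 * frac[1]) if len(frac) > 1 else 0.0
        return out

    def summary(self) -> str:
        """A human-readable summary table of the fitted analysis."""
        h = self.headline()
        lines = [
            "Codon Usage Bias Analysis",
            "=" * 58,
            f"{'Genes analysed':<34}{h['n_genes']:>24}",
            f"{'Mean ENC':<34}{h['mean_enc']:>24.3f}",
            f"{'Mean GC (%)':<34}{h['mean_gc']:>24.3f}",
            f"{'Mean GC3 (%)':<34}{h['mean_gc3']:>24.3f}",
            f"{'Mean AT bias (A3/(A3+T3))':<34}{h['mean_at_bias']:>24.4f}",
            f"{'Mean GC bias (G3/(G3+C3))':<34}{h['mean_gc_bias']:>24.4f}",
        ]
        if self.neutrality is not None:
            lines += [
                f"{'Neutrality slope (GC12~GC3)':<34}{h['neutrality_slope']:>24.4f}",
                f"{'Neutrality r':<34}{h['neutrality_r']:>24.4f}",
            ]
        if self.coa_result is not None:
            lines += [
                f"{'CoA axis 1 inertia (%)':<34}{h['coa_axis1_inertia_pct']:>24.2f}",
                f"{'CoA axis 2 inertia (%)':<34}{h['coa_axis2_inertia_pct']:>24.2f}",
            ]
        over = ", ".join(h["over_represented_codons"]) or "none"
        under = ", ".join(h["under_represented_codons"]) or "none"
        lines += [
            "-" * 58,
            f"Over-represented codons (RSCU > 1.6):  {over}",
            f"Under-represented codons (RSCU < 0.6): {under}",
            "=" * 58,
        ]
        return "\n".join(lines)

    # -- export --------------------------------------------------------------

    def to_directory(self, out_dir: str | Path, run_config: dict | None = None) -> Path:
        """Write the full TSV/JSON report bundle.

        Floats are written at 4 decimals (composition at 2, matching
        the conventional reporting style); TSVs are tab-separated with
        '.' decimals and a fixed column order.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def tsv(df: pd.DataFrame, name: str, decimals: int = 4, index: bool = False):
            df.round(decimals).to_csv(out / name, sep="\t", index=index)

        if self.model.qc_report is not None:
            tsv(
                self.model.qc_report.to_frame([g.id for g in self.model.genes]),
                "qc_report.tsv",
            )
        tsv(composition.composition_frame(self.composition_profiles), "composition.tsv", 2)
        tsv(self.rscu_matrix, "rscu.tsv", index=True)
        mean_df = pd.DataFrame(
            {
                "codon": list(self.rscu_mean.rscu),
                "mean_rscu": list(self.rscu_mean.rscu.values()),
                "category": [
                    self.rscu_mean.categories.get(c, "NA") for c in self.rscu_mean.rscu
                ],
            }
        )
        tsv(mean_df, "rscu_mean.tsv")
        tsv(codon_usage.enc_frame(self.enc_scores), "enc.tsv")
        tsv(evolutionary.parity_frame(self.parity_points), "parity.tsv")

        if self.neutrality is not None:
            neut = pd.DataFrame(
                {
                    "id": [p.id for p in self.composition_profiles],
                    "GC3": [p.GC3 for p in self.composition_profiles],
                    "GC12": [p.GC12 for p in self.composition_profiles],
                    "residual": self.neutrality.residuals,
                }
            )
            tsv(neut, "neutrality.tsv")

        corr_frames = []
        if self.enc_composition_corr is not None:
            df = self.enc_composition_corr.to_frame()
            df["slope"] = [self.enc_composition_fits[x].slope for x in df["x"]]
            df["intercept"] = [self.enc_composition_fits[x].intercept for x in df["x"]]
            corr_frames.append(df)
        if self.base_corr is not None:
            corr_frames.append(self.base_corr.to_frame())
        if corr_frames:
            tsv(pd.concat(corr_frames, ignore_index=True), "correlations.tsv")
        if self.codon_gc3 is not None:
            tsv(self.codon_gc3, "codon_gc3_correlations.tsv")

        if self.coa_result is not None:
            k = min(self.coa_result.k, 10)
            tsv(self.coa_result.gene_coords.iloc[:, :k], "coa_genes.tsv", index=True)
            tsv(self.coa_result.codon_coords.iloc[:, :k], "coa_codons.tsv", index=True)
            tsv(coa.inertia_frame(self.coa_result), "coa_inertia.tsv")

        tsv(self.context_matrix.observed, "context_observed.tsv", index=True)
        tsv(self.context_matrix.residuals, "context_residuals.tsv", index=True)
        row_order, col_order = self.context_order
        codons = list(self.context_matrix.residuals.index)
        tsv(
            pd.DataFrame(
                {
                    "rank": range(64),
                    "row_codon": [codons[i] for i in row_order],
                    "col_codon": [codons[i] for i in col_order],
                }
            ),
            "context_order.tsv",
        )
        if self.context_mean_residuals is not None:
            tsv(self.context_mean_residuals, "context_mean_residuals.tsv", index=True)

        tsv(protein.protein_frame(self.protein_profiles), "protein_props.tsv")
        if self.protein_enc_fits is not None:
            tsv(
                pd.DataFrame(
                    {
                        "property": list(self.protein_enc_fits),
                        "slope": [f.slope for f in self.protein_enc_fits.values()],
                        "intercept": [f.intercept for f in self.protein_enc_fits.values()],
                        "r": [f.r for f in self.protein_enc_fits.values()],
                        "p_value": [f.p_value for f in self.protein_enc_fits.values()],
                        "n": [f.n for f in self.protein_enc_fits.values()],
                    }
                ),
                "protein_enc_regressions.tsv",
            )
        if self.mfe_corr is not None:
            tsv(self.mfe_corr.to_frame(), "mfe_correlations.tsv")

        with open(out / "summary.json", "w") as handle:
            json.dump(self.headline(), handle, indent=2)
        if run_config is not None:
            with open(out / "run_config.json", "w") as handle:
                json.dump(run_config, handle, indent=2)
        return out

    # -- plots ---------------------------------------------------------------

    def plot_neutrality(self, ax=None):
        """GC12 vs GC3 scatter with the fitted regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        gc3 = [p.GC3 for p in self.composition_profiles]
        gc12 = [p.GC12 for p in self.composition_profiles]
        ax.scatter(gc3, gc12, s=12, alpha=0.7)
        if self.neutrality is not None:
            xs = np.linspace(min(gc3), max(gc3), 50)
            ax.plot(xs, self.neutrality.predict(xs), color="crimson")
            ax.set_title(
                f"slope={self.neutrality.slope:.3f}, r={self.neutrality.r:.3f}"
            )
        ax.set_xlabel("GC3 (%)")
        ax.set_ylabel("GC12 (%)")
        return ax

    def plot_parity(self, ax=None):
        """PR2 bias plot: AT bias vs GC bias with the 0.5 centre lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            [p.gc_bias for p in self.parity_points],
            [p.at_bias for p in self.parity_points],
            s=12,
            alpha=0.7,
        )
        ax.axhline(0.5, color="grey", lw=0.8)
        ax.axvline(0.5, color="grey", lw=0.8)
        ax.set_xlabel("G3/(G3+C3)")
        ax.set_ylabel("A3/(A3+T3)")
        return ax

    def plot_enc_vs(self, feature: str, ax=None):
        """ENC against one composition feature, with its OLS line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        comp = {p.id: p for p in self.composition_profiles}
        pts = [
            (getattr(comp[s.id], feature), s.enc)
            for s in self.enc_scores
            if s.id in comp and not math.isnan(s.enc)
        ]
        xs, ys = zip(*pts)
        ax.scatter(xs, ys, s=12, alpha=0.7)
        if self.enc_composition_fits and feature in self.enc_composition_fits:
            fit = self.enc_composition_fits[feature]
            grid = np.linspace(min(xs), max(xs), 50)
            ax.plot(grid, fit.predict(grid), color="crimson")
        ax.set_xlabel(f"{feature} (%)")
        ax.set_ylabel("ENC")
        return ax
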