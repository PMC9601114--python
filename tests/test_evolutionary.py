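"""Parity rule 2, neutrality regression, and the correlation suite."""

import math

import numpy as np
import pytest

from cubkit import (
    CodingSequence,
    GeneratorSpec,
    base_vs_base3,
    codon_vs_gc3,
    composition_profile,
    correlate_mfe,
    count_codons,
    enc,
    enc_composition_suite,
    generate_genes,
    generate_mfe,
    load_mfe_table,
    neutrality_fit,
    parity_point,
    pearson,
    rscu,
)
from cubkit.evolutionary import (
    ENC_FEATURES,
    ols_fit,
    parity_point_from_counts,
    third_position_counts,
)

from conftest import make_cds


class TestParity:
    def test_center_at_equal_counts(self):
        point = parity_point_from_counts("g", {"A": 7, "T": 7, "G": 2, "C": 3})
        assert point.at_bias == pytest.approx(0.5)

    def test_direct_ratio(self):
        point = parity_point_from_counts("g", {"A": 3, "T": 1, "G": 1, "C": 1})
        assert point.at_bias == pytest.approx(0.75)

    def test_boundary_zero(self):
        point = parity_point_from_counts("g", {"A": 1, "T": 1, "G": 0, "C": 5})
        assert point.gc_bias == pytest.approx(0.0)

    def test_zero_denominator_nan(self):
        point = parity_point_from_counts("g", {"A": 0, "T": 0, "G": 1, "C": 1})
        assert math.isnan(point.at_bias)

    def test_stop_excluded_by_default(self):
        # codons ATG, AAA, TAA have third bases G, A, A
        gene = CodingSequence("g", "ATGAAATAA")
        excl = third_position_counts(gene)
        incl = third_position_counts(gene, include_stop=True)
        assert excl == {"A": 1, "T": 0, "G": 1, "C": 0}
        assert incl == {"A": 2, "T": 0, "G": 1, "C": 0}

    def test_doubling_counts_preserves_biases(self, small_gene_set):
        gene = small_gene_set[0]
        counts = third_position_counts(gene)
        doubled = {b: 2 * n for b, n in counts.items()}
        a = parity_point_from_counts("a", counts)
        b = parity_point_from_counts("b", doubled)
        assert a.at_bias == pytest.approx(b.at_bias)
        assert a.gc_bias == pytest.approx(b.gc_bias)


class TestPearsonOls:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed(self):
        r, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_brute_force_agreement(self, rng):
        """Matches the raw covariance/sd formula to near machine precision."""
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r, _ = pearson(x, y)
            brute = np.sum((x - x.mean()) * (y - y.mean())) / (
                np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_nan(self):
        r, p = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_na_pairs_dropped(self):
        r, _ = pearson([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 100])
        assert r == pytest.approx(1.0)

    def test_ols_self_consistency(self, rng):
        """slope = r * sd_y / sd_x; residuals sum to zero with no trend."""
        x = rng.normal(size=100)
        y = 0.7 * x + rng.normal(size=100)
        fit = ols_fit(x, y)
        assert fit.slope == pytest.approx(
            fit.r * np.std(y, ddof=1) / np.std(x, ddof=1), abs=1e-9
        )
        assert abs(fit.residuals.sum()) < 1e-8
        resid_fit = ols_fit(x, fit.residuals)
        assert resid_fit.slope == pytest.approx(0.0, abs=1e-9)


class TestNeutrality:
    def test_identity_line(self):
        class P:  # minimal profile stub
            def __init__(self, v):
                self.GC3 = v
                self.GC12 = v

        fit = neutrality_fit([P(40), P(50), P(60)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_gc3_raises(self):
        class P:
            GC3 = 50.0
            GC12 = 45.0

        with pytest.raises(ValueError):
            neutrality_fit([P(), P(), P()])

    def test_slope_recovery_on_generated_data(self):
        """Recovers the generator's GC12~GC3 slope within 0.05 at n=200."""
        spec = GeneratorSpec(
            n_genes=200,
            length_codons=(300, 600),
            gc12_slope=0.3,
            gc12_intercept=35.0,
            gc12_noise_sd=1.0,
            seed=7,
        )
        profiles = [composition_profile(g) for g in generate_genes(spec)]
        fit = neutrality_fit(profiles)
        assert abs(fit.slope - 0.3) < 0.05


@pytest.fixture(scope="module")
def fitted(small_gene_set):
    profiles = [composition_profile(g) for g in small_gene_set]
    scores = [enc(count_codons(g)) for g in small_gene_set]
    return enc_composition_suite(profiles, scores)


class TestEncCompositionSuite:

    def test_exactly_12_pairs(self, fitted):
        report, fits = fitted
        assert len(report.pairs) == 12
        assert set(fits) == set(ENC_FEATURES)

    def test_gc3_negatively_correlated_with_enc(self, fitted):
        """High GC3 in the generator means stronger codon-ending skew."""
        report, _ = fitted
        rows = {x: r for x, _, r, _, _ in report.pairs}
        assert rows["GC3"] < 0

    def test_self_regression_sanity(self, small_gene_set):
        scores = [enc(count_codons(g)) for g in small_gene_set]
        vals = [s.enc for s in scores]
        fit = ols_fit(vals, vals)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)


class TestCodonVsGc3:
    def test_labels_and_row_count(self, small_gene_set):
        profiles = [composition_profile(g) for g in small_gene_set]
        rscus = [rscu(count_codons(g)) for g in small_gene_set]
        df = codon_vs_gc3(rscus, profiles)
        assert len(df) <= 59
        assert set(df["ending"]) <= {"GC", "AT"}

    def test_gc_ending_sign_under_gc3_gradient(self, small_gene_set):
        """Ala: GCC tracks GC3 positively, GCA negatively, by construction."""
        profiles = [composition_profile(g) for g in small_gene_set]
        rscus = [rscu(count_codons(g)) for g in small_gene_set]
        df = codon_vs_gc3(rscus, profiles).set_index("codon")
        assert df.loc["GCC", "r"] > 0
        assert df.loc["GCA", "r"] < 0

    def test_constant_gc3_all_nan(self):
        # same third-base multiset in every gene -> GC3 has zero variance
        genes = [
            make_cds("a", "CTT", "CTT"),
            make_cds("b", "GTT", "GTT"),
            make_cds("c", "CTT", "GTT"),
        ]
        profiles = [composition_profile(g) for g in genes]
        assert len({p.GC3 for p in profiles}) == 1
        rscus = [rscu(count_codons(g)) for g in genes]
        df = codon_vs_gc3(rscus, profiles)
        assert df["r"].isna().all()


class TestBaseVsBase3:
    def test_16_pairs(self, small_gene_set):
        profiles = [composition_profile(g) for g in small_gene_set]
        report = base_vs_base3(profiles)
        assert len(report.pairs) == 16

    def test_homogeneous_positive(self, small_gene_set):
        profiles = [composition_profile(g) for g in small_gene_set]
        rows = {(x, y): r for x, y, r, _, _ in base_vs_base3(profiles).pairs}
        # genes share one GC propensity, so overall G tracks G3
        assert rows[("G", "G3")] > 0
        assert rows[("C", "C3")] > 0


class TestMfe:
    def test_load_and_absolute_value(self, tmp_path):
        path = tmp_path / "mfe.tsv"
        path.write_text("id\tmfe_kcal_mol\ng1\t-212.2\ng2\t-3155.12\ng3\t5.0\n")
        records = load_mfe_table(path)
        assert [r.id for r in records] == ["g1", "g2"]  # positive row rejected
        assert records[0].abs_mfe == pytest.approx(212.2)

    def test_correlations_on_generated_data(self, small_gene_set):
        records = generate_mfe(small_gene_set, coupling=(0.3, 0.5, 10.0), seed=3)
        profiles = [composition_profile(g) for g in small_gene_set]
        scores = [enc(count_codons(g)) for g in small_gene_set]
        report = correlate_mfe(records, scores, profiles)
        rows = {x: r for x, _, r, _, _ in report.pairs}
        assert set(rows) == {"ENC", "GC", "GC1", "GC2", "GC3"}
        assert rows["GC"] > 0  # |mFE| grows with GC by construction

    def test_empty_overlap_raises(self, small_gene_set):
        records = []
        profiles = [composition_profile(g) for g in small_gene_set]
        scores = [enc(count_codons(g)) for g in small_gene_set]
        with pytest.raises(ValueError):
            correlate_mfe(records, scores, profiles)
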