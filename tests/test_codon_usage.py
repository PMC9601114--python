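"""Codon counts, RSCU (with the 0.5 zero-replacement) and Wright's ENC."""

import math

import numpy as np
import pytest

from cubkit import CodingSequence, count_codons, enc, mean_rscu, rscu
from cubkit.codon_usage import (
    LESS_FREQUENT,
    MORE_FREQUENT,
    OVER,
    UNDER,
    categorize,
    pooled_rscu,
    rscu_matrix,
)
from cubkit.genetic_code import (
    AA_TO_CODONS,
    DEGENERACY_CLASSES,
    DEGENERATE_AAS,
    DEGENERATE_CODONS,
    STOP_CODONS,
)

from conftest import make_cds, random_cds


class TestCountCodons:
    def test_simple(self):
        counts = count_codons(CodingSequence("g", "ATGAAATAA"))
        assert counts.counts["ATG"] == 1
        assert counts.counts["AAA"] == 1
        assert counts.counts["TAA"] == 1
        assert counts.total == 3

    def test_frame_walk(self):
        counts = count_codons(CodingSequence("g", "ATGTTTTTTTTCTAA"))
        assert counts.counts["TTT"] == 2
        assert counts.counts["TTC"] == 1

    def test_total_is_codon_count(self, rng):
        gene = random_cds(rng, 100)
        assert count_codons(gene).total == gene.n_codons


class TestRscu:
    def test_direct_substitution(self):
        profile = rscu(count_codons(make_cds("g", "TTT", "TTT", "TTC")))
        assert profile.rscu["TTT"] == pytest.approx(4 / 3)
        assert profile.rscu["TTC"] == pytest.approx(2 / 3)

    def test_equal_usage_gives_one(self):
        codons = [c for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]]
        profile = rscu(count_codons(make_cds("g", *codons)))
        for c in DEGENERATE_CODONS:
            assert profile.rscu[c] == pytest.approx(1.0)

    def test_zero_replacement_rule(self):
        # TTT:4, TTC:0 -> counts (4, 0.5), totals 4.5
        profile = rscu(count_codons(make_cds("g", *["TTT"] * 4)))
        assert profile.rscu["TTT"] == pytest.approx(4 / (4.5 / 2))
        assert profile.rscu["TTC"] == pytest.approx(0.5 / (4.5 / 2))

    def test_absent_amino_acid_is_nan(self):
        profile = rscu(count_codons(make_cds("g", "TTT")))
        assert math.isnan(profile.rscu["GGG"])

    def test_exactly_59_keys(self, rng):
        profile = rscu(count_codons(random_cds(rng, 50)))
        assert len(profile.rscu) == 59
        assert set(profile.rscu) == set(DEGENERATE_CODONS)
        assert not set(profile.rscu) & STOP_CODONS
        assert "ATG" not in profile.rscu and "TGG" not in profile.rscu

    def test_sum_to_degeneracy_property(self, rng):
        """For amino acids with all codons observed, RSCU sums to n_i."""
        for _ in range(25):
            profile = rscu(count_codons(random_cds(rng, rng.integers(50, 400))))
            for aa in DEGENERATE_AAS:
                vals = [profile.rscu[c] for c in AA_TO_CODONS[aa]]
                if not any(math.isnan(v) for v in vals):
                    assert sum(vals) == pytest.approx(len(vals), abs=1e-9)


class TestRscuHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.sampled_from(DEGENERATE_CODONS), min_size=1, max_size=200
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sum_to_degeneracy_for_fully_observed_aas(self, codons):
        profile = rscu(count_codons(make_cds("h", *codons)))
        for aa in DEGENERATE_AAS:
            vals = [profile.rscu[c] for c in AA_TO_CODONS[aa]]
            if not any(math.isnan(v) for v in vals):
                assert sum(vals) == pytest.approx(len(vals), abs=1e-9)
        # defined RSCU values are always non-negative
        assert all(
            v >= 0 for v in profile.rscu.values() if not math.isnan(v)
        )


@pytest.mark.parametrize(
    "value,category",
    [
        (1.7, OVER),
        (1.6, MORE_FREQUENT),
        (1.0, MORE_FREQUENT),
        (0.99, LESS_FREQUENT),
        (0.6, LESS_FREQUENT),
        (0.59, UNDER),
    ],
)
def test_category_boundaries(value, category):
    assert categorize(value) == category


class TestMeanRscu:
    def test_single_profile_identity(self, rng):
        profile = rscu(count_codons(random_cds(rng, 100)))
        mean = mean_rscu([profile])
        for c in DEGENERATE_CODONS:
            if not math.isnan(profile.rscu[c]):
                assert mean.rscu[c] == pytest.approx(profile.rscu[c])

    def test_mean_and_category(self):
        a = rscu(count_codons(make_cds("a", *["CTG"] * 3, "CTT")))
        b = rscu(count_codons(make_cds("b", *["CTG"] * 5, "CTT")))
        mean = mean_rscu([a, b])
        expected = (a.rscu["CTG"] + b.rscu["CTG"]) / 2
        assert mean.rscu["CTG"] == pytest.approx(expected)
        assert mean.categories["CTG"] == OVER

    def test_nan_ignored_in_mean(self):
        with_phe = rscu(count_codons(make_cds("a", "TTT", "TTT", "TTC")))
        without = rscu(count_codons(make_cds("b", "GGG")))
        mean = mean_rscu([with_phe, without])
        assert mean.rscu["TTT"] == pytest.approx(with_phe.rscu["TTT"])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_rscu([])

    def test_pooled_mode(self):
        a = count_codons(make_cds("a", "TTT"))
        b = count_codons(make_cds("b", "TTC"))
        pooled = pooled_rscu([a, b])
        assert pooled.rscu["TTT"] == pytest.approx(1.0)
        assert pooled.rscu["TTC"] == pytest.approx(1.0)

    def test_matrix_shape(self, small_gene_set):
        profiles = [rscu(count_codons(g)) for g in small_gene_set]
        mat = rscu_matrix(profiles)
        assert mat.shape == (len(small_gene_set), 59)


class TestEnc:
    def test_maximal_bias_is_20(self):
        """One codon per degenerate amino acid, each twice: every F = 1."""
        codons = [c for aa in DEGENERATE_AAS for c in (AA_TO_CODONS[aa][0],) * 2]
        score = enc(count_codons(make_cds("g", *codons)))
        assert score.enc == pytest.approx(20.0)
        for k in (2, 3, 4, 6):
            assert score.class_means[k] == pytest.approx(1.0)

    def test_uniform_usage_capped_to_61(self):
        """Every synonymous codon twice: raw ENC is 102, capped to 61."""
        codons = [c for c in DEGENERATE_CODONS for _ in range(2)]
        score = enc(count_codons(make_cds("g", *codons)))
        assert score.enc == pytest.approx(61.0)
        # raw class means F = 1/(2k-1)
        for k in (2, 3, 4, 6):
            assert score.class_means[k] == pytest.approx(1 / (2 * k - 1))

    def test_missing_class_gives_nan(self):
        score = enc(count_codons(make_cds("g", "TTT", "TTT")))
        assert math.isnan(score.enc)
        assert "class" in score.reason

    def test_missing_ile_imputed(self):
        """No Ile: F3 is imputed as (F2+F4)/2 and ENC stays defined."""
        codons = []
        for aa in DEGENERATE_AAS:
            if aa == "I":
                continue
            codons += [AA_TO_CODONS[aa][0]] * 2
        score = enc(count_codons(make_cds("g", *codons)))
        assert not math.isnan(score.enc)
        assert score.class_means[3] == pytest.approx(
            (score.class_means[2] + score.class_means[4]) / 2
        )

    def test_relabeling_symmetry(self):
        """ENC only sees within-amino-acid frequencies, not which codon."""
        for aa in ("L", "K"):
            codons = AA_TO_CODONS[aa]
            base = []
            for other in DEGENERATE_AAS:
                if other != aa:
                    base += [AA_TO_CODONS[other][0]] * 3
            a = enc(count_codons(make_cds("a", *base, *[codons[0]] * 5)))
            b = enc(count_codons(make_cds("b", *base, *[codons[-1]] * 5)))
            assert a.enc == pytest.approx(b.enc)

    def test_long_uniform_gene_near_cap(self, rng):
        gene = random_cds(rng, 3000)
        score = enc(count_codons(gene))
        assert score.enc >= 60.5

    def test_monotone_decrease_with_bias(self):
        """Median ENC strictly decreases as generator bias grows."""
        from cubkit import GeneratorSpec, generate_genes

        medians = []
        for b in (0.0, 1.0, 4.0):
            spec = GeneratorSpec(
                n_genes=20, length_codons=(300, 300), gc3_target=0.5,
                bias_strength=b, seed=5,
            )
            encs = [enc(count_codons(g)).enc for g in generate_genes(spec)]
            medians.append(float(np.median(encs)))
        assert medians[0] > medians[1] > medians[2]
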