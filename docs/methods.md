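# Methods

This note records the statistical definitions, conventions and design
choices implemented in `cubkit`, and what the synthetic-data tests do
and do not demonstrate about real data.

## CDS validation

A record is admitted only if, after uppercasing and U→T mapping, it is
an unambiguous {A,C,G,T} string whose length is a multiple of three
and at least 6 nt, starts with ATG (CTG/GTG/TTG optionally accepted
via `allow_alt_starts`, off by default — curated CDS sets should not
need them), ends with TAA/TAG/TGA, and contains no internal stop.
Checks run in a fixed order (ambiguous base, length, too short, start,
internal stop, terminal stop) and each rejection reports the first
failure only, so QC tables are unambiguous. Sequences with ambiguous
bases are rejected rather than N-masked because every downstream
formula assumes resolved bases. Duplicate FASTA ids are disambiguated
with a numeric suffix and a warning.

## Composition

Percentages are computed over the full CDS including the terminal stop
(the CDS as retrieved is the unit of analysis); `exclude_stop` exists
for sensitivity checks and moves any percentage by at most one codon's
worth. With all codons counted, overall GC equals the mean of GC1,
GC2, GC3 exactly, which the tests assert. Dataset means are unweighted
per-gene averages: a 300-codon gene and a 3,000-codon gene contribute
equally, matching the convention of reporting per-gene statistics.

## RSCU

RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij). When an amino acid is present but
one of its codons has count zero, that count is replaced by 0.5 before
forming the ratio, so the replacement inflates the denominator too
(TTT:4, TTC:0 gives 1.778/0.222, not 2/0.25). Codons of absent amino
acids are NaN, never zero. The replacement is confined to RSCU; ENC
and composition always see raw counts. Category thresholds: over-
represented > 1.6, under-represented < 0.6, more frequent [1, 1.6],
less frequent [0.6, 1). Dataset-level RSCU is the per-gene mean
(NaN-ignoring), with categories re-derived from the means; a pooled-
counts mode is available behind a flag for comparison.

## ENC

Wright's estimator. Per amino acid with total count n ≥ 2,
F̂ = (n Σ p_i² − 1)/(n − 1). Amino acids with n < 2 or F̂ ≤ 0 are
excluded from their class mean (the estimator is undefined or
uninformative there). Degeneracy classes in the standard code:
2-fold {C,D,E,F,H,K,N,Q,Y}, 3-fold {I}, 4-fold {A,G,P,T,V},
6-fold {L,R,S}. ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6. If Ile is
absent, F̄3 is imputed as (F̄2 + F̄4)/2 — the standard fallback, since
Ile is the lone 3-fold amino acid; if any of F̄2/F̄4/F̄6 is missing the
score is NA with a reason. Raw values are capped into [20, 61]; genes
with near-uniform usage routinely exceed 61 before capping (the
all-codons-twice construction gives a raw 102), and 20/61 are treated
as the meaningful endpoints of the scale.

## Parity rule 2 and neutrality

Parity coordinates are A3/(A3+T3) (Y) and G3/(G3+C3) (X) from
third-position counts over all codons *excluding* the terminal stop by
default: the stop's third base is constrained by the stop alphabet and
would distort single-gene toys; `include_stop` restores it (composition
percentages remain stop-inclusive — the two uses are independent
switches). A zero denominator yields NaN with a warning.

The neutrality fit is OLS (with intercept) of GC12 on GC3, via the
standard closed form; slope, intercept, Pearson r, the two-sided p and
per-gene residuals are all reported, and the OLS identity
slope = r·sd(GC12)/sd(GC3) is asserted in tests. Constant GC3 is an
error (undefined slope), not a silent NaN.

All correlations are Pearson product-moment with two-sided p-values
from the t transform with n − 2 df; NA pairs are dropped pairwise and
zero variance yields NaN. Significance is annotated at p < 0.01 with
no multiple-testing correction — the suite reports the conventional
per-comparison values, and readers should treat the 12-pair ENC suite
and the 59 per-codon correlations accordingly.

## Correspondence analysis

Classical CA applied to the gene × 59-codon RSCU matrix directly,
treating RSCU as abundance (the common practice in codon-usage work):
proportions P, masses r and c, SVD of
D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, principal coordinates
F = D_r^{-1/2}UΣ and G = D_c^{-1/2}VΣ, inertia fraction σ_a²/Σσ².
NaN RSCU is imputed as 0 with a logged count (CA needs complete
non-negative input); all-zero columns are excluded from the
decomposition and returned with zero coordinates; identical rows give
zero total inertia and all genes at the origin. Axes are reported to
k = 10 in the TSV export; the full decomposition is kept in memory.
Tests verify inertia conservation against a brute-force chi-square
computation, the transition formulas, and eigenvalue agreement with an
explicit eigendecomposition on small random tables.

## Codon-pair context

Adjacent in-frame codon pairs pooled over genes into a 64 × 64 table
(5′ codon in rows, alphabetical order), start codon participating as
the first 5′ member and the terminal stop as the last 3′ member.
Expected counts from the independence model E_ij = row_i col_j / N;
residuals are *adjusted* Pearson residuals
(O − E)/√(E(1 − row/N)(1 − col/N)), chosen because they have unit
asymptotic variance under independence, making cells comparable; cells
with E = 0 get residual 0. The pooled matrix is the primary output; a
mean of per-gene residual matrices is available (`pooled_context` off)
when long genes should not dominate. Heatmap ordering comes from
average-linkage hierarchical clustering with Euclidean distance on
residual rows and columns separately.

## Protein properties

Translation uses the standard code with the stop dropped. GRAVY is the
mean Kyte–Doolittle (1982) hydropathy (per-residue scale −4.5 to 4.5;
whole-protein values in practice fall roughly in ±2). Aromaticity is
the F/W/Y fraction. pI solves net charge = 0 by bisection on [0, 14]
to 0.001 pH units under the Henderson–Hasselbalch model with the
EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1), echoed in code constants. Learned pI
predictors give different absolute values; any classical pKa set
preserves the protein *ordering*, which is all the downstream
ENC-vs-pI regression consumes — tests assert ordering agreement with
an independent implementation, not value equality.

## Synthetic data generator

Defaults describe the study conditions used throughout the tests:
224 genes, lengths uniform over 120–1100 codons (including start and
stop), per-gene GC3 drawn uniformly from 0.35–0.85 (a broad mammalian-
like dispersion), bias concentration 1.0, GC12 = 0.213·GC3 + 36 with
Gaussian noise (sd 2 percentage points) — a weak positive coupling of
the kind neutrality analyses detect in mammalian gene panels. Met/Trp
are injected at 4% total frequency; amino acids are otherwise sampled
from the 18 degenerate ones.

Mechanics, per gene: (1) synonymous-codon weights within each amino
acid are exponentially tilted toward G/C-ending codons, with the tilt
solved by bisection so the *expected* third-position GC of the whole
gene (start, stop, Met/Trp included) equals the drawn GC3 target;
(2) final codon probabilities are drawn from a Dirichlet centred on
those weights with concentration k/b (b = bias strength; b = 0 uses
the weights exactly, so GC3 = 0.5 and b = 0 yields uniform synonymous
usage and ENC near the cap; large b concentrates each amino acid on
one preferred codon and drives ENC toward 20); (3) the amino-acid
sampling distribution is exponentially tilted toward residues whose
codons are G/C-rich at positions 1–2 (Ala/Gly/Pro high, Lys/Asn/Phe
low), solved by bisection so the expected GC12 hits
slope·ĝ3 + intercept + noise, where ĝ3 is the expected GC3 under the
gene's *drawn* codon probabilities — anchoring the target to ĝ3 rather
than the nominal GC3 removes the errors-in-variables attenuation that
codon-sampling noise would otherwise impose on the recovered
neutrality slope (residual attenuation from multinomial noise at
300–600 codons is below 0.01 on a slope of 0.2–0.3). A two-step fixed
point handles the weak feedback of the amino-acid tilt on expected
GC3. All draws flow from one `numpy` generator seeded by the spec.

Synthetic mFE values follow |mFE| = 0.45·length_nt·(1 + 0.5·GC/100)
plus Gaussian noise (sd 50 kcal/mol), clamped non-negative — folding
energy magnitudes grow with transcript length and GC pairing strength,
at magnitudes comparable to folded mRNAs in this length range.

What the generator does *not* emulate: real amino-acid composition,
isochore structure, dinucleotide avoidance (e.g. CpG), splice-site or
expression-level covariates, or evolutionary dynamics. Passing tests
therefore demonstrate that the estimators recover the statistical
structure they target under controlled conditions, not that any
biological conclusion about a particular gene panel is reproduced.

## Numerical conventions

TSV exports use tabs, '.' decimals, 4-decimal floats (composition at
2); full precision lives in the in-memory results. Bisections run to
fixed tolerance (60 iterations for generator tilts, 0.001 pH for pI).
Degenerate inputs are errors where a statistic is undefined (constant
regressor, empty gene list, all-zero CA matrix) and NaN-with-reason
where a gene simply lacks information (missing ENC classes, absent
amino acids, zero parity denominators). Analyses that need at least
three genes (regressions, correlations, CA) are skipped on smaller
inputs rather than extrapolated.

## Problem sizes in the test suite

The suite exercises the estimators at sizes where sampling error is
analytically predictable: 50–200 genes of 100–600 codons for the
cross-gene analyses, 3,000-codon genes for near-cap ENC behaviour,
1,000 short random genes for the RSCU identity, 50 replicates per
bias level for the ENC monotonicity check. The full suite runs in
well under a minute on one CPU.
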