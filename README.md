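# cubkit

Codon usage bias (CUB) analysis for sets of protein-coding sequences.

Synonymous codons are not used uniformly: mutation pressure and natural
selection leave quantifiable fingerprints on which codons a genome
prefers. `cubkit` takes a FASTA of coding sequences (CDS), validates
them as complete open reading frames, and computes the standard battery
of codon-usage diagnostics used in molecular-evolution studies of gene
panels (disease gene sets, pathway gene sets, viral genomes):

* **Nucleotide composition** — per-gene A/T/G/C percentages overall and
  at third codon positions; GC, GC1, GC2, GC3 and GC12 = (GC1+GC2)/2.
* **RSCU** — relative synonymous codon usage,
  RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij), with the conventional 0.5
  replacement for zero counts of observed amino acids, and the
  four-way classification (over-represented > 1.6, more frequent
  [1, 1.6], less frequent [0.6, 1), under-represented < 0.6).
* **ENC** — Wright's effective number of codons,
  ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 with
  F̂ = (n Σ p_i² − 1)/(n − 1) per amino acid, capped into [20, 61]
  (20 = one codon per amino acid, 61 = no bias).
* **Parity rule 2** — each gene at (G3/(G3+C3), A3/(A3+T3)); 0.5 is
  the no-bias centre expected under strand-symmetric mutation.
* **Neutrality plot** — OLS regression of GC12 on GC3; slope ≈ 1
  implicates mutation pressure, slope ≈ 0 selection.
* **Correspondence analysis** — chi-square-metric ordination (SVD of
  standardized residuals) of the gene × 59-codon RSCU matrix, with
  per-axis inertia fractions.
* **Codon-pair context** — the 64 × 64 matrix of adjacent in-frame
  codon pairs (5′ codons in rows) against an independence model, as
  adjusted Pearson residuals, with a clustered ordering for heatmaps.
* **Protein properties** — length, GRAVY (mean Kyte–Doolittle
  hydropathy), aromaticity (fraction F/W/Y), isoelectric point
  (Henderson–Hasselbalch bisection, EMBOSS pKa set), each regressed
  against ENC.
* **mFE correlations** — given a user-supplied table of minimum free
  energies from an external RNA-folding tool, correlations of |mFE|
  with ENC and the GC measures.

A fully controllable synthetic-CDS generator (length distribution, GC3
level, codon-bias concentration, GC12–GC3 coupling, matched synthetic
mFE values) makes every stage testable without downloads.

## Worked example

Generate a 60-gene synthetic set and analyse it end to end:

```sh
cubkit synth -n 60 --seed 7 -o demo
cubkit run demo.fasta --mfe-table demo_mfe.tsv -o demo_out
```

prints

```
Codon Usage Bias Analysis
==========================================================
Genes analysed                                          60
Mean ENC                                            39.173
Mean GC (%)                                         53.544
Mean GC3 (%)                                        61.875
Mean AT bias (A3/(A3+T3))                           0.4513
Mean GC bias (G3/(G3+C3))                           0.4471
Neutrality slope (GC12~GC3)                         0.2063
Neutrality r                                        0.7996
CoA axis 1 inertia (%)                               19.95
CoA axis 2 inertia (%)                                6.14
----------------------------------------------------------
Over-represented codons (RSCU > 1.6):  none
Under-represented codons (RSCU < 0.6): none
==========================================================
```

Mean ENC ≈ 39 reflects the generator's moderate bias concentration;
the neutrality slope ≈ 0.21 recovers the GC12–GC3 coupling the
generator imposed (mutation pressure explains ~21% of the GC12
variation, the rest is held in place as selection would); the parity
biases sit just below the 0.5 centre (slight T-over-A and C-over-G
preference at third positions, driven by the GC3 range). `demo_out/`
contains the full TSV bundle (composition, per-gene RSCU matrix, ENC,
parity/neutrality coordinates and residuals, the correlation suite,
CoA coordinates and inertias, context matrices and clustering order,
protein properties) plus `summary.json` with these headline numbers.

The same analysis is available as a library:

```python
from cubkit import CodonUsageModel

model = CodonUsageModel.from_fasta("demo.fasta", mfe_table="demo_mfe.tsv")
results = model.fit()
print(results.summary())
results.plot_neutrality()
results.to_directory("demo_out")
```

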