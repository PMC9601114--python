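"""Standard genetic code tables and physicochemical constants.

Everything downstream (RSCU, ENC, correspondence analysis, protein
properties) is defined relative to the standard (NCBI table 1) nuclear
code: 61 sense codons, 3 stops, and the 59 "degenerate" sense codons
obtained by further dropping ATG (Met) and TGG (Trp), the only two
amino acids encoded by a single codon.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_BASES = "ACGT"

#: all 64 codons in alphabetical order (the fixed row/column order used
#: for codon-context matrices and TSV exports)
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"
ALT_START_CODONS: frozenset[str] = frozenset({"CTG", "GTG", "TTG"})

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (alphabetical)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

#: the 18 amino acids with >1 codon, i.e. those that carry usage-bias signal
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, cs in AA_TO_CODONS.items() if len(cs) > 1)
)

#: the 59 sense codons of degenerate amino acids (64 - 3 stops - ATG - TGG)
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(AA_TO_CODONS[CODON_TO_AA[c]]) > 1
)

#: Wright's degeneracy classes in the standard code.  Ile is the lone
#: 3-fold amino acid; Leu/Ser/Arg are 6-fold.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    2: ("C", "D", "E", "F", "H", "K", "N", "Q", "Y"),
    3: ("I",),
    4: ("A", "G", "P", "T", "V"),
    6: ("L", "R", "S"),
}

AA_DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: Kyte & Doolittle (1982) hydropathy indices; GRAVY is their mean over
#: a protein's residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_AAS: frozenset[str] = frozenset({"F", "W", "Y"})

#: EMBOSS default pKa values for the Henderson-Hasselbalch net-charge
#: model used by the pI solver: termini plus the ionizable side chains.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

#: side chains that are positively charged when protonated
BASIC_SIDE_CHAINS: frozenset[str] = frozenset({"H", "K", "R"})
#: side chains that are negatively charged when deprotonated
ACIDIC_SIDE_CHAINS: frozenset[str] = frozenset({"C", "D", "E", "Y"})

GC_BASES: frozenset[str] = frozenset({"G", "C"})


def ends_gc(codon: str) -> bool:
    """True if the codon's third base is G or C."""
    return codon[2] in GC_BASES
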