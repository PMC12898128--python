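"""Curated worked-example sequences for the Ataxin-2 family.

Small, hand-checkable inputs drawn from public database entries: repeat
region codon strings in run-length notation, local peptides around the
polyQ/polyA repeats, the two pathogenic tandem-duplication peptides, and
PAM2 candidate cores from trypanosomatids. These drive the worked examples
in ``analysis/`` and the regression tests; they are inputs, not expected
outputs.
"""

# Canonical healthy-allele polyQ repeat template of human ATXN2 exon 1:
# a CAG tract with two stabilizing CAA interruptions, encoding 22 Gln.
CANONICAL_22Q_TEMPLATE = "(CAG)_8_-CAA-(CAG)_4_-CAA-(CAG)_8_"

# Repeat-region codon strings of distant Ataxin-2 orthologs, in the same
# run-length notation (bold ATG markup ** retained where present).
GRACILARIOPSIS_30Q = (
    "(CAA)_3_CAG(CAA)_2_(CAG)_2_(CAA)_2_(CAG)_2_(CAA)_5_(CAG)_6_CAA(CAG)_2_(CAA)_4_"
)

SYMBIODINIUM_73Q = (
    "CAG(CAA)_2_(CAG)_2_CAA**ATG**(CAG)_2_CAA(CAG)_2_CAA(CAG)_2_CAA(CAG)_2_CAA"
    "(CAG)_4_CAA(CAG)_2_CAA(CAG)_6_CAA(CAG)_3_CAA**ATG**(CAG)_2_CAA(CAG)_2_"
    "(CAA)_2_(CAG)_2_CAA(CAG)_2_CAA(CAG)_4_(CAA)_2_(CAG)_3_(CAA)_3_(CAG)_3_CAA"
    "(CAG)_2_CAA(CAG)_3_**ATG**CAG"
)

CONDYLOSTYLUS_45Q = (
    "(CAA)_2_CAG(CAA)_7_CAG(CAA)_8_(CAG)_3_(CAA)_4_CAG(CAA)_5_CAG(CAA)_3_CAGCAA-"
    "(CAG)_3_(CAA)_4_"
)

DICTYOSTELIUM_29Q = "(CAA)_29_"

#: all five repeat codon decompositions keyed by a short label
CODON_DECOMPOSITIONS = {
    "human_canonical_22Q": CANONICAL_22Q_TEMPLATE,
    "gracilariopsis_30Q": GRACILARIOPSIS_30Q,
    "symbiodinium_73Q": SYMBIODINIUM_73Q,
    "condylostylus_45Q": CONDYLOSTYLUS_45Q,
    "dictyostelium_29Q": DICTYOSTELIUM_29Q,
}

# Local peptides around the N-terminal repeat region.
# Human ATXN2 residues 156-202 (UniProt Q99700), spanning the 23Q tract.
HUMAN_POLYQ_PEPTIDE = "YGPLTMSLKPQQQQQQQQQQQQQQQQQQQQQQQPPPAAANVRKPGGS"

# Ostrich (Struthio camelus) N-terminal fragment: polyA analog of the
# mammalian polyQ repeat (XP_068766831.1).
OSTRICH_POLYA_PEPTIDE = "MSLKQAAAAAQAA"

# Primate monkey N-terminal polyQ fragment (XP_054298120.1).
MONKEY_POLYQ_PEPTIDE = "MSLKPQQQQQQQQQQQQQQQQPPAAA"

# Pathogenic tandem duplications in the exon-1A encoded region of ATXN2.
# dup21: residues 145-151 repeated (21 bp at DNA level), Japanese SCA2 case.
DUP21_PEPTIDE = "ARPAPGCPRPAPGCPRPACEPV"
# dup9: residues 38-40 repeated (9 bp), Swedish SCA3/ALS families.
DUP9_PEPTIDE = "PARRSGRSGRGGGG"

# LSm-proximal alternative translation start (exon 3B).
LSM_START_PEPTIDE = "MRMVHILTSVV"

# Candidate PAM2 precursor cores in trypanosomatid Ataxin-2 family members.
TRYPANOSOMATID_PAM2_CORES = {
    "Perkinsela": "LNPNATAFLP",
    "Leishmania": "PNPSATPFVP",
    "Trypanosoma": "FNPAATPYTP",
    "Phytomonas": "PNPAAAPFVP",
    "Leptomonas": "PNPSATPFVP",
}
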