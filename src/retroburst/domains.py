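"""Consensus peptide templates for the five canonical LTR-retrotransposon domains.

The internal (pol/gag) region of an autonomous LTR-retrotransposon encodes, in
superfamily-specific order, a capsid protein (GAG), an aspartic protease (PR),
an integrase (INT), a reverse transcriptase (RT) and an RNase H (RH).  Copia
elements carry the integrase upstream of the reverse transcriptase
(GAG-PR-INT-RT-RH); Gypsy elements carry it downstream of the RNase H
(GAG-PR-RT-RH-INT).  These synthetic consensi include the canonical catalytic
motifs (CCHC zinc knuckle in GAG, DTG in PR, the DDE triad spacing in INT,
YVDD in RT) and are shared by the simulator, which plants them, and the
classifier, which searches for them.  A loader accepts user-supplied profile
sets for real genomes.
"""

DOMAIN_NAMES = ("GAG", "PR", "INT", "RT", "RH")

COPIA_ORDER = ("GAG", "PR", "INT", "RT", "RH")
GYPSY_ORDER = ("GAG", "PR", "RT", "RH", "INT")

# Synthetic consensus peptides (not derived from any database entry).
DOMAIN_PEPTIDES = {
    "GAG": (
        "MSKAQEWLNRLTPAQRAEVLKMGVSEDALRNWIAQTKPECFNCGKIGHFARE"
        "CPNKRVMTLD"
    ),
    "PR": (
        "LEPVMIDTGASHSFISKRFAEQHGLKTEPLRQPMSVSLADGRKQVSDIVTAQ"
    ),
    "INT": (
        "FQTDNGREFVNHEVQAFLKEHGIHHRLTAPYTPQQNGVAERMNRTLMEKARCML"
        "HDAGLPKSFWAEAV"
    ),
    "RT": (
        "LDLKNAFLHGDLEEEVYMKQPPGFEDPKYPNHVCKLNKALYGLKQAPRAWFERF"
        "STVIQEFGFKQSYVDDTLFVGK"
    ),
    "RH": (
        "KAVKYIWKYLKGTTDYGLWYPKGEDFELVGYSDSDWAGCPDDRKSTSGYAFMLG"
        "G"
    ),
}

# One codon per amino acid keeps the planted cassette deterministic and easy
# to project back to nucleotide coordinates.
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def encode_peptide(peptide: str) -> str:
    """Back-translate a peptide into nucleotide sequence (one fixed codon per residue)."""
    return "".join(_CODON[aa] for aa in peptide)
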