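"""Genetic-code constants shared across the package.

The standard nuclear code is taken from Biopython's codon tables; every
module works on DNA-alphabet codons (A/C/G/T) in the 5'->3' reading frame.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense (amino-acid coding) codons, sorted lexicographically.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: codon -> one-letter amino acid, sense codons only.
AA_OF: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> sorted tuple of synonymous codons.
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(AA_OF.items()):
    SYNONYMS.setdefault(_aa, ())
    SYNONYMS[_aa] = SYNONYMS[_aa] + (_codon,)

assert len(SENSE_CODONS) == 61
assert len(STOP_CODONS) == 3


def translate(codons: list[str] | tuple[str, ...]) -> str:
    """Translate a codon list to a one-letter protein string.

    Stop codons translate to ``*`` wherever they occur; validation of
    where stops are allowed is the job of :mod:`csckit.sequence_io`.
    """
    return "".join("*" if c in STOP_CODONS else AA_OF[c] for c in codons)
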