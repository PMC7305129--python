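"""Small nucleotide/protein sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.standard_dna_table

#: codon -> amino acid, stops mapped to ``*``; lookups outside the 64
#: unambiguous codons (e.g. containing N) fall back to ``X``
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> synonymous codons (sorted, for deterministic sampling)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
STOP_CODONS: list[str] = sorted(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, offset: int) -> str:
    """Translate ``seq`` starting at ``offset`` (0..2); trailing partial
    codon dropped, ambiguous codons become ``X``, stops become ``*``."""
    get = CODON_TO_AA.get
    end = len(seq) - (len(seq) - offset) % 3
    return "".join(get(seq[i : i + 3], "X") for i in range(offset, end, 3))


def back_translate(protein: str, rng: np.random.Generator, add_stop: bool = True) -> str:
    """Encode ``protein`` with uniformly sampled synonymous codons."""
    codons = [AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in protein]
    if add_stop:
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute ``round(divergence * len)`` positions to a different residue."""
    from .markers import AMINO_ACIDS

    n_mut = int(round(divergence * len(protein)))
    if n_mut == 0:
        return protein
    positions = rng.choice(len(protein), size=n_mut, replace=False)
    residues = list(protein)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return "".join(residues)
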