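"""Shared pairwise alignment helpers.

Protein scoring follows the BLASTP convention: BLOSUM62 with gap open 11 /
extend 1 (a gap of length *k* costs ``11 + k``), e-values from the
Karlin-Altschul formula with the standard gapped parameters for that scheme
(lambda = 0.267, K = 0.041). Percent identity is identities over alignment
columns, gap columns included.
"""

from __future__ import annotations

import math

from Bio import Align
from Bio.Align import substitution_matrices

KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)


def protein_aligner(mode: str = "local", free_end_gaps: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global" if mode in ("global", "glocal") else "local"
    # open includes the first gapped position: gap of length k costs 11 + k
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    if mode == "glocal" or free_end_gaps:
        try:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    return aligner


def evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul e-value of a raw alignment score for a query of
    length ``m`` against a database of ``n`` total residues."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def bit_score(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / LN2


def alignment_identity(alignment) -> tuple[float, int]:
    """Percent identity over all alignment columns (gaps included)."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0
    return 100.0 * counts.identities / columns, columns
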