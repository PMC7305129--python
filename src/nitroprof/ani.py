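"""Fragment-based average nucleotide identity (ANI).

The query genome is cut into non-overlapping fragments (3,000 b by the
convention of fragment-based ANI estimators); each fragment is aligned to
its best location in the reference, on either strand, by banded edit
alignment (edlib infix mode). Fragments reaching the minimum identity
(default 80%) count as aligned, and ANI is the mean identity over aligned
fragments, reported only when the aligned fraction reaches
``min_aligned_fraction`` (default 0.2). The measure is asymmetric
(query -> reference); a symmetric mean of both orientations is available.
ANI >= 95% is the conventional same-species boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .seqs import revcomp


@dataclass(frozen=True)
class ANIParams:
    fragment_length: int = 3000
    min_fragment_identity: float = 80.0
    min_aligned_fraction: float = 0.2
    species_threshold: float = 95.0

    def __post_init__(self):
        if not 0 < self.min_aligned_fraction <= 1:
            raise ValueError("min_aligned_fraction must be in (0, 1]")
        for t in (self.min_fragment_identity, self.species_threshold):
            if not 0 < t <= 100:
                raise ValueError("identity thresholds must be in (0, 100]")


@dataclass(frozen=True)
class ANIResult:
    query_id: str
    reference_id: str
    ani: float | None
    n_fragments_total: int
    n_fragments_aligned: int


def _as_contigs(genome) -> list[str]:
    if isinstance(genome, str):
        return [genome.upper()]
    if isinstance(genome, dict):
        return [genome[c].upper() for c in sorted(genome)]
    return [str(s).upper() for s in genome]


def _identity_vs(fragment: str, reference: str, k: int) -> float | None:
    """Best-location percent identity (matches / alignment columns) of the
    fragment against one reference strand; None when nothing within band."""
    res = edlib.align(fragment, reference, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    cols = matches = 0
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        cols += int(n)
        if op == "=":
            matches += int(n)
    return 100.0 * matches / cols if cols else None


def fragment_ani(
    query,
    reference,
    params: ANIParams = ANIParams(),
    query_id: str = "query",
    reference_id: str = "reference",
) -> ANIResult:
    """Fragment-based ANI of ``query`` against ``reference`` (asymmetric).

    Inputs are sequences, contig dicts, or contig lists. Raises when the
    query has no complete fragment.
    """
    q_contigs = _as_contigs(query)
    r_contigs = _as_contigs(reference)
    L = params.fragment_length
    fragments = [
        contig[i : i + L]
        for contig in q_contigs
        for i in range(0, len(contig) - L + 1, L)
    ]
    if not fragments:
        raise ValueError(f"query shorter than one fragment ({L} b)")
    ref_fwd = r_contigs
    ref_rev = [revcomp(c) for c in r_contigs]
    # d <= 0.2 * cols and cols <= L + d gives d <= 0.25 L; pad the band
    k = int(L * (1 - params.min_fragment_identity / 100) * 1.3) + 10

    identities = []
    n_aligned = 0
    for frag in fragments:
        best = None
        for ref in (*ref_fwd, *ref_rev):
            if len(ref) < len(frag):
                continue
            ident = _identity_vs(frag, ref, k)
            if ident is not None and (best is None or ident > best):
                best = ident
        if best is not None and best >= params.min_fragment_identity:
            n_aligned += 1
            identities.append(best)
    ani = None
    if n_aligned / len(fragments) >= params.min_aligned_fraction and identities:
        ani = sum(identities) / len(identities)
    return ANIResult(query_id, reference_id, ani, len(fragments), n_aligned)


def symmetric_ani(a, b, params: ANIParams = ANIParams()) -> float | None:
    """Mean of both orientations; None when either orientation is absent."""
    ab = fragment_ani(a, b, params)
    ba = fragment_ani(b, a, params)
    if ab.ani is None or ba.ani is None:
        return None
    return (ab.ani + ba.ani) / 2.0


def species_match(result: ANIResult, threshold: float = 95.0) -> bool:
    """True iff ANI is defined and reaches the species threshold."""
    return result.ani is not None and result.ani >= threshold
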