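"""Synthetic seed proteins for the nitrification gene catalog.

Every gene the simulator and the genotyping targets know about has a single
*seed* protein: a deterministic, randomly generated amino-acid sequence that
stands in for the real gene family (real reference alignments cannot be
redistributed here, and nothing downstream depends on biochemistry — only on
sequence identity structure). Seeds are reproducible: they are derived from a
fixed per-gene RNG stream, so profiles, genomes and reference databases built
from them are bit-stable across runs and machines.

Two seeds carry real biological constraints used by the motif rules:

* ``cynS`` (cyanase) has the conserved catalytic residues Arg96, Glu99 and
  Ser122 (1-based) fixed, so the cyanase active-site rule can be anchored to
  the packaged reference frame.
* ``hyfG`` (group 4 [Ni-Fe] hydrogenase large subunit) carries the two CxxC
  cysteine motifs that ligate the NiFe center.

Ammonia-oxidizer ``amoA`` comes in two unrelated seeds, mirroring the fact
that archaeal and bacterial ammonia monooxygenases are profiled by separate
models (``amoA_AOA`` vs ``amoA_AOB``); comammox *Nitrospira* amoA belongs to
the bacterial model's family.
"""

from __future__ import annotations

import hashlib

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: protein length (residues) for every known gene family
GENE_LENGTHS: dict[str, int] = {
    # profiling markers
    "rpoB": 400,
    "amoA_AOA": 250,
    "amoA_AOB": 250,
    "nxrB": 430,
    # remaining nitrification pathway genes
    "amoB": 230,
    "amoC": 240,
    "hao": 350,
    "nxrA": 450,
    # accessory repertoire targets (urea, cyanate, nitrite handling,
    # hydrogenases, transporters, cytochromes)
    "ureC": 300,
    "urtA": 280,
    "nrfA": 320,
    "nirK": 260,
    "nirA": 290,
    "narK": 250,
    "nirC": 180,
    "cynA": 200,
    "cynB": 170,
    "cynD": 160,
    "cynS": 156,
    "hupL": 310,
    "hypB": 220,
    "hyfG": 300,
    "hybL": 300,
    "hydB": 280,
    "fdhA": 330,
    "amt": 220,
    "Rh50": 230,
    "cycA": 120,
    "occ": 260,
}

#: residues that must be present in a seed, 1-based position -> residue
_PINNED_RESIDUES: dict[str, dict[int, str]] = {
    # catalytic triad of cyanases
    "cynS": {96: "R", 99: "E", 122: "S"},
    # two NiFe-ligating CxxC motifs of group 4 hydrogenase large subunits
    "hyfG": {40: "C", 43: "C", 255: "C", 258: "C"},
}


def _gene_rng(gene_name: str) -> np.random.Generator:
    """Deterministic RNG stream per gene, independent of Python hashing."""
    digest = hashlib.sha256(f"nitroprof-seed:{gene_name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def seed_protein(gene_name: str) -> str:
    """Return the fixed seed protein for ``gene_name``.

    Raises ``KeyError`` for genes outside the catalog.
    """
    length = GENE_LENGTHS[gene_name]
    rng = _gene_rng(gene_name)
    aa = rng.choice(list(AMINO_ACIDS), size=length)
    for pos, res in _PINNED_RESIDUES.get(gene_name, {}).items():
        aa[pos - 1] = res
    return "".join(aa)


def marker_seed_for(gene_name: str, guild: str) -> tuple[str, str]:
    """Seed (family name, protein) used when a genome of ``guild`` carries
    ``gene_name``.

    The only guild-dependent gene is ``amoA``: archaea draw from the
    ``amoA_AOA`` family, bacteria (AOB and comammox) from ``amoA_AOB``.
    """
    if gene_name == "amoA":
        family = "amoA_AOA" if guild == "AOA" else "amoA_AOB"
    else:
        family = gene_name
    return family, seed_protein(family)
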