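"""Marker-gene community profiling from unassembled reads.

Implements the read-level profiling workflow: six-frame ORF calling on raw
reads, profile search for the four nitrification markers (*rpoB*,
``amoA_AOA``, ``amoA_AOB``, *nxrB*) at a detection e-value of 1e-3, best-hit
taxonomic classification against a labeled protein database at 1e-6, and the
single-copy normalization that turns hit counts into community relative
abundances:

    A[h, t] = 100 * (n[h, t] / L_h) / (sum_t n[rpoB, t] / L_rpoB)

where ``n[h, t]`` is the number of reads whose best ORF hits profile ``h``
and classifies to taxon ``t``, and ``L_h`` is the profile's match-state
length. Because *rpoB* is single-copy, the rows for ``h = rpoB`` sum to
exactly 100% and each taxon's value estimates its share of community cells;
a functional gene present at *c* copies per genome shows up at *c* times its
host's *rpoB* abundance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from .markers import AMINO_ACIDS, seed_protein
from .seqs import revcomp, translate_frame
from .synthetic import ReferenceDB, SimulatedRead

MARKER_NAMES = ("rpoB", "amoA_AOA", "amoA_AOB", "nxrB")

_VALID_READ = re.compile(r"^[ACGTN]+$")
_PEPTIDE_RE = re.compile(r"[^*]+")


@dataclass(frozen=True)
class Peptide:
    read_id: str
    frame: int  # {-3..-1, 1..3}
    sequence: str


@dataclass(frozen=True)
class ProfileModel:
    """A registered protein profile: name, match-state length and the engine
    handle that scores peptides against it."""

    marker_name: str
    model_length: int
    engine: "SearchEngine"
    handle: object

    def __post_init__(self):
        if self.model_length < 1:
            raise ValueError("model_length must be >= 1")


@dataclass
class MarkerHit:
    read_id: str
    orf_frame: int
    marker_name: str
    bit_score: float
    e_value: float
    peptide: str
    taxon: str | None = None
    ref_id: str | None = None
    identity: float | None = None


class SearchEngine(Protocol):
    """Contract for pluggable profile-search engines: build a profile from a
    seed protein, then map peptides to (bit score, e-value)."""

    def build(self, marker_name: str, seed: str) -> ProfileModel: ...

    def search(
        self, profile: ProfileModel, peptides: Sequence[tuple[str, str]], e_max: float
    ) -> list[tuple[str, float, float]]:
        """Return ``(peptide_name, bit_score, e_value)`` for peptides scoring
        at e-value <= e_max."""
        ...


class PyhmmerEngine:
    """Profile-HMM engine backed by pyhmmer (HMMER3).

    Profiles are single-sequence HMMs built from the packaged seed proteins;
    e-values use the pipeline's default database-size convention (number of
    target peptides).
    """

    def __init__(self):
        import pyhmmer

        self._pyhmmer = pyhmmer
        self.alphabet = pyhmmer.easel.Alphabet.amino()
        self.background = pyhmmer.plan7.Background(self.alphabet)
        self.builder = pyhmmer.plan7.Builder(self.alphabet)

    def build(self, marker_name: str, seed: str) -> ProfileModel:
        seq = self._pyhmmer.easel.TextSequence(
            name=marker_name.encode(), sequence=seed
        ).digitize(self.alphabet)
        hmm, _, _ = self.builder.build(seq, self.background)
        return ProfileModel(marker_name, hmm.M, self, hmm)

    def search(self, profile, peptides, e_max):
        easel = self._pyhmmer.easel
        seqs = easel.DigitalSequenceBlock(
            self.alphabet,
            [
                easel.TextSequence(name=name.encode(), sequence=seq).digitize(self.alphabet)
                for name, seq in peptides
            ],
        )
        pipeline = self._pyhmmer.plan7.Pipeline(self.alphabet, background=self.background)
        try:
            top = pipeline.search_hmm(profile.handle, seqs)
        except Exception as exc:  # pragma: no cover - engine failure path
            raise RuntimeError(f"profile search failed for {profile.marker_name}") from exc
        out = []
        for hit in top:
            if hit.evalue <= e_max:
                name = hit.name.decode() if isinstance(hit.name, bytes) else hit.name
                out.append((name, float(hit.score), float(hit.evalue)))
        return out


class PSSMEngine:
    """Self-contained position-specific scoring matrix engine.

    Scores are best ungapped log-odds placements of a peptide along the
    profile; e-values come from a Gumbel tail fitted to a seeded random-
    peptide null at build time, scaled by the number of target peptides.
    A lightweight alternative to the HMM engine satisfying the same search
    contract.
    """

    def __init__(self, match_prob: float = 0.7, n_null: int = 2000, null_len: int = 60, seed: int = 7):
        self.match_prob = match_prob
        self.n_null = n_null
        self.null_len = null_len
        self.seed = seed
        self._aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def _encode(self, seq: str) -> np.ndarray:
        idx = self._aa_index
        return np.array([idx.get(a, -1) for a in seq], dtype=np.int64)

    def _raw_score(self, matrix: np.ndarray, pep: np.ndarray) -> float:
        L, n = matrix.shape[0], len(pep)
        valid = pep >= 0
        best = -np.inf
        min_overlap = min(15, n, L)
        for offset in range(-(n - min_overlap), L - min_overlap + 1):
            p_lo, p_hi = max(0, -offset), min(n, L - offset)
            rows = np.arange(p_lo, p_hi) + offset
            cols = pep[p_lo:p_hi]
            ok = valid[p_lo:p_hi]
            score = matrix[rows[ok], cols[ok]].sum()
            if score > best:
                best = score
        return float(best)

    def build(self, marker_name: str, seed: str) -> ProfileModel:
        L, A = len(seed), len(AMINO_ACIDS)
        probs = np.full((L, A), (1 - self.match_prob) / (A - 1))
        probs[np.arange(L), self._encode(seed)] = self.match_prob
        matrix = np.log2(probs * A)
        rng = np.random.default_rng(self.seed)
        null_scores = np.array(
            [
                self._raw_score(matrix, rng.integers(0, A, size=self.null_len))
                for _ in range(self.n_null)
            ]
        )
        # Gumbel fit by method of moments
        scale = np.sqrt(6.0) * null_scores.std() / np.pi
        loc = null_scores.mean() - np.euler_gamma * scale
        handle = {"matrix": matrix, "loc": loc, "scale": scale}
        return ProfileModel(marker_name, L, self, handle)

    def search(self, profile, peptides, e_max):
        h = profile.handle
        out = []
        n_targets = max(len(peptides), 1)
        for name, seq in peptides:
            s = self._raw_score(h["matrix"], self._encode(seq))
            z = (s - h["loc"]) / h["scale"]
            # Gumbel survival; clipped for numerical safety
            pval = float(1.0 - np.exp(-np.exp(-min(z, 700.0))))
            ev = n_targets * pval
            if ev <= e_max:
                out.append((name, s, ev))
        return out


def build_default_profiles(engine: SearchEngine | None = None) -> dict[str, ProfileModel]:
    """The four marker profiles of the workflow, built from packaged seeds."""
    if engine is None:
        engine = PyhmmerEngine()
    return {name: engine.build(name, seed_protein(name)) for name in MARKER_NAMES}


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------


def predict_orfs(
    reads: Sequence[SimulatedRead] | Sequence[tuple[str, str]],
    min_peptide_len: int = 20,
) -> list[Peptide]:
    """Six-frame translation; peptides are maximal stop-free segments of
    length >= ``min_peptide_len``. Reads with non-ACGTN characters are
    rejected with a warning."""
    items = [(r.read_id, r.sequence) if isinstance(r, SimulatedRead) else r for r in reads]
    if not items:
        raise ValueError("reads must be non-empty")
    peptides: list[Peptide] = []
    for read_id, seq in items:
        seq = seq.upper()
        if not _VALID_READ.match(seq):
            warnings.warn(f"read {read_id} contains non-ACGTN characters; skipped")
            continue
        rc = revcomp(seq)
        for frame_sign, template in ((1, seq), (-1, rc)):
            for offset in range(3):
                aa = translate_frame(template, offset)
                for m in _PEPTIDE_RE.finditer(aa):
                    if m.end() - m.start() >= min_peptide_len:
                        peptides.append(
                            Peptide(read_id, frame_sign * (offset + 1), m.group())
                        )
    return peptides


# ---------------------------------------------------------------------------
# profile search
# ---------------------------------------------------------------------------


def search_markers(
    peptides: Sequence[Peptide],
    profiles: dict[str, ProfileModel] | Sequence[ProfileModel],
    e_max: float = 1e-3,
) -> list[MarkerHit]:
    """Search every peptide against every profile; keep at most one hit per
    (read, marker): lowest e-value, ties by highest bit score, then lowest
    frame."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if not peptides:
        return []
    named = [(f"{i}", p.sequence) for i, p in enumerate(peptides)]
    hits: list[MarkerHit] = []
    for profile in profiles:
        best: dict[str, MarkerHit] = {}
        for name, score, ev in profile.engine.search(profile, named, e_max):
            pep = peptides[int(name)]
            hit = MarkerHit(
                read_id=pep.read_id,
                orf_frame=pep.frame,
                marker_name=profile.marker_name,
                bit_score=score,
                e_value=ev,
                peptide=pep.sequence,
            )
            prev = best.get(pep.read_id)
            if prev is None or (hit.e_value, -hit.bit_score, hit.orf_frame) < (
                prev.e_value,
                -prev.bit_score,
                prev.orf_frame,
            ):
                best[pep.read_id] = hit
        hits.extend(best.values())
    return hits


# ---------------------------------------------------------------------------
# taxonomic classification
# ---------------------------------------------------------------------------


def classify_hits(
    hits: Sequence[MarkerHit],
    reference_db: ReferenceDB,
    e_max_tax: float = 1e-6,
    rank: str = "genus",
) -> list[MarkerHit]:
    """Assign each hit the taxon of its best-scoring reference protein.

    Best = highest Smith-Waterman score (equivalently lowest Karlin-Altschul
    e-value); ties broken by highest percent identity, then lexicographic
    reference id. Hits with no reference at e <= ``e_max_tax`` become
    ``"unclassified"``.
    """
    if not reference_db.proteins:
        raise ValueError("reference database is empty")
    aligner = _align.protein_aligner("local")
    ref_ids = sorted(reference_db.proteins)
    ref_seqs = [reference_db.proteins[r] for r in ref_ids]
    db_residues = sum(len(s) for s in ref_seqs)
    tax = reference_db.taxonomy.set_index("protein_id")
    label_col = "genome_id" if rank == "genome" else rank

    cache: dict[str, tuple[str | None, str | None, float | None]] = {}
    out: list[MarkerHit] = []
    for hit in hits:
        pep = hit.peptide
        if pep in cache:
            taxon, ref_id, ident = cache[pep]
        else:
            scores = np.array([aligner.score(ref, pep) for ref in ref_seqs])
            best = scores.max()
            ev = _align.evalue(best, len(pep), db_residues)
            if ev > e_max_tax:
                taxon, ref_id, ident = "unclassified", None, None
            else:
                tied = [i for i in np.flatnonzero(scores == best)]
                if len(tied) > 1:
                    idents = []
                    for i in tied:
                        aln = aligner.align(ref_seqs[i], pep)[0]
                        idents.append(_align.alignment_identity(aln)[0])
                    order = sorted(
                        zip(tied, idents), key=lambda t: (-t[1], ref_ids[t[0]])
                    )
                    choice, ident = order[0]
                else:
                    choice = tied[0]
                    aln = aligner.align(ref_seqs[choice], pep)[0]
                    ident = _align.alignment_identity(aln)[0]
                ref_id = ref_ids[choice]
                taxon = str(tax.loc[ref_id, label_col])
            cache[pep] = (taxon, ref_id, ident)
        out.append(replace(hit, taxon=taxon, ref_id=ref_id, identity=ident))
    return out


# ---------------------------------------------------------------------------
# hit tables and normalization
# ---------------------------------------------------------------------------


def tally_hits(hits: Sequence[MarkerHit], sample: str = "S1") -> pd.DataFrame:
    """Long-format hit table: one row per (sample, marker, taxon) count."""
    rows = [(sample, h.marker_name, h.taxon or "unclassified") for h in hits]
    df = pd.DataFrame(rows, columns=["sample", "marker", "taxon"])
    return (
        df.groupby(["sample", "marker", "taxon"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )


def normalize_hits(
    hit_table: pd.DataFrame, profiles: dict[str, ProfileModel] | Sequence[ProfileModel]
) -> pd.DataFrame:
    """Length-normalize hit counts and express them relative to total
    length-normalized *rpoB* hits, in percent.

    The denominator uses ALL retained *rpoB* hits, classified or not. A
    sample with zero *rpoB* hits raises (no silent NaN).
    """
    if isinstance(profiles, dict):
        lengths = {m: p.model_length for m, p in profiles.items()}
    else:
        lengths = {p.marker_name: p.model_length for p in profiles}
    if "rpoB" not in lengths:
        raise ValueError("an rpoB profile is required for normalization")
    unknown = set(hit_table["marker"]) - set(lengths)
    if unknown:
        raise ValueError(f"markers without registered profiles: {sorted(unknown)}")
    out_rows = []
    for sample, sub in hit_table.groupby("sample"):
        rpob = sub.loc[sub["marker"] == "rpoB", "count"].sum()
        if rpob == 0:
            raise ValueError(f"sample {sample!r} has zero rpoB hits; cannot normalize")
        denom = rpob / lengths["rpoB"]
        for _, row in sub.iterrows():
            a = 100.0 * (row["count"] / lengths[row["marker"]]) / denom
            out_rows.append((sample, row["marker"], row["taxon"], a))
    return pd.DataFrame(out_rows, columns=["sample", "marker", "taxon", "abundance_percent"])


def comammox_fraction(
    normalized: pd.DataFrame,
    copy_assumption: int = 1,
    marker: str = "amoA_AOB",
    taxon: str = "Nitrospira",
) -> pd.Series:
    """Percent of the total community attributed to comammox *Nitrospira*:
    the *Nitrospira*-classified bacterial ``amoA`` abundance divided by the
    assumed amoA copies per genome (one, by default)."""
    if marker not in set(normalized["marker"]):
        raise ValueError(f"marker {marker!r} not present in the table")
    sub = normalized[(normalized["marker"] == marker) & (normalized["taxon"] == taxon)]
    per_sample = sub.groupby("sample")["abundance_percent"].sum()
    all_samples = normalized["sample"].unique()
    return per_sample.reindex(all_samples, fill_value=0.0) / copy_assumption


def profile_reads(
    reads,
    profiles: dict[str, ProfileModel],
    reference_db: ReferenceDB,
    sample: str = "S1",
    e_max: float = 1e-3,
    e_max_tax: float = 1e-6,
    rank: str = "genus",
    min_peptide_len: int = 20,
) -> tuple[list[MarkerHit], pd.DataFrame, pd.DataFrame]:
    """Full per-sample pipeline: ORFs -> profile search -> classification ->
    normalized abundance table. Returns (hits, hit_table, normalized)."""
    peptides = predict_orfs(reads, min_peptide_len=min_peptide_len)
    hits = search_markers(peptides, profiles, e_max=e_max)
    hits = classify_hits(hits, reference_db, e_max_tax=e_max_tax, rank=rank)
    table = tally_hits(hits, sample=sample)
    return hits, table, normalize_hits(table, profiles)
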