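"""MAG relative abundance by filtered read recruitment.

Reads are mapped against the full genome-bin set; an alignment is retained
only if its score ratio — score divided by the read's maximum attainable
score — reaches ``min_score_ratio`` (default 0.908, i.e. roughly 95%
identity under the default +1/-1/-1 scheme), and each read keeps at most the
``max_sites`` best-scoring sites (default ten) across all bins. A read then
contributes one count to every bin in which it retains at least one site;
bin relative abundance is mapped reads over the caller-supplied sample read
total. Reads retained in two or more bins form the crossover set used to
quantify ambiguous recruitment between closely related genomes.

The mapper is k-mer seeded (exact 15-mers, both strands) with banded
edit-distance extension via edlib; the contract is the score-ratio filter,
not the seeding heuristic, and the scoring scheme is configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .seqs import revcomp
from .synthetic import SimulatedRead

_K = 15  # seed length; guarantees a hit for <= (250/15 - 1) ~ 15 substitutions


@dataclass(frozen=True)
class RecruitmentParams:
    min_score_ratio: float = 0.908
    max_sites: int = 10
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -1

    def __post_init__(self):
        if not 0 < self.min_score_ratio <= 1:
            raise ValueError("min_score_ratio must be in (0, 1]")
        if self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    bin_id: str
    contig_id: str
    position: int  # 0-based start on the contig
    strand: str
    score: int
    score_ratio: float


@dataclass
class RecruitmentProfile:
    """Per-bin mapped-read counts and relative abundances for one sample."""

    sample: str
    counts: pd.DataFrame  # bin_id, mapped_read_count, relative_abundance
    read_bins: dict[str, frozenset[str]]  # read_id -> bins where retained
    total_reads: int

    @property
    def crossover_read_set(self) -> set[str]:
        return {r for r, bins in self.read_bins.items() if len(bins) >= 2}


class _BinIndex:
    """Exact k-mer index over all contigs of all bins."""

    def __init__(self, bins: dict[str, dict[str, str]], k: int = _K):
        self.k = k
        self.contigs: list[tuple[str, str, str]] = []  # (bin_id, contig_id, seq)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for bin_id in sorted(bins):
            for contig_id in sorted(bins[bin_id]):
                seq = bins[bin_id][contig_id].upper()
                ci = len(self.contigs)
                self.contigs.append((bin_id, contig_id, seq))
                for pos in range(len(seq) - k + 1):
                    self.index.setdefault(seq[pos : pos + k], []).append((ci, pos))

    def candidates(self, read: str, span: int) -> set[tuple[int, int]]:
        """Candidate (contig index, window diagonal) pairs for one read
        orientation; diagonals binned to half-read resolution."""
        k = self.k
        out: set[tuple[int, int]] = set()
        half = max(span // 2, 1)
        for qpos in range(0, len(read) - k + 1):
            for ci, rpos in self.index.get(read[qpos : qpos + k], ()):
                diag = rpos - qpos
                out.add((ci, diag // half))
                out.add((ci, diag // half + 1))
        return out


def _score_from_cigar(cigar: str, params: RecruitmentParams) -> int:
    score = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n)
        if op == "=":
            score += n * params.match_score
        elif op in "XM":
            score += n * params.mismatch_score
        else:
            score += n * params.gap_score
    return score


def load_bins(source) -> dict[str, dict[str, str]]:
    """Normalize bin input: mapping of bin_id -> {contig_id: seq} or
    bin_id -> path-to-FASTA, or a directory of per-bin FASTA files."""
    import os

    from Bio import SeqIO

    if isinstance(source, (str, os.PathLike)) and os.path.isdir(source):
        source = {
            os.path.splitext(name)[0]: os.path.join(source, name)
            for name in sorted(os.listdir(source))
            if name.endswith((".fa", ".fasta", ".fna"))
        }
    out: dict[str, dict[str, str]] = {}
    for bin_id, val in source.items():
        if isinstance(val, dict):
            out[bin_id] = {c: s.upper() for c, s in val.items()}
        else:
            try:
                out[bin_id] = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(val, "fasta")}
            except OSError as exc:
                raise IOError(f"cannot read bin FASTA for {bin_id!r}: {exc}") from exc
    return out


def recruit(
    reads,
    bins,
    params: RecruitmentParams = RecruitmentParams(),
    sample: str = "S1",
    total_reads: int | None = None,
) -> tuple[RecruitmentProfile, list[AlignmentRecord]]:
    """Map reads to the bin set and apply the score-ratio filter and the
    best-``max_sites`` cap.

    ``total_reads`` is the normalization denominator (defaults to the number
    of input reads); the caller supplies it when abundances should be
    relative to a larger sample. Deterministic and independent of read
    order.
    """
    bin_map = load_bins(bins)
    if not bin_map:
        raise ValueError("bins must be non-empty")
    items = [(r.read_id, r.sequence) if isinstance(r, SimulatedRead) else r for r in reads]
    index = _BinIndex(bin_map)

    records: list[AlignmentRecord] = []
    read_bins: dict[str, frozenset[str]] = {}
    for read_id, seq in sorted(items):
        seq = seq.upper()
        L = len(seq)
        max_score = L * params.match_score
        # score >= r*L implies edit distance <= L(1-r)/2 under +1/-1/-1
        k_limit = int(np.ceil(L * (1 - params.min_score_ratio) / 2)) + 2
        sites: dict[tuple[str, str, int, str], AlignmentRecord] = {}
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for ci, diag_bin in index.candidates(oriented, L):
                bin_id, contig_id, ref = index.contigs[ci]
                half = max(L // 2, 1)
                w_lo = max(diag_bin * half - L, 0)
                w_hi = min(diag_bin * half + half + 2 * L, len(ref))
                window = ref[w_lo:w_hi]
                if len(window) < _K:
                    continue
                res = edlib.align(oriented, window, mode="HW", task="path", k=k_limit)
                if res["editDistance"] < 0:
                    continue
                for loc_start, _loc_end in res["locations"]:
                    score = _score_from_cigar(res["cigar"], params)
                    ratio = score / max_score
                    if ratio < params.min_score_ratio:
                        continue
                    pos = w_lo + (loc_start or 0)
                    key = (bin_id, contig_id, pos, strand)
                    rec = AlignmentRecord(read_id, bin_id, contig_id, pos, strand, score, ratio)
                    if key not in sites or score > sites[key].score:
                        sites[key] = rec
        if not sites:
            continue
        kept = sorted(
            sites.values(), key=lambda r: (-r.score, r.bin_id, r.contig_id, r.position)
        )[: params.max_sites]
        records.extend(kept)
        read_bins[read_id] = frozenset(r.bin_id for r in kept)

    denom = total_reads if total_reads is not None else len(items)
    rows = []
    for bin_id in sorted(bin_map):
        count = sum(1 for bins_ in read_bins.values() if bin_id in bins_)
        rows.append((bin_id, count, count / denom if denom else 0.0))
    counts = pd.DataFrame(rows, columns=["bin_id", "mapped_read_count", "relative_abundance"])
    profile = RecruitmentProfile(sample=sample, counts=counts, read_bins=read_bins, total_reads=denom)
    return profile, records


def crossover_stats(
    profiles: RecruitmentProfile | list[RecruitmentProfile],
    bin_subset: set[str] | None = None,
) -> tuple[dict[str, float | None], float | None]:
    """Fraction of recruited reads retained in >= 2 bins of ``bin_subset``,
    per sample, plus the median over samples with a defined value."""
    if isinstance(profiles, RecruitmentProfile):
        profiles = [profiles]
    fractions: dict[str, float | None] = {}
    for p in profiles:
        if bin_subset is None:
            relevant = {r: b for r, b in p.read_bins.items()}
        else:
            relevant = {
                r: b & bin_subset for r, b in p.read_bins.items() if b & bin_subset
            }
        if not relevant:
            fractions[p.sample] = None
            continue
        multi = sum(1 for b in relevant.values() if len(b) >= 2)
        fractions[p.sample] = multi / len(relevant)
    defined = [f for f in fractions.values() if f is not None]
    median = float(np.median(defined)) if defined else None
    return fractions, median


def summarize_bins(
    profiles: RecruitmentProfile | list[RecruitmentProfile],
    bin_metadata: pd.DataFrame,
    group_by: str = "genus",
) -> pd.DataFrame:
    """Per-sample per-group summed relative abundances (stacked-bar table).

    ``bin_metadata`` must have a ``bin_id`` column plus the grouping column;
    bins without metadata raise an error listing the offending ids.
    """
    if isinstance(profiles, RecruitmentProfile):
        profiles = [profiles]
    meta = bin_metadata.set_index("bin_id")
    rows = []
    for p in profiles:
        missing = sorted(set(p.counts["bin_id"]) - set(meta.index))
        if missing:
            raise ValueError(f"bins without metadata: {missing}")
        joined = p.counts.join(meta[group_by], on="bin_id")
        for group, sub in joined.groupby(group_by):
            rows.append((p.sample, group, sub["relative_abundance"].sum()))
    return pd.DataFrame(rows, columns=["sample", group_by, "relative_abundance"])
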