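"""Synthetic nitrifying-community generator.

Builds genomes for the five guilds of a nitrifying biofilm — comammox
*Nitrospira*, strict nitrite-oxidizing *Nitrospira* (NOB), ammonia-oxidizing
bacteria (*Nitrosomonas*), ammonia-oxidizing archaea (*Nitrosocosmicus*) and
heterotrophs — with guild-specific gene repertoires (single-copy *rpoB*
everywhere, multi-copy *nxrB* in *Nitrospira*), then simulates shotgun reads
with known per-genome ground truth. Everything is seeded, so downstream
profiling, recruitment and genotyping can be tested against exact truth
tables without any external data.

Gene sequences are seeded-random codon encodings of per-genome mutated
copies of the packaged family seed proteins (:mod:`nitroprof.markers`), so a
profile built from a seed detects every genome's copy while genomes remain
distinguishable at the protein level. Intergenic background is i.i.d. with a
specified GC content.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import GENE_LENGTHS, marker_seed_for
from .seqs import back_translate, mutate_protein, revcomp, translate_frame

GUILDS = ("comammox", "NOB", "AOB", "AOA", "heterotroph")

_DEFAULT_GENUS = {
    "comammox": "Nitrospira",
    "NOB": "Nitrospira",
    "AOB": "Nitrosomonas",
    "AOA": "Nitrosocosmicus",
    "heterotroph": "Rhodoferax",
}

_AMO_GENES = {"amoA", "amoB", "amoC"}
_NXR_GENES = {"nxrA", "nxrB"}


@dataclass(frozen=True)
class GeneSpec:
    """One gene family carried by a genome.

    ``nucleotide_length`` is always ``3 * protein_length + 3`` (coding
    sequence plus stop codon).
    """

    gene_name: str
    copy_number: int = 1
    protein_length: int | None = None

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError(f"{self.gene_name}: copy_number must be >= 1")
        if self.protein_length is None:
            if self.gene_name not in GENE_LENGTHS and self.gene_name != "amoA":
                raise KeyError(f"unknown gene family {self.gene_name!r}")
            length = GENE_LENGTHS.get(self.gene_name, GENE_LENGTHS.get("amoA_AOB"))
            object.__setattr__(self, "protein_length", length)

    @property
    def nucleotide_length(self) -> int:
        return 3 * self.protein_length + 3


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    guild: str
    genome_length: int
    genes: tuple[GeneSpec, ...]
    gc_content: float = 0.5
    genus: str | None = None
    #: amino-acid divergence of this genome's proteins from the family seeds
    divergence: float = 0.08

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}")
        if self.genus is None:
            object.__setattr__(self, "genus", _DEFAULT_GENUS[self.guild])
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        names = {g.gene_name for g in self.genes}
        for g in self.genes:
            if g.gene_name == "rpoB" and g.copy_number != 1:
                raise ValueError("rpoB must be single-copy in every genome")
        if self.guild == "comammox":
            required = _AMO_GENES | {"hao", "nxrA", "nxrB"}
            if not required <= names:
                raise ValueError(f"comammox genome missing {sorted(required - names)}")
        elif self.guild == "NOB":
            if not _NXR_GENES <= names or names & (_AMO_GENES | {"hao"}):
                raise ValueError("NOB genomes carry nxrA/nxrB and no amo/hao genes")
        elif self.guild in ("AOB", "AOA"):
            if not names & _AMO_GENES or names & _NXR_GENES:
                raise ValueError(f"{self.guild} genomes carry amo genes and no nxr genes")
        coding = sum(g.copy_number * g.nucleotide_length for g in self.genes)
        if coding > self.genome_length:
            raise ValueError(
                f"{self.genome_id}: {coding} nt of genes exceed genome_length "
                f"{self.genome_length}"
            )


@dataclass(frozen=True)
class CommunitySpec:
    genomes: tuple[GenomeSpec, ...]
    relative_abundances: tuple[float, ...]
    read_length: int = 250
    n_reads: int = 100_000
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "genomes", tuple(self.genomes))
        object.__setattr__(self, "relative_abundances", tuple(self.relative_abundances))
        if len(self.genomes) != len(self.relative_abundances):
            raise ValueError("one relative abundance per genome required")
        if abs(sum(self.relative_abundances) - 1.0) > 1e-12:
            raise ValueError("relative abundances must sum to 1")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene copy; 0-based half-open coordinates, forward strand
    unless ``strand == '-'``."""

    gene_name: str
    family: str
    copy_index: int
    start: int
    end: int
    strand: str
    protein_id: str
    protein: str


@dataclass
class Genome:
    spec: GenomeSpec
    sequence: str
    features: list[GeneFeature]

    @property
    def genome_id(self) -> str:
        return self.spec.genome_id

    @property
    def proteome(self) -> dict[str, str]:
        return {f.protein_id: f.protein for f in self.features}

    def gene_sequence(self, feature: GeneFeature) -> str:
        sub = self.sequence[feature.start : feature.end]
        return revcomp(sub) if feature.strand == "-" else sub


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str


@dataclass
class TruthTable:
    """Ground truth of a simulated sample.

    ``reads`` has one row per read (genome of origin, start, strand, number
    of substitution errors); ``genomes`` carries per-genome truth (relative
    abundance and the length-weighted expected read fraction);
    ``copy_numbers`` is the long-format gene copy table.
    """

    reads: pd.DataFrame
    genomes: pd.DataFrame
    copy_numbers: pd.DataFrame


def _derived_seed(seed: int, tag: str) -> int:
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def build_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Materialize a :class:`GenomeSpec` into sequence + annotation + proteome.

    Each gene family gets one genome-specific protein (the family seed
    mutated at ``spec.divergence``); every copy of the gene is an independent
    synonymous codon encoding of that protein, inserted at non-overlapping
    positions on a random strand. Deterministic in ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    copies: list[tuple[GeneSpec, str, str, int]] = []  # (gene, family, protein, copy_idx)
    for gene in sorted(spec.genes, key=lambda g: g.gene_name):
        family, seed_prot = marker_seed_for(gene.gene_name, spec.guild)
        if len(seed_prot) != gene.protein_length:
            seed_prot = (seed_prot * (gene.protein_length // len(seed_prot) + 1))[
                : gene.protein_length
            ]
        protein = mutate_protein(seed_prot, spec.divergence, rng)
        for copy_idx in range(1, gene.copy_number + 1):
            copies.append((gene, family, protein, copy_idx))

    coding = sum(g.nucleotide_length for g, _, _, _ in copies)
    intergenic = spec.genome_length - coding
    if intergenic < 0:
        raise ValueError("genes do not fit in genome_length")
    order = rng.permutation(len(copies))
    gap_sizes = rng.multinomial(intergenic, np.full(len(copies) + 1, 1.0 / (len(copies) + 1)))

    p_bases = np.array(
        [(1 - spec.gc_content) / 2, spec.gc_content / 2, spec.gc_content / 2, (1 - spec.gc_content) / 2]
    )
    bases = np.array(list("ACGT"))

    def background(n: int) -> str:
        if n == 0:
            return ""
        return "".join(rng.choice(bases, size=n, p=p_bases))

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for slot, idx in enumerate(order):
        gap = background(int(gap_sizes[slot]))
        parts.append(gap)
        pos += len(gap)
        gene, family, protein, copy_idx = copies[idx]
        nt = back_translate(protein, rng)
        strand = "-" if rng.random() < 0.5 else "+"
        inserted = revcomp(nt) if strand == "-" else nt
        protein_id = f"{spec.genome_id}|{gene.gene_name}_{copy_idx}"
        features.append(
            GeneFeature(
                gene_name=gene.gene_name,
                family=family,
                copy_index=copy_idx,
                start=pos,
                end=pos + len(nt),
                strand=strand,
                protein_id=protein_id,
                protein=protein,
            )
        )
        parts.append(inserted)
        pos += len(nt)
    parts.append(background(int(gap_sizes[-1])))
    sequence = "".join(parts)
    assert len(sequence) == spec.genome_length
    features.sort(key=lambda f: f.start)
    return Genome(spec=spec, sequence=sequence, features=features)


def build_community_genomes(community: CommunitySpec) -> list[Genome]:
    """Build every genome of the community with per-genome derived seeds."""
    return [
        build_genome(spec, _derived_seed(community.seed, spec.genome_id))
        for spec in community.genomes
    ]


def simulate_reads(
    community: CommunitySpec, genomes: list[Genome] | None = None
) -> tuple[list[SimulatedRead], TruthTable]:
    """Simulate single-end shotgun reads with per-read truth labels.

    Genome of origin is drawn with probability proportional to
    ``relative_abundance x genome_length`` (shotgun reads sample DNA mass,
    not cells); start positions are uniform; strands are 50/50; substitution
    errors are i.i.d. at ``error_rate``. Fully deterministic in
    ``community.seed``.
    """
    if genomes is None:
        genomes = build_community_genomes(community)
    lengths = np.array([len(g.sequence) for g in genomes])
    if community.read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest genome")
    abund = np.asarray(community.relative_abundances, dtype=float)
    weights = abund * lengths
    weights = weights / weights.sum()

    rng = np.random.default_rng(_derived_seed(community.seed, "reads"))
    n = community.n_reads
    L = community.read_length
    origins = rng.choice(len(genomes), size=n, p=weights)
    starts = np.empty(n, dtype=np.int64)
    for gi, length in enumerate(lengths):
        mask = origins == gi
        starts[mask] = rng.integers(0, length - L + 1, size=int(mask.sum()))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    n_errors = (
        rng.binomial(L, community.error_rate, size=n)
        if community.error_rate > 0
        else np.zeros(n, dtype=int)
    )

    base_order = "ACGT"
    reads: list[SimulatedRead] = []
    rows = []
    width = len(str(n - 1))
    for i in range(n):
        g = genomes[origins[i]]
        frag = g.sequence[starts[i] : starts[i] + L]
        if strands[i] == "-":
            frag = revcomp(frag)
        k = int(n_errors[i])
        if k:
            positions = rng.choice(L, size=k, replace=False)
            chars = list(frag)
            for p in positions:
                alternatives = base_order.replace(chars[p], "") or base_order
                chars[p] = alternatives[rng.integers(len(alternatives))]
            frag = "".join(chars)
        read_id = f"read_{i:0{width}d}"
        reads.append(SimulatedRead(read_id, frag))
        rows.append((read_id, g.genome_id, int(starts[i]), strands[i], k))

    reads_df = pd.DataFrame(rows, columns=["read_id", "genome_id", "start", "strand", "n_errors"])
    genome_df = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "guild": [g.spec.guild for g in genomes],
            "genus": [g.spec.genus for g in genomes],
            "genome_length": lengths,
            "relative_abundance": abund,
            "read_weight": weights,
        }
    )
    copy_rows = [
        (g.genome_id, gene.gene_name, gene.copy_number)
        for g in genomes
        for gene in g.spec.genes
    ]
    copy_df = pd.DataFrame(copy_rows, columns=["genome_id", "gene_name", "copy_number"])
    return reads, TruthTable(reads=reads_df, genomes=genome_df, copy_numbers=copy_df)


@dataclass
class ReferenceDB:
    """Labeled protein reference set used for taxonomic classification."""

    proteins: dict[str, str]
    taxonomy: pd.DataFrame  # protein_id, gene_family, genome_id, genus, guild

    def taxon_of(self, protein_id: str, rank: str = "genus") -> str:
        row = self.taxonomy.loc[self.taxonomy.protein_id == protein_id].iloc[0]
        return row["genome_id"] if rank == "genome" else row[rank]


def build_reference_db(genomes: list[Genome]) -> ReferenceDB:
    """One protein record per gene copy per genome, with taxonomy labels."""
    if not genomes:
        raise ValueError("genomes must be non-empty")
    proteins: dict[str, str] = {}
    rows = []
    for g in genomes:
        for f in g.features:
            if f.protein_id in proteins:
                raise ValueError(f"duplicate protein id {f.protein_id!r}")
            proteins[f.protein_id] = f.protein
            rows.append((f.protein_id, f.family, g.genome_id, g.spec.genus, g.spec.guild))
    taxonomy = pd.DataFrame(
        rows, columns=["protein_id", "gene_family", "genome_id", "genus", "guild"]
    )
    return ReferenceDB(proteins=proteins, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# default community
# ---------------------------------------------------------------------------

_COMAMMOX_GENES = (
    GeneSpec("rpoB"),
    GeneSpec("amoA"),
    GeneSpec("amoB"),
    GeneSpec("amoC"),
    GeneSpec("hao"),
    GeneSpec("nxrA"),
    GeneSpec("nxrB", copy_number=2),
)


def default_genome_specs(genome_length: int = 50_000) -> list[GenomeSpec]:
    """Six-genome reference community: two comammox *Nitrospira*, one NOB
    *Nitrospira*, one AOB, one AOA, one heterotroph. *Nitrospira* genomes
    carry two *nxrB* copies; *cynS* is planted in two genomes (one comammox,
    one NOB). Equal genome lengths keep read fractions equal to cell
    abundances."""
    return [
        GenomeSpec("CMX1", "comammox", genome_length, _COMAMMOX_GENES + (GeneSpec("cynS"),)),
        GenomeSpec("CMX2", "comammox", genome_length, _COMAMMOX_GENES),
        GenomeSpec(
            "NOB1",
            "NOB",
            genome_length,
            (GeneSpec("rpoB"), GeneSpec("nxrA"), GeneSpec("nxrB", copy_number=2), GeneSpec("cynS")),
        ),
        GenomeSpec(
            "AOB1",
            "AOB",
            genome_length,
            (GeneSpec("rpoB"), GeneSpec("amoA"), GeneSpec("amoB"), GeneSpec("amoC"), GeneSpec("hao")),
        ),
        GenomeSpec(
            "AOA1",
            "AOA",
            genome_length,
            (GeneSpec("rpoB"), GeneSpec("amoA"), GeneSpec("amoB"), GeneSpec("amoC")),
        ),
        GenomeSpec("HET1", "heterotroph", genome_length, (GeneSpec("rpoB"), GeneSpec("ureC"))),
    ]


DEFAULT_ABUNDANCES = (0.25, 0.10, 0.15, 0.12, 0.08, 0.30)


def default_community(
    seed: int,
    n_reads: int = 100_000,
    read_length: int = 250,
    error_rate: float = 0.001,
) -> CommunitySpec:
    """The default simulated sample used throughout the test suite."""
    return CommunitySpec(
        genomes=tuple(default_genome_specs()),
        relative_abundances=DEFAULT_ABUNDANCES,
        read_length=read_length,
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: list[SimulatedRead], path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            attrs = f"ID={f.protein_id};gene={f.gene_name};family={f.family}"
            fh.write(
                f"{genome.genome_id}\tnitroprof\tCDS\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


def read_sequences(path) -> list[SimulatedRead]:
    """Read FASTA or FASTQ into :class:`SimulatedRead` records."""
    from Bio import SeqIO

    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    return [SimulatedRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]
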