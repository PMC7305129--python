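# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Marker profiling and single-copy normalization

Community composition is estimated directly from unassembled reads. Each
read is translated in all six frames; maximal stop-free segments of at
least 20 residues are retained as candidate ORFs. Peptides are searched
against four protein profiles — the taxonomic marker *rpoB* and the
functional markers *amoA* (separate archaeal and bacterial models, since
the two families are unrelated at the profile level; comammox *Nitrospira*
amoA belongs to the bacterial model) and *nxrB* — keeping hits at e-value
≤ 1e-3, at most one hit per (read, marker): lowest e-value, then highest
bit score, then lowest frame. Retained hits are classified by their
best-scoring reference protein (Smith–Waterman, BLOSUM62, gap 11/1,
Karlin–Altschul e-value ≤ 1e-6, λ = 0.267, K = 0.041); ties break by
highest percent identity, then lexicographic reference id; hits without a
qualifying reference are "unclassified".

Counts n[h, t] per (sample, marker h, taxon t) are normalized both to
profile length and to total length-normalized *rpoB* hits:

    A[h, t] = 100 · (n[h, t] / L_h) / (Σ_t n[rpoB, t] / L_rpoB)

The *rpoB* denominator includes *all* retained *rpoB* hits, classified or
not, so the *rpoB* rows sum to exactly 100 % by construction. Because
*rpoB* is single-copy, the expected number of reads producing a *rpoB* hit
for a genome is proportional to its cell abundance times the (shared)
detectable gene footprint — independent of genome size — so A[rpoB, t]
estimates the share of community *cells*, and a functional gene at *c*
copies per genome appears at *c*× its host's *rpoB* value. A residual bias
of order (footprint/L) mismatch between markers remains (the detectable
footprint is gene length + read length − 2·minimum-detectable overlap, and
dividing by L_h only approximately cancels it); for the packaged marker
lengths it is below 1 % of the ratio.

The profile-search engine is pluggable behind a small contract
(peptides → bit score, e-value). The default engine builds
single-sequence profile HMMs with pyhmmer (HMMER3); a self-contained PSSM
engine (ungapped log-odds placement scored against a Gumbel null fitted to
seeded random peptides) ships as an alternative. The computation of record
is the thresholding and normalization, not HMM internals. ORF calling is
plain six-frame translation with no frameshift model; that is adequate for
substitution-only reads, and is a documented divergence from error-model-
aware gene callers used on real data.

## Read recruitment to genome bins

Reads are aligned against the full bin set with a k-mer-seeded
(exact 15-mers, both strands) candidate search followed by banded
edit-distance alignment (edlib, infix mode). Alignments are scored with a
configurable scheme, by default +1 match / −1 mismatch / −1 per gap
column, and the score ratio is score / (read length × match score). Only
sites with ratio ≥ 0.908 are retained — under the default scheme that is
≈95 % identity (a 250-b read tolerates 11 substitutions, ratio 0.912, but
not 12, ratio 0.904) — and each read keeps at most its 10 best sites
(ties by lowest bin, contig, position). A read increments the count of
every bin where it retains a site (integer counting; the multi-bin reads
form the reported crossover set). Relative abundance divides mapped reads
by a caller-supplied sample total, defaulting to the number of input
reads. Seeding with k = 15 guarantees an exact seed exists whenever a
250-b read carries ≤ 12 substitutions, so the filter boundary is exact.

## Functional genotyping

Gene presence calls use reciprocal best hits between bin and reference
proteomes: local alignment with BLOSUM62, gap open 11 / extend 1, best hit
by score (equivalently lowest Karlin–Altschul e-value; ties lexicographic),
pair emitted only if mutual at e ≤ 1e-6 (the same cutoff as taxonomic
classification; reciprocal-BLAST pipelines rarely publish theirs). Percent
identity is identities over all alignment columns, gaps included, and the
repertoire matrix keeps the maximum identity across reference genomes.

Guild classification consumes presence/absence of amoA, amoB, amoC, hao,
nxrA and nxrB; the classes (complete comammox, near-comammox missing only
nxrB, candidate with ≥2 amo genes, strict NOB, none) are mutually
exclusive and exhaustive by construction. The packaged twelve-bin RBC
*Nitrospira* repertoire partitions 3 / 4 / 5 across near-comammox / NOB /
candidate.

Motif rules are anchored by semi-global alignment (free end gaps) of the
candidate to the rule's reference sequence, so insertions and terminal
padding do not shift residue coordinates; a required position that falls
in an alignment gap is reported unalignable and fails the rule. Motif
patterns (CxxC, minimum two) are counted by a non-overlapping
left-to-right scan of the candidate itself. Reference sequences for the
rules are the packaged synthetic seeds with the biologically constrained
residues pinned (cyanase Arg96/Glu99/Ser122; two CxxC sites in hyfG).

Protein clustering is greedy length-sorted centroid clustering
(UCLUST-style): sequences in decreasing length order join the first
representative with global identity (matches / columns of a minimum-edit
global alignment) at or above the threshold (default 0.99), else found a
new cluster; deterministic given the input.

Bin quality gating retains completeness ≥ 80 % and contamination
strictly < 5 % (inclusive and exclusive boundaries respectively).

## Fragment ANI

The query is cut into non-overlapping 3,000-b fragments (the convention of
fragment-based ANI estimators). Each fragment is aligned to its
best location on either strand of the reference by banded edit alignment;
fragments with identity ≥ 80 % count as aligned, ANI is their mean
identity, and the value is reported only when ≥ 20 % of fragments align.
The measure is asymmetric (query → reference); a symmetric mean is
available. Identity is matches over alignment columns, so a genome versus
itself (or its reverse complement) is exactly 100.0. Cross-tool agreement
with other fragment/k-mer ANI estimators is expected only to a few tenths
of an ANI point.

## Community summaries

Ammonia-oxidizer proportions mirror qPCR practice: AO_total =
comammox amoA + AOB amoA + AOA 16S copies; pie fractions divide by
AO_total; the percent of total community divides by bacterial 16S + AOA
16S. The archaeal 16S copies are added to the denominator because
bacterial 16S primers do not amplify archaea; no per-genome gene
copy-number correction is applied at either step. Bray–Curtis
dissimilarity is Σ|x−y| / Σ(x+y) on relative abundances; ordination is
classical scaling (double-centering + eigendecomposition), reporting the
raw eigenvalue spectrum including negative eigenvalues (no Cailliez
correction), returning coordinates on positive axes only, with each axis'
sign fixed so its first nonzero coordinate is positive. Spearman
concordance uses midranks; the two-sided p-value is exact by permutation
for n ≤ 9 and a t-approximation otherwise; constant inputs are reported
as undefined rather than NaN.

## Synthetic community generator

The generator emulates the statistical structure the analyses assume, not
biology: each gene family has a fixed synthetic seed protein; each genome
carries a genome-specific variant (8 % amino-acid divergence from the
seed by default — close enough for profile detection, divergent enough
that ~80-residue read peptides classify to the right genome); each gene
copy is an independent synonymous codon encoding placed at a random
position and strand in i.i.d. background of specified GC. Reads are
single-end, drawn from genomes proportional to abundance × length (shotgun
reads sample DNA mass), uniform starts, both strands, i.i.d. substitution
errors, constant quality; everything derives from one integer seed.

The default test community has six genomes of equal length (50 kb): two
comammox *Nitrospira* (25 %, 10 %), one NOB *Nitrospira* (15 %, like the
comammox genomes carrying two *nxrB* copies), one *Nitrosomonas* AOB
(12 %), one *Nitrosocosmicus* AOA (8 %) and one heterotroph (30 %), with
*cynS* planted in one comammox and one NOB genome. The default sample is
100,000 × 250-b reads at error rate 0.001 — sized so the full pipeline
runs in about two minutes on one CPU while leaving hundreds to thousands
of marker hits per sample for stable fractions. Equal genome lengths make
read fractions coincide with cell abundances, so both readings of "truth"
agree in tests.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: real profile HMMs trained on curated
alignments (seeds are random proteins); homology *between* gene families
(e.g. nxrB vs. narH cross-detection, a known overestimation route in real
profiles); indels and quality-dependent sequencing error; frameshifted
ORFs; strain microdiversity below the per-genome divergence scale;
compositional biases of real genomes; and real reference-database
incompleteness. Tests demonstrate the correctness of the computations
under their stated assumptions, not profiling accuracy on environmental
metagenomes.

## Numerical and interface choices

* Detection thresholds: e ≤ 1e-3 (profile search), e ≤ 1e-6 (taxonomic
  classification and BBH). One retained hit per (read, marker) prevents a
  single read from contributing multiple counts.
* Alignment ties always break deterministically (score, then identity,
  then lexicographic ids; recruitment sites by bin/contig/position), so
  all outputs are independent of input order.
* Normalization refuses samples with zero *rpoB* hits instead of emitting
  NaN; crossover fractions with no recruited reads are reported absent.
* Gene coordinates are 0-based half-open on the forward strand, reverse
  strand flagged; FASTQ is Phred-33 with constant quality.
* Derived seeds are hashed (SHA-256) from the master seed plus a role tag,
  keeping every stage independently reproducible and below 2^31.

## Known limitations

Profiling runtime is dominated by the Python-side classification
alignments (~1 minute per 100k reads); the recruitment mapper is a
reference implementation, not a competitor to production read mappers; the
Karlin–Altschul parameters are the standard gapped BLOSUM62 constants
rather than being re-estimated per scoring scheme; and the packaged
twelve-bin repertoire uses synthetic placeholder ids for the three
strict-NOB bins.
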