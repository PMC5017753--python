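# Methods

This note documents the models and algorithmic choices behind `phagebin`,
the defaults that matter, and what the bundled synthetic data can and
cannot demonstrate.

## Coordinates and alphabet

All user-facing coordinates are 1-based inclusive (EMBOSS/GFF3 convention);
internal code uses 0-based half-open slices, converted at dataclass
boundaries. On ingest sequences are uppercased and every non-ACGT letter is
collapsed to `N` (count logged). `N` never matches anything: TNF windows
containing `N` are skipped, CRISPR seeds cannot span `N`, and the aligner
scores `N` against anything (including `N`) as a mismatch.

## Tetranucleotide signatures

The binning feature is the canonical tetranucleotide frequency vector.
A tetramer and its reverse complement are the same evidence on opposite
strands, so the 256 tetramers collapse into 136 classes (16 are
reverse-complement palindromes; (256−16)/2 + 16 = 136), each named by its
lexicographically smaller member (A<C<G<T). Counting all overlapping
4-mer windows of one strand under this canonicalization makes profiles
strand-invariant by construction. Frequencies are normalized by the number
of *counted* windows, so contigs with ambiguity runs remain comparable.

Defaults: contigs are profiled only when strictly longer than 1000 nt
(short contigs give noisy signatures); reference genomes are cut into
consecutive 5000 nt fragments, keeping a final remainder when it is at
least `min_len`. Feature columns are z-standardized across all rows before
map training (standard ESOM practice; constant columns are left at zero);
this is configurable for exact-replication experiments.

## ESOM binning

A standard online self-organizing map is trained on the profile matrix:
per sample, the best-matching unit (BMU; minimal Euclidean distance, ties
row-major) is found and every node is pulled toward the sample with a
Gaussian kernel over toroidal grid distance. Learning rate decays linearly
0.5 → 0.05 and the kernel radius from max(rows, cols)/2 → 1 over 20
epochs. The grid defaults to ≈ 5·√N nodes at a ~1.6:1 aspect ratio with a
10×16 floor; topology is toroidal. Training is a pure function of
(seed, data): weight initialization and the per-epoch shuffle come from a
single seeded generator, and two runs with the same seed are bit-identical.
The mean BMU distance (quantization error) is recorded per epoch.

The U-matrix assigns each node the mean Euclidean distance of its weight
to its 8 toroidal neighbours; cluster valleys are low, boundaries high.
Cluster extraction is deliberately algorithmic rather than visual: nodes
at or below the `quantile` (default **0.4**) of all U-values are valley
nodes; 8-connected toroidal components of valley nodes are clusters,
numbered by decreasing size; every ridge node joins the cluster of its
nearest valley node by toroidal Chebyshev distance (the metric consistent
with 8-connectivity), ties to the lower cluster id. The 0.4 default was
chosen so that somewhat less than half the map counts as valley — at 0.5
adjacent basins of compositionally similar sources can bridge through the
threshold, while 0.4 keeps basins separated and proved robust across
community and training seeds on the synthetic benchmark.

A cluster is attributed to a reference genome when that genome's fragments
form a strict majority of the reference fragments in the cluster *and*
number at least `min_host_fragments` (default 5); otherwise the cluster is
reported as "no host". The hierarchical-clustering view
(`hclust_profiles`) uses scipy's agglomerative clustering (Euclidean,
average linkage by default) and exports the leaf-ordered matrix.

## CRISPR array detection

Detection is CRT-style: an exact 8-mer recurring at spacings compatible
with repeat + spacer bounds (defaults: repeat 23–55 nt, spacer 17–72 nt,
≥ 3 repeats) seeds a candidate; instances are extended column-by-column
under a majority-rule consensus with a per-instance mismatch budget
(1 interior, +2 for terminal instances). The *final* repeat boundaries,
however, are the maximal run of columns that are identical in **every**
instance, scanning outward from the seed. Rationale: boundary columns
accepted on budget can occasionally be followed by a coincidentally
conserved column, which would misplace the boundary; restricting the
reported repeat to the unanimous core makes exact repeats exactly
recoverable, at the cost that genuinely degenerate terminal columns of
real arrays are pushed into the neighbouring spacers rather than kept in
the repeat — a documented limitation. Overlapping candidates are resolved
by keeping the one with more repeats, then the longer repeat.

Spacers are emitted in array order; exact duplicates within a database
collapse to one entry with a multiplicity count. An array whose spacers
are mutually too similar (≥ 60 % of the longer spacer aligning identically
between any pair) is flagged `questionable` — an explicit, reproducible
stand-in for the manual removal of repeat-rich false positives. Arrays can
be labeled with a host by aligning the repeat consensus against known
labeled repeats (both strands; identity ≥ 0.85 covering ≥ 80 % of the
known repeat).

## Spacer–protospacer matching

Every spacer is aligned against every contig on both strands with an
affine-gap Smith–Waterman (match +1, mismatch −2, gap open −5, gap extend
−2; a length-L gap scores open + (L−1)·extend). Identity counts matched
columns over *all* alignment columns including gaps; coverage is the
aligned fraction of the spacer. Matching a spacer on the minus strand is
implemented as aligning its reverse complement on the plus strand and is
exactly symmetric.

Two retention regimes mirror the two use cases:

* **strict** (host attribution): identity ≥ 0.90 and E ≤ 1e−5. The
  literature this tool follows states the cut-off as e−5 in one place and
  e−6 in another; 1e−5 is the default and `strict_evalue` exposes both.
* **survey** (divergence scans): identity ≥ 0.70 and coverage ≥ 0.85.

E-values use the ungapped Karlin–Altschul formula `E = K·m·n·exp(−λS)`
with m the spacer length and n the total subject length searched. λ is
solved numerically from Σ pᵢpⱼ·e^(λs) = 1 under uniform base composition
(for +1/−2 this has the closed form λ = ln((3+√21)/2) ≈ 1.33271, used as
an independent regression check). K has no comparably simple closed form;
it is estimated once per scoring scheme by a deterministic Monte Carlo
Gumbel-location fit on ungapped alignments of fixed-seed random pairs and
cached. The estimate is order-of-magnitude accurate, which is sufficient
for thresholding at 1e−5: a planted exact 36-mer scores E ≈ 1e−14 on the
default community, ten orders below the cut-off, and no finite-size edge
correction is applied (documented limitation for very short queries).

One optimal alignment is reported per (spacer, contig, strand); among
equal-scoring alignments the one with the smallest subject start, then
query start, is chosen (optimal end cells enumerated subject-major, each
traced back preferring diagonal moves). Suboptimal alignment enumeration
is out of scope; downstream counts are of "contigs with at least one hit",
which this supports.

## ORF calling and domain annotation

ORFs are maximal stop-free stretches between stop codons in all six frames
— getorf's default "find 0" semantics: no ATG requirement, stretches
abutting the sequence ends included, each stretch trimmed to a codon
multiple from its downstream end, reported when ≥ `minsize` (default
300 nt). This choice is prominent because ATG-anchored calling would
change every downstream count. Translation uses the standard code;
reverse-strand coordinates map back to the forward strand via L−x+1.

Domain annotation is *ingested*, not recomputed: hmmsearch `--domtblout`
tables are parsed (per-domain independent E-value, bit score, alignment
coordinates), and each hit takes its role from the endolysin catalog —
23 catalytic cell-wall-hydrolase domains, 12 cell-wall-binding domains,
and 3 non-lysis controls (portal, virE, NinC); accessions are recorded for
the five domains whose accessions the survey fixed (PF00182, PF05838,
PF01464, PF01551, PF09374), all others match by name. Per ORF, overlapping
hits are resolved by bit score and the ordered architecture is reported,
with `canonical_endolysin` true when a catalytic domain is followed by a
binding domain. A thin wrapper can invoke an external `hmmsearch` when one
is on PATH, but no pipeline stage requires it.

## Survey statistics

* **Targeting table**: a domain instance is targeted when ≥ 1 retained
  spacer match overlaps its nucleotide interval by ≥ 1 bp (the
  coordinate-space equivalent of matching spacers against domain
  sequences). Percentages are stored at full precision and rendered to 10
  significant digits only at export.
* **Presence matrix**: per (domain, bin) hit counts coded min(count, 2) —
  absent / single / multiple — with an extra column for the sub-1 kb
  contig pool; orphan ORFs are a hard error.
* **Rarefaction**: mean ± sd of distinct annotation ids in `reps` seeded
  subsamples drawn without replacement at each depth; an explicit
  subsampling statistic replacing an external web service.
* **Read-class percentages**: full-precision 100·count/total with
  fixed-decimal rendering.
* **Spacer accounting**: per-host totals plus a floor-divide individuals
  estimate assuming ~100 unique spacers per host cell.

## Synthetic communities

`make_community` generates the study conditions used throughout the tests:
3 hosts, 60 host-derived phage contigs per host plus 20 "free" contigs
(200 viral contigs), host genomes of 60 kb, contig lengths uniform in
1200–4000 nt, 5 implanted spacers of 36 nt per host between 30 nt repeats,
substitution rate 0, seed 7.

Each host is an order-3 Markov chain whose conditionals are Dirichlet(1)
draws blended toward uniform by `1 − bias` (default bias 0.75). Order 3 is
the natural choice here because an order-3 chain determines tetranucleotide
statistics directly, so `bias` tunes exactly the separability the binner
sees. Host-derived contigs reuse their host's chain (shared signature);
all free contigs share one additional chain, emulating a coherent phage
group with no sampled host and making "expected clusters = hosts + 1"
well defined. Contig lengths (1.2–4 kb) sit in the range where TNF
signatures are informative but noisy, and 36 nt spacers with 30 nt repeats
are typical array dimensions. Protospacer sets whose first (or last) bases
are all identical are resampled: such a locus has a genuinely ambiguous
repeat boundary (the conserved column would belong to the repeat under any
detector), so exact-recovery conditions exclude it.

Everything is a pure function of the community seed (child streams are
spawned per host/stage), and the truth manifest records every phage
parentage, protospacer interval and spacer string; at mutation 0 each
spacer extracted from the manifest equals its protospacer window exactly.

What the generator does **not** emulate: sequencing error and chimeras,
assembly artifacts, uneven taxon abundance, shared ancestry between hosts,
horizontally transferred regions, real repeat degeneracy, and PAM
constraints. Passing the planted-truth suite therefore demonstrates that
the mechanisms are implemented correctly and are recoverable under clean
conditions — not that real viromes will bin at the same purity. An
optional read simulator adds MDA-style lognormal per-window depth bias
(reads ~Normal(359, 0.2·359) nt truncated at 40) for read-level tests
only; assembly is out of scope.

## Numerical and degenerate-input choices

* TNF profiles of all-N or < 4 nt sequences are explicit errors.
* SOM training on an all-equal U-matrix yields one cluster spanning the
  grid; the extraction quantile must lie strictly in (0, 1).
* BMU ties break row-major; ridge-attachment ties to the lower cluster id.
* z-standardization leaves zero-variance feature columns at zero.
* The alignment DP uses integer scores throughout; empty or zero-score
  alignments are returned as score 0 with no columns.
* Atomic file writes (temp + rename) ensure reruns are bit-identical for
  identical configs; the run manifest stores a config hash and versions,
  no timestamps.
* Problem sizes in the test and acceptance runs (200-contig communities,
  20 detector replicates, 200 alignment oracle pairs, 100 ORF oracle
  contigs) were chosen as the smallest sizes at which the statistics are
  stable.

## Known limitations

* The Karlin–Altschul K is a calibrated estimate, not the exact lattice
  constant; E-values are order-of-magnitude.
* Repeat boundary placement requires column unanimity, so degenerate
  terminal repeat columns in real arrays migrate into spacers.
* No PAM analysis, no array orientation (leader-side) inference, no
  Cas-gene detection.
* The U-matrix is computed with toroidal neighbourhoods; non-toroidal
  grids are supported in training only.
* Profile-HMM scoring itself is out of scope; domain hits arrive from
  standard hmmsearch tables.
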