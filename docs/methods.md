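# Methods

This note documents the models and procedures implemented in `ugtfam`, the
parameters that matter, the design choices made where several defensible
options existed, and what the synthetic-data generator does and does not
emulate.

## Motif model and scanning

A fuzzy motif is an ordered list of elements, each a residue class (e.g.
`[FW]`), a single residue, or the wildcard `x`, with an optional repeat range
`(m)` or `(m,n)`. The built-in PSPG consensus compiles to 27 elements with a
total width between 41 and 45 residues. The family's traditional "44-amino-
acid" description falls inside that interval, but the pattern itself does not
pin the width to 44; the package reports the computed bounds rather than
forcing the nominal figure.

Matching policy: scanning is leftmost-start; at each start the wildcard
repeats take the smallest viable assignment (greedy-minimal with
backtracking), which both fixes the per-element spans and yields the shortest
match at that start; scanning resumes after the match end, so reported
matches never overlap. This is exactly the behavior of a lazy-quantifier
regular expression under `finditer`, which is what the test suite uses as an
independent oracle. An `overlapping=True` mode enumerates the shortest match
at every start instead. The ambiguity code X is matched by wildcards only,
never by residue classes — a conservative choice so that low-quality
sequence cannot satisfy a specific residue requirement.

Family classification requires at least one match; when a protein has
several, the most C-terminal is reported as its PSPG box, reflecting the
motif's C-terminal location in this family. Conservation profiles are built
over matches of the modal width (other widths are counted and excluded,
since a position-wise logo needs fixed columns); a position is called
conserved when its modal residue reaches 95% of contributing matches.

## Distances, neighbor joining, bootstrap

Distances are counts of differing alignment columns. Columns gapped in
either member of a pair are removed for that pair (pairwise deletion);
complete deletion — dropping every column with any gap before comparing — is
available as a mode, since either convention is defensible for protein
alignments of this kind and published analyses are often ambiguous about
which was used.

Neighbor joining is the classic Saitou–Nei agglomeration on the Q criterion.
Determinism is guaranteed by (a) sorting taxa lexicographically on input,
(b) breaking Q ties by the lexicographically smallest pair of cluster keys
(a cluster's key is its alphabetically first leaf), and (c) symmetrizing the
input matrix so floating-point asymmetries cannot hide tie candidates.
Negative branch lengths — a known NJ artifact on non-additive data — are
clamped to zero, with the raw values retained in a diagnostic log. On
additive matrices the algorithm provably recovers the generating topology,
and the test suite verifies this against exhaustive least-squares topology
search up to eight taxa.

Bootstrap supports resample alignment columns with replacement; each
replicate's RNG stream derives from (seed, replicate index), so results are
independent of execution order and reproducible per replicate. Support of an
internal edge is the fraction of replicate trees containing the same leaf
bipartition. A replicate that leaves some pair with zero comparable columns
is skipped rather than crashing the run; with realistic alignments this is
vanishingly rare.

## Group assignment and duplication counting

Queries are assigned to the 16 canonical groups A–P by reference anchors:
for each query leaf, the smallest clade (either side of any edge) containing
the query and at least one anchor decides the call — if all its anchors
share one group, the query takes that group with the edge's bootstrap
support; if anchors of different groups are mixed, the query is
"unassigned". This is a clade-based rule, not nearest-neighbor distance,
matching how the groups are defined in the literature, and it depends only
on tree shape (invariant to leaf order and rooting).

Duplication counting uses species overlap: under a given rooting, an
internal node is a duplication if its two child subtrees share at least one
species. Every edge is evaluated as a root placement and the rooting with
the minimum count is reported, ties broken by a deterministic edge order.
Directed-subtree memoization makes this linear in the number of edges.

## Clusters, Ka/Ks, clock dating

A gene cluster chains family members along a chromosome by single linkage on
start coordinates with a strict `< 200 kb` window (configurable). Tandem
pairs must co-occur in a cluster and either be adjacent within it or — when
a list of non-family gene loci is supplied — have no such gene between them;
all other family pairs are segmental candidates.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions averaged
over both sequences; observed differences resolved by averaging over all
mutational pathways through the differing codon positions, excluding
pathways that pass through a stop codon (if every pathway does, all are
averaged); Jukes–Cantor correction d = −3/4 ln(1 − 4p/3), undefined
("saturated") at p ≥ 3/4. Mutations that would create a stop codon count as
nonsynonymous in site counting. Gapped or ambiguous codon pairs are dropped
before counting. The implementation is cross-checked in the tests against an
independent NG86 implementation on simulated pairs.

Note one arithmetic consequence of the saturation rule: a single codon pair
differing synonymously (TTT vs TTC) has p_s = 1/(1/3) = 3 and is therefore
saturated on its own; a defined Ks > 0 requires surrounding context. The
tests exercise both the bare and in-context cases.

Dating assumes a strict clock: T = Ks / (2λ), with λ = 9.1 × 10⁻⁹
synonymous substitutions per site per year as the default rate appropriate
for *Populus*; λ is a parameter of `ClockParams`. Identical pairs are kept
and flagged "recent" (age 0) rather than dropped. A configurable Ks ceiling
(default 3.0) leaves clearly saturated pairs undated, standing in for
database-side saturation filters that cannot be reproduced offline. When
duplicated-block assignments are available, block-mean Ks aggregation is
provided; per-pair Ks is the default because block definitions normally come
from an external synteny resource.

## Intron architecture

Intron phase is the cumulative coding length upstream of the junction modulo
3; `protein_pos` is the 0-based index of the codon containing the first
coding base after the intron (for phase 0, the codon following the
boundary) — a single stated convention, since annotation practice varies.
Splice sites are projected into alignment space by walking the gene's gapped
row. Insertion events cluster marks of identical phase whose columns lie
within a tolerance (default 0 — exact column match; ±2 available for noisy
alignments) and are numbered I-1, I-2, … left to right at the median member
column. Event calling is invariant to gene input order.

## Expression

TPM per sample: rate = count/length (length = summed CDS length, the
quantity the generator controls), scaled so each column sums to 10⁶. The
retention filter keeps genes whose mean TPM is ≥ 1 (inclusive) in both
conditions, the condition value being the mean over that condition's
replicates. Regulation is called on fold change (stress + ε)/(control + ε)
with pseudocount ε = 0.5 to guard zero denominators; fold ≥ 1.5 is "up",
≤ 1/1.5 "down", otherwise "unchanged". The 1.5 default is the conventional
fold-change cutoff for direction calls without dispersion modeling; it is
configurable, and the three-way partition is exhaustive and exclusive by
construction. No p-values are computed — the pipeline deliberately stops at
descriptive direction calls. Heatmap ordering is agglomerative clustering
with Euclidean distance and average linkage (UPGMA), with rows pre-sorted by
gene id so tie resolution, and hence leaf order, is independent of input row
order. Co-expression is thresholded |Pearson r| (default 0.9) across
samples; zero-variance genes are excluded with a log entry. Microarray-style
intensity matrices run through the same clustering path with the TPM filter
skipped, via the matrix unit tag.

## Synthetic data: what it emulates, and what it does not

The generator produces each stage's inputs with recorded ground truth, all
randomness flowing through `numpy.random.default_rng([seed, stage])` so a
(config, seed) pair determines every output byte.

- *Proteomes*: i.i.d.-uniform residue background with one pattern instance
  (drawn uniformly from the pattern's language) planted at a C-terminal-
  biased offset in a configurable fraction of proteins; negatives are
  verified motif-free by the scanner itself, so the recorded truth is exact.
  Real proteomes have residue composition bias and homologous structure that
  this background lacks; passing tests demonstrate scanner correctness, not
  real-world discovery rates.
- *Families*: a random binary topology over groups (long branches, default
  0.30 expected substitutions/site) with one anchor plus round-robin queries
  per group (short branches, 0.02). Substitution is per-site uniform
  replacement — no rate heterogeneity, no indels — so bootstrap supports on
  deep splits saturate by design.
- *Duplicate pairs*: ancestral CDS built from 4-fold degenerate codons
  (exactly one synonymous site per codon under NG86), one copy mutated at
  third positions of distinct codons until the realized synonymous
  difference count matches the Jukes–Cantor inversion of the target Ks.
  Divergence is therefore tracked exactly: Ka is 0 by construction and the
  Ks estimate is deterministic given the target, isolating estimator error
  from simulation noise.
- *Gene models*: one shared protein length, so the implied alignment is
  gap-free and column equals residue; intron plans (default 83:92:12:1:3
  genes with 0–4 introns, a 35-member phase-1 shared event at residue 160
  and a 3-member phase-0 event at residue 300) are realized through coding
  offsets and re-derived with the extraction code at generation time as a
  consistency guard.
- *Expression*: negative-binomial counts (gamma–Poisson, dispersion 0.01 —
  small enough that a planted 42-up/42-down/152-retained plan is recovered
  exactly at the default threshold; dispersion is a config field) around
  planned relative abundances. Because TPM is compositional, regulated genes
  are planned as mirrored up/down couples (up: x → 4x; down: 4x → x) so the
  two conditions carry equal total abundance and realized fold changes stay
  at the planned 4.0 rather than drifting with the normalization. Retention
  violators are exactly silent in at least one condition: with a few hundred
  genes sharing the TPM million, even one stray read exceeds the 1-TPM
  floor, as in shallow libraries. Counts are otherwise exchangeable across
  genes — no GC or length bias beyond the TPM length term.

Default scenario shape: 200 genes, 16 groups, 50 queries, 300-column
alignment, clusters of 2–15 members (one per chromosome plus distant
singletons), Ks targets {0.1, 0.5, 1.0} at 300 codons, three replicates per
condition. These sizes keep the full recovery suite fast on a laptop while
preserving the structural features — group count, cluster-size envelope,
intron-plan ratios, retained/regulated counts — of a genome-scale UGT family
survey.

## Numerical and degenerate-input choices

- Jukes–Cantor at p = 0 returns exactly 0.0 (not −0.0).
- NJ on all-equal distance matrices resolves arbitrarily but reproducibly via
  the lexicographic tie-break.
- `retention_filter` tags its output `tpm_filtered` since dropped rows break
  the 10⁶ column-sum invariant of a true TPM matrix.
- Empty inputs: empty FASTA yields an empty collection; an empty match set
  is a valid scan result; `profile_motif` and `heatmap_order` require at
  least one match / two genes and raise otherwise.
- The pipeline validates its YAML config strictly (unknown keys rejected,
  `schema_version: 1` required) and checks every enabled stage's inputs
  before running anything; a mid-run failure is recorded in the manifest
  with the failing stage.

## Known limitations

- No profile-HMM search: the consensus pattern is the identification
  instrument; HMM-based discovery would require a published training set.
- No alignment construction (alignments are consumed, not computed) and no
  ML/Bayesian tree inference.
- No genome-wide synteny block detection; segmental calls are "not tandem"
  candidates, not synteny-anchored assignments.
- Expression analysis offers no statistical testing, by design.
- The species-overlap duplication count assumes a binary tree (NJ output);
  multifurcations would need explicit resolution first.
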