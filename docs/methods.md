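# Methods

This note documents the models, conventions and numerical choices behind
`bhlhsurvey`, and what the synthetic-data generators do and do not emulate.

## Domain model and scoring profile

The bHLH domain is modelled as 55 consensus columns partitioned into four
regions: basic (columns 1–15), helix 1 (16–28), loop (29–42) and helix 2
(43–55). A position-specific scoring profile is built from a packaged seed
alignment of 12 domain sequences; the score of residue *a* at column *j* is

    S(j, a) = log2( ((c_ja + τ·b_a) / (n + τ)) / b_a )

with count `c_ja`, pseudocount τ = 1, and background frequencies `b_a`
(uniform 1/20 by default, configurable). Per-column source probabilities
sum to 1 by construction.

**Scanning** is a glocal alignment: every profile column must be consumed,
the protein's ends are free, gaps are affine. Penalties are `gap_open = 10`
and `gap_extend = 2` bits. These are deliberately large relative to the
worst conserved-column mismatch (~8 bits): cheaper gaps let the aligner
"repair" a single diverged residue at a conserved column with a
deletion/insertion pair, which corrupts the column map that the downstream
residue rules and intron projection depend on. Ties between optimal
alignments are broken toward the smallest start, then the fewest gaps, so
scans are bit-reproducible; the dynamic program is verified against
exhaustive alignment enumeration on small instances.

**Score cutoff.** `min_score = 52.9` bits. Calibrated once as the mean
planted-domain score minus three standard deviations within the
lowest-scoring binding category (atypical domains, whose stripped basic
region costs ~45 bits) of a 200-domain synthetic calibration set (seed
20200314). Pooled calibration across categories is inappropriate here
because the score distribution is bimodal by category and the pooled
mean−3σ would sit above genuine atypical domains. Random background
sequences score below 0 bits, so the margin is wide on both sides.

## DNA-binding residue grammar

Binding capacity is decided entirely from domain columns:

1. fewer than 5 basic residues (default set {R, K, H}, configurable) among
   basic-region columns mapped to actual residues → **atypical**;
2. else if every E-box site column (defaults: Glu-13, Arg-16, Arg-17)
   carries an allowed residue: all G-box site columns (His/Lys-9, Glu-13,
   Arg-17) present → **G-box**, otherwise → **E-box**;
3. else → **non-E-box**.

A column aligned to a gap never counts as an allowed residue. Whether His
belongs in the basic count is a genuine convention choice; we include it
(it is a basic amino acid) and expose the set in the packaged site
configuration. Conservation statistics use strict identity (percent =
100 × modal count / non-gap count; flags at strictly >70% and >90%);
similarity-group conservation would flag more columns but requires an
arbitrary grouping.

## Intron patterns

An intron is located by its coding offset (nucleotides of CDS preceding it
in transcription order); `phase = offset mod 3`. A phase-0 intron after
residue *r* is treated as position *r* for anchor matching — a convention
is required and this one makes phase-0 and phase-1 sites at the same codon
map to the same residue. Events inside the domain take the nearest mapped
consensus column (ties toward the smaller column).

The packaged registry holds eight signatures of 0–2 (anchor column, phase)
sites anchored at Arg-11, Phe-21, Lys-33, Leu-50, with the structural
relations validated at load time: f = a minus its first site, e = a minus
its second, c = e plus a Leu-50 site, and exactly one signature (k) has no
in-domain intron. A gene matches a signature iff its in-domain (column,
phase) multiset equals the signature's sites with each column within
±tolerance (default 2 residues — insertion positions wobble relative to the
alignment, and ±2 still separates every signature pair). Pattern j's sites
are the most variable; its tolerance is kept equal to the global default
rather than widened, so diverged j-like genes fall into "unclassified"
instead of being force-fitted. No match, or an ambiguous match (logged),
returns "unclassified".

## Phylogeny

p-distance with pairwise deletion: for each sequence pair only columns
where both carry non-gap residues are scored; a pair with zero shared
columns is an error, not a silent zero. Neighbor-joining minimises the
standard Q-criterion; ties are broken lexicographically on the index pair,
so topologies are reproducible. Negative branch lengths are clamped to 0
and logged. On additive matrices the implementation reproduces the
generating topology and path distances to 1e-9 (verified against a
brute-force least-squares topology search).

Bootstrap resamples alignment columns with replacement (default 1000
replicates as is conventional; tests and the acceptance script use 100 for
speed) and scores each internal edge by the fraction of replicate trees
containing the same bipartition; a fixed seed makes supports reproducible.

**Subfamily assignment.** The tree is unrooted, so a "clade" is realised as
either side of an internal edge. An unlabeled tip receives the label of the
smallest supported side (support ≥ `min_support`, default 0.5 — the
literature states no universal cutoff) that contains it together with
reference tips of exactly one label. Supported sides that mix labels are
surfaced as diagnostics rather than split automatically, mirroring how
surveys handle subfamilies that manual curation later subdivides. A
consequence of the two-sided realisation: with only two reference labels in
the tree, no query can be orphaned.

## Duplication origins

Collinear blocks are longest monotone chains of homolog anchor pairs per
chromosome pair (both orientations; strict monotonicity on both sides; rank
gaps ≤ `max_gap` = 5; ≥ `min_pairs` = 3 anchors; overlaps resolved greedily
by chain length, then smaller start rank). The defaults are typical
synteny-tool settings; both are configurable and echoed in reports.
Classification uses the precedence **inherited** (member of an inter-genome
block) > **segmental** (intra-genome block) > **tandem** (same-chromosome
homolog with at most `max_intervening` = 0 genes between — "fewer than one
intervening gene" read literally as adjacency; many surveys use ≤ 5, so the
parameter is exposed) > **dispersed**. The precedence order itself is a
design decision: the three positive classes are reported as disjoint in
surveys without a stated order, and genome-wide inheritance is the
strongest, least local signal.

## Expression and qPCR

- **Filtering**: a gene is kept iff its maximum FPKM across samples is
  ≥ `min_fpkm` (default 1.0, boundary inclusive). The max-across-samples
  reading keeps genes expressed only at specific stages.
- **Heat values**: log2(FPKM + 1). The +1 pseudocount keeps zeros finite
  and maps 0 → 0.
- **Blocks**: agglomerative clustering with 1 − Pearson distance and
  average linkage (the common HCL default), cut into k groups (default 7).
  Constant rows have undefined correlation; they are assigned to the
  nearest block centroid by Euclidean distance and logged. Block ids are
  renumbered in order of first appearance for determinism.
- **Tissue specificity**: per-gene z = (x − mean)/sd (sample sd, n−1);
  samples with z strictly above 3 are flagged; constant rows yield all-zero
  z and no flags.
- **Hormone response**: log2FC = log2((treated+1)/(control+1)) per
  timepoint; responsive iff max |log2FC| ≥ `fc_threshold` (default 1.0 —
  a 2-fold change; this cutoff is a package choice, exposed as a flag and
  echoed in reports) and the winning condition reaches `min_fpkm`.
  Direction follows the sign of the strongest fold change; the multi-
  hormone summary counts genes responsive to ≥ 2 hormones.
- **qPCR**: ΔCt per replicate = Ct_target − Ct_reference;
  ΔΔCt = mean ΔCt(condition) − mean ΔCt(control); RQ = 2^−ΔΔCt. Welch's
  t-test compares per-replicate ΔCt sets of condition vs control (two-
  sided; Welch–Satterthwaite df); a single replicate skips the test with a
  warning. The control's RQ is exactly 1 by construction. At three
  replicates per group — the usual technical-replicate count — the Welch
  correction is conservative: the acceptance script's 10,000-simulation
  null experiment measures a type-I rate of ≈ 0.033–0.037 at the nominal
  0.05 level (scipy's Welch implementation gives the same rate), which is a
  property of the test at tiny n, not of this implementation.

## Percentages and reports

Summary percentages are reported to one decimal, rounded half-up;
"typical" aggregates the three DNA-binding categories. One caveat: a
602-member family with 299 G-box binders gives 49.668%, which rounds
half-up to 49.7 — sources that truncate print 49.6, so this one value is
compared at one-decimal granularity in the tests.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their parameters and a seed
(byte-identical reruns). They emulate the *structure* of real survey
inputs: domains sampled column-wise from the profile with site residues
forced to one binding category; UTR-less gene models (plus and minus
strand) whose CDS splits realise a registry signature within a jitter;
hybrid + two progenitor genomes with planted collinear runs, adjacent
tandem pairs and isolated dispersed genes; FPKM matrices as block-mean ×
lognormal noise (sd 0.15 on log2) with spike genes and sub-threshold genes;
Ct tables with Gaussian cycle noise (sd 0.2).

They do **not** emulate: alignment uncertainty in real domain calls,
nested/overlapping synteny blocks or rearrangements inside blocks, UTRs
and alternative isoforms, read-level noise or FPKM estimation error,
correlated replicate structure in qPCR, or sequence evolution along the
tree (subfamily clades come from prototype + noise, not a substitution
process). Passing recovery tests therefore demonstrates correctness of the
decision rules and algorithms under clean planted signal, not robustness
to every artefact of real genome annotations.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path: 200-protein proteomes, 16 gene models (two per pattern), 6-taxon
trees with 100 bootstrap replicates, a 35-gene planted hybrid genome,
48–58-gene expression matrices over 50 samples, and 10,000 null
simulations for the Welch calibration.
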