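# Methods

This note documents the models and procedures implemented in
`gmrsd_context`, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Domain architecture

A protein's architecture is decided from its accepted domain hits.  A hit
is accepted when its E-value is **strictly below** 0.001 and its model
coverage **strictly above** 0.8 (boundary values rejected; the thresholds
are exposed as `evalue_max` / `coverage_min`).  DUF262 marks the GmrS
domain and DUF1524 the GmrD domain; both present with the DUF262 region
N-terminal of the DUF1524 region gives the double-domain class.  Repeated
hits of one domain type are merged into a union span — architecture is
treated as a set of domain types, not of hit instances.  If the two core
regions overlap, or appear in reversed order, the protein is flagged
`core_overlap` and classified by the better-scoring core hit; this keeps
the invariant that a double-domain call always has S before D.

**Single-domain pairing.**  A genome contributes a merged pair exactly when
it holds one GmrS-only and one GmrD-only protein; the merged sequence is S
followed by D.  The rule deliberately does not require the absence of
double-domain proteins in the genome — the quoted counting rule constrains
only single-domain copies — but pairs from genomes that also encode
double-domain proteins are flagged `double_present` so downstream users can
filter them.

## Alignment merging

The merge combines two alignments that both extend one fixed backbone of
double-domain sequences (one adds GmrS-only, the other GmrD-only
sequences).  Its precondition is that the backbone sub-alignments agree
column-for-column after removing columns that are gap in every backbone
row; this is exactly the situation produced by profile-addition alignment
(each added set only inserts all-backbone-gap columns).  At each backbone
junction the merged alignment opens a gap stretch of width
`max(overflow_A, overflow_B)` — the maximal overflow demanded by either
side's added sequences — applied identically to every backbone row, and
the two sides' insert columns are overlaid left-aligned.  This is the
minimal padding satisfying the construction; homology between insert
columns of the two sides is not asserted (insert states are unalignable by
construction).  Postconditions checked by tests: restricting the merge to
backbone ids and deleting all-gap columns reproduces the input backbone
alignment exactly, and no row's ungapped sequence is altered.

## Conservation and motifs

Column conservation is the frequency of the modal non-gap residue **over
all sequences** (gapped rows count in the denominator: a gap is a
non-match).  The `+` mark requires frequency strictly greater than the
threshold (default 0.95), so 19/20 = 0.95 is *not* marked.  Ties on the
modal residue break alphabetically for determinism.  Comparison is
case-insensitive; the unknown residue `X` never matches any motif element,
including the wildcard — an unknown residue is never evidence.

Motifs use the field's compact notation (fixed letters, `(A/B)`
alternatives, lowercase `x` wildcard).  Scanning is exhaustive over all
(possibly overlapping) start positions.  The weakly conserved 21-element W
motif is scanned by the same engine with no special-casing.  The
consensus-based alignment scan reports column windows where every pattern
element is satisfied by the column's modal residue at frequency at least
`min_column_freq`.

## Neighborhood enrichment

The genomic neighborhood of a focal gene is the k ORFs upstream plus k
downstream on the same contig (default k = 10; truncated at contig edges,
no wrap-around by default).  The focal protein is excluded from its own
window, but a focal gene lying inside another focal's window counts as a
neighbor — which is how family self-clustering (DUF262 near GmrSD genes)
remains observable.  Hits are reduced per protein to top-scoring
non-overlapping matches by a greedy pass in ascending E-value order
(threshold 1e-3, configurable; ties broken by envelope start then domain id
for determinism).

Counts are **domain instances**, not proteins: x₁/n₁ over the de-duplicated
neighborhood protein set (a protein shared by overlapping windows counts
once; per-window counting is available), x₂/n₂ over all proteins of the
focal-carrying genomes (neighborhood included, as with whole-proteome
backgrounds; exclusion is available).  Each of the M observed domains gets
a two-proportion confidence interval at the Bonferroni-adjusted individual
level 1 − α/M; a domain is enriched iff its interval lies entirely above
zero.  Results are emitted most-enriched-first; the `rank` field numbers
them 1..M in that order by default (`descending`), or in the literal
smallest-lower-bound-first numbering under `ascending`.

**The interval.**  The CI is the classical continuity-corrected interval of
the two-sample equal-proportions test:
`diff ± (z·se + CC)` with `CC = min(½(1/n₁+1/n₂), |diff|)`, clamped to
[−1, 1]; `correct=False` gives the plain Wald interval.  The correction
makes the interval conservative: at p₁ = p₂ = 0.1 with n₁ = n₂ = 500 the
exact coverage of the nominal-95 % corrected interval (computed by summing
the binomial lattice) is 0.9608, while the plain interval's is 0.9495.
Calibration statements at the nominal level therefore refer to the plain
interval; the corrected interval is validated as conservative (coverage at
or above nominal).  With Bonferroni levels and sparse counts the corrected
interval makes the familywise enrichment call strongly conservative — on
null simulations with M = 200 domains the observed familywise error is far
below the α = 0.05 bound.

## Coevolution

Support values are parsed from Newick internal-node labels; if any value
exceeds 1, the whole tree is taken to use the percentage dialect and all
supports are divided by 100.  Splits with support strictly below the
threshold (default 0.8) are collapsed into polytomies; a split at exactly
0.8 is retained.  Splits with missing support are collapsed (conservative)
and logged.  Leaves without an assigned counterpart in the other tree are
pruned, degree-2 nodes suppressed.  Congruence is computed on the trees as
unrooted: leaves are relabeled by association pair id, non-trivial
bipartitions are collected as two-sided sets, and RF is the size of the
symmetric difference, normalized by the total number of non-trivial splits
in both trees (0 for two stars).  Polytomies are compared as observed —
resolving them would inject information the support filter deliberately
removed.

## Synthetic data: what it emulates, and what it does not

`simulate_genomes` emulates the data regime of a neighborhood survey —
on the order of 100 genomes, one focal GmrSD-like gene per genome,
near-complete ±10-ORF windows, and a domain vocabulary with uniform
background frequencies (defaults: 100 genomes × 60 ORFs, 50 domains, one
hit per protein, configurable to 0–3).  Focal genes are placed uniformly
at random with a minimum separation of 2k+1 ORFs so windows never overlap,
which keeps calibration replicates independent.  Within windows, enriched
domains have their odds multiplied before renormalization; the truth set
records exactly the domains with multiplier > 1.  Focal proteins carry a
DUF262+DUF1524 signature.  It does **not** emulate: non-uniform domain
frequencies across genomes, operonic structure, strand correlation, or
annotation noise — so passing tests demonstrate the statistics and
bookkeeping, not robustness to real-world annotation artifacts.

`simulate_family` plants the five signature motifs at fixed offsets within
an S region and a D region (each half of the minimum double-domain length;
length variation is confined to a C-terminal tail so motif columns line up
across members).  Each motif is first *realized* once — one concrete
residue per element — and then, per sequence and column, the consensus
residue is kept with probability c (the conservation level) or redrawn
uniformly from the 20-letter alphabet, giving a modal-column frequency of
c + (1−c)/20.  At c = 1 every planted motif matches its pattern exactly.
Background residues are i.i.d. uniform, which makes the random-match
expectation of a motif analytic (product of element cardinalities / 20);
real proteomes have biased composition, so real-data false-positive rates
will differ.  Domain hits are noise-free by construction.

`simulate_tree_pair` grows a random unrooted binary topology by sequential
random edge attachment, then derives the second tree by n SPR moves chosen
uniformly over valid (prune-edge, regraft-edge) pairs — the standard
discordance model; regrafting onto the original position is allowed, so a
single SPR occasionally leaves the topology unchanged.  Supports are drawn
i.i.d. from a configurable sampler (default uniform on [0, 1]), which is a
caricature of real SH-like supports (those correlate with branch length).

## Numerical and degenerate-input choices

* Residue coordinates are 1-based closed on disk (hmmscan convention) and
  0-based half-open internally.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed gives bit-identical outputs, including Newick strings.
* Empty inputs: empty hit list → OTHER architecture; empty count table →
  empty enrichment result; empty association → empty pruned trees with a
  warning; all-gap column → frequency 0, unmarked.
* The acceptance script runs the familywise-error study at 300 null
  replicates and the recovery study at 20 seeds (the test suite uses 1,000
  and 20 respectively); both sizes give standard errors comfortably inside
  the asserted bounds.

## Known limitations

* The enrichment model treats domain instances as independent draws;
  overlap between the neighborhood set and the background set (the default
  configuration) slightly biases differences toward zero, adding to the
  conservatism of the call.
* The merge requires its backbone-identity precondition; alignments whose
  shared rows were re-aligned independently (not produced by profile
  addition) are rejected rather than reconciled.
* Tanglegram output is data only (two Newick files plus a link table);
  rendering is left to dedicated viewers.
* No attempt is made to reproduce database-era survey numbers (homolog
  counts, the specific list of enriched PFAM domains); those depend on
  historical database snapshots and external search tools, and the
  package's claims are calibrated on synthetic data with planted truth.
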