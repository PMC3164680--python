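# Methods

This note records the models behind `igsfootprint`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real data.

## Spacer model and orthology

A spacer is the interval between two consecutive annotated features on a
contig, in 0-based half-open coordinates (GFF3 I/O converts to 1-based
closed).  Orientation is a function of the flanking strands only: equal
strands → tandem; (+,−) → convergent (both genes transcribe into the
spacer); (−,+) → divergent.  Overlapping genes yield zero-length records
that are flagged and excluded from analysis.

Orthologous spacers are matched by the unordered pair of flanking ortholog
ids.  This is valid only in genomes with conserved gene order; the package
targets exactly that situation.  When a gene has been deleted in one
lineage, the merged spacer there has a different flanking pair and is
matched only among the taxa that share each pair — deletions therefore
shrink the taxon set of the affected spacer rather than corrupting it.

Two delimiter conventions are supported: pseudogenes delimit spacers
(per-genome feature bookkeeping, the default for `extract_igs`) or are
merged into spacers (`spacers_ignore_pseudogenes`, the pipeline default),
since decaying pseudogenes are spacer content from the footprinting point
of view.  The analyzable set keeps alignments of ≥ 50 columns with no
zero-length member.

## Alignment

The built-in engine is a progressive aligner: global pairwise
profile–profile dynamic programming with affine gaps (match +1, mismatch
−1, gap open −4, gap extend −1), merged along the species tree (or a
merge order derived from pairwise identities when no tree is given).
Traceback ties are broken diagonal → up → left, which makes the output a
pure function of the inputs.  Coding sequences are aligned at the protein
level and back-translated, so gaps fall on codon boundaries and every
row's codons survive the round trip.

No attempt is made to match any external aligner column-for-column; all
downstream statistics are engine-agnostic, and an external engine can be
injected through `align_set(..., engine=...)`.  Aligner parameters for
spacers are a declared choice: nothing in the statistics depends on them
beyond the usual sensitivity of alignment length.  Note that mean pairwise
identity measured on alignments exceeds the site-level identity of the
underlying sequences (≈ 0.58 vs ≈ 0.52 at the default simulation depth)
because an optimizing aligner preferentially pairs matching residues; the
generator's calibration target is defined on the true site-to-site
homology, where the analytic expectation is exact.

## Conserved k-mers, blocks, and the null

A conserved k-mer is a **maximal** run of ≥ `min_k` alignment columns that
are gap-free and identical across the chosen taxon set (`min_k` = 5 for
counting spacers with conservation; coverage fractions use k ≥ 6; both are
config keys).  Only maximal runs are counted — counting sub-windows would
double-count columns and make coverage fractions meaningless.  Blocks
chain k-mers whose separation is strictly < 30 columns; an isolated k-mer
qualifies alone iff k ≥ 10.  Densities are per 100 alignment columns.

Depth partitioning (`nested_kmer_partition`) takes strictly nested taxon
sets ordered deepest-first.  Each maximal run of the shallowest set is
assigned once, to the deepest subset in which ≥ `min_k` of its columns
remain conserved.  This makes the per-depth lists disjoint and their union
equal to the shallowest scan — each conserved region is counted exactly
once, at the greatest phylogenetic depth it survives.

The null model shuffles each row's non-gap residues among that row's
non-gap positions: per-row composition and the gap architecture are
preserved *exactly* (tested as exact invariants), while positional
homology is destroyed.  A column-permutation mode (columns shuffled within
gap-pattern classes) is provided as a sensitivity check; it preserves
column-level identity and breaks only contiguity.  Replicate streams are
derived from (seed, replicate index, spacer index), so results do not
depend on iteration order.  Default 100 replicates per alignment.

## Element calls

All scans require a hit in **every** taxon at mutually overlapping
alignment columns; "perfect" means exact and at identical columns,
"near-perfect" tolerates one mismatched taxon with ≤ 1 mismatch.

- **Shine-Dalgarno**: consensus `AGGAG`, scanned 4–20 nt upstream of the
  start codon of the abutting gene (forward-strand right flank, or the
  reverse complement for a reverse-strand left flank).  The window and
  mismatch tolerance are config keys; the defaults are declared choices.
- **Terminators**: per-taxon hairpin scan — stem ≥ 4 pairs (Watson–Crick
  or G·U, ≤ 1 mismatch), loop 3–8 nt, followed within 5 nt by ≥ 3 T in a
  7-nt window; score = stem pair-weight sum (G−C 3, A−T 2, G·U 1).  Both
  strands are scanned.
- **Sigma-32**: bipartite −35/−10 scan, default `CTTGAA … CCCCAT` with a
  13–17 nt spacer and ≤ 2 total mismatches.  The consensus is data
  (a `MotifModel`, loadable from TSV), not code.
- **Known sRNAs**: a reference catalogue row matches when the spacer has
  the same flanking ortholog pair (positional orthology) *and* a local
  alignment of the reference sequence scores ≥ half its length.

Hairpin and bipartite calls are additionally required to intersect a
conserved k-mer (`restrict_to_conserved`): on ~85% A+T sequence, weak
hairpins satisfying the thresholds occur constantly by chance, and it is
the conserved-block context that carries the evidence.  Single-motif SD
calls carry their own four-taxon conservation requirement and are exempt.
Overlapping same-type calls collapse to the best-scoring one.

## Structure significance

The fold score is a consensus-weighted Nussinov maximum-pairing score
(pair weights G−C 3, A−T 2, G·U 1; minimum loop 3), averaged over the
ungapped rows and negated so lower = more structured.  It is an energy
*proxy* in arbitrary units, not kcal/mol — which is sufficient because
significance is defined entirely within the shuffle family of the same
alignment.  The alignment, trimmed to its block span, is compared with 100
composition-preserving shuffles by a one-sided *t*:
t = (mean₀ − actual) / (sd₀·√(1 + 1/R)), p from Student's t on R−1 df.
The √(1 + 1/R) term is the prediction-interval correction for comparing a
single observation against a sample mean; without it the test's type-I
error is badly inflated.  Calibration on neutral synthetic alignments
gives an empirical rejection rate statistically compatible with α = 0.05.
Degenerate compositions whose shuffles are identical to the input are
flagged untestable.  Raw p is reported and drives the significance flag;
the selection rule for which spacers get the test is a config predicate,
defaulting to "has a k-mer block and no prior element call".

## Erosion

Pseudogene calling aligns a candidate to an intact reference homolog
(start codon, terminal stop, no internal stop) and enumerates:
premature stops in reference-projected codons; frameshifts = internal gap
runs of length ≢ 0 (mod 3); truncation = undisrupted fraction < 0.8 of the
reference length.  Terminal overhangs are scored as truncation, not
frameshift.  A frameshift inside a reference mononucleotide run of ≥ 6
(configurable) is flagged homopolymeric — the dominant inactivation mode
in these genomes.

Event mapping is Sankoff dynamic programming over the state chain
intact → pseudogene → absent with unit transition costs and reversals
forbidden (intact → absent is one loss event).  Ties are resolved toward
the less derived state at internal nodes, which pushes events toward the
tips, so a disruption private to one genome lands on that genome's
terminal branch.  Polytomies are handled natively (each child branch
independently).  The mapping equals exhaustive search over all
irreversible assignments on every matrix tested (≤ 8 taxa, 500 random
cases).

Ka/Ks is the Nei–Gojobori counting method: per-codon site fractions with
stop-creating changes counted nonsynonymous, pathway averaging over
multi-hit codons (paths through stops excluded when a stop-free path
exists), Jukes–Cantor correction.  The correction's domain ends at
p = 3/4; p_s ≥ 0.749 is reported as saturated/inestimable, the condition
under which perfect k-mer conservation becomes informative.  An ML
estimator can be substituted upstream; the counting estimate is the
built-in route and agrees with an independent reference implementation on
stop-free pairs.

## Synthetic evolution

Substitutions follow HKY85 with stationary frequencies set by the G+C
target (spacers 0.15, coding 0.26) and transition/transversion ratio 2.0,
rate-normalised; branch transition matrices are exact exponentials.  The
default four-taxon tree,
`(Sg:0.75,(Ua:0.45,(Ak:0.25,Ap:0.25):0.15):0.15)`, has root-to-leaf depth
0.9 expected substitutions/site; the analytic mean pairwise neutral
identity is 0.518, i.e. the saturated regime in which footprinting is
meaningful.  The tree was fixed from the closed-form identity expectation,
not fitted to test outcomes.

Planted elements substitute at `omega_element` = 0.02 × the neutral rate
and are immune to indels; for Shine-Dalgarno elements the gap between the
motif and the spacer end is also length-shielded (its sequence stays
neutral) because ribosome geometry constrains motif-to-start spacing — a
planted "functional" SD that drifted out of the scan window would be a
contradiction in terms.  Neutral sites receive indels at 0.05 events per
substitution, deletion:insertion 3:1, geometric lengths (mean 3).  An
optional decay switch turns an element neutral below a named branch, for
testing depth-restricted conservation.

Coding sequences evolve with per-position rate multipliers
(0.05, 0.02, 5.0): positions 1–2 slow, position 3 saturating.  These
values were chosen so the resulting counting-method Ka across taxon pairs
(≈ 0.12–0.15) and frequently saturated Ks match the divergence regime of
the study system; substitutions creating internal stops are reverted.
Whole-genome assembly alternates simulated spacers and genes with shared
gene order and strands; inactivation events (homopolymeric frameshift,
premature stop, or outright loss) apply to all taxa descending from a
named branch, and all truth (element coordinates per taxon, events per
branch) is emitted alongside.

What the synthetic tests show: the scanner, null, element callers and
event mapper recover exactly what was planted, at calibrated false-positive
rates, under the composition/divergence regime the method assumes.  What
they do not show: robustness to annotation error, to ortholog
misassignment, to rearrangement (absent in the target genomes by
assumption), or to alignment failure modes beyond those the built-in
aligner produces.

## Problem sizes and determinism

Default test/acceptance problem sizes — 10–16 genes, spacers of 80–400 nt,
100 shuffle replicates, 200-alignment calibrations, 500-case mapping
oracles — were chosen as the smallest sizes at which every statistic is
comfortably away from its small-sample regime.  Every stochastic stage
consumes a generator derived from one root seed plus structural indices,
so identical configs reproduce byte-identical outputs regardless of
iteration order.

## Known limitations

- The progressive aligner is O(L²) per merge and intended for spacer- and
  gene-sized sequences, not chromosomes.
- The terminator heuristic trades specificity for transparency; outside
  conserved blocks it is deliberately not trusted.
- The Nussinov proxy ignores stacking thermodynamics; only within-family
  shuffle comparisons are meaningful, never absolute scores.
- Pseudogene mutation counts depend on the pairwise alignment; heavily
  decayed remnants (< ~40% identity) may align poorly and default to the
  truncation route.
- `match_orthologous_igs` assumes each ortholog appears at most once per
  genome (no paralogy).
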