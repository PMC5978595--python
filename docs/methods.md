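# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Sequence divergence (4DTv)

### Site rule

A third codon position enters the 4DTv computation only when (a) both
codons are complete (no `-` or `N` anywhere in either codon — ambiguous
codons are skipped whole, a conservative and easily testable rule), (b)
both codons belong to one of the eight fourfold-degenerate families of the
standard code, and (c) the first two codon nucleotides are identical across
the pair.  Requiring identical prefixes — not merely that both codons are
fourfold degenerate — guarantees that any third-position difference is
synonymous in both sequences and that the two sites share a family.  The
prefix set is derived from the standard codon table at import rather than
hard-coded.

### Correction

Raw transversion proportions are corrected as `d = -1/2·ln(1 - 2p)`.
Under a substitution process with separate transition and transversion
rates and equal base frequencies, a site whose lineage pair has accumulated
an expected `τ` transversions per site differs by a transversion with
probability `(1 - e^(-2τ))/2`; the correction inverts this, so `d`
estimates `τ` regardless of the transition rate.  This closed form is what
makes the simulator's Monte-Carlo checks exact.  `p ≥ 0.5` is saturation:
the record is flagged and `d` is NaN (no exception), because saturated
pairs are expected in deep comparisons and must not abort a scan.  A
configurable raw mode (`p` itself) is available by simply using `p_raw`.

Pairs with fewer than `min_sites = 10` qualifying sites are flagged
`low_confidence` and excluded from distribution summaries by default —
with so few sites, a single transversion moves `p` by ≥ 0.1 and the
corrected value is dominated by discretisation noise.

Known small-sample property: because `d(p)` is convex, the mean of
per-pair corrected values overestimates `τ` slightly when per-pair site
counts are small, and the KDE mode underestimates the peak position at
high divergence (the transformation stretches the upper tail, thinning its
density).  At the recent-WGD scale (τ ≈ 0.12, ≥ 80 sites/pair at 300
codons) both effects are far below the sampling noise; at γ scale
(τ ≈ 0.6) they are visible, which is why distribution peaks for deeply
diverged pairs are only meaningful on long alignments.

### Distribution peaks and timing verdicts

Corrected values are summarised by a Gaussian KDE with Silverman
bandwidth evaluated on a fixed grid `[0, 1.5]` in steps of 0.001; local
maxima with prominence above 5% of the global maximum are reported as
secondary peaks (the γ-scale peak next to a recent-WGD peak).  Inputs with
zero variance return the common value directly (a KDE is singular there).
The duplication-vs-speciation verdict compares the paralog peak with each
ortholog peak using the larger of the two KDE bandwidths as the
simultaneity tolerance: two peaks closer than the bandwidth cannot be
resolved by the estimator, so the verdict is "simultaneous" rather than an
over-claimed ordering.

## Synthetic CDS families

Families evolve on a user-supplied rooted species tree whose newick branch
lengths are the *transversion* component (expected transversions per site);
the transition component is `ts_tv_ratio` (default 2.0, a typical coding
transition:transversion ratio) times that.  Root sequences are drawn
codon-by-codon uniformly from the 61 sense codons; all positions evolve by
the two-parameter process, vectorised per branch; mutations creating a stop
codon are rejected and the codon re-evolved from its parent, keeping
sequences coding without materially biasing 4D sites at the simulated
divergences.  Indels are not simulated, so pairs are aligned by
construction — the generator tests the divergence estimator, not an
aligner.

The WGD is planted at the *top* of the chosen branch: for a
Bernoulli(`retention`) subset of families both copies traverse the full
branch and its subtree.  The truth sidecar records, per family, the gene
tree (newick, `SPECIES__family_copy` leaves), the exact path transversion
distance for every leaf pair, and each pair's paralog/ortholog class from
the true tree.

Not emulated: rate variation across sites and lineages, codon-usage and
base-composition bias, gene conversion between WGD copies, and
post-duplication loss along the subtree (retention is all-or-nothing per
family).  Passing tests therefore show estimator correctness under the
model the correction assumes, not robustness to alignment error or rate
heterogeneity in real data.

## k-mer histograms and genome size

The generator places `genome_size` distinct k-mers on a discretised normal
around `peak_depth` with standard deviation `dispersion·√peak_depth`
(dispersion 1 ≈ Poisson width; default 0.5 models a tight single-copy
peak), sampled as one multinomial draw so the total genomic mass is
conserved.  Error k-mers are confined to depths 1–3 with counts decaying
10× per depth unit and contribute `error_mass_fraction` (default 0.05) of
total mass — confining them guarantees a detectable valley, which is what
the estimator's truncation step requires.  Not emulated: heterozygosity
shoulders, repeat-induced high-depth tails, GC-dependent coverage.

The estimator discards everything at or below the first local minimum of
the 3-bin moving-average smoothed counts (window 3 is the minimal smoothing
that kills single-bin jitter), takes `D` as the smoothed argmax beyond the
valley (ties: larger raw count, then smaller depth), and reports
`Σ d·k_d / D` over post-valley depths; the discarded error mass is also
excluded from the numerator, consistent with treating it as non-genomic
(a `full_sum` flag restores the complete numerator for comparison).
Failure modes raise with advice to pass `peak_depth` manually: no valley
(monotone decreasing counts), modal depth directly adjacent to the valley,
or raw counts still rising at the largest depth (truncated peak).
Reading `D` as the modal depth — not the largest observed depth — is the
only reading under which the formula returns a genome-scale number.

## Genetic maps, anchoring and pseudomolecules

The map simulator lays scaffolds end-to-end along each linkage group with
a constant 5 cM/Mb gradient, draws marker positions uniformly within each
scaffold, and plants two defect types: inverted scaffolds (default 25%,
cM decreasing with bp) and chimeric scaffolds (two segments from different
linkage groups, each segment carrying the full marker complement, junction
recorded as truth).  Maps are noiseless by default — marker order is exact
— because the downstream guarantees being tested (perfect recall,
correlation 1.0) are properties of the algorithms, not of noisy data.

Chimera detection requires `min_support = 2` markers on each of two or
more linkage groups; a single stray marker yields a warning, not a split —
automation replaces the visual inspection a human curator would apply, and
two markers are the minimum that distinguishes a misplaced marker from a
misjoined scaffold.  Breakpoints go at the midpoint between the innermost
markers of adjacent blocks: without assembly-graph evidence the midpoint
is the unbiased choice.  Splitting conserves length exactly and re-bases
marker coordinates to the second child.

Anchoring assigns each scaffold to its majority linkage group, orders by
mean cM with ties broken by descending length then lexicographic id
(a deterministic convention; the data cannot order equal-cM scaffolds),
and orients by the sign of the Spearman correlation between bp and cM.
Scaffolds with fewer than two informative markers get `?`, are emitted in
forward orientation, and keep `?` in the AGP (which expresses unknown
orientation natively).  Within-LG order discordance is reported through
the correlation table, never auto-split.  Pseudomolecules join scaffolds
with 1000-N spacers (`total = Σ lengths + (n-1)·1000`, asserted as a
layout invariant); the AGP v2.1 table (gap rows: `scaffold`/`yes`/`map`)
regenerates the FASTA byte-identically.  Coordinates are 1-based inclusive
in map tables and AGP, matching both conventions.

## Mate-pair classification

Orientation is derived from the strands of the leftmost and rightmost
reads (FR = inward/paired-end, RF = outward/pre-Nextera mate-pair,
same-strand = tandem), which makes it invariant under swapping ends.
Outer distance is the difference of leftmost coordinates; read length is
folded into the insert.  Pairs on different scaffolds or with an unmapped
end are "unresolved" and excluded from the chimera denominator — such
pairs are legitimately informative for scaffolding and cannot be
adjudicated against a draft.  The accepted window defaults to
`[0.5, 2]·nominal_insert`; a percentile window (1st–99th of same-scaffold
expected-orientation distances) can be estimated from data but should only
be trusted on libraries already known to be clean, since heavy
contamination inflates the upper percentile.  The simulator plants
chimeras as half orientation violations and half distance violations drawn
uniformly from `[2.5, 3.5]·insert_mean`, far from any sensible window, so
truth-separability holds whenever `insert_sd ≪ insert_mean`.

## Clustering, expression filter, reconciliation

All clustering thresholds are strict inequalities (`> 100 bp`, `> 97%`,
`< 1%`), so boundary hits fail and a transcript at exactly the floor is
kept; clusters are connected components of the qualifying-hit graph, which
makes the output invariant under edge order and direction.

Reconciliation is classical LCA (species-overlap) mapping of *given*
rooted gene trees — the joint estimation of gene and species trees that a
tool like Phyldog performs is replaced by this deterministic rule, because
the quantity of interest is the per-branch duplication count, not the tree
search.  Each node maps to the species-tree LCA of its leaf species
(computed by walking parent pointers from a precomputed leaf index); a
node is a duplication iff it maps where one of its children maps, and is
charged to the species-tree branch above its mapped node.  Non-binary
species-tree nodes are handled as-is (the LCA is well defined); non-binary
gene-tree roots are midpoint-rooted with a warning, since the mapping
needs a root.  Per-branch proportions count a family once per branch
regardless of duplication multiplicity — "how many families were
duplicated here", the quantity a WGD inflates — and families, not genes,
are the unit throughout.  Leaf pairs are orthologs or paralogs according
to the event at their gene-tree MRCA.

## Assembly statistics

Nx uses the cumulative-sum-reaches-x% convention (ties included), matching
common assembler reports; Lx is the 1-based rank.  GC is computed over
unambiguous bases.  Annotation summaries resolve exons to genes through
the Parent chain and count introns as per-gene `exons - 1`; genome
fractions use per-sequence interval unions so overlapping gene models are
not double-counted.  Percentages and means are reported to one decimal.

## Problem sizes and determinism

Every generator takes a mandatory seed and records it in its truth
sidecar; identical inputs and seed give byte-identical outputs.  The test
and acceptance runs use desk-scale sizes chosen to keep each statistical
check's sampling error well below its tolerance: 1000 families × 300
codons for divergence recovery, 10 000 mate pairs, 20 seeded histograms at
10⁶ k-mers (283 × 10⁶ in the acceptance script, matching the published
scale), 9 535 exhaustively enumerated gene trees (every canonical rooted
binary topology with ≤ 6 leaves over a 4-species tree) for the
reconciliation oracle, and 1000 random instances for the N50 oracle.
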