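# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and topology

Internal coordinates are 0-based half-open everywhere; on-disk tables
(feature TSVs, repeat catalogs) are 1-based inclusive. Topology is declared
per contig (default linear), never inferred. On circular contigs,
subsequence extraction wraps across the origin, and a repeat copy that
spans the origin is reported with `end > contig_length` (its folded pieces
are used for coverage accounting). GC content excludes N from the
denominator; repetitive, MTPT and coding percentages are computed on
union-merged intervals so overlapping hits are never double counted.

## Repeat discovery

Dispersed repeats are found by genome self-comparison: exact shared words of
length min(50, `min_len`) seed ungapped extensions. At `min_identity=100`
the extension is maximal-exact, and the output provably equals brute-force
all-pairs substring enumeration (the test suite checks this against an
independent O(n²) shift-comparison oracle). Below 100, extension is an
x-drop scan (match +1, mismatch −3, drop 12) trimmed back to the
best-scoring endpoints — the regime appropriate for the near-identical
repeats that dominate organelle genomes. Both strands are searched;
circular contigs are searched across the origin by doubling, with
fold-equivalent and period-length self-matches suppressed. Pairs whose
copies overlap or come within 10 bp on one contig are tandem, not
interspersed, and are discarded; symmetric duplicates and pairs contained
in longer pairs (same orientation) are collapsed.

Repeat units are the connected components of the copy graph (copies are
nodes, pairs with identity >= 95% are edges); copies whose intervals
reciprocally overlap by >= 50% of the shorter are the same node, and
boundary jitter between partner-specific maximal matches is collapsed into
one locus per unit member. Length classes are fixed at 50–99, 100–199,
200–499, 500–999 and >= 1000 bp; group comparisons of per-genome class
densities use the two-sided Wilcoxon rank-sum test (exact null for small
tie-free samples).

## Recombination read support

"Supporting read pair" is deliberately strict, because the raw notion is
underdetermined: both mates must align end-to-end (infix alignment of the
full read, edit distance <= 5% of read length, via edlib) and concordantly
(inward-facing, insert within bounds); the pair's aligned span must anchor
at least 20 bp of unique flank on *both* sides of the repeat copy
(junction-informative — pairs inside the repeat carry no conformational
signal); and its total edit distance must beat the other three conformations
by >= 2 (uniquely best). Everything else that aligns somewhere is counted
ambiguous, so classified + ambiguous equals the pairs passing the alignment
contract — an invariant the tests assert. The activity call (>= 2
alternative pairs and f >= 1%) guards against isolated chimeric library
artifacts. Wilson intervals are used because alternative counts are often
small, where Wald intervals misbehave.

The insert-size boundary (350 bp) routes long repeats to the long-read
path: single reads, 1000 bp flanks, the same informativeness and uniqueness
contract. A whole-catalog survey routes read pairs to candidate conformation
sets through a shared 21-mer index so each pair is only aligned where it can
match.

## Local alignment, MTPT, synteny

Local alignment is delegated to NCBI BLAST+ (`blastn -task blastn`,
e-value 1e-5, dust off); the operative filters are length and identity
(MTPT: >= 100 bp at >= 80%; synteny: > 250 bp at >= 80%), applied on top of
the raw hits. MTPT content is the union coverage of hits against one or
more labelled plastid references, as a percentage of mitogenome length.
Synteny blocks are resolved greedily best-score-first, with lower-scoring
hits *trimmed* at overlaps with kept blocks (dropped when the remainder is
not longer than the length floor) so that blocks never overlap on either
genome; trimming rather than discarding avoids losing long blocks to
few-bp boundary overlaps. Nonsyntenic regions (> 250 bp of the coverage
complement) are classified base-by-base with precedence repetitive →
plastid-like → other-mitochondrial-like → unclassified, which makes the
reported percentages disjoint by construction.

## Rates

Block pairs are globally aligned with unit costs (edlib), adequate for the
near-identical syntenic segments this stage sees. Alignment columns take
the highest-precedence class (exon > intron > RNA > intergenic) annotated
at that position in *either* genome; mask intervals (e.g. HGT-flagged
regions) drop columns before segmentation. ts/tv are reported as raw
proportions per ungapped aligned site — so the printed total is exactly
ts + tv — with TN93 provided separately as the model-corrected distance
(returning missing on saturation). A gap run of g <= 20 bp counts as one
indel event; longer runs are excluded from both the numerator and the site
denominator.

Exon segments get an amino-acid-guided codon alignment: the reading frame
comes from the exon feature (features are assumed to start in frame 0 on
their annotated strand), both ungapped sequences are trimmed to frame,
translated, protein-aligned (BLOSUM62) and threaded back to codons. dN/dS
is Nei–Gojobori (1986): synonymous/nonsynonymous site counts averaged over
both sequences (changes to stops counted nonsynonymous), pathway-averaged
difference counts for multi-hit codons (stop-crossing pathways excluded
when avoidable), Jukes–Cantor correction. The implementation is checked
against exhaustive pathway enumeration on every <= 2-difference sense-codon
pair and against Biopython's independent NG86 implementation.

## Mutation spectrum

Ancestral states are reconstructed marginally (not jointly) under GTR+Γ
with 4 discrete categories; marginal reconstruction matches the per-node
posterior outputs branch counting traditionally consumes. Base frequencies
are empirical; exchangeabilities (GT fixed at 1), the gamma shape and a
global branch-length scale are ML-fitted on the fixed topology with
L-BFGS-B over log-parameters; site patterns are compressed; transition
matrices come from the symmetrized eigendecomposition; zero-length branches
are floored at 1e-8. Site masks (e.g. RNA-editing positions) are applied
to the alignment before any likelihood or counting.

Branch counts compare parent/child states column-wise and collapse each
difference into its strand-symmetric type. A column is skipped on a branch
when either endpoint is a gap/ambiguity or a reconstructed endpoint has
posterior < 0.5 — this avoids counting reconstruction artifacts and makes
totals auditable. Branches with >= 20 substitutions enter the enrichment
ranking (ties broken by total count, then branch id) and the Tukey HSD
across the six types (one-way layout of per-branch proportions, studentized
range; a degenerate all-equal layout reports p = 1). No additional
multiple-testing correction is layered on top of HSD.

## Synthetic data

The generator emulates the statistical structure each stage assumes, not
sequencing physics. Genomes are i.i.d. draws at a target GC with planted
elements (repeat pairs of configured length/identity/orientation, an MTPT
copied verbatim from a generated plastid donor, two-exon genes with
stop-free frames) laid out on evenly spaced slots with random jitter; the
margin around each element (insert mean + 4 SD) keeps every recombination
junction window disjoint and probe-able. Reads are 150 bp pairs with
normal insert (350 ± 35 by default, matching a standard short-insert
shotgun library), uniform circular-aware fragment starts, uniform per-base
substitution errors, and truth tags naming each fragment's source
conformation; fragments falling inside a recombining repeat's junction
window are drawn from the alternative conformation with the configured
probability. Not emulated: quality-score profiles, GC-coverage bias,
indel sequencing errors, chimeric library artifacts — so passing tests
demonstrate estimator correctness under the stated model, not robustness
to every real-library pathology.

Sequence evolution draws Poisson(t·L) substitution events per branch and
samples each event's collapsed type directly from the configured flow
distribution, applying it to a uniformly chosen eligible site. A 4×4 rate
matrix parameterized by the six flows was considered and rejected: a
matrix's realized flows match its parameters only at its own stationary
composition, whereas direct event sampling makes the simulated spectrum
equal the configured one in expectation at any GC. Indels are realized as
deletions only (1–20 bp gap runs, inherited by descendants); insertions
would require threading a growing alignment through every branch for no
additional test power.

## Problem sizes and determinism

The recovery checks run at desk scale: 25–50 random genomes of 6–20 kb for
the repeat oracle, 25–50 replicates per mixture fraction at 60x coverage
over a single-repeat locus, a 50 kb / 20-pair genome for the activity
survey, and a 50 kb five-taxon alignment (total tree length 0.05) for the
spectrum. At these sizes the binomial/Poisson sampling error is comfortably
inside the stated tolerances (±0.02 on mixture fractions, ±0.03 on type
proportions, ±0.005 on TN93 at d = 0.05). Every random draw flows from an
explicit integer seed; identical configurations produce byte-identical
artifacts, which the CLI verifies with SHA-256 digests in its run manifest.

## Known limitations

- Exon frames are taken from the feature start (phase 0 assumed); partial
  exons entering a block mid-codon are trimmed to frame rather than
  phase-corrected, and segments with unresolvable frames (internal stops)
  are excluded from the codon set.
- The repeat finder's sub-identity mode reports maximal x-drop runs, which
  can differ by a few bp from an optimal-alignment definition of repeat
  boundaries; at 100% identity the output is exactly the maximal-match set.
- Synteny block trimming resolves query and subject overlaps independently,
  so a trimmed block's two spans may differ slightly in length; coverage
  totals use the query span.
- The classifier treats the four conformations of one repeat pair in
  isolation; reads from elsewhere in the genome that happen to align are
  absorbed by the uniqueness margin and the ambiguous bucket rather than
  modelled explicitly.
- NG86 assumes equal mutability when counting sites, so under
  transition-biased mutation neutral sequence yields omega < 1; this is a
  property of the estimator, preserved deliberately.
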