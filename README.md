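# mitodyn

Comparative dynamics of plant mitochondrial genomes, as a tested Python
library: interspersed-repeat discovery, quantification of repeat-mediated
recombination from short-read support, detection of plastid-derived
insertions (MTPTs), pairwise synteny and per-sequence-class substitution /
indel / dN-dS rates, and branch-wise mutation spectra on a fixed phylogeny.
A synthetic-data generator provides exact ground truth for every stage, so
the whole pipeline is verifiable by parameter recovery without any external
data.

## Who this is for

Plant organelle genomics groups comparing newly assembled mitogenomes:
angiosperm mitochondrial genomes recombine through dispersed repeats,
accumulate plastid-derived insertions, and show strongly lineage- and
type-biased substitution spectra. This package reimplements that analysis
stack as a reusable, seeded, fully testable library with a thin `mitodyn`
CLI on top.

## The statistics at the core

**Recombination frequency.** For a dispersed repeat pair with copies 1 and 2,
four references are built from the assembly: the parental conformations
R1/R2 (each copy with its own 300 bp flanks) and the alternative
conformations A1/A2 with downstream flanks exchanged (reverse-complemented
for inverted pairs). A read pair supports a conformation when both mates
align end-to-end and concordantly, anchor at least 20 bp of unique flank on
*both* sides of the repeat copy, and beat the other three references by a
margin. The recombination frequency is

    f = (nA1 + nA2) / (nR1 + nR2 + nA1 + nA2)

with a Wilson 95% interval; a pair is *active* when at least two alternative
pairs are seen and f >= 1%. Repeats longer than the library insert are
assessed with single long reads and 1000 bp flanks instead.

**Rates.** Syntenic blocks (local alignments > 250 bp at >= 80% identity)
are partitioned into exons / introns / RNA genes / intergenic by annotation
precedence. Per class: transition and transversion proportions per aligned
site (so total = ts + tv exactly), indel events (gap runs <= 20 bp), the
TN93 model-corrected distance, and for exons Nei–Gojobori (1986) dN/dS with
pathway averaging and Jukes–Cantor correction.

**Spectrum.** On a fixed rooted topology, marginal ancestral states are
reconstructed under GTR+Γ (ML parameters, two-pass pruning). Each branch's
substitutions are collapsed into six strand-symmetric types (C:G>T:A,
A:T>G:C, C:G>A:T, C:G>G:C, A:T>T:A, A:T>C:G); branches with >= 20
substitutions enter enrichment rankings and a Tukey HSD comparison of type
proportions.

## Worked example

`examples/02_recombination_frequency.py` simulates 60x paired-end coverage
over a 20 kb genome in which one 100 bp repeat pair recombines in 30% of
molecules, then recovers that fraction from read support alone:

```
repeat pair: 100 bp direct, copies at 490 and 1570
read support: R1=31 R2=24 A1=11 A2=12 ambiguous=64
recombination frequency: 0.295 (95% CI 0.205-0.404), active=True
```

R1/R2 count junction-spanning read pairs supporting the assembled
(parental) arrangements, A1/A2 those supporting the flank-swapped
(recombinant) arrangements; 0.295 recovers the planted mixture fraction
0.30 within its confidence interval. The other scripts in `examples/` walk
through repeat densities, MTPT/synteny detection, per-class rates
(`04_substitution_rates.py` prints a Table-style ts/tv/TN93/dN/dS summary)
and the branch mutation spectrum.

## Command line

```
mitodyn simulate --config sim.yaml --out dir/     # synthetic data + truth
mitodyn repeats  --genome g.fa --out repeats.tsv
mitodyn recomb   --genome g.fa --repeats r.tsv --reads-1 a.fq --reads-2 b.fq --out out.tsv
mitodyn mtpt     --mito mt.fa --plastid own=pt.fa --out mtpt.tsv
mitodyn synteny  --genome-a a.fa --genome-b b.fa --out blocks.tsv
mitodyn rates    --genome-a a.fa --genome-b b.fa --features-a a.tsv --features-b b.tsv --out rates.tsv
mitodyn spectrum --tree t.nwk --aln genes.fa --mask editing_sites.tsv --out spectrum.tsv
mitodyn full     --config sim.yaml --out run/     # chained pipeline + manifest
```

Every subcommand is a thin wrapper over a library function; `full` writes a
run manifest with SHA-256 digests of all outputs so deterministic stages can
be verified on re-run.
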