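"""Per-sequence-class substitution and dN/dS rates for a genome pair.

Evolves a sister genome from an annotated synthetic mitogenome at 0.02
substitutions/site total divergence, partitions the syntenic alignment into
exon/intron/intergenic classes and prints the Table-style rate summary.
"""

from mitodyn import genomecomp, ratecalc, synthforge
from mitodyn.core_io import GenomeRecord

cfg = synthforge.SimConfig(seed=21, genome_length=60_000, n_genes=8,
                           topology="linear")
genome, truth = synthforge.simulate_genome(cfg)
_, aln, _ = synthforge.simulate_evolution(
    "(A:0.01,B:0.01);", genome["mt1"].sequence,
    [0.4, 0.2, 0.1, 0.1, 0.1, 0.1], seed=33)

ga = {"mt1": GenomeRecord("mt1", aln["A"], "linear")}
gb = {"mtB": GenomeRecord("mtB", aln["B"], "linear")}
features_b = truth.features.assign(contig_id="mtB")

blocks = genomecomp.synteny_blocks(ga, gb).blocks
segments = ratecalc.partition_classes(blocks, ga, gb, truth.features, features_b)
rates = ratecalc.pairwise_rates(segments)

print(f"{'class':<12}{'ts':>9}{'tv':>9}{'ts+tv':>9}{'TN93':>9}"
      f"{'dN':>9}{'dS':>9}{'omega':>7}")
for cls, r in rates.items():
    dn = f"{r.dn:.4f}" if r.dn is not None else "-"
    ds = f"{r.ds:.4f}" if r.ds is not None else "-"
    om = f"{r.omega:.2f}" if r.omega is not None else "-"
    print(f"{cls:<12}{r.ts:>9.5f}{r.tv:>9.5f}{r.total:>9.5f}"
          f"{r.tn93:>9.5f}{dn:>9}{ds:>9}{om:>7}")
print("ts/tv are raw proportions per aligned site (so ts+tv is the total "
      "substitution rate); TN93 is the model-corrected distance; the planted "
      "pairwise divergence was 0.02 everywhere.")
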