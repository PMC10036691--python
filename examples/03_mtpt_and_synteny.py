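"""Detect plastid-derived insertions (MTPTs) and pairwise synteny.

Plants a 500 bp plastid fragment into a 50 kb synthetic mitogenome, detects
it against the donor plastid, then compares the genome with a rotated copy
of itself and classifies whatever falls outside the syntenic blocks.
"""

from mitodyn import genomecomp, synthforge
from mitodyn.core_io import GenomeRecord

cfg = synthforge.SimConfig(seed=19, genome_length=50_000,
                           mtpt=synthforge.MTPTPlan(length=500))
genome, truth = synthforge.simulate_genome(cfg)

mtpt = genomecomp.detect_mtpt(genome, {"own": truth.plastid})
print(f"MTPT content: {mtpt.content_percent:.2f}% of the mitogenome "
      f"({len(mtpt.hits)} hits >=100 bp at >=80% identity; planted 500 bp = 1.00%)")

seq = genome["mt1"].sequence
partner = {"rot": GenomeRecord("rot", seq[20_000:] + seq[:20_000], "circular")}
syn = genomecomp.synteny_blocks(genome, partner)
print(f"synteny vs rotated self: {syn.n_blocks} blocks totaling "
      f"{syn.total_length} bp ({100 * syn.coverage_a:.1f}% of the genome)")

# drop one block to create a nonsyntenic region, then account for it
acc = genomecomp.classify_nonsyntenic(
    genome, syn, mtpt=mtpt)
print(f"nonsyntenic sequence: {acc.total_length} bp "
      f"(a rotation is fully syntenic, so none is expected here)")
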