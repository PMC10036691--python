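"""Synthetic genomes, reads and alignments with known ground truth.

Every analysis stage in this package is verifiable by parameter recovery:
this module plants dispersed repeat pairs, plastid-derived insertions (MTPTs)
and gene features into pseudo-random genomes, draws paired-end reads from a
mixture of parental and recombinant conformations at a configured alternative
fraction, and evolves sequences along a fixed tree with configured
substitution-type flows — logging the exact truth for each.

All randomness flows from the mandatory ``seed``; identical configurations
produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import recombveri
from .core_io import GenomeRecord, extract_subsequence, make_features, reverse_complement
from .repeatscan import Copy, RepeatCatalog, RepeatPair, cluster_units
from .specmut import COLLAPSED_TYPES, TYPE_MOVES, label_internal_nodes, node_name

BASES = np.array(list("ACGT"))

_SENSE_CODONS = None  # lazily built list of non-stop codons


@dataclasses.dataclass
class RepeatPlan:
    length: int = 80
    orientation: str = "direct"       # "direct" | "inverted"
    identity: float = 100.0           # percent identity between the two copies
    alt_fraction: float = 0.0         # recombinant (alternative) molecule fraction


@dataclasses.dataclass
class MTPTPlan:
    length: int = 500                 # bp copied from the plastid donor
    donor_start: int = 0


@dataclasses.dataclass
class ReadPlan:
    read_length: int = 150
    insert_mean: int = 350            # bp, Illumina library insert
    insert_sd: int = 35
    coverage: float = 60.0
    error_rate: float = 0.001         # per-base substitution error


@dataclasses.dataclass
class SimConfig:
    seed: int
    genome_length: int = 100_000
    gc: float = 0.45
    topology: str = "circular"
    repeats: list[RepeatPlan] = dataclasses.field(default_factory=list)
    mtpt: MTPTPlan | None = None
    n_genes: int = 0                  # two-exon genes planted for rate tests
    reads: ReadPlan = dataclasses.field(default_factory=ReadPlan)


@dataclasses.dataclass
class SimTruth:
    catalog: RepeatCatalog
    alt_fractions: list[float]                 # parallel to catalog.pairs
    mtpt_intervals: list[tuple[str, int, int]]
    features: pd.DataFrame
    plastid: dict[str, GenomeRecord] | None = None


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .ratecalc import CODON_TABLE
        _SENSE_CODONS = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    return _SENSE_CODONS


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = _sense_codons()
    # avoid methionine-start pedantry; any in-frame stop-free sequence will do
    return "".join(rng.choice(codons, size=n_codons))


def _mutate_copy(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_mut = round(len(seq) * (1.0 - identity / 100.0))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def simulate_genome(config: SimConfig) -> tuple[dict[str, GenomeRecord], SimTruth]:
    """Build a genome with planted repeats, MTPT and genes, plus truth tables.

    Elements are laid out on evenly spaced slots with random jitter so that
    every planted element keeps at least ``margin`` bp of unique sequence on
    each side (margin = insert_mean + 4*insert_sd, the window within which a
    read pair can probe a recombination junction; this also keeps junction
    windows of distinct planted elements disjoint).
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    margin = config.reads.insert_mean + 4 * config.reads.insert_sd

    elements: list[tuple[str, int, object]] = []  # (kind, length, payload)
    for i, plan in enumerate(config.repeats):
        rep = _random_seq(rng, plan.length, config.gc)
        copy_b = _mutate_copy(rng, rep, plan.identity)
        if plan.orientation == "inverted":
            copy_b = reverse_complement(copy_b)
        elements.append(("repeatA", plan.length, (i, rep)))
        elements.append(("repeatB", plan.length, (i, copy_b)))

    plastid = None
    if config.mtpt is not None:
        donor = _random_seq(rng, max(20_000, config.mtpt.donor_start + config.mtpt.length),
                            config.gc - 0.07)
        plastid = {"pt1": GenomeRecord("pt1", donor, "circular")}
        insert = donor[config.mtpt.donor_start:config.mtpt.donor_start + config.mtpt.length]
        elements.append(("mtpt", config.mtpt.length, insert))

    for g in range(config.n_genes):
        exon1 = _random_cds(rng, 100)            # 300 bp
        intron = _random_seq(rng, 150, config.gc)
        exon2 = _random_cds(rng, 100)
        elements.append(("gene", 300 + 150 + 300, (g, exon1, intron, exon2)))

    slot = max((e[1] for e in elements), default=0) + 2 * margin
    if elements and slot * len(elements) > L:
        raise ValueError(
            f"infeasible plan: {len(elements)} elements need {slot * len(elements)} bp "
            f"but genome is {L} bp")

    genome_arr = np.array(list(_random_seq(rng, L, config.gc)))
    order = rng.permutation(len(elements))
    placements: list[tuple[str, int, int, object]] = []
    for rank, ei in enumerate(order):
        kind, elen, payload = elements[ei]
        base = rank * slot + margin
        jitter = int(rng.integers(0, max(1, slot - elen - 2 * margin + 1)))
        start = base + jitter
        placements.append((kind, start, start + elen, payload))

    pairs_tmp: dict[int, dict[str, tuple[int, int]]] = {}
    mtpt_intervals: list[tuple[str, int, int]] = []
    feature_rows: list[tuple] = []
    for kind, start, end, payload in placements:
        if kind in ("repeatA", "repeatB"):
            idx, seq = payload
            genome_arr[start:end] = list(seq)
            pairs_tmp.setdefault(idx, {})[kind] = (start, end)
        elif kind == "mtpt":
            genome_arr[start:end] = list(payload)
            mtpt_intervals.append(("mt1", start, end))
        elif kind == "gene":
            g, exon1, intron, exon2 = payload
            genome_arr[start:end] = list(exon1 + intron + exon2)
            gid = f"gene{g + 1}"
            feature_rows.append(("mt1", start, start + 300, "+", "exon", gid))
            feature_rows.append(("mt1", start + 300, start + 450, "+", "intron", gid))
            feature_rows.append(("mt1", start + 450, end, "+", "exon", gid))

    pairs: list[RepeatPair] = []
    alt_fractions: list[float] = []
    for idx in sorted(pairs_tmp):
        plan = config.repeats[idx]
        (a0, a1) = pairs_tmp[idx]["repeatA"]
        (b0, b1) = pairs_tmp[idx]["repeatB"]
        ca, cb = Copy("mt1", a0, a1), Copy("mt1", b0, b1)
        if (b0, b1) < (a0, a1):
            ca, cb = cb, ca
        pairs.append(RepeatPair(ca, cb, plan.orientation, plan.length, plan.identity))
        alt_fractions.append(plan.alt_fraction)
    order_idx = sorted(range(len(pairs)),
                       key=lambda i: (pairs[i].copy_a.contig, pairs[i].copy_a.start))
    pairs = [pairs[i] for i in order_idx]
    alt_fractions = [alt_fractions[i] for i in order_idx]

    genome = {"mt1": GenomeRecord("mt1", "".join(genome_arr), config.topology)}
    catalog = RepeatCatalog(pairs=pairs, units=cluster_units(pairs))
    features = make_features(feature_rows) if feature_rows else make_features([])
    truth = SimTruth(catalog=catalog, alt_fractions=alt_fractions,
                     mtpt_intervals=mtpt_intervals, features=features,
                     plastid=plastid)
    return genome, truth


# ---------------------------------------------------------------------------
# paired-end reads

@dataclasses.dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    source: str       # "parental" | "alt"
    pair_index: int   # planted repeat-pair index, -1 if none


def simulate_reads(
    genome: Mapping[str, GenomeRecord],
    truth: SimTruth,
    plan: ReadPlan,
    seed: int,
) -> list[ReadPair]:
    """Draw paired-end reads from a parental/recombinant conformation mixture.

    Fragment starts are uniform (circular-aware).  For each planted repeat
    pair with alternative fraction ``f`` > 0, fragments falling entirely
    within the junction window around either copy are drawn from the
    corresponding alternative conformation (A1 at copy A, A2 at copy B) with
    probability ``f``.  Read names carry the source truth tag.
    """
    rng = np.random.default_rng(seed)
    total = sum(rec.length for rec in genome.values())
    n_pairs = int(round(plan.coverage * total / (2 * plan.read_length)))
    frag_cap = plan.insert_mean + 4 * plan.insert_sd
    W = frag_cap  # junction window half-width beyond the repeat copy

    # per planted pair: zones and alternative templates on each copy's side
    zones = []  # (pair_idx, contig, zone_start, zone_len, parental_tpl, alt_tpl, f, conf)
    for j, (pair, f) in enumerate(zip(truth.catalog.pairs, truth.alt_fractions)):
        if f <= 0:
            continue
        conf = recombveri.build_conformations(genome, pair, flank=W)
        for copy, alt_name in ((pair.copy_a, "A1"), (pair.copy_b, "A2")):
            rec = genome[copy.contig]
            z0 = copy.start - W
            zlen = copy.length + 2 * W
            parental = extract_subsequence(rec, z0 % rec.length,
                                           (z0 + zlen) % rec.length) \
                if rec.is_circular else rec.sequence[max(z0, 0):z0 + zlen]
            alt = conf.sequences[alt_name]
            if alt_name == "A2" and pair.orientation == "inverted":
                # A2 is reported on copy A's strand; reads do not care about
                # strand, but offsets must match the genomic zone of copy B,
                # so flip it back onto copy B's genomic strand
                alt = reverse_complement(alt)
            zones.append((j, copy.contig, z0, zlen, parental, alt, f, alt_name))

    reads: list[ReadPair] = []
    contigs = list(genome.values())
    lengths = np.array([r.length for r in contigs], dtype=float)
    probs = lengths / lengths.sum()
    for i in range(n_pairs):
        rec = contigs[rng.choice(len(contigs), p=probs)]
        flen = int(np.clip(round(rng.normal(plan.insert_mean, plan.insert_sd)),
                           plan.read_length, frag_cap))
        if rec.is_circular:
            start = int(rng.integers(0, rec.length))
        else:
            start = int(rng.integers(0, max(1, rec.length - flen + 1)))
        source, pair_idx = "parental", -1
        fragment = None
        for (j, contig, z0, zlen, parental, alt, f, alt_name) in zones:
            if contig != rec.contig_id:
                continue
            off = (start - z0) % rec.length if rec.is_circular else start - z0
            if 0 <= off and off + flen <= zlen:
                if rng.random() < f:
                    fragment = alt[off:off + flen]
                    source, pair_idx = f"alt:{alt_name}", j
                else:
                    fragment = parental[off:off + flen]
                    source, pair_idx = "parental", j
                break
        if fragment is None:
            fragment = extract_subsequence(rec, start, (start + flen) % rec.length) \
                if rec.is_circular else rec.sequence[start:start + flen]
        mate1 = fragment[:plan.read_length]
        mate2 = reverse_complement(fragment)[:plan.read_length]
        if rng.random() < 0.5:
            mate1, mate2 = mate2, mate1
        mate1 = _add_errors(rng, mate1, plan.error_rate)
        mate2 = _add_errors(rng, mate2, plan.error_rate)
        name = f"frag{i}|src={source}|pair={pair_idx}"
        reads.append(ReadPair(name, mate1, mate2, source, pair_idx))
    return reads


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for p in rng.choice(len(seq), size=n_err, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def write_fastq_pairs(reads: Sequence[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{'I' * len(r.seq1)}\n")
            f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{'I' * len(r.seq2)}\n")


# ---------------------------------------------------------------------------
# sequence evolution along a fixed tree

def simulate_evolution(
    tree,
    root_sequence: str | int,
    type_proportions: Sequence[float],
    seed: int,
    deletion_rate: float = 0.0,
    gc: float = 0.45,
):
    """Evolve a root sequence along a rooted tree with configured type flows.

    ``type_proportions`` gives the six collapsed-type flows in the order of
    :data:`COLLAPSED_TYPES`; branch lengths are expected substitutions per
    site.  Substitution events are drawn per branch as Poisson(t * L) and
    each event's type follows the configured flow distribution exactly (the
    event is applied to a uniformly chosen site carrying an eligible source
    base), so the simulated genome-wide spectrum equals the configured one in
    expectation at any base composition.  Deletions (gap runs of 1–20 bp) are
    planted at ``deletion_rate`` events per site per unit branch length and
    inherited by descendants.

    Returns ``(node_sequences, leaf_alignment, truth_counts)`` where
    ``truth_counts`` is a DataFrame of per-branch logged events by type.
    """
    import dendropy

    props = np.asarray(type_proportions, dtype=float)
    if props.shape != (6,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("type_proportions must be six values summing to 1")
    rng = np.random.default_rng(seed)

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    label_internal_nodes(tree)

    if isinstance(root_sequence, int):
        root_sequence = _random_seq(rng, root_sequence, gc)
    L = len(root_sequence)

    node_seqs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    root = tree.seed_node
    node_seqs[node_name(root)] = np.array(list(root_sequence))

    cg = frozenset("CG")
    at = frozenset("AT")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root or edge.tail_node is None:
            continue
        parent = node_seqs[node_name(edge.tail_node)]
        child = parent.copy()
        t = edge.length or 0.0
        branch_counts = np.zeros(6, dtype=int)
        n_events = rng.poisson(t * L)
        for _ in range(n_events):
            ti = rng.choice(6, p=props)
            source = cg if COLLAPSED_TYPES[ti].startswith("C:G") else at
            for _try in range(10_000):
                pos = int(rng.integers(0, L))
                if child[pos] in source:
                    break
            else:
                continue  # no eligible site left
            child[pos] = TYPE_MOVES[COLLAPSED_TYPES[ti]][child[pos]]
            branch_counts[ti] += 1
        n_del = rng.poisson(deletion_rate * t * L)
        for _ in range(n_del):
            dlen = int(rng.integers(1, 21))
            pos = int(rng.integers(0, max(1, L - dlen)))
            child[pos:pos + dlen] = "-"
        name = node_name(edge.head_node)
        node_seqs[name] = child
        counts[name] = branch_counts

    leaf_aln = {node_name(leaf): "".join(node_seqs[node_name(leaf)])
                for leaf in tree.leaf_node_iter()}
    truth = pd.DataFrame(
        {name: c for name, c in counts.items()}, index=list(COLLAPSED_TYPES)).T
    truth.index.name = "branch"
    node_sequences = {name: "".join(arr) for name, arr in node_seqs.items()}
    return node_sequences, leaf_aln, truth

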