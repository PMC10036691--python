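"""Per-sequence-class substitution, indel and dN/dS rates for genome pairs.

Syntenic blocks between two annotated genomes are partitioned into four
sequence classes — exons, introns, RNA genes and intergenic — and for each
class the transition (ts) and transversion (tv) proportions, total
substitution rate (ts + tv), indel rate (gap runs <= 20 bp count as one
event each; longer runs are excluded from both numerator and denominator),
TN93 model-corrected distance, and for exons the Nei–Gojobori (NG86)
nonsynonymous/synonymous rates dN, dS and their ratio omega are computed.

ts/tv are reported as raw proportions per ungapped aligned site, so the
printed identity total = ts + tv holds exactly; TN93 is provided separately
as the model-corrected distance.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import re
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeRecord, reverse_complement

# standard genetic code (plant mitochondria use the standard code)
from Bio.Data import CodonTable as _BioCodonTable

_tbl = _BioCodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_tbl.forward_table)
CODON_TABLE.update({c: "*" for c in _tbl.stop_codons})

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
CLASS_PRECEDENCE = {"exon": 3, "intron": 2, "RNA": 1, "intergenic": 0}
_CLASS_BY_RANK = {v: k for k, v in CLASS_PRECEDENCE.items()}


# ---------------------------------------------------------------------------
# pairwise global alignment (edit-distance path; sequences here are
# near-identical syntenic segments, where unit costs are appropriate)

def global_align(a: str, b: str) -> tuple[str, str]:
    """Global (Needleman–Wunsch, unit-cost) alignment of two sequences."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    out_a, out_b = [], []
    ia = ib = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op in "=XM":
            out_a.append(a[ia:ia + n]); out_b.append(b[ib:ib + n])
            ia += n; ib += n
        elif op == "I":          # edlib: I consumes the query (a)
            out_a.append(a[ia:ia + n]); out_b.append("-" * n)
            ia += n
        elif op == "D":          # D consumes the target (b)
            out_a.append("-" * n); out_b.append(b[ib:ib + n])
            ib += n
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# class partitioning

@dataclasses.dataclass
class SequenceClassAlignment:
    """One aligned segment of a single sequence class."""

    seq_class: str                 # exon | intron | RNA | intergenic
    aligned_a: str
    aligned_b: str
    contig_a: str
    start_a: int                   # genomic start on genome A (0-based)
    end_a: int
    gene_id: str | None = None
    codon_a: str | None = None     # codon-aware alignment (exons only)
    codon_b: str | None = None


def _class_profile(genome: Mapping[str, GenomeRecord],
                   features: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-base class rank arrays (precedence exon > intron > RNA > intergenic)."""
    profile = {cid: np.zeros(rec.length, dtype=np.int8)
               for cid, rec in genome.items()}
    for row in features.itertuples():
        cls = "RNA" if row.feature_class in ("rRNA", "tRNA") else row.feature_class
        rank = CLASS_PRECEDENCE[cls]
        if row.contig_id not in profile:
            raise ValueError(f"feature on unknown contig {row.contig_id!r}")
        arr = profile[row.contig_id]
        if row.end > arr.size:
            raise ValueError("feature outside genome bounds")
        np.maximum(arr[row.start:row.end], rank, out=arr[row.start:row.end])
    return profile


def _gene_lookup(features: pd.DataFrame):
    exons = features[features["feature_class"] == "exon"]

    def lookup(contig: str, pos: int):
        for row in exons.itertuples():
            if row.contig_id == contig and row.start <= pos < row.end:
                return row
        return None

    return lookup


def partition_classes(
    blocks: pd.DataFrame,
    genome_a: Mapping[str, GenomeRecord],
    genome_b: Mapping[str, GenomeRecord],
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    exclusion_mask: Iterable[tuple[str, int, int]] = (),
) -> list[SequenceClassAlignment]:
    """Split aligned syntenic blocks into per-class aligned segments.

    Each block pair is globally aligned; every alignment column is labelled
    with the highest-precedence class annotated at its position in *either*
    genome, and maximal runs of one label become segments.  Columns falling
    in ``exclusion_mask`` intervals on genome A (e.g. HGT-flagged regions)
    are dropped before segmentation.  Exon segments additionally carry an
    amino-acid-guided codon alignment.
    """
    prof_a = _class_profile(genome_a, features_a)
    prof_b = _class_profile(genome_b, features_b)
    find_gene_a = _gene_lookup(features_a)
    mask_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in exclusion_mask:
        mask_by_contig.setdefault(contig, []).append((s, e))

    segments: list[SequenceClassAlignment] = []
    for row in blocks.itertuples():
        qc, sc = row.query_id, row.subject_id
        qs, qe = int(row.q_start), int(row.q_end)
        ss, se = int(row.s_start), int(row.s_end)
        seq_a = genome_a[qc].sequence[qs:qe]
        seq_b = genome_b[sc].sequence[ss:se]
        if row.strand == "-":
            seq_b = reverse_complement(seq_b)
        aln_a, aln_b = global_align(seq_a, seq_b)

        width = len(aln_a)
        labels = np.zeros(width, dtype=np.int8)
        keep = np.ones(width, dtype=bool)
        pos_a_col = np.full(width, -1, dtype=np.int64)
        ia, ib = 0, 0
        masked = mask_by_contig.get(qc, [])
        for col in range(width):
            ga = qs + ia if aln_a[col] != "-" else -1
            if row.strand == "-":
                gb = se - 1 - ib if aln_b[col] != "-" else -1
            else:
                gb = ss + ib if aln_b[col] != "-" else -1
            rank = 0
            if ga >= 0:
                rank = max(rank, int(prof_a[qc][ga]))
                pos_a_col[col] = ga
                if any(s <= ga < e for s, e in masked):
                    keep[col] = False
            if gb >= 0:
                rank = max(rank, int(prof_b[sc][gb]))
            labels[col] = rank
            if aln_a[col] != "-":
                ia += 1
            if aln_b[col] != "-":
                ib += 1

        # maximal runs of one label over the kept columns
        col = 0
        while col < width:
            if not keep[col]:
                col += 1
                continue
            rank = labels[col]
            run_cols = []
            while col < width and keep[col] and labels[col] == rank:
                run_cols.append(col)
                col += 1
            sub_a = "".join(aln_a[c] for c in run_cols)
            sub_b = "".join(aln_b[c] for c in run_cols)
            g_positions = [pos_a_col[c] for c in run_cols if pos_a_col[c] >= 0]
            seg = SequenceClassAlignment(
                seq_class=_CLASS_BY_RANK[int(rank)],
                aligned_a=sub_a, aligned_b=sub_b, contig_a=qc,
                start_a=min(g_positions) if g_positions else qs,
                end_a=max(g_positions) + 1 if g_positions else qs)
            if seg.seq_class == "exon":
                feat = find_gene_a(qc, seg.start_a)
                if feat is not None:
                    seg.gene_id = feat.gene_id
                    _attach_codon_alignment(seg, feat)
            segments.append(seg)
    return segments


def _attach_codon_alignment(seg: SequenceClassAlignment, exon_feat) -> None:
    """Amino-acid-guided codon alignment for an exon segment.

    The reading frame is taken from the exon feature on genome A (features
    are assumed to start in frame on their annotated strand); both ungapped
    segment sequences are trimmed to that frame, translated, the proteins
    aligned, and the alignment threaded back onto codons.
    """
    a = seg.aligned_a.replace("-", "")
    b = seg.aligned_b.replace("-", "")
    if exon_feat.strand == "-":
        offset = (exon_feat.end - (seg.end_a)) % 3
    else:
        offset = (seg.start_a - exon_feat.start) % 3
    trim = (3 - offset) % 3
    a, b = a[trim:], b[trim:]
    a = a[: len(a) - len(a) % 3]
    b = b[: len(b) - len(b) % 3]
    if len(a) < 3 or len(b) < 3:
        return
    if exon_feat.strand == "-":
        a, b = reverse_complement(a), reverse_complement(b)
    codons_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    # drop a trailing stop if the segment happens to end a CDS
    while codons_a and CODON_TABLE.get(codons_a[-1]) == "*":
        codons_a.pop()
    while codons_b and CODON_TABLE.get(codons_b[-1]) == "*":
        codons_b.pop()
    if not codons_a or not codons_b:
        return
    if any(CODON_TABLE.get(c, "X") == "*" for c in codons_a + codons_b):
        return  # internal stop: frame not recoverable for this segment
    prot_a = "".join(CODON_TABLE.get(c, "X") for c in codons_a)
    prot_b = "".join(CODON_TABLE.get(c, "X") for c in codons_b)
    pa, pb = _align_proteins(prot_a, prot_b)
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(pa, pb):
        if ca != "-" and cb != "-":
            out_a.append(codons_a[ia]); out_b.append(codons_b[ib])
            ia += 1; ib += 1
        elif ca != "-":
            ia += 1
        else:
            ib += 1
    seg.codon_a = "".join(out_a)
    seg.codon_b = "".join(out_b)


def _align_proteins(a: str, b: str) -> tuple[str, str]:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# event counting

@dataclasses.dataclass
class EventCounts:
    ts: int
    tv: int
    indels: int          # gap runs <= max_indel bp, one event each
    sites: int           # ungapped aligned ACGT columns (long-gap cols excluded)


def count_events(aligned_a: str, aligned_b: str, max_indel: int = 20) -> EventCounts:
    """Count transitions, transversions and indel events in an aligned pair.

    A contiguous gap run of length g <= ``max_indel`` counts as one indel
    event; runs with g > ``max_indel`` are excluded entirely (their columns
    do not enter the site denominator).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    ts = tv = indels = sites = 0
    i = 0
    n = len(aligned_a)
    while i < n:
        ca, cb = aligned_a[i], aligned_b[i]
        if ca == "-" or cb == "-":
            # maximal run of gap columns on one side
            gap_in_a = ca == "-"
            j = i
            while j < n and (aligned_a[j] == "-" if gap_in_a
                             else aligned_b[j] == "-"):
                if (aligned_b[j] == "-" if gap_in_a else aligned_a[j] == "-"):
                    break  # gap switches side: treat as a separate run
                j += 1
            if j == i:
                j = i + 1
            if j - i <= max_indel:
                indels += 1
            i = j
            continue
        if ca in "ACGT" and cb in "ACGT":
            sites += 1
            if ca != cb:
                if {ca, cb} <= PURINES or {ca, cb} <= PYRIMIDINES:
                    ts += 1
                else:
                    tv += 1
        i += 1
    return EventCounts(ts=ts, tv=tv, indels=indels, sites=sites)


# ---------------------------------------------------------------------------
# TN93 distance

def tn93_distance(aligned_a: str, aligned_b: str) -> float | None:
    """Tamura–Nei (1993) distance from an aligned pair, substitutions/site.

    Uses the two transition proportions (purine P1, pyrimidine P2), the
    transversion proportion Q, and empirical base frequencies averaged over
    both sequences.  Returns ``None`` when a logarithm argument is
    non-positive (saturation).
    """
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b)
             if x in "ACGT" and y in "ACGT"]
    if not pairs:
        raise ValueError("no ungapped sites")
    n = len(pairs)
    counts = {b: 0.0 for b in "ACGT"}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 0.5
        counts[y] += 0.5
        if x != y:
            st = {x, y}
            if st <= PURINES:
                p1 += 1
            elif st <= PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    freq = {b: c / n for b, c in counts.items()}
    pa, pc, pg, pt = freq["A"], freq["C"], freq["G"], freq["T"]
    pr, py = pa + pg, pc + pt
    P1, P2, Q = p1 / n, p2 / n, q / n
    if min(pa, pc, pg, pt) == 0:
        return None
    k1 = 2 * pa * pg / pr
    k2 = 2 * pt * pc / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    w1 = 1 - P1 / k1 - Q / (2 * pr)
    w2 = 1 - P2 / k2 - Q / (2 * py)
    w3 = 1 - Q / (2 * pr * py)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return None
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) dN/dS

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Changes producing stop codons count as nonsynonymous, following the
    standard NG86 convention.
    """
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All orders of the differing positions are enumerated; pathways passing
    through a stop codon are excluded (if every pathway hits a stop, all are
    used).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*":
                hit_stop = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((hit_stop, steps))
    valid = [steps for hit, steps in pathways if not hit]
    if not valid:
        valid = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in valid:
        for cur, nxt in steps:
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(valid), nd / len(valid)


@dataclasses.dataclass
class DnDsResult:
    dn: float
    ds: float
    omega: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def dnds(codon_a: str, codon_b: str) -> DnDsResult:
    """NG86 dN/dS with Jukes–Cantor correction on a codon alignment.

    Synonymous/nonsynonymous site counts are averaged over both sequences;
    multi-hit codons use pathway averaging.  ``omega`` is ``None`` when
    dS = 0.
    """
    if len(codon_a) != len(codon_b) or len(codon_a) % 3:
        raise ValueError("codon alignment length must match and divide by 3")
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i:i + 3], codon_b[i:i + 3]
        if "-" in ca or "-" in cb or set(ca + cb) - set("ACGT"):
            continue
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            raise ValueError(f"internal stop codon at position {i}")
        n_codons += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        d_s, d_n = _pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    omega = dn / ds if ds and ds > 0 else None
    return DnDsResult(dn=dn, ds=ds, omega=omega, syn_sites=s_sites,
                      nonsyn_sites=n_sites, syn_diffs=sd, nonsyn_diffs=nd)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# per-class aggregate rates

@dataclasses.dataclass
class PairwiseRates:
    seq_class: str
    ts: float                   # transitions per ungapped aligned site
    tv: float
    r: float | None             # ts/tv, None when tv = 0
    total: float                # ts + tv (exactly)
    tn93: float | None
    dn: float | None
    ds: float | None
    omega: float | None
    indel_rate: float
    sites: int


def pairwise_rates(
    segments: Sequence[SequenceClassAlignment],
) -> dict[str, PairwiseRates]:
    """Aggregate per-class rates: events summed across segments, then divided.

    dN/dS is computed on the concatenation of all exon codon alignments.
    Classes with zero aligned sites are omitted.
    """
    by_class: dict[str, list[SequenceClassAlignment]] = {}
    for seg in segments:
        by_class.setdefault(seg.seq_class, []).append(seg)
    out: dict[str, PairwiseRates] = {}
    for cls, segs in sorted(by_class.items()):
        ts = tv = indels = sites = 0
        cat_a: list[str] = []
        cat_b: list[str] = []
        for seg in segs:
            ev = count_events(seg.aligned_a, seg.aligned_b)
            ts += ev.ts; tv += ev.tv; indels += ev.indels; sites += ev.sites
            cat_a.append(seg.aligned_a)
            cat_b.append(seg.aligned_b)
        if sites == 0:
            continue
        dn = ds = omega = None
        if cls == "exon":
            codon_a = "".join(s.codon_a for s in segs if s.codon_a)
            codon_b = "".join(s.codon_b for s in segs if s.codon_b)
            if codon_a:
                res = dnds(codon_a, codon_b)
                dn, ds, omega = res.dn, res.ds, res.omega
        out[cls] = PairwiseRates(
            seq_class=cls,
            ts=ts / sites, tv=tv / sites,
            r=(ts / tv) if tv else None,
            total=(ts + tv) / sites,
            tn93=tn93_distance("".join(cat_a), "".join(cat_b)),
            dn=dn, ds=ds, omega=omega,
            indel_rate=indels / sites,
            sites=sites)
    return out


def compare_rates(rates_a: Sequence[float], rates_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided t-test between two lists of per-segment/per-gene rates."""
    res = stats.ttest_ind(list(rates_a), list(rates_b))
    return float(res.statistic), float(res.pvalue)


def rates_table(rates: Mapping[str, PairwiseRates]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in rates.values()]
    return pd.DataFrame(rows)
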