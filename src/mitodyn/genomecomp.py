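"""Pairwise genome comparison: local alignment, MTPT detection, synteny.

Local alignment is delegated to NCBI BLAST+ (``blastn -task blastn``,
``-evalue 1e-5``), the standard tool for organelle-scale homology search at
the >=80% identity regime used here; this module owns the filtering
(length/identity thresholds), overlap resolution, coverage accounting and
classification logic built on top of the raw hits.

MTPTs (mitochondrial plastid-derived sequences) are plastid-genome segments
integrated into the mitochondrial genome; they are detected as local hits of
at least 100 bp at >=80% identity against one or more plastid references.
Syntenic blocks between two mitochondrial genomes are local hits longer than
250 bp, greedily resolved so blocks do not overlap on either genome.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (GenomeRecord, coverage_length, merge_intervals,
                      write_genome)
from .repeatscan import RepeatCatalog

_OUTFMT = "6 qseqid sseqid pident length qstart qend sstart send bitscore"


@dataclasses.dataclass
class LocalHit:
    query_id: str
    subject_id: str
    q_start: int          # 0-based half-open on the query
    q_end: int
    s_start: int          # 0-based half-open on the subject (forward strand)
    s_end: int
    strand: str           # "+" | "-"
    length: int           # alignment length (with gaps)
    identity: float       # percent
    score: float

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def _require_blast() -> None:
    for tool in ("blastn", "makeblastdb"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"{tool} not found on PATH")


def local_align(
    query: Mapping[str, GenomeRecord],
    subject: Mapping[str, GenomeRecord],
    min_len: int = 100,
    min_identity: float = 80.0,
    evalue: float = 1e-5,
) -> list[LocalHit]:
    """Maximal gapped local alignments between two sequence sets.

    Both strands are searched; hits shorter than ``min_len`` or below
    ``min_identity`` percent identity are dropped; hits with an identical
    query/subject span are collapsed to the best score.
    """
    if min_identity < 50:
        raise ValueError("min_identity < 50 is not supported")
    _require_blast()
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        write_genome(query, qpath)
        write_genome(subject, spath)
        subprocess.run(
            ["makeblastdb", "-in", str(spath), "-dbtype", "nucl"],
            check=True, capture_output=True)
        proc = subprocess.run(
            ["blastn", "-task", "blastn", "-query", str(qpath), "-db", str(spath),
             "-evalue", str(evalue), "-perc_identity", str(min_identity),
             "-outfmt", _OUTFMT, "-dust", "no"],
            check=True, capture_output=True, text=True)
    hits: dict[tuple, LocalHit] = {}
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        qs, qe, ss, se = int(f[4]), int(f[5]), int(f[6]), int(f[7])
        strand = "+" if ss <= se else "-"
        if strand == "-":
            ss, se = se, ss
        hit = LocalHit(
            query_id=f[0], subject_id=f[1],
            q_start=qs - 1, q_end=qe,
            s_start=ss - 1, s_end=se,
            strand=strand, length=int(f[3]), identity=float(f[2]),
            score=float(f[8]))
        if hit.length < min_len or hit.identity < min_identity:
            continue
        key = (hit.query_id, hit.subject_id, hit.q_start, hit.q_end,
               hit.s_start, hit.s_end, hit.strand)
        if key not in hits or hit.score > hits[key].score:
            hits[key] = hit
    return sorted(hits.values(),
                  key=lambda h: (h.query_id, h.q_start, h.subject_id, h.s_start))


# ---------------------------------------------------------------------------
# MTPT detection

@dataclasses.dataclass
class MTPTResult:
    hits: pd.DataFrame          # LocalHit rows plus a donor label
    content_percent: float      # union coverage on the mitogenome


def detect_mtpt(
    mito: Mapping[str, GenomeRecord],
    plastid_refs: Mapping[str, Mapping[str, GenomeRecord]],
    min_len: int = 100,
    min_identity: float = 80.0,
) -> MTPTResult:
    """Detect plastid-derived insertions in a mitochondrial genome.

    ``plastid_refs`` maps a donor label (e.g. ``own``, ``host``,
    ``reference``) to a plastid genome; every reference is searched and its
    hits labelled.  Content is the union coverage of all hits on the
    mitogenome, as a percentage of total mitogenome length.
    """
    if not plastid_refs:
        raise ValueError("at least one plastid reference is required")
    rows = []
    for label, ref in plastid_refs.items():
        for hit in local_align(mito, ref, min_len=min_len, min_identity=min_identity):
            row = hit.as_row()
            row["donor"] = label
            rows.append(row)
    hits = pd.DataFrame(rows)
    total = sum(rec.length for rec in mito.values())
    covered = 0
    if len(hits):
        for contig, grp in hits.groupby("query_id"):
            covered += coverage_length(zip(grp["q_start"], grp["q_end"]))
    return MTPTResult(hits=hits, content_percent=100.0 * covered / total)


# ---------------------------------------------------------------------------
# synteny

@dataclasses.dataclass
class SyntenyResult:
    blocks: pd.DataFrame        # resolved blocks with block_id
    n_blocks: int
    total_length: int           # cumulative block length
    largest_block: int
    coverage_a: float           # fraction of genome A under blocks
    coverage_b: float


def synteny_blocks(
    genome_a: Mapping[str, GenomeRecord],
    genome_b: Mapping[str, GenomeRecord],
    min_len: int = 250,
    min_identity: float = 80.0,
) -> SyntenyResult:
    """Identify pairwise syntenic blocks (> ``min_len`` bp, greedy-resolved).

    Hits are resolved best-score first; lower-scoring hits are trimmed at
    any overlap with already-kept blocks (and dropped if what remains is not
    longer than ``min_len``), so resolved blocks are non-overlapping per
    genome.
    """
    hits = [h for h in local_align(genome_a, genome_b, min_len=min_len + 1,
                                   min_identity=min_identity)
            if h.length > min_len]
    hits.sort(key=lambda h: (-h.score, -h.length, h.query_id, h.q_start))
    kept: list[LocalHit] = []

    def trim(a0: int, a1: int, b0: int, b1: int) -> tuple[int, int]:
        if a1 <= b0 or b1 <= a0:
            return a0, a1                      # disjoint
        if b0 <= a0 and a1 <= b1:
            return a0, a0                      # contained: empty
        if a0 < b0 and b1 < a1:                # kept block inside: larger side
            return (a0, b0) if (b0 - a0) >= (a1 - b1) else (b1, a1)
        return (b1, a1) if b0 <= a0 else (a0, b0)

    for h in hits:
        q0, q1, s0, s1 = h.q_start, h.q_end, h.s_start, h.s_end
        for k in kept:
            if h.query_id == k.query_id:
                q0, q1 = trim(q0, q1, k.q_start, k.q_end)
            if h.subject_id == k.subject_id:
                s0, s1 = trim(s0, s1, k.s_start, k.s_end)
            if q1 - q0 <= min_len or s1 - s0 <= min_len:
                break
        if q1 - q0 > min_len and s1 - s0 > min_len:
            kept.append(dataclasses.replace(
                h, q_start=q0, q_end=q1, s_start=s0, s_end=s1,
                length=q1 - q0))
    kept.sort(key=lambda h: (h.query_id, h.q_start))
    rows = [dict(h.as_row(), block_id=i) for i, h in enumerate(kept)]
    blocks = pd.DataFrame(rows)

    len_a = sum(rec.length for rec in genome_a.values())
    len_b = sum(rec.length for rec in genome_b.values())
    cov_a = cov_b = 0
    if kept:
        for contig in {h.query_id for h in kept}:
            cov_a += coverage_length((h.q_start, h.q_end) for h in kept
                                     if h.query_id == contig)
        for contig in {h.subject_id for h in kept}:
            cov_b += coverage_length((h.s_start, h.s_end) for h in kept
                                     if h.subject_id == contig)
    total_block_len = sum(h.q_end - h.q_start for h in kept)
    return SyntenyResult(
        blocks=blocks, n_blocks=len(kept), total_length=total_block_len,
        largest_block=max((h.q_end - h.q_start for h in kept), default=0),
        coverage_a=cov_a / len_a if len_a else 0.0,
        coverage_b=cov_b / len_b if len_b else 0.0)


# ---------------------------------------------------------------------------
# nonsyntenic-region accounting

@dataclasses.dataclass
class NonsyntenicAccounting:
    total_length: int                       # bp in regions > min_region bp
    fractions: dict[str, float]             # percent of nonsyntenic length
    regions: list[tuple[str, int, int]]


def classify_nonsyntenic(
    genome_a: Mapping[str, GenomeRecord],
    synteny: SyntenyResult,
    repeat_catalog: RepeatCatalog | None = None,
    mtpt: MTPTResult | None = None,
    foreign_mito: Mapping[str, GenomeRecord] | None = None,
    min_region: int = 250,
    min_len: int = 100,
    min_identity: float = 80.0,
) -> NonsyntenicAccounting:
    """Account for genome-A sequence outside syntenic blocks.

    Regions (> ``min_region`` bp of the block-coverage complement) are
    classified base-by-base with precedence repetitive > plastid-like >
    other-mitochondrial-like > unclassified, so the category percentages are
    disjoint.  The foreign-mitochondrial category is assessed by aligning
    each region against ``foreign_mito`` when supplied.
    """
    regions: list[tuple[str, int, int]] = []
    for contig, rec in genome_a.items():
        if len(synteny.blocks):
            cov = merge_intervals(
                (int(r.q_start), int(r.q_end))
                for r in synteny.blocks.itertuples()
                if r.query_id == contig)
        else:
            cov = []
        pos = 0
        for s, e in cov + [(rec.length, rec.length)]:
            if s - pos > min_region:
                regions.append((contig, pos, s))
            pos = max(pos, e)
    total = sum(e - s for _, s, e in regions)
    if total == 0:
        return NonsyntenicAccounting(0, {}, [])

    rep_ivs: dict[str, list[tuple[int, int]]] = {}
    if repeat_catalog is not None:
        for contig, s, e in repeat_catalog.copy_intervals(genome_a):
            rep_ivs.setdefault(contig, []).append((s, e))
    pt_ivs: dict[str, list[tuple[int, int]]] = {}
    if mtpt is not None and len(mtpt.hits):
        for r in mtpt.hits.itertuples():
            pt_ivs.setdefault(r.query_id, []).append((int(r.q_start), int(r.q_end)))
    fm_ivs: dict[str, list[tuple[int, int]]] = {}
    if foreign_mito is not None:
        region_seqs = {
            f"{c}:{s}-{e}": GenomeRecord(f"{c}:{s}-{e}",
                                         genome_a[c].sequence[s:e], "linear")
            for c, s, e in regions}
        for hit in local_align(region_seqs, foreign_mito,
                               min_len=min_len, min_identity=min_identity):
            contig, span = hit.query_id.rsplit(":", 1)
            off = int(span.split("-")[0])
            fm_ivs.setdefault(contig, []).append(
                (off + hit.q_start, off + hit.q_end))

    counts = {"repetitive": 0, "plastid_like": 0,
              "other_mitochondrial_like": 0, "unclassified": 0}
    for contig, s, e in regions:
        rep = merge_intervals([(max(a, s), min(b, e))
                               for a, b in rep_ivs.get(contig, [])])
        pt = merge_intervals([(max(a, s), min(b, e))
                              for a, b in pt_ivs.get(contig, [])])
        fm = merge_intervals([(max(a, s), min(b, e))
                              for a, b in fm_ivs.get(contig, [])])
        rep_len = coverage_length(rep)
        pt_only = _subtract(pt, rep)
        pt_len = coverage_length(pt_only)
        fm_only = _subtract(fm, merge_intervals(rep + pt))
        fm_len = coverage_length(fm_only)
        counts["repetitive"] += rep_len
        counts["plastid_like"] += pt_len
        counts["other_mitochondrial_like"] += fm_len
        counts["unclassified"] += (e - s) - rep_len - pt_len - fm_len
    fractions = {k: 100.0 * v / total for k, v in counts.items()}
    return NonsyntenicAccounting(total_length=total, fractions=fractions,
                                 regions=regions)


def _subtract(intervals: Iterable[tuple[int, int]],
              minus: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-subtract merged interval list ``minus`` from ``intervals``."""
    out: list[tuple[int, int]] = []
    for s, e in merge_intervals(intervals):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
        if cur < e:
            out.append((cur, e))
    return out
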