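"""Genome, feature-table and site-mask I/O plus circular-coordinate arithmetic.

Conventions used throughout the package:

* internal coordinates are 0-based half-open; on-disk tables are 1-based
  inclusive (GFF3 convention);
* every contig carries an explicit topology (``circular`` or ``linear``),
  declared by the user, defaulting to linear;
* sequences are uppercase strings over ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_TOPOLOGIES = ("circular", "linear")
FEATURE_CLASSES = ("exon", "intron", "rRNA", "tRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class GenomeRecord:
    """One contig: sequence plus declared topology."""

    contig_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in VALID_TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-IUPAC characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


def read_genome(
    path: str | Path,
    topology_map: Mapping[str, str] | None = None,
    default_topology: str = "linear",
) -> dict[str, GenomeRecord]:
    """Read a FASTA file into an ordered mapping of :class:`GenomeRecord`.

    ``topology_map`` assigns a topology per contig id; contigs absent from the
    map get ``default_topology``.
    """
    topology_map = dict(topology_map or {})
    records: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        topology = topology_map.get(rec.id, default_topology)
        records[rec.id] = GenomeRecord(rec.id, str(rec.seq), topology)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_genome(genome: Mapping[str, GenomeRecord] | Iterable[GenomeRecord],
                 path: str | Path, width: int = 70) -> None:
    if isinstance(genome, Mapping):
        genome = genome.values()
    with open(path, "w") as fh:
        for rec in genome:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


def extract_subsequence(record: GenomeRecord, start: int, end: int) -> str:
    """Extract ``[start, end)``; on circular contigs coordinates wrap.

    With ``start > end`` on a circular contig the suffix+prefix concatenation
    across the origin is returned.  Wrap on a linear contig is an error.
    """
    n = record.length
    if record.is_circular:
        start %= n
        end %= n
        if start <= end:
            return record.sequence[start:end]
        return record.sequence[start:] + record.sequence[:end]
    if not (0 <= start <= end <= n):
        raise ValueError(
            f"coordinates [{start}, {end}) invalid on linear contig "
            f"{record.contig_id!r} of length {n}"
        )
    return record.sequence[start:end]


# ---------------------------------------------------------------------------
# feature tables

FEATURE_COLUMNS = ["contig_id", "start", "end", "strand", "feature_class", "gene_id"]


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a GFF3-like TSV feature table (1-based inclusive on disk).

    Returns a DataFrame with 0-based half-open ``start``/``end``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=FEATURE_COLUMNS, dtype={
        "contig_id": str, "start": int, "end": int, "strand": str,
        "feature_class": str, "gene_id": str})
    return _validate_features(df.assign(start=df["start"] - 1))


def _validate_features(df: pd.DataFrame) -> pd.DataFrame:
    if (df["start"] > df["end"]).any():
        raise ValueError("feature with start > end")
    bad = set(df["feature_class"]) - set(FEATURE_CLASSES)
    if bad:
        raise ValueError(f"unknown feature classes {sorted(bad)}")
    if not set(df["strand"]) <= {"+", "-"}:
        raise ValueError("strand must be + or -")
    return df.reset_index(drop=True)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out[FEATURE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def make_features(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build an in-memory feature table from (contig, start0, end0, strand, class, gene)."""
    return _validate_features(pd.DataFrame(list(rows), columns=FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# site masks

def read_site_mask(path: str | Path) -> np.ndarray:
    """Read a tab/newline-delimited list of 0-based alignment columns to exclude."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.extend(int(tok) for tok in line.split("\t"))
    return np.unique(np.asarray(values, dtype=int))


def apply_site_mask(alignment: Mapping[str, str], mask: np.ndarray) -> dict[str, str]:
    """Drop masked columns from every sequence of an equal-width alignment."""
    widths = {len(s) for s in alignment.values()}
    if len(widths) != 1:
        raise ValueError("alignment sequences differ in width")
    width = widths.pop()
    mask = np.asarray(mask, dtype=int)
    if mask.size and (mask.min() < 0 or mask.max() >= width):
        raise ValueError("mask index outside alignment width")
    keep = np.ones(width, dtype=bool)
    keep[mask] = False
    keep_list = keep.tolist()
    return {name: "".join(c for c, k in zip(seq, keep_list) if k)
            for name, seq in alignment.items()}


# ---------------------------------------------------------------------------
# interval helpers and genome statistics

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge half-open intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


@dataclasses.dataclass
class GenomeStats:
    contig_count: int
    total_length: int
    gc_content: float          # percent, N excluded from the denominator
    repetitive_content: float  # percent of genome under merged repeat copies
    mtpt_content: float        # percent under merged plastid-derived hits
    coding_proportion: float   # percent under merged exons


def gc_percent(seq: str) -> float:
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return 100.0 * gc / acgt if acgt else 0.0


def _check_bounds(genome: Mapping[str, GenomeRecord], contig: str, start: int, end: int) -> None:
    if contig not in genome:
        raise ValueError(f"interval on unknown contig {contig!r}")
    if not (0 <= start <= end <= genome[contig].length):
        raise ValueError(f"interval [{start}, {end}) outside contig {contig!r}")


def genome_stats(
    genome: Mapping[str, GenomeRecord],
    repeat_intervals: Iterable[tuple[str, int, int]] = (),
    mtpt_intervals: Iterable[tuple[str, int, int]] = (),
    features: pd.DataFrame | None = None,
) -> GenomeStats:
    """Summary statistics: GC%, repetitive%, MTPT% and coding% of a genome.

    Coverage percentages are computed on union-merged intervals per contig so
    overlapping hits are not double counted.
    """
    total = sum(rec.length for rec in genome.values())
    gc = sum(rec.sequence.count("G") + rec.sequence.count("C") for rec in genome.values())
    acgt = sum(rec.length - rec.sequence.count("N") for rec in genome.values())

    def pct_coverage(intervals: Iterable[tuple[str, int, int]]) -> float:
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e in intervals:
            _check_bounds(genome, contig, s, e)
            per_contig.setdefault(contig, []).append((s, e))
        covered = sum(coverage_length(ivs) for ivs in per_contig.values())
        return 100.0 * covered / total

    exon_ivs: list[tuple[str, int, int]] = []
    if features is not None:
        exon = features[features["feature_class"] == "exon"]
        exon_ivs = list(zip(exon["contig_id"], exon["start"], exon["end"]))

    return GenomeStats(
        contig_count=len(genome),
        total_length=total,
        gc_content=100.0 * gc / acgt if acgt else 0.0,
        repetitive_content=pct_coverage(repeat_intervals),
        mtpt_content=pct_coverage(mtpt_intervals),
        coding_proportion=pct_coverage(exon_ivs),
    )


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into name -> (gapped) sequence."""
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not aln:
        raise ValueError(f"no records in {path}")
    return aln


def write_alignment_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


def translate(seq: str) -> str:
    return str(Seq(seq).translate())
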