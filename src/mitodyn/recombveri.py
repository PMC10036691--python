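"""Repeat-mediated recombination: conformations, read support, frequency.

For a dispersed repeat pair, recombination between the two copies exchanges
their flanking sequences.  Four references are built per pair — the two
parental conformations read from the assembly (R1, R2) and the two
alternative conformations with swapped downstream flanks (A1, A2).  Read
pairs are assigned to the conformation they uniquely support, subject to an
end-to-end alignment contract and a junction-informativeness requirement
(unique flank anchored on *both* sides of the repeat copy), and the
recombination frequency is the alternative fraction of informative reads:

    f = (nA1 + nA2) / (nR1 + nR2 + nA1 + nA2)

with a Wilson 95% interval.  A pair is called recombinationally active when
at least two alternative-supporting pairs are seen and f >= 1%.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core_io import GenomeRecord, extract_subsequence, reverse_complement
from .repeatscan import RepeatCatalog, RepeatPair

CONF_NAMES = ("R1", "R2", "A1", "A2")


@dataclasses.dataclass
class ConformationSet:
    """Four references for one repeat pair, all on copy A's strand."""

    pair: RepeatPair
    flank: int
    sequences: dict[str, str]              # name -> sequence
    repeat_span: dict[str, tuple[int, int]]  # name -> repeat interval in sequence
    truncated: dict[str, tuple[int, int]]    # name -> (left, right) flank truncation


@dataclasses.dataclass
class ClassifyParams:
    anchor_len: int = 20          # unique-flank bp required on each side
    score_margin: int = 2         # best conformation must win by >= this
    max_mismatch_frac: float = 0.05
    min_insert: int = 0
    max_insert: int = 700


@dataclasses.dataclass
class ReadSupportTally:
    n_r1: int = 0
    n_r2: int = 0
    n_a1: int = 0
    n_a2: int = 0
    n_ambiguous: int = 0

    @property
    def parental(self) -> int:
        return self.n_r1 + self.n_r2

    @property
    def alternative(self) -> int:
        return self.n_a1 + self.n_a2

    @property
    def informative(self) -> int:
        return self.parental + self.alternative


@dataclasses.dataclass
class RecombinationEstimate:
    frequency: float | None       # None when no informative reads
    ci_low: float | None
    ci_high: float | None
    active: bool
    tally: ReadSupportTally


def _flank_up(genome: Mapping[str, GenomeRecord], contig: str, pos: int,
              flank: int, limit: int) -> tuple[str, int]:
    """Flank ending at ``pos`` (exclusive), truncated to ``limit`` bp available."""
    rec = genome[contig]
    take = min(flank, limit)
    if rec.is_circular:
        return extract_subsequence(rec, (pos - take) % rec.length, pos % rec.length), flank - take
    take = min(take, pos)
    return rec.sequence[pos - take:pos], flank - take


def _flank_down(genome: Mapping[str, GenomeRecord], contig: str, pos: int,
                flank: int, limit: int) -> tuple[str, int]:
    rec = genome[contig]
    take = min(flank, limit)
    if rec.is_circular:
        return extract_subsequence(rec, pos % rec.length, (pos + take) % rec.length), flank - take
    take = min(take, rec.length - pos)
    return rec.sequence[pos:pos + take], flank - take


def build_conformations(
    genome: Mapping[str, GenomeRecord],
    pair: RepeatPair,
    flank: int = 300,
) -> ConformationSet:
    """Build the four reference/alternative sequences for one repeat pair.

    R1/R2 are read verbatim from the genome around each copy; A1 swaps copy
    A's downstream flank for copy B's, A2 the reverse.  For inverted pairs
    copy B's flanks enter reverse-complemented and swapped so that all four
    sequences lie on copy A's strand.  Flanks wrap across circular origins;
    on linear contigs they truncate at the contig end, and when the two
    copies are closer than ``2*flank`` the inner flanks truncate at the gap
    (recorded in ``truncated``).
    """
    ca, cb = pair.copy_a, pair.copy_b
    rec_a, rec_b = genome[ca.contig], genome[cb.contig]
    rep_a = extract_subsequence(rec_a, ca.start, ca.end % rec_a.length
                                if rec_a.is_circular else ca.end)
    rep_b = extract_subsequence(rec_b, cb.start, cb.end % rec_b.length
                                if rec_b.is_circular else cb.end)

    # limit inner flanks to the gap between the copies when they share a contig
    if ca.contig == cb.contig:
        gap = max(0, cb.start - ca.end)
        lim_down_a = gap if cb.start >= ca.end else flank
        lim_up_b = gap if cb.start >= ca.end else flank
    else:
        lim_down_a = lim_up_b = flank

    up_a, tr_ua = _flank_up(genome, ca.contig, ca.start, flank, flank)
    down_a, tr_da = _flank_down(genome, ca.contig, ca.end, flank, lim_down_a)
    up_b, tr_ub = _flank_up(genome, cb.contig, cb.start, flank, lim_up_b)
    down_b, tr_db = _flank_down(genome, cb.contig, cb.end, flank, flank)

    if pair.orientation == "direct":
        seqs = {
            "R1": up_a + rep_a + down_a,
            "R2": up_b + rep_b + down_b,
            "A1": up_a + rep_a + down_b,
            "A2": up_b + rep_b + down_a,
        }
        spans = {
            "R1": (len(up_a), len(up_a) + len(rep_a)),
            "R2": (len(up_b), len(up_b) + len(rep_b)),
            "A1": (len(up_a), len(up_a) + len(rep_a)),
            "A2": (len(up_b), len(up_b) + len(rep_b)),
        }
        trunc = {"R1": (tr_ua, tr_da), "R2": (tr_ub, tr_db),
                 "A1": (tr_ua, tr_db), "A2": (tr_ub, tr_da)}
    else:
        # copy B's locus on copy A's strand reads rc(down_b) + rc(rep_b) + rc(up_b)
        rc_up_b = reverse_complement(up_b)
        rc_down_b = reverse_complement(down_b)
        rc_rep_b = reverse_complement(rep_b)
        seqs = {
            "R1": up_a + rep_a + down_a,
            "R2": rc_down_b + rc_rep_b + rc_up_b,
            "A1": up_a + rep_a + rc_up_b,
            "A2": rc_down_b + rc_rep_b + down_a,
        }
        spans = {
            "R1": (len(up_a), len(up_a) + len(rep_a)),
            "R2": (len(rc_down_b), len(rc_down_b) + len(rc_rep_b)),
            "A1": (len(up_a), len(up_a) + len(rep_a)),
            "A2": (len(rc_down_b), len(rc_down_b) + len(rc_rep_b)),
        }
        trunc = {"R1": (tr_ua, tr_da), "R2": (tr_db, tr_ub),
                 "A1": (tr_ua, tr_ub), "A2": (tr_db, tr_da)}
    return ConformationSet(pair=pair, flank=flank, sequences=seqs,
                           repeat_span=spans, truncated=trunc)


# ---------------------------------------------------------------------------
# read-pair classification

def _best_placements(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """End-to-end (infix) alignments of ``query`` in ``target`` within ``k``
    edits; returns (distance, start, end) for every optimal location."""
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    return [(res["editDistance"], s, e + 1) for s, e in res["locations"]]


def _score_pair_on_conformation(
    seq1: str, seq2: str, target: str, k: int, params: ClassifyParams
) -> tuple[int, int, int] | None:
    """Best concordant placement of a read pair on one conformation.

    Returns ``(total_edits, span_start, span_end)`` over both mates, or None.
    Proper orientation: one mate forward, the other reverse-complemented,
    facing inward, insert within bounds.
    """
    best = None
    for fwd, rev in ((seq1, reverse_complement(seq2)),
                     (seq2, reverse_complement(seq1))):
        for d1, s1, e1 in _best_placements(fwd, target, k):
            for d2, s2, e2 in _best_placements(rev, target, k):
                if s2 < s1:          # mates must face inward: fwd mate leftmost
                    continue
                insert = e2 - s1
                if not (params.min_insert <= insert <= params.max_insert):
                    continue
                cand = (d1 + d2, s1, e2)
                if best is None or cand[0] < best[0]:
                    best = cand
    return best


def _junction_informative(span: tuple[int, int], repeat_span: tuple[int, int],
                          anchor: int) -> bool:
    s, e = span
    rs, re = repeat_span
    return s <= rs - anchor and e >= re + anchor


def classify_read_pairs(
    conf: ConformationSet,
    read_pairs: Iterable[tuple[str, str]],
    params: ClassifyParams | None = None,
) -> ReadSupportTally:
    """Tally uniquely-best, junction-informative read pairs per conformation.

    A read pair counts for a conformation iff both mates align end-to-end and
    concordantly within the mismatch budget, the aligned span anchors at
    least ``anchor_len`` bp of flank on both sides of the repeat copy, and
    its total edit distance is better by at least ``score_margin`` than on
    the other three conformations.  Everything else that aligns anywhere is
    ambiguous; pairs aligning nowhere are not counted at all.
    """
    params = params or ClassifyParams()
    tally = ReadSupportTally()
    names = list(CONF_NAMES)
    for seq1, seq2 in read_pairs:
        k = int(params.max_mismatch_frac * max(len(seq1), len(seq2)))
        scores: dict[str, tuple[int, int, int]] = {}
        for name in names:
            hit = _score_pair_on_conformation(seq1, seq2, conf.sequences[name],
                                              k, params)
            if hit is not None:
                scores[name] = hit
        if not scores:
            continue
        ranked = sorted(scores.items(), key=lambda kv: kv[1][0])
        best_name, (best_d, s, e) = ranked[0]
        runner_d = ranked[1][1][0] if len(ranked) > 1 else None
        unique = runner_d is None or (runner_d - best_d) >= params.score_margin
        informative = _junction_informative((s, e), conf.repeat_span[best_name],
                                            params.anchor_len)
        if unique and informative:
            field = {"R1": "n_r1", "R2": "n_r2", "A1": "n_a1", "A2": "n_a2"}[best_name]
            setattr(tally, field, getattr(tally, field) + 1)
        else:
            tally.n_ambiguous += 1
    return tally


def classify_long_reads(
    conf: ConformationSet,
    reads: Iterable[str],
    params: ClassifyParams | None = None,
) -> ReadSupportTally:
    """Single-read variant of the classification contract (long reads)."""
    params = params or ClassifyParams()
    tally = ReadSupportTally()
    for read in reads:
        k = int(params.max_mismatch_frac * len(read))
        scores: dict[str, tuple[int, int, int]] = {}
        for name in CONF_NAMES:
            target = conf.sequences[name]
            best = None
            for q in (read, reverse_complement(read)):
                for d, s, e in _best_placements(q, target, k):
                    if best is None or d < best[0]:
                        best = (d, s, e)
            if best is not None:
                scores[name] = best
        if not scores:
            continue
        ranked = sorted(scores.items(), key=lambda kv: kv[1][0])
        best_name, (best_d, s, e) = ranked[0]
        runner_d = ranked[1][1][0] if len(ranked) > 1 else None
        unique = runner_d is None or (runner_d - best_d) >= params.score_margin
        informative = _junction_informative((s, e), conf.repeat_span[best_name],
                                            params.anchor_len)
        if unique and informative:
            field = {"R1": "n_r1", "R2": "n_r2", "A1": "n_a1", "A2": "n_a2"}[best_name]
            setattr(tally, field, getattr(tally, field) + 1)
        else:
            tally.n_ambiguous += 1
    return tally


def estimate_recombination(
    tally: ReadSupportTally,
    min_alt_reads: int = 2,
    min_frequency: float = 0.01,
) -> RecombinationEstimate:
    """Frequency, Wilson 95% CI and the activity call for one tally."""
    n = tally.informative
    if n == 0:
        return RecombinationEstimate(None, None, None, False, tally)
    f = tally.alternative / n
    lo, hi = proportion_confint(tally.alternative, n, alpha=0.05, method="wilson")
    active = tally.alternative >= min_alt_reads and f >= min_frequency
    return RecombinationEstimate(f, float(lo), float(hi), active, tally)


# ---------------------------------------------------------------------------
# whole-catalog survey

@dataclasses.dataclass
class SurveyParams:
    flank_short: int = 300
    flank_long: int = 1000
    insert_size: int = 350        # repeats at or above this need long reads
    classify: ClassifyParams = dataclasses.field(default_factory=ClassifyParams)
    candidate_kmer: int = 21


def _candidate_index(conf_sets: Sequence[ConformationSet], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, conf in enumerate(conf_sets):
        for seq in conf.sequences.values():
            for j in range(0, len(seq) - k + 1):
                index.setdefault(seq[j:j + k], set()).add(i)
    return index


def recombination_survey(
    genome: Mapping[str, GenomeRecord],
    catalog: RepeatCatalog,
    read_pairs: Sequence[tuple[str, str]] | None,
    long_reads: Sequence[str] | None = None,
    params: SurveyParams | None = None,
) -> pd.DataFrame:
    """Estimate recombination activity for every repeat pair in a catalog.

    Repeats shorter than the library insert size are assessed with read
    pairs (flank 300); longer repeats with single long reads (flank 1000);
    pairs with no applicable read set are reported ``not-evaluated``.  Read
    pairs are routed to candidate conformation sets via a shared k-mer index
    so each pair is only aligned where it can possibly match.
    """
    params = params or SurveyParams()
    rows = []
    short_pairs = [(i, p) for i, p in enumerate(catalog.pairs)
                   if p.length < params.insert_size]
    long_pairs = [(i, p) for i, p in enumerate(catalog.pairs)
                  if p.length >= params.insert_size]

    results: dict[int, tuple[RecombinationEstimate, str]] = {}

    if short_pairs and read_pairs:
        confs = [build_conformations(genome, p, params.flank_short)
                 for _, p in short_pairs]
        index = _candidate_index(confs, params.candidate_kmer)
        buckets: dict[int, list[tuple[str, str]]] = {i: [] for i in range(len(confs))}
        k = params.candidate_kmer
        for seq1, seq2 in read_pairs:
            cands: set[int] = set()
            for seq in (seq1, seq2):
                for j in range(0, len(seq) - k + 1, 10):
                    cands |= index.get(seq[j:j + k], set())
            for ci in cands:
                buckets[ci].append((seq1, seq2))
        for ci, (orig_i, pair) in enumerate(short_pairs):
            tally = classify_read_pairs(confs[ci], buckets[ci], params.classify)
            results[orig_i] = (estimate_recombination(tally), "paired")
    else:
        for orig_i, _ in short_pairs:
            results[orig_i] = (
                estimate_recombination(ReadSupportTally()), "not-evaluated")

    if long_pairs and long_reads:
        for orig_i, pair in long_pairs:
            conf = build_conformations(genome, pair, params.flank_long)
            tally = classify_long_reads(conf, long_reads, params.classify)
            results[orig_i] = (estimate_recombination(tally), "long")
    else:
        for orig_i, _ in long_pairs:
            results[orig_i] = (
                estimate_recombination(ReadSupportTally()), "not-evaluated")

    for i, pair in enumerate(catalog.pairs):
        est, method = results[i]
        t = est.tally
        rows.append({
            "pair_id": i, "length": pair.length, "orientation": pair.orientation,
            "n_r1": t.n_r1, "n_r2": t.n_r2, "n_a1": t.n_a1, "n_a2": t.n_a2,
            "n_ambiguous": t.n_ambiguous,
            "frequency": est.frequency, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "active": est.active, "method": method,
        })
    return pd.DataFrame(rows)


def survey_summary(survey: pd.DataFrame) -> dict:
    """Active fraction overall and for repeats under the insert-size bound."""
    evaluated = survey[survey["method"] != "not-evaluated"]
    out = {"n_pairs": int(len(survey)), "n_evaluated": int(len(evaluated))}
    if len(evaluated):
        out["active_fraction"] = float(evaluated["active"].mean())
        short = evaluated[evaluated["length"] < 350]
        out["active_fraction_lt350"] = (float(short["active"].mean())
                                        if len(short) else None)
    return out
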