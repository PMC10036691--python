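"""Interspersed (dispersed) repeat discovery by genome self-comparison.

Finds maximal near-identical repeat pairs of at least ``min_len`` bp on both
strands, excluding self-matches and tandem hits (copies that overlap or abut),
groups copies into repeat units (families of near-identical copies), and
computes length-class densities plus group comparisons.

The detection core seeds on exact shared words and extends each seed to a
maximal ungapped run.  With ``min_identity=100`` the output is exactly the set
of maximal exact dispersed matches; below 100 the extension is an x-drop scan
(match +1, mismatch -3) trimmed back to the best-scoring endpoints, the regime
appropriate for the near-identical repeats that dominate organelle genomes.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GenomeRecord, reverse_complement

LENGTH_CLASSES: tuple[tuple[int, float], ...] = (
    (50, 99), (100, 199), (200, 499), (500, 999), (1000, float("inf")))

TANDEM_GAP = 10       # copies closer than this are tandem, not interspersed
XDROP = 12            # x-drop threshold for sub-identity extension
MATCH, MISMATCH = 1, -3


@dataclasses.dataclass(frozen=True)
class Copy:
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class RepeatPair:
    """Two dispersed copies of one repeat, with relative orientation."""

    copy_a: Copy
    copy_b: Copy
    orientation: str       # "direct" | "inverted"
    length: int
    identity: float        # percent

    def copies(self) -> tuple[Copy, Copy]:
        return (self.copy_a, self.copy_b)


@dataclasses.dataclass
class RepeatCatalog:
    pairs: list[RepeatPair]
    units: list[list[Copy]]

    def copy_intervals(
        self, genome: Mapping[str, GenomeRecord] | None = None
    ) -> list[tuple[str, int, int]]:
        """Copy intervals; origin-wrapped copies (end > contig length, only
        possible on circular contigs) are split into two in-bounds pieces when
        the genome is supplied."""
        out: list[tuple[str, int, int]] = []
        for p in self.pairs:
            for c in p.copies():
                if genome is not None and c.end > genome[c.contig].length:
                    n = genome[c.contig].length
                    out.append((c.contig, c.start, n))
                    out.append((c.contig, 0, c.end - n))
                else:
                    out.append((c.contig, c.start, c.end))
        return out


@dataclasses.dataclass
class RepeatStats:
    genome_length: int
    class_counts: dict[tuple[int, float], int]
    class_densities: dict[tuple[int, float], float]   # repeats per kb

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def _length_class(length: int) -> tuple[int, float] | None:
    for lo, hi in LENGTH_CLASSES:
        if lo <= length <= hi:
            return (lo, hi)
    return None


# ---------------------------------------------------------------------------
# detection

def _extend_exact(sa: str, ia: int, sb: str, ib: int, k: int) -> tuple[int, int, int]:
    """Maximal exact extension of a seed match sa[ia:ia+k] == sb[ib:ib+k].

    Returns (offset_left, offset_right, length): the match spans
    sa[ia-off_l : ia+k+off_r].
    """
    left = 0
    while ia - left - 1 >= 0 and ib - left - 1 >= 0 and sa[ia - left - 1] == sb[ib - left - 1]:
        left += 1
    right = 0
    la, lb = len(sa), len(sb)
    while ia + k + right < la and ib + k + right < lb and sa[ia + k + right] == sb[ib + k + right]:
        right += 1
    return left, right, k + left + right


def _extend_xdrop(sa: str, ia: int, sb: str, ib: int, k: int) -> tuple[int, int, int]:
    """X-drop ungapped extension; returns (off_l, off_r, n_matches) at best score."""

    def run(direction: int, base_a: int, base_b: int) -> tuple[int, int]:
        best_off = 0
        best_score = 0
        best_matches = 0
        score = 0
        matches = 0
        off = 0
        la, lb = len(sa), len(sb)
        while True:
            pa = base_a + direction * (off + 1) if direction < 0 else base_a + off
            pb = base_b + direction * (off + 1) if direction < 0 else base_b + off
            if not (0 <= pa < la and 0 <= pb < lb):
                break
            if sa[pa] == sb[pb]:
                score += MATCH
                matches += 1
            else:
                score += MISMATCH
            off += 1
            if score > best_score:
                best_score, best_off, best_matches = score, off, matches
            if best_score - score >= XDROP:
                break
        return best_off, best_matches

    off_l, m_l = run(-1, ia, ib)
    off_r, m_r = run(+1, ia + k, ib + k)
    return off_l, off_r, k + m_l + m_r


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _canonical_mod(pos: int, length: int, n: int, circular: bool) -> tuple[int, int]:
    """Map a hit on the doubled circular sequence back to [0, n)."""
    if circular:
        pos %= n
    return pos, pos + length


def find_repeats(
    genome: Mapping[str, GenomeRecord],
    min_len: int = 50,
    min_identity: float = 90.0,
) -> RepeatCatalog:
    """Detect all maximal dispersed repeat pairs of at least ``min_len`` bp.

    Both strands are searched; circular contigs are searched across the
    origin.  Tandem pairs (copies overlapping or separated by < 10 bp on one
    contig) and self-matches are excluded.  Symmetric duplicates and hits
    whose copies are both contained in a longer reported pair are collapsed.
    """
    if min_len < 20:
        raise ValueError("min_len < 20: seeding undefined")
    if not genome:
        raise ValueError("empty genome")
    k = min(min_len, 50)
    exact = min_identity >= 100.0

    # working sequences: circular contigs are doubled so matches cross the origin
    work: dict[str, tuple[str, int, bool]] = {}
    for cid, rec in genome.items():
        if rec.is_circular and rec.length > k:
            work[cid] = (rec.sequence + rec.sequence, rec.length, True)
        else:
            work[cid] = (rec.sequence, rec.length, False)

    index: dict[str, list[tuple[str, int]]] = {}
    for cid, (seq, n, circular) in work.items():
        limit = (2 * n - k) if circular else (len(seq) - k)
        for i in range(limit + 1):
            if circular and i >= n:
                break
            index.setdefault(seq[i : i + k], []).append((cid, i))
    # for circular contigs we must also seed positions in [n, 2n-k] so that
    # origin-spanning copies pair with interior ones; add them but mark modulo
    for cid, (seq, n, circular) in work.items():
        if not circular:
            continue
        for i in range(n, min(2 * n - k, len(seq) - k) + 1):
            index.setdefault(seq[i : i + k], []).append((cid, i))

    raw: dict[tuple, RepeatPair] = {}

    def record(ca: str, a0: int, a1: int, cb: str, b0: int, b1: int,
               orientation: str, identity: float) -> None:
        na = work[ca][1]
        nb = work[cb][1]
        # fold coordinates of circular contigs into [0, n)
        if work[ca][2]:
            shift = (a0 // na) * na if a0 >= na else 0
            a0, a1 = a0 - shift, a1 - shift
            if a0 >= na:
                return
        if work[cb][2]:
            shift = (b0 // nb) * nb if b0 >= nb else 0
            b0, b1 = b0 - shift, b1 - shift
            if b0 >= nb:
                return
        if (ca, a0, a1) == (cb, b0, b1):
            return                       # self-match
        length = a1 - a0
        if length < min_len or length > min(na, nb):
            return
        if ca == cb:                     # tandem / overlapping copies
            lo, hi = sorted([(a0, a1), (b0, b1)])
            gap = hi[0] - lo[1]
            if gap < TANDEM_GAP:
                # on circular contigs also check the wrap-around gap
                if not work[ca][2] or (na - (hi[1] - lo[0])) >= TANDEM_GAP:
                    if gap < TANDEM_GAP:
                        return
            if work[ca][2] and (na - (hi[1] - lo[0])) < TANDEM_GAP:
                return
        first, second = sorted([(ca, a0, a1), (cb, b0, b1)])
        key = (first, second, orientation)
        pair = RepeatPair(Copy(*first), Copy(*second), orientation, length,
                          round(identity, 2))
        old = raw.get(key)
        if old is None or pair.identity > old.identity:
            raw[key] = pair

    extend = _extend_exact if exact else _extend_xdrop
    rc_work = {cid: reverse_complement(seq) for cid, (seq, _, _) in work.items()}

    seen_seed_pairs: set[tuple] = set()
    for kmer, occs in index.items():
        rc = reverse_complement(kmer)
        # direct repeats: all pairs of occurrences of the same word
        if len(occs) > 1:
            for (ca, ia), (cb, ib) in itertools.combinations(occs, 2):
                if ca == cb and work[ca][2]:
                    # doubled circular contig: skip period-n self-images and
                    # pairs whose fold-equivalent is already enumerated
                    n_ = work[ca][1]
                    if (ib - ia) % n_ == 0:
                        continue
                    if ia >= n_ and ib >= n_:
                        continue
                elif work[ca][2] and work[cb][2] and \
                        ia >= work[ca][1] and ib >= work[cb][1]:
                    continue
                sa, sb = work[ca][0], work[cb][0]
                off_l, off_r, n_match = extend(sa, ia, sb, ib, k)
                a0, a1 = ia - off_l, ia + k + off_r
                length = a1 - a0
                identity = 100.0 * n_match / length
                if identity < min_identity:
                    continue
                record(ca, a0, a1, cb, ib - off_l, ib + k + off_r, "direct", identity)
        # inverted repeats: pair occurrences of the word with those of its rc;
        # process each unordered word pair once via canonical ordering
        if rc in index and kmer <= rc:
            for (ca, ia), (cb, jb) in itertools.product(occs, index[rc]):
                if ca == cb and work[ca][2]:
                    n_ = work[ca][1]
                    if ia >= n_ and jb >= n_:
                        continue
                elif work[ca][2] and work[cb][2] and \
                        ia >= work[ca][1] and jb >= work[cb][1]:
                    continue
                sig = tuple(sorted([(ca, ia), (cb, jb)]))
                if sig in seen_seed_pairs:
                    continue
                seen_seed_pairs.add(sig)
                # the occurrence sb[jb:jb+k] equals rc(kmer); as an inverted
                # match, extend sa forward against rc(sb) at the mirrored spot
                sa = work[ca][0]
                sb_len = len(work[cb][0])
                rb = rc_work[cb]
                jb_r = sb_len - (jb + k)       # position of kmer in rc(sb)
                off_l, off_r, n_match = extend(sa, ia, rb, jb_r, k)
                a0, a1 = ia - off_l, ia + k + off_r
                length = a1 - a0
                identity = 100.0 * n_match / length
                if identity < min_identity:
                    continue
                # map back from rc(sb) coordinates to sb coordinates
                b0 = sb_len - (jb_r + k + off_r)
                b1 = sb_len - (jb_r - off_l)
                record(ca, a0, a1, cb, b0, b1, "inverted", identity)

    pairs = _collapse_contained(list(raw.values()))
    units = cluster_units(pairs)
    return RepeatCatalog(pairs=pairs, units=units)


def _collapse_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose two copies are both contained in a longer pair's copies."""
    pairs = sorted(pairs, key=lambda p: (-p.length, p.copy_a.contig, p.copy_a.start))
    kept: list[RepeatPair] = []

    def contains(outer: Copy, inner: Copy) -> bool:
        return (outer.contig == inner.contig and outer.start <= inner.start
                and inner.end <= outer.end)

    for p in pairs:
        redundant = False
        for q in kept:
            if q.orientation != p.orientation:
                continue
            if ((contains(q.copy_a, p.copy_a) and contains(q.copy_b, p.copy_b)) or
                    (contains(q.copy_a, p.copy_b) and contains(q.copy_b, p.copy_a))):
                redundant = True
                break
        if not redundant:
            kept.append(p)
    kept.sort(key=lambda p: (p.copy_a.contig, p.copy_a.start, p.copy_b.contig,
                             p.copy_b.start, p.orientation))
    return kept


# ---------------------------------------------------------------------------
# repeat units

def cluster_units(
    pairs: Sequence[RepeatPair],
    identity_threshold: float = 95.0,
    overlap_frac: float = 0.5,
) -> list[list[Copy]]:
    """Group repeat copies into units (connected components of the pair graph).

    Copies whose genomic intervals reciprocally overlap by at least
    ``overlap_frac`` of the shorter copy are treated as the same node; pairs
    with identity >= ``identity_threshold`` contribute edges.
    """
    copies: list[Copy] = []
    for p in pairs:
        copies.extend(p.copies())
    copies = sorted(set(copies), key=lambda c: (c.contig, c.start, c.end))
    if not copies:
        return []

    parent = list(range(len(copies)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    idx = {c: i for i, c in enumerate(copies)}
    # merge co-located copies (same locus reported with slightly different ends)
    for i in range(len(copies)):
        a = copies[i]
        for j in range(i + 1, len(copies)):
            b = copies[j]
            if a.contig != b.contig or b.start >= a.end:
                break  # copies are sorted; nothing later can overlap a
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= overlap_frac * min(a.length, b.length):
                union(i, j)
    for p in pairs:
        if p.identity >= identity_threshold:
            union(idx[p.copy_a], idx[p.copy_b])

    groups: dict[int, list[Copy]] = {}
    for i, c in enumerate(copies):
        groups.setdefault(find(i), []).append(c)
    units = [_dedupe_loci(g, overlap_frac) for g in groups.values()]
    return sorted(units, key=lambda g: (g[0].contig, g[0].start))


def _dedupe_loci(copies: list[Copy], overlap_frac: float) -> list[Copy]:
    """Collapse near-identical intervals (boundary jitter from different
    partner pairs) into one representative locus each."""
    copies = sorted(copies, key=lambda c: (c.contig, c.start, c.end))
    loci: list[Copy] = []
    for c in copies:
        if loci:
            last = loci[-1]
            ov = min(last.end, c.end) - max(last.start, c.start)
            if c.contig == last.contig and ov >= overlap_frac * min(
                    last.length, c.length):
                loci[-1] = Copy(last.contig, min(last.start, c.start),
                                max(last.end, c.end))
                continue
        loci.append(c)
    return loci


# ---------------------------------------------------------------------------
# statistics

def repeat_stats(catalog: RepeatCatalog,
                 genome: Mapping[str, GenomeRecord]) -> RepeatStats:
    """Per-length-class counts and densities (repeats per kb of genome)."""
    total_len = sum(rec.length for rec in genome.values())
    if total_len == 0:
        raise ValueError("zero-length genome")
    counts = {cls: 0 for cls in LENGTH_CLASSES}
    for p in catalog.pairs:
        cls = _length_class(p.length)
        if cls is not None:
            counts[cls] += 1
    kb = total_len / 1000.0
    densities = {cls: n / kb for cls, n in counts.items()}
    return RepeatStats(genome_length=total_len, class_counts=counts,
                       class_densities=densities)


def compare_density(
    group_a: Sequence[RepeatStats],
    group_b: Sequence[RepeatStats],
    length_class: tuple[int, float] = (50, 99),
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-genome densities of one class.

    Returns ``(statistic, p_value)``; the exact null distribution is used for
    small samples without ties.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    xa = [s.class_densities[length_class] for s in group_a]
    xb = [s.class_densities[length_class] for s in group_b]
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                             method="exact" if (len(xa) < 25 and len(xb) < 25
                                                and len(set(xa + xb)) == len(xa + xb))
                             else "asymptotic")
    return float(res.statistic), float(res.pvalue)
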