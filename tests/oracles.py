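"""Independent brute-force oracles used by the test-suite and acceptance checks.

These deliberately avoid the seeded/hashed code paths of the package: the
repeat oracle enumerates maximal exact matches by exhaustive shift
comparison (numpy vectorised all-pairs scan), which is O(n^2) and only
usable on small genomes.
"""

from __future__ import annotations

import numpy as np

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


def _true_runs(mask: np.ndarray):
    """Yield (start, length) of maximal runs of True."""
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e - s)


def exact_repeat_pairs(seq: str, min_len: int = 50, tandem_gap: int = 10) -> set:
    """All maximal exact dispersed repeat pairs of one linear sequence.

    Returns a set of ``((startA, endA), (startB, endB), orientation)`` with
    copies sorted, tandem pairs (gap < tandem_gap) excluded, and pairs whose
    copies are both contained in a longer pair's copies (same orientation)
    collapsed.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairs: set = set()
    for d in range(1, n):
        mask = arr[:-d] == arr[d:]
        for s, length in _true_runs(mask):
            if length < min_len:
                continue
            a = (s, s + length)
            b = (s + d, s + d + length)
            if b[0] - a[1] >= tandem_gap:       # gap = d - length
                pairs.add((a, b, "direct"))
    t = np.frombuffer(_revcomp(seq).encode(), dtype=np.uint8)
    for off in range(-(n - 1), n):
        i0, i1 = max(0, -off), min(n, n - off)
        if i1 - i0 < min_len:
            continue
        mask = arr[i0:i1] == t[i0 + off:i1 + off]
        for s, length in _true_runs(mask):
            if length < min_len:
                continue
            a_start = i0 + s
            p = a_start + off
            b_start = n - p - length
            a = (a_start, a_start + length)
            b = (b_start, b_start + length)
            if a == b:
                continue
            lo, hi = sorted([a, b])
            if hi[0] - lo[1] >= tandem_gap:
                pairs.add((lo, hi, "inverted"))
    return _drop_contained(pairs)


def _drop_contained(pairs: set) -> set:
    def contains(outer, inner):
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    ordered = sorted(pairs, key=lambda p: -(p[0][1] - p[0][0]))
    kept: list = []
    for a, b, orient in ordered:
        redundant = any(
            o == orient and ((contains(ka, a) and contains(kb, b)) or
                             (contains(ka, b) and contains(kb, a)))
            for ka, kb, o in kept)
        if not redundant:
            kept.append((a, b, orient))
    return set(kept)


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p-value by complete enumeration."""
    import itertools

    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "exact enumeration assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    nx = len(x)
    stats = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), nx)]
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats)


def tukey_q_pvalue(mean_diff: float, mse: float, n_per_group: int,
                   k_groups: int, df: int) -> float:
    """Hand-computed Tukey HSD adjusted p for one pair (balanced layout)."""
    from scipy.stats import studentized_range

    q = abs(mean_diff) / np.sqrt(mse / n_per_group)
    return float(studentized_range.sf(q, k_groups, df))
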