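"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive — plain Python, exhaustive where
feasible — and shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

from typing import Mapping, Sequence

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pam_matches(three_mer: str, pattern: str) -> bool:
    return all(b in IUPAC_SETS[p] for b, p in zip(three_mer, pattern))


def window_profile(proto: str, window: str, seed_len: int) -> tuple[int, int]:
    """(seed_mm, nonseed_mm) by direct per-position comparison; N in the
    window is always a mismatch."""
    boundary = len(proto) - seed_len
    s = n = 0
    for i in range(len(proto)):
        if window[i] != proto[i] or window[i] == "N":
            if i >= boundary:
                s += 1
            else:
                n += 1
    return s, n


def naive_scan(
    sequences: Mapping[str, str],
    proto: str,
    pam_patterns: Sequence[str],
    seed_len: int,
    exclude_n: bool = False,
) -> list[tuple[str, int, str, int, int, str]]:
    """Exhaustive sliding-window scan over both strands.

    Returns (chrom, start, strand, seed_mm, nonseed_mm, pam_class) for
    every PAM-adjacent window, with start/end of the protospacer segment
    in + strand coordinates and no mismatch budget applied (the caller
    filters).  The first matching PAM pattern wins, as in the scanner's
    contract.
    """
    W = len(proto)
    hits = []
    for chrom, fwd in sequences.items():
        L = len(fwd)
        for strand in "+-":
            seq = fwd if strand == "+" else revcomp(fwd)
            for i in range(L - W - 2):
                pam = seq[i + W:i + W + 3]
                pam_class = None
                for pattern in pam_patterns:
                    if pam_matches(pam, pattern):
                        pam_class = pattern
                        break
                if pam_class is None:
                    continue
                window = seq[i:i + W]
                if exclude_n and "N" in window + pam:
                    continue
                smm, nmm = window_profile(proto, window, seed_len)
                start = i if strand == "+" else L - (i + W)
                hits.append((chrom, start, strand, smm, nmm, pam_class))
    return hits


def filter_scan(
    hits: Sequence[tuple[str, int, str, int, int, str]],
    max_seed: int,
    max_nonseed: int,
    pam_patterns: Sequence[str],
) -> set[tuple[str, int, str, int, int, str]]:
    """Apply budgets/PAM set to unfiltered naive_scan output.

    PAM re-resolution matters when the allowed set shrinks: a window whose
    3-mer matches several patterns is classed by the first allowed one.
    """
    out = set()
    for chrom, start, strand, smm, nmm, pam_class in hits:
        if pam_class not in pam_patterns:
            continue
        if smm <= max_seed and nmm <= max_nonseed:
            out.add((chrom, start, strand, smm, nmm, pam_class))
    return out


# ---------------------------------------------------------------------------
# Indel normalization


def canonical_edit(seq: str, pos: int, ref: str, alt: str):
    """Canonical (pos, ref, alt) of an edit by reconstruction.

    Applies the edit to the full sequence, then re-derives the unique
    leftmost parsimonious anchored encoding: longest common suffix first,
    then longest common prefix of the remainders.  Independent of any
    shift-based algorithm.
    """
    start = pos - 1
    assert seq[start:start + len(ref)] == ref
    edited = seq[:start] + alt + seq[start + len(ref):]
    if seq == edited:
        raise ValueError("edit is a no-op")
    # longest common suffix
    s = 0
    while (
        s < len(seq) and s < len(edited) and seq[len(seq) - 1 - s] == edited[len(edited) - 1 - s]
    ):
        s += 1
    a, b = seq[:len(seq) - s], edited[:len(edited) - s]
    # longest common prefix of the remainders
    p = 0
    while p < len(a) and p < len(b) and a[p] == b[p]:
        p += 1
    core_ref, core_alt = a[p:], b[p:]
    if core_ref and core_alt:
        return (p + 1, core_ref, core_alt)
    # pure indel: anchor on the preceding base (or the following one at
    # the contig start)
    if p > 0:
        return (p, seq[p - 1] + core_ref, seq[p - 1] + core_alt)
    nxt = seq[len(core_ref)] if core_ref else seq[0]
    return (1, core_ref + nxt, core_alt + nxt)


def equivalent_encodings(seq: str, pos: int, ref: str, alt: str, limit: int = 50):
    """All VCF encodings (within a +-limit bp window) that produce the same
    edited sequence, by exhaustive enumeration over anchored candidates."""
    start = pos - 1
    edited = seq[:start] + alt + seq[start + len(ref):]
    out = []
    max_len = max(len(ref), len(alt)) + limit
    lo = max(0, start - limit)
    hi = min(len(seq), start + limit)
    for p in range(lo, hi + 1):
        for rl in range(0, max_len + 1):
            if p + rl > len(seq):
                break
            r = seq[p:p + rl]
            # alt length is forced by the overall length change
            need = len(edited) - p - (len(seq) - (p + rl))
            if need < 0:
                continue
            a = edited[p:p + need]
            if not r or not a or r == a:
                continue
            if seq[:p] + a + seq[p + rl:] == edited:
                out.append((p + 1, r, a))
    return out


# ---------------------------------------------------------------------------
# Interval / ranking helpers


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def all_pairs_min_distance(v_iv, site_ivs):
    """Brute-force minimum edge distance from one interval to many."""
    return min(interval_gap(v_iv, s) for s in site_ivs)


# ---------------------------------------------------------------------------
# Single-indel recovery and global alignment


def single_indel_explanations(reference: str, read: str):
    """Every position at which one contiguous indel turns reference into
    read; exhaustive enumeration.  Returns (kind, 0-based pos, bases)
    tuples, leftmost first."""
    d = len(read) - len(reference)
    out = []
    if d < 0:
        size = -d
        for p in range(len(reference) - size + 1):
            if reference[:p] + reference[p + size:] == read:
                out.append(("del", p, reference[p:p + size]))
    elif d > 0:
        size = d
        for p in range(len(read) - size + 1):
            if read[:p] + read[p + size:] == reference:
                out.append(("ins", p, read[p:p + size]))
    return out


def nw_affine(
    ref: str,
    query: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> int:
    """Optimal global affine-gap alignment score (Gotoh three-state DP,
    end gaps penalized).  ``gap_open`` is the score of the first gap
    column, ``gap_extend`` of each further column."""
    NEG = -10 ** 9
    n, m = len(ref), len(query)
    M = [NEG] * (m + 1)
    X = [NEG] * (m + 1)   # gap in query (ref consumed)
    Y = [NEG] * (m + 1)   # gap in ref (query consumed)
    M[0] = 0
    for j in range(1, m + 1):
        Y[j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        prevM, prevX, prevY = M[:], X[:], Y[:]
        M = [NEG] * (m + 1)
        X = [NEG] * (m + 1)
        Y = [NEG] * (m + 1)
        X[0] = gap_open + (i - 1) * gap_extend
        for j in range(1, m + 1):
            sub = match if ref[i - 1] == query[j - 1] else mismatch
            M[j] = max(prevM[j - 1], prevX[j - 1], prevY[j - 1]) + sub
            X[j] = max(prevM[j] + gap_open, prevX[j] + gap_extend,
                       prevY[j] + gap_open)
            Y[j] = max(M[j - 1] + gap_open, Y[j - 1] + gap_extend,
                       X[j - 1] + gap_open)
    return max(M[m], X[m], Y[m])
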