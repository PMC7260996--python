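"""Low-level sequence utilities: GC content, N50, suffix-array MUM detection.

The maximal-unique-match (MUM) finder is built on a prefix-doubling suffix
array with a Kasai LCP pass.  A MUM between sequences ``a`` and ``b`` is an
exact match that occurs exactly once in each sequence and cannot be extended
left or right.  On the generalized suffix array of ``a#b$`` every such match
appears as an adjacent suffix pair whose LCP strictly exceeds the LCP with
both flanking suffixes (uniqueness) and whose preceding characters differ
(left-maximality); right-maximality is implied because the LCP is maximal.
"""

from __future__ import annotations

import numpy as np

_GC_BASES = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")

# integer codes for the suffix array: A,C,G,T -> 0..3, sentinels from 4 up
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide sequence.

    Ambiguous bases (anything outside ACGT) are excluded from the
    denominator.  Raises ``ValueError`` on an empty sequence or a sequence
    consisting only of ambiguous bases (undefined GC).
    """
    if not seq:
        raise ValueError("gc_content: empty sequence")
    gc = sum(1 for c in seq if c in _GC_BASES)
    unambig = sum(1 for c in seq if c in _UNAMBIG)
    if unambig == 0:
        raise ValueError("gc_content: no unambiguous bases, GC undefined")
    return gc / unambig


def n50(lengths) -> int:
    """N50: smallest length L such that sequences >= L hold half the total."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50: empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("n50: lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    return lengths[-1]  # pragma: no cover - unreachable


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsort)."""
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    sa = np.argsort(rank, kind="stable")
    if n == 1:
        return sa
    k = 1
    tmp = np.empty(n, dtype=np.int64)
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - k] = rank[k:]
        sa = np.lexsort((rank2, rank))
        tmp[sa[0]] = 0
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (rank2[sa[1:]] != rank2[sa[:-1]])
        tmp[sa[1:]] = np.cumsum(changed)
        rank = tmp.copy()
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def _lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = LCP(suffix sa[i-1], suffix sa[i]); lcp[0] = 0."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def encode_concat(seqs: list[str], start_code: int = 4) -> tuple[np.ndarray, int]:
    """Encode sequences joined by unique non-matching sentinel codes.

    Returns the code array and the next free sentinel code.  Sentinels never
    match anything (each is used once), so matches cannot span members.
    """
    parts: list[np.ndarray] = []
    code = start_code
    for i, s in enumerate(seqs):
        if i > 0:
            parts.append(np.array([code], dtype=np.int64))
            code += 1
        arr = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
        enc = np.full(len(arr), -1, dtype=np.int64)
        for base, c in _BASE_CODE.items():
            enc[arr == ord(base)] = c
        if (enc < 0).any():
            # ambiguous bases become unique sentinels: they never match
            bad = np.flatnonzero(enc < 0)
            enc[bad] = np.arange(code, code + len(bad))
            code += len(bad)
        parts.append(enc)
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64), code


def maximal_unique_matches(a: str, b: str, min_len: int = 20) -> list[tuple[int, int, int]]:
    """Maximal unique matches between two sequences.

    Returns 0-based ``(start_a, start_b, length)`` triples for every exact
    match of length >= ``min_len`` that occurs exactly once in ``a`` and
    exactly once in ``b`` and is extendable in neither direction.
    """
    if not a or not b:
        raise ValueError("maximal_unique_matches: sequences must be non-empty")
    if min_len < 1:
        raise ValueError("maximal_unique_matches: min_len must be >= 1")
    ca, nxt = encode_concat([a])
    cb, nxt2 = encode_concat([b], start_code=nxt)
    sep = np.array([nxt2], dtype=np.int64)
    end = np.array([nxt2 + 1], dtype=np.int64)
    codes = np.concatenate([ca, sep, cb, end])
    return _mums_from_codes(codes, len(a), len(a) + 1, min_len)


def mums_concat(codes: np.ndarray, len_a: int, b_offset: int, min_len: int) -> list[tuple[int, int, int]]:
    """MUMs on a pre-encoded concatenation (positions < len_a belong to a)."""
    return _mums_from_codes(codes, len_a, b_offset, min_len)


def _mums_from_codes(codes: np.ndarray, len_a: int, b_offset: int, min_len: int) -> list[tuple[int, int, int]]:
    n = len(codes)
    sa = _suffix_array(codes)
    lcp = _lcp_array(codes, sa)
    is_a = sa < len_a
    # candidate adjacent pairs from different strings with a long-enough LCP
    pair_lcp = lcp[1:]  # LCP(sa[i], sa[i+1]) for i = 0..n-2
    cand = np.flatnonzero((pair_lcp >= min_len) & (is_a[:-1] != is_a[1:]))
    if len(cand) == 0:
        return []
    # uniqueness: neighbors on both sides share a strictly shorter prefix
    left_lcp = lcp[cand]            # LCP(sa[i-1], sa[i]); lcp[0] = 0
    right_lcp = np.zeros(len(cand), dtype=np.int64)
    inner = cand + 2 < n
    right_lcp[inner] = lcp[cand[inner] + 2]
    ok = (left_lcp < pair_lcp[cand]) & (right_lcp < pair_lcp[cand])
    out: list[tuple[int, int, int]] = []
    for i in cand[ok]:
        p, q = int(sa[i]), int(sa[i + 1])
        pa, pb = (p, q) if p < len_a else (q, p)
        length = int(pair_lcp[i])
        # left-maximality: preceding characters differ (or a boundary)
        if pa > 0 and pb > b_offset and codes[pa - 1] == codes[pb - 1]:
            continue
        out.append((pa, pb - b_offset, length))
    out.sort()
    return out


def merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open [start, end) intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)
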