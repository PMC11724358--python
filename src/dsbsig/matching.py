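"""Junctional sequence-matching rule shared by homology detection and
substitution verification.

A "match" of length L between two sequences means:

* every position below ``mismatch_free_len`` agrees exactly (N never matches);
* beyond that, mismatches are tolerated as long as the running identity of
  the compared prefix never drops below ``identity``;
* the match always ends on an agreeing position.

The reported length is the largest L satisfying all three conditions.
"""

from __future__ import annotations


def match_len(a: str, b: str, mismatch_free_len: int = 10,
              identity: float = 0.9) -> int:
    """Length of the prefix-to-prefix match between ``a`` and ``b``.

    Apply to reversed strings for suffix-to-suffix matching.
    """
    n = min(len(a), len(b))
    matches = 0
    best = 0
    for i in range(n):
        hit = a[i] == b[i] and a[i] != "N"
        if i < mismatch_free_len:
            if not hit:
                break
            matches += 1
            best = i + 1
            continue
        if hit:
            matches += 1
            if matches / (i + 1) >= identity:
                best = i + 1
        else:
            if matches / (i + 1) < identity:
                break
    return best


def prefix_suffix_containment(short: str, long: str,
                              mismatch_free_len: int = 10,
                              identity: float = 0.9) -> tuple[int, int] | None:
    """Check whether ``short`` is a prefix+suffix-preserving sub-sequence of ``long``.

    Returns ``(p, s)`` with ``p + s == len(short)`` — the split of ``short``
    into a prefix matching the start of ``long`` and a suffix matching its
    end — or None when no such split exists.  The split maximizes the prefix
    side for determinism.
    """
    p = match_len(short, long, mismatch_free_len, identity)
    s = match_len(short[::-1], long[::-1], mismatch_free_len, identity)
    if p + s < len(short):
        return None
    p_used = min(p, len(short))
    s_used = len(short) - p_used
    if s_used > s:  # cannot happen given p + s >= len(short), kept as guard
        return None
    return p_used, s_used
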