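"""Independent brute-force oracles used to freeze expected values.

These deliberately re-derive results along a different path than the
package: the homology oracle evaluates the matching rule for *every*
candidate length directly, and the tandem oracle enumerates all
(start, end) windows for every period.
"""

from __future__ import annotations

import numpy as np


def mh_pair_oracle(a: str, b: str, mismatch_free_len: int = 10,
                   identity: float = 0.9) -> int:
    """Largest L such that a[:L] matches b[:L] under the junction rule,
    evaluated exhaustively for every L."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    av = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    bv = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    match = (av == bv) & (av != ord("N"))
    cm = np.cumsum(match)
    L = np.arange(1, n + 1)
    exact_prefix = int(np.argmin(match)) if not match.all() else n
    # condition 1: all positions below min(L, mfl) agree exactly
    cond_exact = np.minimum(L, mismatch_free_len) <= exact_prefix
    # condition 2: running identity never below threshold for any j in [mfl, L]
    ident_ok = cm / L >= identity
    ident_ok[:min(mismatch_free_len - 1, n)] = True  # only binds from j = mfl
    cond_ident = np.logical_and.accumulate(ident_ok)
    # condition 3: ends on a match
    valid = cond_exact & cond_ident & match
    if not valid.any():
        return 0
    return int(L[valid].max())


def junction_mh_oracle(V: str, L: str, R: str, mismatch_free_len: int = 10,
                       identity: float = 0.9) -> int:
    """max(prefix(V) vs prefix(R), suffix(V) vs suffix(L))."""
    return max(mh_pair_oracle(V, R, mismatch_free_len, identity),
               mh_pair_oracle(V[::-1], L[::-1], mismatch_free_len, identity))


def tandem_verdict_oracle(seq: str, min_score: int = 50, max_period: int = 500,
                          min_identity: float = 0.8, match_w: int = 2,
                          mismatch_w: int = -5) -> bool:
    """True iff some window [i, j) at some period qualifies as a tandem
    array (>= 2 copies, identity/score thresholds), by exhaustive window
    enumeration."""
    n = len(seq)
    av = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(1, min(max_period, n // 2) + 1):
        m = (av[p:] == av[:-p]) & (av[p:] != ord("N")) & (av[:-p] != ord("N"))
        k = len(m)
        if k < p:
            continue
        cm = np.concatenate(([0], np.cumsum(m)))
        i_idx, j_idx = np.meshgrid(np.arange(k + 1), np.arange(k + 1),
                                   indexing="ij")
        length = j_idx - i_idx
        matches = cm[j_idx] - cm[i_idx]
        score = match_w * matches + mismatch_w * (length - matches)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(length > 0, matches / np.maximum(length, 1), 0.0)
        ok = (length >= p) & (score >= min_score) & (ident >= min_identity)
        if ok.any():
            return True
    return False


def best_alignment_oracle(flank: str, query: str, identity: float = 0.9,
                          coverage: float = 0.8) -> tuple[int, int] | None:
    """Best gapless local alignment of flank against query over all
    diagonals (exhaustive), honouring the +1/−2 scoring and the
    identity/coverage acceptance thresholds.  Returns (score, query_start)
    or None."""
    fv = np.frombuffer(flank.encode(), dtype=np.uint8)
    qv = np.frombuffer(query.encode(), dtype=np.uint8)
    nf, nq = len(fv), len(qv)
    best: tuple[int, int] | None = None
    for d in range(-nf + 1, nq):
        q0 = max(0, d)
        q1 = min(nq, d + nf)
        if q1 - q0 < 1:
            continue
        f0 = q0 - d
        m = (fv[f0:f0 + (q1 - q0)] == qv[q0:q1]) & \
            (qv[q0:q1] != ord("N")) & (fv[f0:f0 + (q1 - q0)] != ord("N"))
        s = np.where(m, 1, -2)
        c = np.concatenate(([0], np.cumsum(s)))
        runmin = np.minimum.accumulate(c[:-1])
        gains = c[1:] - runmin
        j = int(np.argmax(gains))
        score = int(gains[j])
        if score <= 0:
            continue
        i = int(np.argmin(c[:j + 1]))
        seg_len = j + 1 - i
        n_match = (score + 2 * seg_len) // 3
        if n_match / seg_len < identity or seg_len < coverage * nf:
            continue
        cand = (score, q0 + i)
        if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
    return best
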