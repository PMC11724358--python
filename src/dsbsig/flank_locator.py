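"""Locate variant flanking sequences in the query genome.

A hermetic seed-and-extend engine stands in for an external aligner: exact
k-mer seeds vote for diagonals, and each candidate diagonal is scored with a
gapless banded extension (match +1, mismatch −2).  Only the plus strand is
considered.  Gap penalties exist in the configuration for the optional
external-aligner adapter; the internal engine never opens gaps, which is
sufficient for chromosome-scale assemblies compared at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .io_formats import GenomeStore, encode_seq, N_CODE

log = logging.getLogger(__name__)


@dataclass
class FlankHit:
    """Best plus-strand local placement of one flank in the query genome.

    ``flank_start``/``flank_end`` give the aligned portion of the flank
    itself (0-based half-open, flank-local); clipped flank ends are what
    allow breakpoint recovery on miscalled variants.
    """

    query_chrom: str
    query_start: int
    query_end: int
    flank_start: int
    flank_end: int
    identity: float
    aligned_len: int
    score: int

    def __post_init__(self) -> None:
        assert self.query_start < self.query_end


RELATIONS = ("CONTIGUOUS", "SEPARATED", "OVERLAPPING", "DISCORDANT")


@dataclass
class FlankPair:
    left: FlankHit | None
    right: FlankHit | None
    relation: str
    separation: int  # right.query_start - left.query_end; 0 when DISCORDANT


class KmerIndex:
    """Sorted-kmer index of one chromosome for exact-seed lookup."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        n = len(codes)
        if n < k:
            self.sorted_kmers = np.empty(0, dtype=np.int64)
            self.order = np.empty(0, dtype=np.int64)
            return
        kmers = np.zeros(n - k + 1, dtype=np.int64)
        for j in range(k):
            kmers = kmers * 4 + codes[j:n - k + 1 + j]
        # windows containing N are invalidated
        has_n = np.convolve((codes == N_CODE).astype(np.int32),
                            np.ones(k, dtype=np.int32), mode="valid") > 0
        kmers[has_n] = -1
        self.order = np.argsort(kmers, kind="stable").astype(np.int64)
        self.sorted_kmers = kmers[self.order]

    def positions(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return self.order[lo:hi]


def _index_for(store: GenomeStore, chrom: str, k: int) -> KmerIndex:
    cache = getattr(store, "_kmer_cache", None)
    if cache is None:
        cache = {}
        store._kmer_cache = cache
    key = (chrom, k)
    idx = cache.get(key)
    if idx is None:
        idx = KmerIndex(store.codes(chrom), k)
        cache[key] = idx
    return idx


def extract_flanks(genome: GenomeStore, chrom: str, var_start: int,
                   var_end: int, flank_len: int) -> tuple[str, str]:
    """Reference sequences immediately left/right of [var_start, var_end).

    Flanks are truncated (never padded) at chromosome ends; truncation is
    logged.
    """
    n = genome.lengths[chrom]
    if not (0 <= var_start <= var_end <= n):
        raise ValueError(f"variant [{var_start},{var_end}) outside {chrom} (len {n})")
    left = genome.fetch(chrom, var_start - flank_len, var_start)
    right = genome.fetch(chrom, var_end, var_end + flank_len)
    if len(left) < flank_len or len(right) < flank_len:
        log.debug("flank truncated at %s:[%d,%d): left %d bp, right %d bp",
                  chrom, var_start, var_end, len(left), len(right))
    return left, right


def _best_segment(match: np.ndarray) -> tuple[int, int, int, int]:
    """Best-scoring contiguous segment under +1/−2 scoring.

    Returns (start, end, score, n_matches); score <= 0 means nothing usable.
    """
    s = np.where(match, 1, -2).astype(np.int64)
    c = np.concatenate(([0], np.cumsum(s)))
    runmin = np.minimum.accumulate(c[:-1])
    gains = c[1:] - runmin
    j = int(np.argmax(gains))
    score = int(gains[j])
    if score <= 0:
        return 0, 0, 0, 0
    i = int(np.argmin(c[:j + 1]))
    seg_len = (j + 1) - i
    n_match = (score + 2 * seg_len) // 3
    return i, j + 1, score, n_match


def locate_flank(query: GenomeStore, flank_seq: str, hint_chrom: str,
                 hint_window: tuple[int, int] | None = None,
                 cfg: RunConfig = DEFAULT_CONFIG) -> FlankHit | None:
    """Highest-scoring plus-strand placement of ``flank_seq`` in the query.

    Accepts hits with identity >= cfg.flank_identity over at least
    cfg.flank_coverage of the flank.  Ties are broken toward the smallest
    query_start, then the longest aligned length.  Returns None when nothing
    qualifies.
    """
    if len(flank_seq) < 50:
        raise ValueError("flank_seq shorter than 50 bp")
    if hint_chrom not in query.sequences:
        return None
    fcodes = encode_seq(flank_seq)
    qcodes = query.codes(hint_chrom)
    k = min(cfg.seed_kmer, len(flank_seq))
    idx = _index_for(query, hint_chrom, k)

    lo = hi = None
    if hint_window is not None:
        lo = max(0, hint_window[0])
        hi = min(len(qcodes), hint_window[1])

    offsets = list(range(0, len(fcodes) - k + 1, cfg.seed_stride))
    last = len(fcodes) - k
    if offsets and offsets[-1] != last:
        offsets.append(last)
    diag_chunks: list[np.ndarray] = []
    for o in offsets:
        window = fcodes[o:o + k]
        if (window == N_CODE).any():
            continue
        kmer = 0
        for c in window:
            kmer = kmer * 4 + int(c)
        pos = idx.positions(kmer)
        if lo is not None:
            pos = pos[(pos >= lo) & (pos < hi)]
        if pos.size:
            diag_chunks.append(pos - o)
    if not diag_chunks:
        return None
    diags, counts = np.unique(np.concatenate(diag_chunks), return_counts=True)

    # evaluate the most-voted diagonals; among equal votes, smallest first so
    # the query_start tie-break is honoured even when many diagonals tie
    order = np.lexsort((diags, -counts))
    cand = [int(d) for d in diags[order[:cfg.max_eval_diagonals]]]
    best: FlankHit | None = None
    flen = len(fcodes)
    for d in cand:
        q0 = max(0, d)
        q1 = min(len(qcodes), d + flen)
        if q1 - q0 < k:
            continue
        f0 = q0 - d
        fseg = fcodes[f0:f0 + (q1 - q0)]
        qseg = qcodes[q0:q1]
        match = (fseg == qseg) & (fseg != N_CODE) & (qseg != N_CODE)
        i, j, score, n_match = _best_segment(match)
        if score <= 0:
            continue
        seg_len = j - i
        identity = n_match / seg_len
        if identity < cfg.flank_identity or seg_len < cfg.flank_coverage * flen:
            continue
        hit = FlankHit(
            query_chrom=hint_chrom,
            query_start=q0 + i,
            query_end=q0 + j,
            flank_start=f0 + i,
            flank_end=f0 + j,
            identity=identity,
            aligned_len=seg_len,
            score=score,
        )
        if best is None or (hit.score, -hit.query_start, hit.aligned_len) > (
                best.score, -best.query_start, best.aligned_len):
            best = hit
    return best


def pair_flanks(left_hit: FlankHit | None, right_hit: FlankHit | None) -> FlankPair:
    """Relate two flank hits in query coordinates."""
    if left_hit is None or right_hit is None:
        return FlankPair(left_hit, right_hit, "DISCORDANT", 0)
    if left_hit.query_chrom != right_hit.query_chrom:
        return FlankPair(left_hit, right_hit, "DISCORDANT", 0)
    if right_hit.query_end < left_hit.query_start:
        return FlankPair(left_hit, right_hit, "DISCORDANT", 0)
    sep = right_hit.query_start - left_hit.query_end
    if sep == 0:
        rel = "CONTIGUOUS"
    elif sep > 0:
        rel = "SEPARATED"
    else:
        rel = "OVERLAPPING"
    return FlankPair(left_hit, right_hit, rel, sep)
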