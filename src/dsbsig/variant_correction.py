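"""Correct miscalled variants and classify them as INS/DEL/SUB/EXCEPTION.

The state machine: extract flanks around the called breakpoints, place both
in the query, trim overlapping inner ends up to three rounds, then apply the
three-way contiguity rule.  Clipped flank ends (see
:class:`~dsbsig.flank_locator.FlankHit`) shift the inferred inner breakpoints
in *both* genomes, which is what lets a shifted caller breakpoint resolve to
the true edit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import RunConfig, DEFAULT_CONFIG
from .flank_locator import extract_flanks, locate_flank, pair_flanks
from .io_formats import GenomeStore, RawVariantRecord
from .matching import prefix_suffix_containment

log = logging.getLogger(__name__)

CLASSES = ("INS", "DEL", "SUB", "EXCEPTION")


@dataclass
class CorrectedVariant:
    id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    klass: str
    trim_rounds_used: int = 0
    reason: str = ""

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start

    @property
    def var_len(self) -> int:
        return max(self.ref_len, self.query_len)


def _exception(raw: RawVariantRecord, reason: str, rounds: int = 0) -> CorrectedVariant:
    return CorrectedVariant(
        id=raw.id, ref_chrom=raw.chrom,
        ref_start=raw.pos, ref_end=raw.pos + raw.ref_span,
        query_chrom=raw.chrom, query_start=0, query_end=0,
        klass="EXCEPTION", trim_rounds_used=rounds, reason=reason,
    )


def correct_variant(raw: RawVariantRecord, ref: GenomeStore,
                    query: GenomeStore, cfg: RunConfig = DEFAULT_CONFIG) -> CorrectedVariant:
    """Run the correction state machine for one raw record."""
    chrom = raw.chrom
    if chrom not in ref.sequences:
        return _exception(raw, "unknown_ref_chrom")
    var_start = raw.pos
    var_end = raw.pos + raw.ref_span
    n = ref.lengths[chrom]
    if var_end > n:
        return _exception(raw, "outside_reference")

    left_inner, right_inner = var_start, var_end
    F = cfg.sv_find_len
    rounds = 0
    pair = None
    lhit = rhit = None
    lseq = rseq = ""
    while True:
        left_inner = max(0, left_inner)
        right_inner = min(n, right_inner)
        if left_inner > right_inner:
            return _exception(raw, "trimmed_past_variant", rounds)
        lseq, rseq = extract_flanks(ref, chrom, left_inner, right_inner, F)
        if len(lseq) < cfg.min_flank_len or len(rseq) < cfg.min_flank_len:
            return _exception(raw, "short_flank", rounds)
        lhit = locate_flank(query, lseq, chrom, cfg=cfg)
        rhit = locate_flank(query, rseq, chrom, cfg=cfg)
        pair = pair_flanks(lhit, rhit)
        if pair.relation == "DISCORDANT":
            return _exception(raw, "discordant_flanks", rounds)
        if pair.relation != "OVERLAPPING":
            break
        if rounds >= cfg.max_trim_rounds:
            return _exception(raw, "overlap_unresolved", rounds)
        trim = -pair.separation + 1  # overlap amount + 1 bp safety margin
        left_inner -= trim
        right_inner += trim
        rounds += 1

    # clip-aware inner breakpoints in the reference
    ref_left = (left_inner - len(lseq)) + lhit.flank_end
    ref_right = right_inner + rhit.flank_start
    q_left = lhit.query_end
    q_right = rhit.query_start
    ref_gap = ref_right - ref_left
    q_gap = q_right - q_left

    if ref_gap == 0 and q_gap == 0:
        return _exception(raw, "no_change", rounds)
    base = CorrectedVariant(
        id=raw.id, ref_chrom=chrom, ref_start=ref_left, ref_end=ref_right,
        query_chrom=lhit.query_chrom, query_start=q_left, query_end=q_right,
        klass="SUB", trim_rounds_used=rounds,
    )
    if ref_gap > 0 and q_gap == 0:
        base.klass = "DEL"
        base.query_end = base.query_start
        if base.ref_len < cfg.min_sv_size:
            return _exception(raw, "below_min_size", rounds)
        return base
    if ref_gap == 0 and q_gap > 0:
        base.klass = "INS"
        base.ref_end = base.ref_start
        if base.query_len < cfg.min_sv_size:
            return _exception(raw, "below_min_size", rounds)
        return base
    return verify_substitution(base, ref, query, cfg)


def verify_substitution(cand: CorrectedVariant, ref: GenomeStore,
                        query: GenomeStore, cfg: RunConfig = DEFAULT_CONFIG) -> CorrectedVariant:
    """Reclassify SUB candidates whose one substituted sequence contains the other."""
    if cand.klass != "SUB":
        return cand
    rseq = ref.fetch(cand.ref_chrom, cand.ref_start, cand.ref_end)
    qseq = query.fetch(cand.query_chrom, cand.query_start, cand.query_end)
    if rseq == qseq:
        cand.klass = "EXCEPTION"
        cand.reason = "no_change"
        log.debug("variant %s: identical substituted sequences (caller artifact)", cand.id)
        return cand
    if len(rseq) != len(qseq):
        short, long_ = (qseq, rseq) if len(qseq) < len(rseq) else (rseq, qseq)
        split = prefix_suffix_containment(short, long_,
                                          cfg.mismatch_free_len, cfg.hom_identity)
        if split is not None:
            p, s = split
            if len(rseq) > len(qseq):  # net deletion
                cand.klass = "DEL"
                cand.ref_start += p
                cand.ref_end -= s
                cand.query_start += p
                cand.query_end = cand.query_start
                if cand.ref_len < cfg.min_sv_size:
                    cand.klass = "EXCEPTION"
                    cand.reason = "below_min_size"
            else:  # net insertion
                cand.klass = "INS"
                cand.query_start += p
                cand.query_end -= s
                cand.ref_start += p
                cand.ref_end = cand.ref_start
                if cand.query_len < cfg.min_sv_size:
                    cand.klass = "EXCEPTION"
                    cand.reason = "below_min_size"
            return cand
    return cand


def tally_classes(variants: list[CorrectedVariant], repeats: int = 0) -> dict[str, int]:
    """Count variants by final class; REPEAT count is supplied by the filter."""
    counts = {"INS": 0, "DEL": 0, "SUB": 0, "REPEAT": repeats, "EXCEPTION": 0}
    for v in variants:
        counts[v.klass] += 1
    return counts


def apply_edit(variant: CorrectedVariant, ref: GenomeStore, query: GenomeStore,
               pad: int = 500) -> tuple[str, str]:
    """Locally apply the corrected edit to the reference and return
    (edited reference window, corresponding query window).

    Used by round-trip checks: for a correctly corrected variant the two
    strings are identical.
    """
    rchrom, qchrom = variant.ref_chrom, variant.query_chrom
    left = ref.fetch(rchrom, variant.ref_start - pad, variant.ref_start)
    right = ref.fetch(rchrom, variant.ref_end, variant.ref_end + pad)
    insert = query.fetch(qchrom, variant.query_start, variant.query_end)
    edited = left + insert + right
    qwin = query.fetch(qchrom, variant.query_start - len(left),
                       variant.query_end + len(right))
    return edited, qwin
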