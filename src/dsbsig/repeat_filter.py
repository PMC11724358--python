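"""Tandem-repeat screening of variants and their flanking sequences.

The internal detector mirrors the intent of a classic tandem-repeat finder
parameterized as match +2 / mismatch −5 / indel −7, min score 50, max period
500, min array identity 80%: arrays are found by self-comparison at every
candidate period (no indels within an array, which is adequate at desk
scale).  An optional hook lets callers plug in an external interspersed
repeat screen; when absent that screen is skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .io_formats import GenomeStore, RawVariantRecord, encode_seq, N_CODE
from .variant_correction import CorrectedVariant

log = logging.getLogger(__name__)

_warned_no_hook = False


@dataclass
class TandemArray:
    start: int
    end: int
    period: int
    copy_number: float
    percent_identity: float
    score: int


@dataclass
class RepeatVerdict:
    is_repetitive: bool
    kind: str  # TANDEM | INTERSPERSED | NONE
    period: int | None = None
    copy_number: float | None = None
    matched_fraction: float = 0.0


def find_tandem_repeats(seq: str, min_score: int | None = None,
                        max_period: int | None = None,
                        cfg: RunConfig = DEFAULT_CONFIG) -> list[TandemArray]:
    """Detect maximal tandem arrays (period <= max_period, >= 2 copies,
    >= 80% identity, score >= min_score under +2/−5 weights).

    Arrays whose period is a multiple of an already-reported overlapping
    array's period are suppressed (harmonics).  Results sorted by start.
    """
    if min_score is None:
        min_score = cfg.trf_min_score
    if max_period is None:
        max_period = cfg.trf_max_period
    n = len(seq)
    if n < 10:
        raise ValueError("sequence shorter than 10 bp")
    codes = encode_seq(seq)
    found: list[TandemArray] = []
    for p in range(1, min(max_period, n // 2) + 1):
        a, b = codes[p:], codes[:-p]
        match = (a == b) & (a != N_CODE) & (b != N_CODE)
        scores = np.where(match, cfg.trf_match, cfg.trf_mismatch).astype(np.int64)
        # greedy positive-run segmentation (Kadane-style)
        cur = 0
        seg_start = 0
        best_score = 0
        best_span: tuple[int, int] | None = None
        m = len(scores)

        def flush(i_end: int):
            nonlocal best_score, best_span
            if best_span is None:
                return
            i, j = best_span
            seg = match[i:j]
            n_match = int(seg.sum())
            seg_len = j - i
            if seg_len < p:  # need >= 2 copies
                best_score, best_span = 0, None
                return
            identity = n_match / seg_len
            score = cfg.trf_match * n_match + cfg.trf_mismatch * (seg_len - n_match)
            if score >= min_score and identity >= cfg.trf_min_identity:
                found.append(TandemArray(
                    start=i, end=j + p, period=p,
                    copy_number=(j + p - i) / p,
                    percent_identity=100.0 * identity,
                    score=int(score),
                ))
            best_score, best_span = 0, None

        for i in range(m):
            if cur <= 0:
                cur = 0
                seg_start = i
            cur += int(scores[i])
            if cur > best_score:
                best_score = cur
                best_span = (seg_start, i + 1)
            if cur <= 0:
                flush(i)
        flush(m)

    found.sort(key=lambda t: (t.period, t.start))
    kept: list[TandemArray] = []
    for arr in found:
        harmonic = False
        for k in kept:
            if arr.period % k.period == 0 and arr.period != k.period:
                ov = min(arr.end, k.end) - max(arr.start, k.start)
                if ov >= 0.9 * (arr.end - arr.start):
                    harmonic = True
                    break
        if not harmonic:
            kept.append(arr)
    kept.sort(key=lambda t: (t.start, t.period))
    return kept


def _screen_window(seq: str, cfg: RunConfig) -> RepeatVerdict:
    if len(seq) < 10:
        return RepeatVerdict(False, "NONE")
    arrays = find_tandem_repeats(seq, cfg=cfg)
    if not arrays:
        return RepeatVerdict(False, "NONE")
    covered = np.zeros(len(seq), dtype=bool)
    for a in arrays:
        covered[a.start:a.end] = True
    best = max(arrays, key=lambda a: a.score)
    return RepeatVerdict(True, "TANDEM", period=best.period,
                         copy_number=best.copy_number,
                         matched_fraction=float(covered.mean()))


InterspersedHook = Callable[[str], bool]


def _maybe_interspersed(seq: str, hook: InterspersedHook | None) -> RepeatVerdict | None:
    global _warned_no_hook
    if hook is None:
        if not _warned_no_hook:
            log.warning("no interspersed-repeat hook configured; "
                        "interspersed screening skipped")
            _warned_no_hook = True
        return None
    if hook(seq):
        return RepeatVerdict(True, "INTERSPERSED")
    return None


def repeat_screen_raw(raw: RawVariantRecord, ref: GenomeStore,
                      repeat_find_len: int | None = None,
                      cfg: RunConfig = DEFAULT_CONFIG,
                      interspersed_hook: InterspersedHook | None = None) -> RepeatVerdict:
    """First-pass screen on a raw VCF record: the variant sequence plus
    repeat_find_len bp of reference flank on each side."""
    rfl = cfg.repeat_find_len if repeat_find_len is None else repeat_find_len
    left = ref.fetch(raw.chrom, raw.pos - rfl, raw.pos)
    right = ref.fetch(raw.chrom, raw.pos + raw.ref_span,
                      raw.pos + raw.ref_span + rfl)
    for body in (raw.deleted_seq, raw.inserted_seq):
        if not body:
            continue
        verdict = _screen_window(left + body + right, cfg)
        if verdict.is_repetitive:
            return verdict
        hooked = _maybe_interspersed(left + body + right, interspersed_hook)
        if hooked is not None:
            return hooked
    return RepeatVerdict(False, "NONE")


def repeat_screen(variant: CorrectedVariant, ref: GenomeStore,
                  query: GenomeStore, repeat_find_len: int | None = None,
                  cfg: RunConfig = DEFAULT_CONFIG,
                  interspersed_hook: InterspersedHook | None = None) -> RepeatVerdict:
    """Screen a corrected variant: the variant sequence in the genome that
    carries it, plus repeat_find_len bp of flank on each side."""
    if variant.klass == "EXCEPTION":
        raise ValueError("repeat_screen requires a non-EXCEPTION variant")
    rfl = cfg.repeat_find_len if repeat_find_len is None else repeat_find_len
    windows: list[str] = []
    if variant.ref_len > 0:
        windows.append(
            ref.fetch(variant.ref_chrom, variant.ref_start - rfl,
                      variant.ref_end + rfl))
    if variant.query_len > 0:
        windows.append(
            query.fetch(variant.query_chrom, variant.query_start - rfl,
                        variant.query_end + rfl))
    for w in windows:
        verdict = _screen_window(w, cfg)
        if verdict.is_repetitive:
            return verdict
        hooked = _maybe_interspersed(w, interspersed_hook)
        if hooked is not None:
            return hooked
    return RepeatVerdict(False, "NONE")


def rescreen_corrected(variants: list[CorrectedVariant], ref: GenomeStore,
                       query: GenomeStore, cfg: RunConfig = DEFAULT_CONFIG,
                       ) -> tuple[list[CorrectedVariant], list[CorrectedVariant]]:
    """Second-pass screen on corrected coordinates.

    EXCEPTION variants are not screened and stay in the kept partition
    (their class is already terminal).  kept + repetitive == input.
    """
    kept: list[CorrectedVariant] = []
    repetitive: list[CorrectedVariant] = []
    for v in variants:
        if v.klass == "EXCEPTION":
            kept.append(v)
            continue
        if repeat_screen(v, ref, query, cfg=cfg).is_repetitive:
            repetitive.append(v)
        else:
            kept.append(v)
    return kept, repetitive


def parse_trf_dat(path: str) -> list[TandemArray]:
    """Parse the .dat output of an external tandem-repeat-finder run into
    the same TandemArray records the internal detector produces (adapter for
    the optional external route)."""
    arrays: list[TandemArray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 8 or not parts[0].isdigit():
                continue
            start, end = int(parts[0]) - 1, int(parts[1])
            period = int(parts[2])
            copy_number = float(parts[3])
            pct = float(parts[5])
            score = int(parts[7])
            arrays.append(TandemArray(start, end, period, copy_number, pct, score))
    return arrays
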