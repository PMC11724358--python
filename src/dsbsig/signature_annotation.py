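"""Detect repair signatures: junctional micro/homology for indels, templated
insertions for complex substitutions, tandem-duplication removal.

Micro/homology is computed by direct junctional string comparison (exact
below ``mismatch_free_len``, mismatch-tolerant above it) rather than by a
seed-based aligner: 1–2-bp microhomologies are below any aligner word size
but dominate the observed length distribution, so the junctional rule is the
only way to recover them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .io_formats import GenomeStore, encode_seq, N_CODE
from .matching import match_len
from .variant_correction import CorrectedVariant

log = logging.getLogger(__name__)

MECHANISMS = ("TMEJ", "SSA", "TEMPLATED_INS", "NO_SIGNATURE",
              "TANDEM_DUP", "NOT_DETERMINED")


@dataclass
class SignatureAnnotation:
    variant: CorrectedVariant
    mechanism: str
    hom_len: int = 0
    hom_seq: str = ""
    second_hom_len: int = 0
    template_source: tuple[str, int, int] | None = None


def _variant_context(variant: CorrectedVariant, ref: GenomeStore,
                     query: GenomeStore, window: int) -> tuple[str, str, str]:
    """(V, L, R): the inserted/deleted sequence and its 5'/3' context, all
    taken from the genome that carries the variant sequence."""
    if variant.klass == "DEL":
        g, chrom = ref, variant.ref_chrom
        vs, ve = variant.ref_start, variant.ref_end
    elif variant.klass == "INS":
        g, chrom = query, variant.query_chrom
        vs, ve = variant.query_start, variant.query_end
    else:
        raise ValueError(f"indel context undefined for class {variant.klass}")
    V = g.fetch(chrom, vs, ve)
    L = g.fetch(chrom, vs - window, vs)
    R = g.fetch(chrom, ve, ve + window)
    return V, L, R


def junction_microhomology(variant: CorrectedVariant, ref: GenomeStore,
                           query: GenomeStore,
                           cfg: RunConfig = DEFAULT_CONFIG) -> tuple[int, str]:
    """Micro/homology length and sequence at an indel junction.

    hom = max(match(prefix of V, prefix of R), match(suffix of V, suffix of L));
    ties go to the prefix side.  V is the inserted/deleted sequence, L/R its
    immediate context in the genome carrying V.
    """
    V, L, R = _variant_context(variant, ref, query, cfg.hom_window)
    h_pre = match_len(V, R, cfg.mismatch_free_len, cfg.hom_identity)
    h_suf = match_len(V[::-1], L[::-1], cfg.mismatch_free_len, cfg.hom_identity)
    if h_pre >= h_suf:
        return h_pre, V[:h_pre]
    return h_suf, V[len(V) - h_suf:]


def classify_indel(hom_len: int, baseline: int,
                   cfg: RunConfig = DEFAULT_CONFIG) -> str:
    """TMEJ/SSA/no-signature call from micro/homology length.

    hom < min_signal_len -> NO_SIGNATURE; min_signal_len..baseline
    (inclusive) -> TMEJ; above the baseline -> SSA.
    """
    if hom_len < cfg.min_signal_len:
        return "NO_SIGNATURE"
    if hom_len <= baseline:
        return "TMEJ"
    return "SSA"


def remove_tandem_duplications(annots: list[SignatureAnnotation],
                               cfg: RunConfig = DEFAULT_CONFIG,
                               ) -> tuple[list[SignatureAnnotation], list[SignatureAnnotation]]:
    """Split off annotations whose homology exceeds 90% of the variant size
    (strict inequality); those are relabelled TANDEM_DUP and excluded from
    mechanism statistics."""
    kept: list[SignatureAnnotation] = []
    dups: list[SignatureAnnotation] = []
    for a in annots:
        if a.variant.klass in ("INS", "DEL") and \
                a.hom_len > cfg.tandem_dup_frac * a.variant.var_len:
            a.mechanism = "TANDEM_DUP"
            dups.append(a)
        else:
            kept.append(a)
    return kept, dups


def _locate_template(Q: str, window: str, cfg: RunConfig) -> int | None:
    """Best gapless placement of Q inside window at >= template_identity;
    returns the window offset or None.  Ties go to the smallest offset."""
    nq, nw = len(Q), len(window)
    if nq == 0 or nw < nq:
        return None
    exact = window.find(Q)
    if exact >= 0:
        return exact
    qc = encode_seq(Q)
    wc = encode_seq(window)
    views = np.lib.stride_tricks.sliding_window_view(wc, nq)
    ok = (views == qc) & (views != N_CODE)
    identities = ok.mean(axis=1)
    best = int(np.argmax(identities))
    if identities[best] >= cfg.template_identity:
        ties = np.flatnonzero(identities == identities[best])
        return int(ties[0])
    return None


def detect_templated_insertion(variant: CorrectedVariant, ref: GenomeStore,
                               query: GenomeStore,
                               cfg: RunConfig = DEFAULT_CONFIG) -> SignatureAnnotation:
    """Annotate a complex substitution as a TMEJ templated insertion when

    (a) its query substituted sequence has a near-identical copy within
        ``template_window`` of the reference locus, and
    (b) micro/homology of >= 1 bp flanks both junctions, computed against
        the template's own context.
    """
    if variant.klass != "SUB":
        raise ValueError("templated-insertion detection requires a SUB variant")
    chrom = variant.ref_chrom
    Q = query.fetch(variant.query_chrom, variant.query_start, variant.query_end)
    win_start = max(0, variant.ref_start - cfg.template_window)
    win_end = variant.ref_end + cfg.template_window
    window = ref.fetch(chrom, win_start, win_end)
    no_sig = SignatureAnnotation(variant, "NO_SIGNATURE")
    if len(Q) < 10:
        return no_sig
    off = _locate_template(Q, window, cfg)
    if off is None:
        return no_sig
    t0 = win_start + off
    t1 = t0 + len(Q)
    w = cfg.hom_window
    L = ref.fetch(chrom, variant.ref_start - w, variant.ref_start)
    R = ref.fetch(chrom, variant.ref_end, variant.ref_end + w)
    ctx_l = ref.fetch(chrom, t0 - w, t0)
    ctx_r = ref.fetch(chrom, t1, t1 + w)
    m1 = match_len(L[::-1], ctx_l[::-1], cfg.mismatch_free_len, cfg.hom_identity)
    m2 = match_len(R, ctx_r, cfg.mismatch_free_len, cfg.hom_identity)
    if m1 >= 1 and m2 >= 1:
        return SignatureAnnotation(
            variant, "TEMPLATED_INS",
            hom_len=m1, hom_seq=L[len(L) - m1:], second_hom_len=m2,
            template_source=(chrom, t0, t1),
        )
    return no_sig


def annotate_variants(variants: list[CorrectedVariant], ref: GenomeStore,
                      query: GenomeStore, cfg: RunConfig = DEFAULT_CONFIG,
                      ) -> tuple[list[SignatureAnnotation], int]:
    """Annotate all non-EXCEPTION corrected variants and return
    (annotations, baseline used).

    Indels get their micro/homology measured first; the TMEJ/SSA baseline is
    then either the configured fixed value or derived from the pooled length
    histogram, and indels are classified against it.
    """
    from .mechanism_classifier import find_baseline, histogram_from_lengths

    annots: list[SignatureAnnotation] = []
    for v in variants:
        if v.klass in ("INS", "DEL"):
            hom, seq = junction_microhomology(v, ref, query, cfg)
            annots.append(SignatureAnnotation(v, "NOT_DETERMINED", hom, seq))
        elif v.klass == "SUB":
            annots.append(detect_templated_insertion(v, ref, query, cfg))

    kept, dups = remove_tandem_duplications(annots, cfg)

    if isinstance(cfg.baseline, int):
        baseline = cfg.baseline
    else:
        lengths = [a.hom_len for a in kept
                   if a.variant.klass in ("INS", "DEL") and a.hom_len >= cfg.min_signal_len]
        hist = histogram_from_lengths(lengths)
        try:
            baseline = find_baseline(hist, cfg.lowess_span, cfg.baseline_range)
        except ValueError:
            log.warning("baseline not derivable from data; falling back to 29")
            baseline = 29

    for a in kept:
        if a.variant.klass in ("INS", "DEL"):
            a.mechanism = classify_indel(a.hom_len, baseline, cfg)
    return kept + dups, baseline
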