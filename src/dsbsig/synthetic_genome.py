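"""Deterministic fixture generator.

Builds a random reference, plants mechanism-labelled edits (with forced
mismatch "guards" so the detectable homology equals the planted one
exactly), derives one or more query genomes by applying the edits, and
emits FASTA x2, a deliberately imperfect raw VCF and a truth table.

Miscall offsets shift the emitted VCF breakpoints into the flanking
sequence; offsets that would land strictly inside a planted homology tract
are avoided because the shifted call would be a genuinely equivalent
variant there, making the planted value unrecoverable in principle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeStore, write_fasta

MECHANISMS = ("TMEJ_DEL", "TMEJ_INS", "SSA_DEL", "TEMPLATED_INS",
              "NHEJ_LIKE", "TANDEM_DUP", "REPEAT_EMBEDDED")

GUARD = 8  # forced mismatches after each planted homology tract

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_REPEAT_UNITS = ("TA", "CAG", "AAG", "CAAT")


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _encode_str(s: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate("ACGTN")}
    return np.array([lut[c] for c in s], dtype=np.uint8)


def _trunc_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    for _ in range(10_000):
        x = int(rng.poisson(lam))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated Poisson rejection failed")


def _force_diff(rng: np.random.Generator, codes: np.ndarray, pos: int,
                avoid: int) -> None:
    """Set codes[pos] to a base different from ``avoid``."""
    if codes[pos] != avoid:
        return
    codes[pos] = (avoid + 1 + rng.integers(0, 3)) % 4


@dataclass
class PlantedEvent:
    id: str
    mechanism: str
    chrom: str
    ref_start: int
    ref_end: int            # == ref_start for pure insertions
    inserted: str           # "" for pure deletions
    planted_hom_len: int
    planted_hom_seq: str
    miscall_offset: int = 0
    queries: tuple[int, ...] = (0,)
    query_coords: dict = field(default_factory=dict)  # query idx -> (qs, qe)
    template_source: tuple[int, int] | None = None

    @property
    def del_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SyntheticBundle:
    ref: GenomeStore
    queries: list[GenomeStore]
    vcf_texts: list[str]
    truth: pd.DataFrame
    events: list[PlantedEvent]
    seed: int
    params: dict

    @property
    def query(self) -> GenomeStore:
        return self.queries[0]

    @property
    def vcf_text(self) -> str:
        return self.vcf_texts[0]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["ref"] = outdir / "ref.fa"
        write_fasta(self.ref, paths["ref"])
        for i, (q, vcf) in enumerate(zip(self.queries, self.vcf_texts)):
            suffix = "" if len(self.queries) == 1 else f"_{i}"
            paths[f"query{suffix}"] = outdir / f"query{suffix}.fa"
            write_fasta(q, paths[f"query{suffix}"])
            paths[f"vcf{suffix}"] = outdir / f"raw{suffix}.vcf"
            paths[f"vcf{suffix}"].write_text(vcf)
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["meta"] = outdir / "simulate_meta.json"
        paths["meta"].write_text(json.dumps(
            {"seed": self.seed, "params": self.params}, indent=2))
        return paths


def _slot_extra(mech: str, repeat_array_len: int) -> int:
    if mech == "REPEAT_EMBEDDED":
        return repeat_array_len + 2000
    if mech == "TEMPLATED_INS":
        return 1500
    if mech == "TANDEM_DUP":
        return 500
    return 0


def _plant_indel(rng, codes, s, mech):
    """Deletion with planted junctional homology m (prefix side)."""
    if mech == "TMEJ_DEL":
        m = _trunc_poisson(rng, 8, 2, 18)
        core = int(rng.integers(30, 121))
    elif mech == "SSA_DEL":
        m = _trunc_poisson(rng, 40, 30, 60)
        core = int(rng.integers(20, 151))
    else:  # NHEJ-like deletion
        m = int(rng.integers(0, 2))
        core = int(rng.integers(20, 81))
    d0, d1 = s, s + m + core
    if m:
        codes[d1:d1 + m] = codes[d0:d0 + m]
    for j in range(m, m + GUARD):
        _force_diff(rng, codes, d1 + j, int(codes[d0 + j]))
    for k in range(1, GUARD + 1):
        _force_diff(rng, codes, d1 - k, int(codes[d0 - k]))
    hom_seq = _decode(codes[d0:d0 + m])
    return d0, d1, "", m, hom_seq, None


def _plant_ins(rng, codes, s, mech, gc):
    if mech == "TMEJ_INS":
        m = _trunc_poisson(rng, 8, 2, 18)
        core = int(rng.integers(30, 121))
    else:  # NHEJ-like insertion
        m = int(rng.integers(0, 2))
        core = int(rng.integers(20, 81))
    i = s
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    V = np.concatenate([codes[i:i + m].copy(),
                        rng.choice(4, size=core, p=p).astype(np.uint8)])
    for j in range(m, m + GUARD):
        _force_diff(rng, V, j, int(codes[i + j]))
    for k in range(1, GUARD + 1):
        _force_diff(rng, V, len(V) - k, int(codes[i - k]))
    return i, i, _decode(V), m, _decode(V[:m]), None


def _plant_tandem_dup(rng, codes, s):
    L = int(rng.integers(150, 201))
    i = s
    V = codes[i - L:i].copy()
    for j in range(GUARD):  # keep the prefix-side junction signal at zero
        _force_diff(rng, codes, i + j, int(V[j]))
    return i, i, _decode(V), L, _decode(V), None


def _plant_templated_ins(rng, codes, s):
    dl = int(rng.integers(15, 41))
    tl = dl + int(rng.integers(15, 61))
    m1 = int(rng.integers(1, 9))
    m2 = int(rng.integers(1, 9))
    i, j = s, s + dl
    gap = int(rng.integers(150, 601))
    t0 = j + gap
    t1 = t0 + tl
    codes[t0 - m1:t0] = codes[i - m1:i]
    for k in range(m1 + 1, m1 + GUARD + 1):
        _force_diff(rng, codes, t0 - k, int(codes[i - k]))
    codes[t1:t1 + m2] = codes[j:j + m2]
    for x in range(m2, m2 + GUARD):
        _force_diff(rng, codes, t1 + x, int(codes[j + x]))
    # keep the substituted sequences from containing one another
    _force_diff(rng, codes, t0, int(codes[i]))
    _force_diff(rng, codes, t1 - 1, int(codes[j - 1]))
    Q = _decode(codes[t0:t1])
    return i, j, Q, m1, _decode(codes[i - m1:i]), (t0, t1)


def _plant_repeat_embedded(rng, codes, s, array_len):
    unit = _REPEAT_UNITS[int(rng.integers(0, len(_REPEAT_UNITS)))]
    u = _encode_str(unit)
    a0 = s - array_len // 2
    tiled = np.tile(u, array_len // len(u) + 1)[:array_len]
    codes[a0:a0 + array_len] = tiled
    del_len = 60  # divisible by every unit length used
    d0, d1 = s, s + del_len
    return d0, d1, "", 0, "", None


def generate(counts: dict[str, int], *, genome_len: int | None = None,
             n_chroms: int = 2, gc: float = 0.41, seed: int = 0,
             spacing: int = 5000, miscall_frac: float = 0.3,
             repeat_array_len: int = 600, n_queries: int = 1,
             share_frac: float = 1.0) -> SyntheticBundle:
    """Build a synthetic (reference, query genomes, raw VCF, truth) bundle.

    ``counts`` maps mechanism names (see MECHANISMS) to event counts.  All
    randomness derives from ``seed``; re-running with identical arguments is
    byte-identical.
    """
    for mech in counts:
        if mech not in MECHANISMS:
            raise ValueError(f"unknown mechanism: {mech}")
    rng = np.random.default_rng(seed)

    mech_list: list[str] = []
    for mech in MECHANISMS:
        mech_list.extend([mech] * counts.get(mech, 0))
    order = rng.permutation(len(mech_list))
    mech_list = [mech_list[i] for i in order]
    n_events = len(mech_list)
    if n_events == 0:
        ref = _random_genome(rng, ["chr1"], [20_000], gc)
        return _finalize(ref, [], n_queries, share_frac, rng, seed,
                         dict(counts=counts, gc=gc, spacing=spacing,
                              miscall_frac=miscall_frac))

    margin = 3000
    slots = [spacing + _slot_extra(m, repeat_array_len) for m in mech_list]
    n_chroms = max(1, min(n_chroms, n_events))
    per_chrom: list[list[int]] = [[] for _ in range(n_chroms)]
    for i in range(n_events):
        per_chrom[i % n_chroms].append(i)
    chrom_names = [f"chr{c + 1}" for c in range(n_chroms)]
    chrom_lens = [2 * margin + sum(slots[i] for i in idxs)
                  for idxs in per_chrom]
    if genome_len is not None and sum(chrom_lens) > genome_len:
        raise ValueError(
            f"events need {sum(chrom_lens)} bp but genome_len={genome_len}; "
            "overcrowded configuration")

    ref = _random_genome(rng, chrom_names, chrom_lens, gc)

    events: list[PlantedEvent] = []
    eid = 0
    for c, idxs in enumerate(per_chrom):
        codes = ref.codes(chrom_names[c])
        pos = margin
        for i in idxs:
            mech = mech_list[i]
            slot = slots[i]
            jitter = int(rng.integers(-200, 201))
            s = pos + slot // 2 + jitter
            if mech in ("TMEJ_DEL", "SSA_DEL"):
                planted = _plant_indel(rng, codes, s, mech)
            elif mech == "TMEJ_INS":
                planted = _plant_ins(rng, codes, s, mech, gc)
            elif mech == "NHEJ_LIKE":
                if rng.random() < 0.5:
                    planted = _plant_indel(rng, codes, s, mech)
                else:
                    planted = _plant_ins(rng, codes, s, mech, gc)
            elif mech == "TANDEM_DUP":
                planted = _plant_tandem_dup(rng, codes, s)
            elif mech == "TEMPLATED_INS":
                planted = _plant_templated_ins(rng, codes, s)
            elif mech == "REPEAT_EMBEDDED":
                planted = _plant_repeat_embedded(rng, codes, s, repeat_array_len)
            d0, d1, ins, m, hom_seq, template = planted
            events.append(PlantedEvent(
                id=f"ev{eid:05d}", mechanism=mech, chrom=chrom_names[c],
                ref_start=d0, ref_end=d1, inserted=ins,
                planted_hom_len=m, planted_hom_seq=hom_seq,
                template_source=template,
            ))
            eid += 1
            pos += slot
    # sequences were mutated in place; rebuild the string store
    for c in chrom_names:
        ref.sequences[c] = _decode(ref.codes(c))

    _assign_miscalls(rng, events, miscall_frac)

    return _finalize(ref, events, n_queries, share_frac, rng, seed,
                     dict(counts={m: counts.get(m, 0) for m in MECHANISMS},
                          gc=gc, spacing=spacing, miscall_frac=miscall_frac,
                          repeat_array_len=repeat_array_len,
                          n_queries=n_queries, share_frac=share_frac))


def _random_genome(rng, names, lens, gc) -> GenomeStore:
    store = GenomeStore()
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for name, n in zip(names, lens):
        codes = rng.choice(4, size=n, p=p).astype(np.uint8)
        store.add(name, _decode(codes))
        store._codes[name] = codes
    return store


def _assign_miscalls(rng, events: list[PlantedEvent], frac: float) -> None:
    """Shift a fraction of calls into the flanking sequence.

    Negative offsets move the call upstream (always recoverable); positive
    offsets are used only when they clear the planted homology tract and its
    guard bases, because a breakpoint inside the homology is genuinely
    ambiguous.
    """
    for ev in events:
        if ev.mechanism in ("REPEAT_EMBEDDED", "TEMPLATED_INS"):
            continue
        if rng.random() >= frac:
            continue
        m = ev.planted_hom_len
        lo_pos = m + GUARD + 1
        if rng.random() < 0.5 and lo_pos <= 30:
            ev.miscall_offset = int(rng.integers(lo_pos, 31))
        else:
            ev.miscall_offset = -int(rng.integers(1, 31))


def _finalize(ref, events, n_queries, share_frac, rng, seed, params
              ) -> SyntheticBundle:
    # event -> query assignment
    if n_queries > 1:
        for ev in events:
            if rng.random() < share_frac:
                ev.queries = tuple(range(n_queries))
            else:
                ev.queries = (int(rng.integers(0, n_queries)),)
    queries: list[GenomeStore] = []
    vcf_texts: list[str] = []
    for qi in range(n_queries):
        q, coords = _apply_events(ref, [e for e in events if qi in e.queries])
        for ev_id, (qs, qe) in coords.items():
            ev = next(e for e in events if e.id == ev_id)
            ev.query_coords[qi] = (qs, qe)
        queries.append(q)
        vcf_texts.append(_render_vcf(ref, [e for e in events if qi in e.queries]))

    rows = []
    for ev in events:
        for qi in sorted(ev.query_coords):
            qs, qe = ev.query_coords[qi]
            rows.append(dict(
                event_id=ev.id, query_genome=qi, mechanism=ev.mechanism,
                chrom=ev.chrom, ref_start=ev.ref_start, ref_end=ev.ref_end,
                query_start=qs, query_end=qe,
                planted_hom_len=ev.planted_hom_len,
                planted_hom_seq=ev.planted_hom_seq or ".",
                miscall_offset=ev.miscall_offset,
            ))
    truth = pd.DataFrame(
        rows, columns=["event_id", "query_genome", "mechanism", "chrom",
                       "ref_start", "ref_end", "query_start", "query_end",
                       "planted_hom_len", "planted_hom_seq", "miscall_offset"])
    return SyntheticBundle(ref=ref, queries=queries, vcf_texts=vcf_texts,
                           truth=truth, events=events, seed=seed, params=params)


def _apply_events(ref: GenomeStore, events: list[PlantedEvent]
                  ) -> tuple[GenomeStore, dict[str, tuple[int, int]]]:
    query = GenomeStore()
    coords: dict[str, tuple[int, int]] = {}
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, seq in ref.sequences.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda e: e.ref_start)
        parts: list[str] = []
        prev = 0
        out_len = 0
        for ev in evs:
            if ev.ref_start < prev:
                raise ValueError(f"overlapping events at {chrom}:{ev.ref_start}")
            parts.append(seq[prev:ev.ref_start])
            out_len += ev.ref_start - prev
            qs = out_len
            parts.append(ev.inserted)
            out_len += len(ev.inserted)
            coords[ev.id] = (qs, out_len)
            prev = ev.ref_end
        parts.append(seq[prev:])
        query.add(chrom, "".join(parts))
    return query, coords


def _render_vcf(ref: GenomeStore, events: list[PlantedEvent]) -> str:
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">']
    for chrom, n in ref.lengths.items():
        lines.append(f"##contig=<ID={chrom},length={n}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    recs = []
    for ev in events:
        off = ev.miscall_offset
        p0 = ev.ref_start - 1 + off  # 0-based anchor
        seq = ref.sequences[ev.chrom]
        dl = ev.del_len
        ref_allele = seq[p0:p0 + 1 + dl]
        alt_allele = seq[p0] + ev.inserted
        svtype = "INS" if len(alt_allele) > len(ref_allele) else "DEL"
        recs.append((ev.chrom, p0 + 1, ev.id, ref_allele, alt_allele, svtype))
    recs.sort(key=lambda r: (r[0], r[1], r[2]))
    for chrom, pos, vid, ra, aa, svtype in recs:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ra}\t{aa}\t.\tPASS\tSVTYPE={svtype}")
    return "\n".join(lines) + "\n"


EXPECTED_LABEL = {
    "TMEJ_DEL": "TMEJ", "TMEJ_INS": "TMEJ", "SSA_DEL": "SSA",
    "TEMPLATED_INS": "TEMPLATED_INS", "NHEJ_LIKE": "NO_SIGNATURE",
    "TANDEM_DUP": "TANDEM_DUP", "REPEAT_EMBEDDED": "REPEAT",
}


def truth_compare(truth: pd.DataFrame, annotations: pd.DataFrame,
                  classes: pd.DataFrame | None = None) -> dict:
    """Compare a truth table with pipeline annotations.

    ``annotations`` is the final TSV as a DataFrame (variant_id, mechanism,
    hom_len, ...); ``classes`` the correction-stage CSV (variant_id, class)
    used to resolve events that never reach annotation (REPEAT/EXCEPTION).
    Returns confusion matrix, per-mechanism recall, recovery rate over
    non-repetitive events, homology-length errors and boundary misses.
    """
    if "query_genome" in truth.columns:
        truth = truth[truth["query_genome"] == 0]
    ann_by_id = annotations.set_index("variant_id")
    cls_by_id = classes.set_index("variant_id")["class"] if classes is not None else None

    observed = {}
    hom_detected = {}
    for _, row in truth.iterrows():
        vid = row["event_id"]
        if vid in ann_by_id.index:
            observed[vid] = ann_by_id.loc[vid, "mechanism"]
            hom_detected[vid] = int(ann_by_id.loc[vid, "hom_len"])
        elif cls_by_id is not None and vid in cls_by_id.index:
            observed[vid] = cls_by_id.loc[vid]
        else:
            raise KeyError(f"event {vid} missing from annotations and classes")

    expected = {row["event_id"]: EXPECTED_LABEL[row["mechanism"]]
                for _, row in truth.iterrows()}
    df = pd.DataFrame({
        "expected": pd.Series(expected),
        "observed": pd.Series(observed),
    })
    confusion = pd.crosstab(df["expected"], df["observed"])

    non_rep = df[df["expected"] != "REPEAT"]
    recovery = float((non_rep["expected"] == non_rep["observed"]).mean()) \
        if len(non_rep) else 1.0
    repeat_rows = df[df["expected"] == "REPEAT"]
    repeat_removed = float((repeat_rows["observed"] == "REPEAT").mean()) \
        if len(repeat_rows) else 1.0

    hom_err = []
    boundary = 0
    for _, row in truth.iterrows():
        vid = row["event_id"]
        exp, obs = expected[vid], observed[vid]
        if exp in ("TMEJ", "SSA") and obs in ("TMEJ", "SSA"):
            err = abs(int(row["planted_hom_len"]) - hom_detected.get(vid, 0))
            hom_err.append(err)
            if exp != obs and err == 0:
                boundary += 1
    per_mech_recall = {
        mech: float((grp["expected"] == grp["observed"]).mean())
        for mech, grp in df.groupby("expected")
    }
    return {
        "confusion": confusion,
        "recovery": recovery,
        "repeat_removed": repeat_removed,
        "per_mechanism_recall": per_mech_recall,
        "hom_len_errors": hom_err,
        "boundary_misses": boundary,
        "n_events": len(df),
    }
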