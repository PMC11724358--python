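"""Readers/writers for FASTA, VCF, TSV, BED and CSV, plus the in-memory genome store.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
VCF convention is converted at this boundary and BED files are emitted
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID = set("ACGTN")

# nucleotide byte codes used by the alignment/repeat engines: A C G T -> 0..3, N -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
N_CODE = 4


def encode_seq(seq: str) -> np.ndarray:
    """Encode an uppercase A/C/G/T/N string as uint8 codes (N and anything else -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass
class GenomeStore:
    """Chromosome-keyed nucleotide sequences with coordinate accessors."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._codes: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); clamps to chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of a chromosome (A=0 C=1 G=2 T=3 N=4)."""
        arr = self._codes.get(chrom)
        if arr is None:
            arr = encode_seq(self.sequences[chrom])
            self._codes[chrom] = arr
        return arr

    def add(self, chrom: str, seq: str) -> None:
        if chrom in self.sequences:
            raise ValueError(f"duplicate chromosome name: {chrom!r}")
        if not seq:
            raise ValueError(f"empty sequence for chromosome {chrom!r}")
        self.sequences[chrom] = seq

    # pickling support for worker processes: drop the code cache
    def __getstate__(self):
        return {"sequences": self.sequences}

    def __setstate__(self, state):
        self.sequences = state["sequences"]
        self._codes = {}


@dataclass
class RawVariantRecord:
    """One VCF-derived candidate variant.

    ``pos`` is the 0-based reference coordinate of the first affected base
    (the base after the VCF anchor).  ``ref_allele``/``alt_allele`` keep the
    anchor base, exactly as read from the file.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    caller_type: str  # "INS" or "DEL"
    id: str

    @property
    def size(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def ref_span(self) -> int:
        """Reference bases affected beyond the anchor."""
        return len(self.ref_allele) - 1

    @property
    def inserted_seq(self) -> str:
        """ALT sequence beyond the anchor base."""
        return self.alt_allele[1:]

    @property
    def deleted_seq(self) -> str:
        """REF sequence beyond the anchor base."""
        return self.ref_allele[1:]


def normalize_seq(seq: str, name: str) -> str:
    """Uppercase and map IUPAC ambiguity codes other than N to N (logged)."""
    seq = seq.upper()
    if set(seq) - _VALID:
        bad = sorted(set(seq) - _VALID)
        log.warning(
            "record %s: mapping ambiguity codes %s to N", name, ",".join(bad)
        )
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> GenomeStore:
    """Load a (multi-)FASTA file into a :class:`GenomeStore`.

    Sequences are uppercased; non-ACGTN symbols become N with a warning.
    Duplicate record names or an empty file are hard errors.
    """
    store = GenomeStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        store.add(rec.id, normalize_seq(str(rec.seq), rec.id))
    if not store.sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return store


def write_fasta(store: GenomeStore, path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in store.sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    del width  # Bio.SeqIO wraps at 60 columns


def read_variant_vcf(path: str | Path, min_sv_size: int = 10) -> list[RawVariantRecord]:
    """Ingest a VCF 4.2 file with explicit REF/ALT sequences.

    Records whose allele-length difference is below ``min_sv_size`` are
    dropped; symbolic ALTs without sequence are skipped with a warning.
    Returned records are sorted by (chrom, pos).
    """
    import pysam

    records: list[RawVariantRecord] = []
    dropped = skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            alts = rec.alts or ()
            if not alts or alts[0] is None or alts[0].startswith("<") or "]" in alts[0] or "[" in alts[0]:
                log.warning("skipping symbolic/breakend record at %s:%s", rec.chrom, rec.pos)
                skipped += 1
                continue
            ref = rec.ref.upper()
            alt = alts[0].upper()
            if abs(len(ref) - len(alt)) < min_sv_size:
                dropped += 1
                continue
            caller_type = "INS" if len(alt) > len(ref) else "DEL"
            vid = rec.id if rec.id else f"var{i}"
            # rec.pos is 1-based anchor; first affected base (0-based) == rec.pos
            records.append(
                RawVariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    caller_type=caller_type,
                    id=vid,
                )
            )
    log.info(
        "VCF ingestion: %d retained, %d dropped (<%d bp), %d skipped",
        len(records), dropped, min_sv_size, skipped,
    )
    records.sort(key=lambda r: (r.chrom, r.pos, r.id))
    return records


TSV_COLUMNS = [
    "variant_id", "ref_chrom", "ref_start", "ref_end",
    "query_chrom", "query_start", "query_end",
    "variant_type", "mechanism", "hom_len", "hom_seq",
]

CSV_COLUMNS = ["variant_id", "class"]


def write_outputs(annotations: Iterable, class_rows: Iterable[tuple[str, str]],
                  prefix: str | Path) -> dict[str, Path]:
    """Write the final TSV/BED/CSV trio.

    ``annotations`` is an iterable of :class:`dsbsig.signature_annotation.SignatureAnnotation`;
    ``class_rows`` is (variant_id, correction-stage class) for every raw input
    variant.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    bed_path = prefix.with_suffix(".bed")
    csv_path = prefix.with_suffix(".csv")

    with open(tsv_path, "w") as tsv, open(bed_path, "w") as bed:
        tsv.write("\t".join(TSV_COLUMNS) + "\n")
        bed.write("#chrom\tstart\tend\thom_len\n")
        for ann in annotations:
            v = ann.variant
            tsv.write(
                "\t".join(
                    str(x) for x in (
                        v.id, v.ref_chrom, v.ref_start, v.ref_end,
                        v.query_chrom, v.query_start, v.query_end,
                        v.klass, ann.mechanism, ann.hom_len, ann.hom_seq or ".",
                    )
                ) + "\n"
            )
            bed.write(f"{v.ref_chrom}\t{v.ref_start}\t{v.ref_end}\t{ann.hom_len}\n")

    with open(csv_path, "w") as csv:
        csv.write(",".join(CSV_COLUMNS) + "\n")
        for vid, klass in class_rows:
            csv.write(f"{vid},{klass}\n")

    return {"tsv": tsv_path, "bed": bed_path, "csv": csv_path}
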