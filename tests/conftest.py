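from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dsbsig.config import RunConfig
from dsbsig.io_formats import GenomeStore, read_variant_vcf
from dsbsig.pipeline import run_pipeline
from dsbsig.synthetic_genome import generate

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.41) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def make_store(**chroms: str) -> GenomeStore:
    store = GenomeStore()
    for name, seq in chroms.items():
        store.add(name, seq)
    return store


def write_vcf(path, rows, contigs=None) -> None:
    """rows: (chrom, pos1, id, ref, alt)."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, ln in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={ln}>")
    if not contigs:
        chroms = {r[0] for r in rows}
        for chrom in sorted(chroms):
            lines.append(f"##contig=<ID={chrom},length=1000000>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, vid, ref, alt in rows:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(
        {"TMEJ_DEL": 10, "TMEJ_INS": 5, "SSA_DEL": 5, "NHEJ_LIKE": 5,
         "TEMPLATED_INS": 3, "TANDEM_DUP": 3, "REPEAT_EMBEDDED": 2},
        seed=7)


@pytest.fixture(scope="session")
def small_records(small_bundle, tmp_path_factory):
    vcf = tmp_path_factory.mktemp("vcf") / "raw.vcf"
    vcf.write_text(small_bundle.vcf_text)
    return read_variant_vcf(vcf)


@pytest.fixture(scope="session")
def small_run(small_bundle, small_records):
    return run_pipeline(small_bundle.ref, small_bundle.query,
                        records=small_records, cfg=RunConfig())


def annotations_frame(result) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variant_id": a.variant.id, "mechanism": a.mechanism,
          "hom_len": a.hom_len, "hom_seq": a.hom_seq} for a in result.annotations])


def classes_frame(result) -> pd.DataFrame:
    return pd.DataFrame(result.class_rows, columns=["variant_id", "class"])
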