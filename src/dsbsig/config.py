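"""Run configuration shared by every pipeline stage.

All knobs have the defaults used throughout the documentation; every field
is serialized into the run-metadata JSON so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    ``baseline`` is either the string ``"auto"`` (derive the TMEJ/SSA
    separation point from the data) or a fixed integer length in bp.
    """

    # flank search
    sv_find_len: int = 2000
    min_flank_len: int = 200
    min_sv_size: int = 10
    max_trim_rounds: int = 3
    flank_identity: float = 0.9
    flank_coverage: float = 0.8
    seed_kmer: int = 24
    seed_stride: int = 16
    max_eval_diagonals: int = 50
    hint_radius: int = 1_000_000

    # alignment scoring (match, mismatch, gap open, gap extend)
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -4
    gap_extend: int = -1

    # repeat screening
    repeat_find_len: int = 50
    trf_min_score: int = 50
    trf_max_period: int = 500
    trf_min_identity: float = 0.8
    trf_match: int = 2
    trf_mismatch: int = -5
    trf_indel: int = -7

    # signature detection
    min_signal_len: int = 2
    hom_window: int = 200
    mismatch_free_len: int = 10
    hom_identity: float = 0.9
    template_window: int = 2000
    template_identity: float = 0.9
    template_coverage: float = 0.9
    tandem_dup_frac: float = 0.9
    baseline: int | str = "auto"

    # mechanism classification
    lambda_tmej_box: tuple[float, float] = (5.0, 20.0)
    lambda_ssa_box: tuple[float, float] = (37.0, 50.0)
    baseline_range: tuple[int, int] = (10, 60)
    lowess_span: float = 0.3
    density_window: int = 1_000_000

    # execution
    seed: int = 0
    workers: int = 1
    low_memory: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


DEFAULT_CONFIG = RunConfig()
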