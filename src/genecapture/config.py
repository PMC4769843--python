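"""Run configuration: every tunable threshold in one round-trippable object."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Thresholds and seeds for a full pipeline run.

    Defaults reflect same-species capture data: contig/seed alignments are
    kept at >= 90 % identity over >= 30 nt, tilings tolerate 15 nt of
    cross-contig overlap on the seed, promoter candidates need 100 nt of
    upstream sequence reaching codon 10 or earlier, and probes are 120-mers
    stepped 19/29 nt.
    """

    min_identity: float = 0.90
    min_hsp_len: int = 30
    word_size: int = 11
    ambiguity_ratio: float = 0.90
    overlap_tolerance_nt: int = 15
    max_states: int = 200_000
    min_intron: int = 20
    min_upstream: int = 100
    max_codon: int = 10
    probe_len: int = 120
    step_first: int = 19
    step_rest: int = 29
    rng_seed: int = 0

    def to_file(self, path: str | Path) -> None:
        lines = [f"{name}={getattr(self, name)}" for name in sorted(asdict(self))]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            kwargs[key] = type(default)(float(value)) if isinstance(default, (int, float)) else value
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        payload = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
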