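"""Pipeline configuration: every tunable threshold, with the study defaults.

The on-disk format is flat ``key = value`` lines (INI-style without
sections, ``#`` comments allowed) so the canonical serialization — and
therefore the provenance hash stamped into every output — is bit-exact.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class PipelineConfig:
    seed: int = 0
    # quantify
    min_identity: float = 0.90
    downstream_window: int = 1000
    min_reads: int = 3
    raw_list_scope: str = "any"
    # deg
    q: float = 0.8
    nss: int = 5
    pnr: float = 0.2
    v: float = 0.02
    pseudocount: float = 0.5
    # cluster
    k: int = 5
    restarts: int = 25
    epsilon: float = 0.01
    flat_ratio: float = 1.25
    # enrich
    min_blast: float = 300.0
    min_fc: float = 1.5
    min_pathway_degs: int = 10
    ecm_min_reads: int = 100
    # simulation sizing
    n_contigs: int = 6
    contig_length: int = 60000
    n_genes: int = 40
    reads_per_library: int = 6000
    read_length: int = 100

    def validate(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ConfigError("min_identity must be in [0, 1]")
        if not (0.0 < self.q < 1.0):
            raise ConfigError("q must be in (0, 1)")
        if not (0.0 < self.pnr <= 1.0):
            raise ConfigError("pnr must be in (0, 1]")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.k < 1 or self.nss < 2:
            raise ConfigError("k must be >= 1 and nss >= 2")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        casts = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                values[key] = casts[key](val)
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
        cfg = cls(**values)
        cfg.validate()
        return cfg
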