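"""Run configuration: every pipeline tunable with its default.

Defaults follow the published analysis parameters where the source
states them (expectation <= 3, top 200 targets, upsize 20, site flanks
17/13, central-mismatch range 9-11, MFE bound -20 kcal/mol, e-value
1e-5, co-expression weights 0.4/0.3/0.3, k = 20). The configuration is
serialized verbatim into every output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # miRNA discovery
    evalue_cutoff: float = 1e-5
    max_mismatches: int = 4
    flank: int = 120
    mfe_threshold: float = -20.0
    max_duplex_mismatches: int = 7
    min_stem_pairs: int = 12
    fold_backend: str = "builtin"  # builtin | command
    fold_command: str = ""
    # target prediction
    max_expectation: float = 3.0
    top_n: int = 200
    upsize: int = 20
    core_double: bool = True
    central_range: tuple = (9, 11)
    flank_up: int = 17
    flank_down: int = 13
    upe_enabled: bool = False
    max_upe: float = 25.0
    # GO network
    alpha: float = 0.6
    namespace: str = "BP"
    min_score: float = 0.0
    cluster_tolerance: float = 1e-9
    # co-expression
    weights: tuple = (0.4, 0.3, 0.3)
    k: int = 20
    # simulation / misc
    seed: int = 42

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["central_range"] = list(self.central_range)
        out["weights"] = list(self.weights)
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "central_range" in kwargs:
            kwargs["central_range"] = tuple(kwargs["central_range"])
        if "weights" in kwargs:
            kwargs["weights"] = tuple(kwargs["weights"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def overridden(self, **kwargs) -> "RunConfig":
        """Copy with the given fields replaced (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
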