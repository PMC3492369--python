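"""Run configuration for the command-line front end."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .network import PAIRS

#: default significance threshold on the -log10 scale: -log10(0.05).
#: (A threshold of 2.0 — i.e. p = 0.01 — is common in practice and can be
#: configured; see the methods note on the threshold convention.)
DEFAULT_THRESHOLD = -math.log10(0.05)


@dataclass
class RunConfig:
    chem_gene: Optional[str] = None
    gene_disease: Optional[str] = None
    chem_disease: Optional[str] = None
    dialect: str = PAIRS
    n_override: Optional[int] = None
    n_tests_override: Optional[int] = None
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    out_dir: str = "."
    export_columns: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        for name in ("n_override", "n_tests_override"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise ValueError(f"{name} must be positive when present")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path), "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
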