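"""Run configuration: one structured file driving a whole analysis.

The config is plain YAML with the fields below; it round-trips exactly
(write-then-read identity) and every pipeline run copies its resolved
config, the package version and the seed into the output directory for
provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # inputs
    tree: str | None = None
    species_table: str | None = None
    individual_table: str | None = None
    # column mapping
    species_col: str = "species"
    focal_a: str = "log_A"
    focal_b: str = "log_B"
    control: str = "log_size"
    raw_a: str = "A"                 # raw-scale columns for ratio diagnostics
    raw_b: str = "B"
    log_cols: list = field(default_factory=list)
    # engine options
    engine: str = "pgls"             # "ols" | "pgls"
    lambda_mode: str | float = "ml"
    log_base: float = 10.0
    species_fixed: bool = False
    # thresholds
    alpha: float = 0.05
    min_shift: float = 0.1
    # output
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.engine not in ("ols", "pgls"):
            raise ValueError(f"engine must be 'ols' or 'pgls', got "
                             f"{self.engine!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_columns(self, table) -> None:
        """Fail early if any referenced column is absent from the table."""
        need = [self.focal_a, self.focal_b, self.control]
        missing = [c for c in need if c not in table.data.columns]
        if missing:
            raise KeyError(f"columns {missing} not found in table "
                           f"(have {table.trait_columns()})")
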