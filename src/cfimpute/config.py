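"""Run configuration: every tunable of the imputation pipeline in one
validated, serializable record."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class RunConfig:
    mode: str = "diploid"          # "diploid" | "nipt"
    ff: float | None = None        # fetal fraction, required in nipt mode
    K: int = 40                    # conditioning haplotypes
    min_match_grids: int = 2       # msPBWT match-length filter
    scan_L: int = 8                # neighbours kept per grid in the up/down scan
    maf_threshold: float = 0.01    # common/rare split (folded MAF)
    n_outer: int = 3               # stage-1 refresh iterations
    sweeps: int = 30               # Gibbs sweeps per stage-1 iteration
    burn_in: int = 10              # stage-2 burn-in sweeps
    n_sample: int = 20             # stage-2 sweeps averaged into dosages
    n_chains: int = 3              # independent stage-1 chains (anti-sticking)
    n_gen: float = 100.0           # recombination scaling (effective generations)
    seed: int = 1
    min_mapq: int = 10
    min_baseq: int = 10

    def __post_init__(self):
        if self.mode not in ("diploid", "nipt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nipt" and self.ff is None:
            raise ValueError("nipt mode requires ff (fetal fraction)")
        if self.ff is not None and not 0.0 <= self.ff <= 1.0:
            raise ValueError("ff must be in [0, 1]")
        for name in ("K", "min_match_grids", "scan_L", "n_outer", "sweeps",
                     "burn_in", "n_sample", "n_chains"):
            if getattr(self, name) < 1 and name not in ("burn_in",):
                raise ValueError(f"{name} must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a flat key/value config file; unknown keys are rejected and
        keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
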