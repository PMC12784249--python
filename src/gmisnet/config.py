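"""Run-time parameters for the MILP enumerators and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class MilpParams:
    """Constants and limits of the intervention-enumeration MILPs.

    alpha/M are the small/large constants linking the binary cut indicators
    to the dual variables (alpha*z <= v <= M*z); target_flux (r*) is the flux
    demanded through the target's ON exchange; c forces the target dual to be
    strictly nonzero.  time_limit_per_solution mirrors the 5-minute budget
    used for each enumerated solution on large models.
    """

    alpha: float = 1e-3
    M: float = 1e3
    target_flux: float = 1.0
    c: float = 1e-3
    max_size: int = 5
    max_solutions: int = 1000
    time_limit_per_solution: float = 300.0
    solver: str = "highs"
    seed: int = 0
    tolerance: float = 1e-6
    allow_ki: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < self.M:
            raise ValueError("require 0 < alpha < M")
        if self.target_flux <= 0 or self.c <= 0:
            raise ValueError("target_flux and c must be positive")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (mirrors the CLI flags)."""

    model_path: Path
    layer_paths: list[Path] = field(default_factory=list)
    depth: int = 1
    max_length: int = 5
    gf_row_cap: int = 5
    milp: MilpParams = field(default_factory=MilpParams)
    expression_path: Path | None = None
    output_dir: Path = Path("gmisnet-out")
    seed: int = 0
    combination_strategy: str = "disjunctive"
    allow_ki: bool = True
    expression_threshold: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.depth > 2:
            raise ValueError("regulatory depth is limited to 2")
        if self.max_length < 1 or self.gf_row_cap < 1:
            raise ValueError("length caps must be >= 1")
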