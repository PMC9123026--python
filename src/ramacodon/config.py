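"""Run configuration: statistical parameters shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Statistical parameters of the full analysis.

    Defaults are the values used for all reported comparisons: a 2-degree
    Gaussian kernel on a 128 x 128 torus grid, equalized sample sizes capped
    at N_max = 200, B = 25 bootstrap rounds of K = 200 permutations each
    (5000 permutations per p-value), FDR level q = 0.05, redundancy
    threshold tau = 0.7, and B = 1000 bootstraps for the plot confidence
    bands.
    """

    bandwidth: float = 2.0
    grid_size: int = 128
    n_max: int = 200
    b_test: int = 25
    k_perm: int = 200
    b_plot: int = 1000
    q: float = 0.05
    tau: float = 0.7
    seed: int = 0
    bh_mode: str = "literal"  # "literal" (reject p < alpha_M) or "textbook"

    def __post_init__(self):
        if min(self.bandwidth, self.grid_size, self.n_max, self.b_test,
               self.k_perm, self.b_plot) <= 0:
            raise ValueError("all sizes and scales must be positive")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.bh_mode not in ("literal", "textbook"):
            raise ValueError("bh_mode must be 'literal' or 'textbook'")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def header_lines(self) -> list[str]:
        """Config echo written into every output file header."""
        return [f"# {k} = {v}" for k, v in self.to_dict().items()]


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
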