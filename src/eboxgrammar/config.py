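"""Run configuration: every numeric parameter of the pipeline, with the
study defaults, plus validation and resolved-config provenance."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # randomness
    seed: int = 0
    # trajectory classification
    invariant_p: float = 1e-6
    pseudobulk_group_size: int = 175
    expr_group_size: int = 50
    accessible_min_frac: float = 0.03
    quantile_bins: int = 50
    # motif grammar
    centrality_near_halfwidth: int = 50
    centrality_distal_start: int = 250
    centrality_distal_end: int = 750
    per_peak_near_halfwidth: int = 100
    per_peak_distal_threshold: int = 200
    spacing_max_gap: int = 30
    score_bins: int = 10
    window_fraction: float = 0.4
    resize_width: int = 1500
    # methylation
    meth_flank: int = 1000
    meth_bin: int = 10
    delta_halfwidth: int = 5
    # conservation
    maf_min: float = 0.05
    pss_halfwidth: int = 50
    nss_range: tuple[int, int] = (200, 400)
    mk_subsets: int = 100
    # io
    inputs: dict = field(default_factory=dict)
    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        if self.nss_range[0] >= self.nss_range[1]:
            raise ValueError(f"nss_range must be increasing, got {self.nss_range}")
        if self.nss_range[0] <= self.pss_halfwidth:
            raise ValueError("NSS window must start beyond the PSS window")
        if self.centrality_distal_start <= self.centrality_near_halfwidth:
            raise ValueError("distal window must start beyond the near window")
        if not 0 < self.invariant_p < 1:
            raise ValueError("invariant_p must be in (0, 1)")
        if not 0 <= self.accessible_min_frac <= 1:
            raise ValueError("accessible_min_frac must be in [0, 1]")
        for name in ("pseudobulk_group_size", "expr_group_size",
                     "quantile_bins", "score_bins", "mk_subsets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for role, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input role {role!r}: {path} not found")
        return self

    def dump(self, path) -> None:
        """Write the resolved configuration next to the outputs."""
        d = dataclasses.asdict(self)
        d["nss_range"] = list(self.nss_range)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_config(path=None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "nss_range" in data:
        data["nss_range"] = tuple(data["nss_range"])
    cfg = RunConfig(**data)
    return cfg.validate()
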