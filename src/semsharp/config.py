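"""Pipeline configuration: every tunable constant in one (de)serializable place."""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional, Union

from .mlv import DEFAULT_SPARSITY_MODE, SparsityMode


@dataclasses.dataclass
class PipelineConfig:
    """All constants of the scoring pipeline with their shipped defaults.

    Attributes
    ----------
    sigma
        Gaussian scale of the cartoon-texture filter (pixels).
    a1, a2
        Soft-threshold knees on the LTV reduction rate.
    block_size, step
        Analysis-block geometry of the sharpness maps (pixels).
    tau1, tau2
        Slope-to-S1 sigmoid parameters.
    mu
        Spectral/spatial fusion exponent.
    pool_fraction
        Fraction of top S3 blocks averaged into S.
    edge_threshold_fraction
        Relative edge-response threshold on the MLV map.
    sparsity_mode
        Reading of edge sparsity ("width" or "spacing"); the default is the
        mode calibrated to decrease monotonically with blur.
    eta
        Weight of the S term in the final fusion Q.
    max_s_ref, max_d_ref
        Optional fixed normalizers for reproducible single-image scoring;
        when None, batch maxima are used.
    """

    sigma: float = 3.0
    a1: float = 0.25
    a2: float = 0.5
    block_size: int = 32
    step: int = 16
    tau1: float = -3.0
    tau2: float = 2.0
    mu: float = 0.5
    pool_fraction: float = 0.01
    edge_threshold_fraction: float = 0.1
    sparsity_mode: SparsityMode = DEFAULT_SPARSITY_MODE
    eta: float = 0.3
    max_s_ref: Optional[float] = None
    max_d_ref: Optional[float] = None

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: Union[str, os.PathLike]) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
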