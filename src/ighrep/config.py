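"""Pipeline configuration: every tunable constant in one serializable object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import yaml

from .align import AlignParams


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants, with the protocol's fixed values as defaults.

    ``subsample_depth`` = 4,000 aligned consensus molecules (samples below it
    are discarded), ``abs_threshold`` = 0.023 ABS units for a positive
    rejection call, ``cfddna_threshold`` = 1.0% donor DNA for the comparator
    label. ``mutated_igm_min_rate`` is the V mutation rate at or above which
    an IgM molecule counts as mutated (the assay itself does not pin this
    constant; 0.01 is the package default).
    """

    uid_len_each: int = 8
    max_primer_mismatches: int = 2
    aligner: AlignParams = field(default_factory=AlignParams)
    mutated_igm_min_rate: float = 0.01
    subsample_depth: int = 4000
    highly_expressed_min: int = 2
    abs_threshold: float = 0.023
    cfddna_threshold: float = 1.0
    bootstrap_reps: int = 2000
    bootstrap_seed: int = 0
    #: days relative to the first rejection event pooled into the pre-/post fits
    pre_window_days: Tuple[int, int] = (-120, 0)
    post_window_days: Tuple[int, int] = (0, 90)
    seed: int = 0

    def validate(self) -> None:
        if min(self.uid_len_each, self.subsample_depth, self.highly_expressed_min) < 1:
            raise ValueError("counts must be positive")
        if self.max_primer_mismatches < 0 or self.bootstrap_reps < 1:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.mutated_igm_min_rate <= 1.0:
            raise ValueError("mutated_igm_min_rate must be in [0, 1]")
        if not 0.0 <= self.aligner.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.abs_threshold < 0 or self.cfddna_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pre_window_days"] = list(self.pre_window_days)
        d["post_window_days"] = list(self.post_window_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "aligner" in d and isinstance(d["aligner"], dict):
            d["aligner"] = AlignParams(**d["aligner"])
        for key in ("pre_window_days", "post_window_days"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as h:
            yaml.safe_dump(self.to_dict(), h, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as h:
            return cls.from_dict(yaml.safe_load(h))

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
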