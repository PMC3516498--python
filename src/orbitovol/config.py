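"""Measurement-protocol configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ValidationError


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of the slice-measurement and comparison protocol.

    Defaults follow the published protocol: five coronal slices at 4.8 mm
    ventrodorsal intervals from the orbital frame toward the apex, areas
    measured by 3 raters x 3 repeats, paired t-tests at alpha = 0.05.

    ``frame_offset_mm`` shifts slice 1 relative to the canonical frame
    plane (y = 0 after alignment); the default places slice 1 exactly at
    the frame plane.
    """

    n_slices: int = 5
    interval_mm: float = 4.8
    alpha: float = 0.05
    bone_threshold: float | str = "auto"
    max_gap_mm: float = 10.0
    n_raters: int = 3
    n_repeats: int = 3
    frame_offset_mm: float = 0.0

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if self.interval_mm <= 0:
            raise ValidationError("interval_mm must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.max_gap_mm <= 0:
            raise ValidationError("max_gap_mm must be > 0")
        if isinstance(self.bone_threshold, str) and self.bone_threshold != "auto":
            raise ValidationError("bone_threshold must be a number or 'auto'")
        if self.n_raters < 1 or self.n_repeats < 1:
            raise ValidationError("n_raters and n_repeats must be >= 1")

    def slice_positions(self):
        """World-y positions (mm) of the slice planes, slice 1 first."""
        return [
            self.frame_offset_mm - k * self.interval_mm for k in range(self.n_slices)
        ]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "ProtocolConfig":
        return cls(**json.loads(Path(path).read_text()))
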