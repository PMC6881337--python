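"""The aligned dual-energy image pair shared by the simulator and decomposition."""

from __future__ import annotations

from dataclasses import dataclass

from .images import HUImage


@dataclass
class DECTPair:
    """Co-registered low-energy and high-energy HU images from one acquisition."""

    low: HUImage
    high: HUImage
    physics_name: str = ""

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape:
            raise ValueError("low and high images must share one shape")
        if (self.low.subject_id, self.low.slice_id) != (self.high.subject_id, self.high.slice_id):
            raise ValueError("low and high images must share subject/slice identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.low.shape
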