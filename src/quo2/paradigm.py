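"""Respiratory gas paradigm: timed hypercapnia and hyperoxia blocks.

The default schedule is the 18-minute interleaved protocol: two 2-min
hypercapnic blocks and two 3-min hyperoxic blocks, each hypercapnic block
followed by at least one minute of normocapnia before the next hyperoxic
block, and each hyperoxic block followed by three minutes of normoxia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

Block = Tuple[float, float]  # (onset s, duration s)


@dataclass(frozen=True)
class GasParadigm:
    """Block timing of the gas challenges within one functional run."""

    total_duration: float  # s
    hc_blocks: Tuple[Block, ...] = field(default_factory=tuple)
    ho_blocks: Tuple[Block, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hc_blocks", tuple(tuple(map(float, b)) for b in self.hc_blocks))
        object.__setattr__(self, "ho_blocks", tuple(tuple(map(float, b)) for b in self.ho_blocks))
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        blocks = sorted(self.hc_blocks + self.ho_blocks)
        for onset, dur in blocks:
            if dur <= 0 or onset < 0 or onset + dur > self.total_duration:
                raise ValueError(f"block ({onset}, {dur}) outside [0, {self.total_duration}]")
        for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
            if o1 + d1 > o2:
                raise ValueError("gas blocks overlap")

    @property
    def all_blocks(self) -> Tuple[Block, ...]:
        return tuple(sorted(self.hc_blocks + self.ho_blocks))


def make_default_paradigm() -> GasParadigm:
    """The 18-minute alternating HC/HO schedule (1080 s total).

    HC at 0 and 540 s (120 s each), HO at 180 and 720 s (180 s each); the
    stated block and rest durations fill the run exactly, so the first
    hypercapnic block starts at t = 0 and baselines are identified from the
    normocapnic/normoxic rests.
    """
    return GasParadigm(
        total_duration=1080.0,
        hc_blocks=((0.0, 120.0), (540.0, 120.0)),
        ho_blocks=((180.0, 180.0), (720.0, 180.0)),
    )
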