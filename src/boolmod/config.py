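"""Run configuration shared by CLI commands and batch scripts."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .network import DEFAULT_ENUMERATION_CAP


@dataclass(frozen=True)
class RunConfig:
    """Bundled knobs for a control-analysis run.

    cap            exhaustive-enumeration cap, in bits
    kinds          control kinds searched: "node", "edge" or "both"
    allow_negation permit the rule-negating node control (mu-, mu+) = (1, 1)
    max_size       largest control-set cardinality searched
    seed           seed for every stochastic step; recorded in all outputs
    """

    cap: int = DEFAULT_ENUMERATION_CAP
    kinds: str = "both"
    allow_negation: bool = False
    max_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.cap < 1:
            raise ValueError("enumeration cap must be positive")
        if self.max_size < 0:
            raise ValueError("max control size must be >= 0")
        if self.kinds not in ("node", "edge", "both"):
            raise ValueError(f"kinds must be 'node', 'edge' or 'both', got {self.kinds!r}")

    def as_dict(self) -> dict:
        return asdict(self)
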