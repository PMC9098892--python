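"""Run configuration: session schedule, detection and bootstrap parameters.

Sessions are opaque ordered labels supplied by the user (never sorted
lexically), so both a fixed 3-day imaging schedule and irregular schedules
are representable. One global seed expands into per-module child seeds via
:func:`plasticity._util.child_seed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._util import child_seed

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    session_order: list[str] = field(
        default_factory=lambda: ["B1", "B2", "3d", "6d", "9d", "12d", "15d", "18d"]
    )
    baseline_sessions: list[str] = field(default_factory=lambda: ["B1", "B2"])
    persistence_denominator: str = "post_baseline"  # or "all_sessions"
    # calcium detection
    frame_rate_hz: float = 30.0
    cutoff_hz: float = 10.0
    neuropil_alpha: float = 0.7
    k_sigma: float = 3.0
    min_duration_frames: int = 20
    # bootstrap
    bootstrap_iterations: int = 10000
    bootstrap_level: float = 0.95
    bootstrap_unit: str = "neuron"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.session_order) != len(set(self.session_order)):
            raise ValueError("session_order labels must be unique")
        extra = set(self.baseline_sessions) - set(self.session_order)
        if extra:
            raise ValueError(f"baseline sessions not in session_order: {sorted(extra)}")
        if self.persistence_denominator not in ("post_baseline", "all_sessions"):
            raise ValueError("persistence_denominator must be post_baseline|all_sessions")
        if not 0 < self.cutoff_hz < self.frame_rate_hz / 2:
            raise ValueError("cutoff_hz must lie in (0, Nyquist)")
        if self.neuropil_alpha < 0 or self.k_sigma <= 0 or self.min_duration_frames < 1:
            raise ValueError("detection parameters out of range")
        if not 0 < self.bootstrap_level < 1 or self.bootstrap_iterations < 1:
            raise ValueError("bootstrap parameters out of range")

    def module_seed(self, module: str) -> int:
        return child_seed(self.seed, module)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
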