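"""In-memory containers for per-transition chromatograms of one PRM run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromatogram", "PrmRun"]


@dataclass
class Chromatogram:
    """One extracted-ion trace: intensity versus retention time (minutes)."""

    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError(f"{self.transition_id}: times/intensities shape mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"{self.transition_id}: time points must be strictly increasing"
            )
        if np.any(~np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError(
                f"{self.transition_id}: intensities must be finite and non-negative"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PrmRun:
    """All transition traces acquired for one injected sample."""

    chromatograms: dict[str, Chromatogram] = field(default_factory=dict)
    sample_id: str | None = None

    def __getitem__(self, transition_id: str) -> Chromatogram:
        return self.chromatograms[transition_id]

    def __contains__(self, transition_id: str) -> bool:
        return transition_id in self.chromatograms

    def __len__(self) -> int:
        return len(self.chromatograms)

    @property
    def transition_ids(self) -> list[str]:
        return list(self.chromatograms)
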