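"""Acquisition protocol for the dual-time saturation-recovery DCE sequence.

The protocol interleaves a fast dynamic sequence (high temporal resolution,
covering the bolus first pass) with a slow sequence (lower temporal
resolution, covering the minutes-long leakage phase).  Both use a saturation
prepulse with delay ``td_ms``, so the signal follows the saturation-recovery
law ``S = S0 * (1 - exp(-TD * R1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and relaxometry parameters of the dual-time DCE acquisition.

    Defaults reproduce a 3 T dual-time protocol: fast sequence with a 3.2 s
    dynamic scan interval and 29 volumes, slow sequence with a 30.5 s
    interval and 30 volumes, TR/TE/TD = 5.3/2.5/120 ms.

    Parameters
    ----------
    tr_ms, te_ms, td_ms
        Repetition time, echo time, and saturation delay time (ms).  Only
        ``td_ms`` enters the saturation-recovery signal model.
    flip_deg
        Readout flip angle (degrees).  Carried as metadata; the pure
        saturation-recovery model is flip-angle independent.
    fast_interval_s, n_fast
        Dynamic scan interval (s) and volume count of the fast sequence.
    slow_interval_s, n_slow
        Dynamic scan interval (s) and volume count of the slow sequence.
    n_precontrast_fast, n_precontrast_slow
        Number of volumes acquired before contrast arrival in each sequence;
        they define the per-voxel baseline signal.
    r1_relaxivity
        Longitudinal relaxivity of the contrast agent (L mmol^-1 s^-1,
        equivalently s^-1 per mM).  Default 5.0, typical for gadobutrol at
        3 T.
    """

    tr_ms: float = 5.3
    te_ms: float = 2.5
    td_ms: float = 120.0
    flip_deg: float = 30.0
    fast_interval_s: float = 3.2
    n_fast: int = 29
    slow_interval_s: float = 30.5
    n_slow: int = 30
    n_precontrast_fast: int = 5
    n_precontrast_slow: int = 2
    r1_relaxivity: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tr_ms", "te_ms", "td_ms", "fast_interval_s",
                     "slow_interval_s", "r1_relaxivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, "
                                 f"got {getattr(self, name)}")
        if not (self.n_fast >= self.n_precontrast_fast >= 1):
            raise ValueError(
                f"need n_fast >= n_precontrast_fast >= 1, got "
                f"{self.n_fast} / {self.n_precontrast_fast}")
        if not (self.n_slow >= self.n_precontrast_slow >= 1):
            raise ValueError(
                f"need n_slow >= n_precontrast_slow >= 1, got "
                f"{self.n_slow} / {self.n_precontrast_slow}")

    @property
    def td_s(self) -> float:
        """Saturation delay in seconds."""
        return self.td_ms / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)
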