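"""The in-memory MS/MS spectrum container shared by all modules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["Spectrum"]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 spectrum: precursor m/z, optional RT, peak list.

    Peaks are (m/z, intensity) pairs kept sorted by m/z; intensities must be
    finite and non-negative.  Charge +1 is assumed throughout (positive-mode
    alkaloid ions).  ``rt`` is in minutes.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...] = ()
    rt: float | None = None
    metadata: tuple[tuple[str, str], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        for mz, inten in self.peaks:
            if not (math.isfinite(mz) and math.isfinite(inten)) or inten < 0:
                raise ValueError(f"invalid peak ({mz}, {inten})")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
        )

    def filter_intensity(self, floor: float) -> "Spectrum":
        """Drop peaks below an absolute intensity floor."""
        return replace(
            self, peaks=tuple(p for p in self.peaks if p[1] >= floor)
        )

    @property
    def fragment_mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)
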