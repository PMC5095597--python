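"""Z-spectrum container: normalized water signal versus saturation offset."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .spinsystem import InvalidInputError


@dataclass
class ZSpectrum:
    """Saturation offsets (ppm, ascending) with normalized signals.

    ``z0`` is the reference signal acquired after far-off-resonance
    saturation (+/-100 ppm by convention) and is the normalizer for all
    quantification metrics.  ``b0_shift`` records any applied field-offset
    correction (0 until corrected).
    """

    offsets: np.ndarray
    signals: np.ndarray
    z0: float = 1.0
    b0_shift: float = 0.0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.offsets.ndim != 1 or self.offsets.shape != self.signals.shape:
            raise InvalidInputError("offsets and signals must be matching 1-D arrays")
        if self.offsets.size == 0:
            raise InvalidInputError("spectrum must contain at least one offset")
        if np.any(np.diff(self.offsets) <= 0):
            raise InvalidInputError("offsets must be strictly increasing")
        if self.z0 <= 0:
            raise InvalidInputError("z0 must be > 0")
        if np.any(self.signals < -0.05) or np.any(self.signals > 1.05):
            raise InvalidInputError("signals outside [-0.05, 1.05]")

    def __len__(self) -> int:
        return self.offsets.size

    def interp(self, ppm):
        """Piecewise-cubic interpolation of the signal at arbitrary ppm."""
        if self.offsets.size < 4:
            return np.interp(ppm, self.offsets, self.signals)
        spline = CubicSpline(self.offsets, self.signals)
        return spline(ppm)

    def mirrored(self) -> "ZSpectrum":
        """The spectrum reflected about 0 ppm."""
        return replace(
            self,
            offsets=-self.offsets[::-1].copy(),
            signals=self.signals[::-1].copy(),
        )

    def copy(self) -> "ZSpectrum":
        return replace(self, offsets=self.offsets.copy(), signals=self.signals.copy())
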