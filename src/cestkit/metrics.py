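"""Non-model-based CEST quantification metrics.

Four metrics evaluated at a target offset ``omega`` (2.8 ppm by default)
with flanking spacing ``delta_omega`` (1.4 ppm):

* ``mtr_asym`` — asymmetry, 100*(Z(-w) - Z(w))/Z0
* ``apt_star`` — three-offset contrast against the mean of the flanks
* ``mtr_rex``  — inverse-Z three-offset contrast, 100*(1/Z(w) - 1/Zref)
* ``arex``     — mtr_rex divided by the water T1

All values are reported on a common %M0 scale so that downstream
sensitivity coefficients are comparable across metrics.  Negative APT* and
MTR_Rex values (no discernible CEST peak, e.g. at short water T2) are
unphysical and clipped to zero; clipping is applied after ROI averaging by
the pipeline, so the scalar functions expose a ``clip`` switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .spinsystem import InvalidInputError
from .zspectrum import ZSpectrum

__all__ = [
    "MetricParams",
    "MetricValue",
    "b0_correct",
    "mtr_asym",
    "apt_star",
    "mtr_rex",
    "arex",
    "roi_statistics",
]


@dataclass(frozen=True)
class MetricParams:
    """Target offset and flanking spacing, both in ppm."""

    omega: float = 2.8
    delta_omega: float = 1.4
    #: use the mean of the two flanking offsets for Zref (three-offset
    #: convention); False selects the half-difference form for audit.
    zref_mean: bool = True

    def __post_init__(self) -> None:
        if self.delta_omega <= 0:
            raise InvalidInputError("delta_omega must be > 0")

    def validate_range(self, spec: ZSpectrum) -> None:
        lo, hi = spec.offsets[0], spec.offsets[-1]
        for o in (self.omega, -self.omega,
                  self.omega - self.delta_omega, self.omega + self.delta_omega):
            if not (lo <= o <= hi):
                raise InvalidInputError(
                    f"offset {o} ppm outside sampled range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class MetricValue:
    """A metric value in %M0 with its ROI spread."""

    metric_name: str
    value: float
    sd: float = 0.0
    n_voxels: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")


def _zref(spec: ZSpectrum, p: MetricParams) -> float:
    z_plus = float(spec.interp(p.omega + p.delta_omega))
    z_minus = float(spec.interp(p.omega - p.delta_omega))
    if p.zref_mean:
        return 0.5 * (z_plus + z_minus)
    return z_plus - 0.5 * z_minus


def b0_correct(spec: ZSpectrum, search_window: float = 1.5) -> ZSpectrum:
    """Shift the Z-spectrum minimum to 0 ppm.

    The sub-sample minimum is located on a cubic-spline interpolant within
    ``+/-search_window`` ppm; the signals are then re-interpolated onto the
    original offset grid.  If the minimum lands on the window boundary the
    spectrum is returned unshifted with a warning.
    """
    spline = CubicSpline(spec.offsets, spec.signals)
    lo = max(spec.offsets[0], -search_window)
    hi = min(spec.offsets[-1], search_window)
    grid = np.linspace(lo, hi, 257)
    coarse = grid[int(np.argmin(spline(grid)))]
    res = minimize_scalar(
        spline, bounds=(max(lo, coarse - 0.3), min(hi, coarse + 0.3)),
        method="bounded", options={"xatol": 1e-6},
    )
    shift = float(res.x)
    if min(abs(shift - lo), abs(shift - hi)) < 1e-3:
        warnings.warn(
            "Z-spectrum minimum at the search-window boundary; no shift applied",
            stacklevel=2,
        )
        return replace(spec, b0_shift=0.0)
    corrected = spline(spec.offsets + shift)
    return ZSpectrum(
        offsets=spec.offsets.copy(),
        signals=np.clip(corrected, -0.05, 1.05),
        z0=spec.z0,
        b0_shift=shift,
    )


def mtr_asym(spec: ZSpectrum, p: MetricParams = MetricParams()) -> MetricValue:
    """Asymmetry metric, 100*(Z(-w) - Z(w))/Z0 in %M0."""
    p.validate_range(spec)
    value = 100.0 * (float(spec.interp(-p.omega)) - float(spec.interp(p.omega))) / spec.z0
    return MetricValue("mtr_asym", value)


def apt_star(spec: ZSpectrum, p: MetricParams = MetricParams(),
             clip: bool = True) -> MetricValue:
    """Three-offset contrast, 100*(Zref - Z(w))/Z0 in %M0.

    Zref is the mean of the two flanking offsets w +/- dw.  Negative values
    are clipped to zero when ``clip`` is set.
    """
    p.validate_range(spec)
    value = 100.0 * (_zref(spec, p) - float(spec.interp(p.omega))) / spec.z0
    if clip:
        value = max(value, 0.0)
    return MetricValue("apt_star", value)


def mtr_rex(spec: ZSpectrum, p: MetricParams = MetricParams(),
            clip: bool = True) -> MetricValue:
    """Inverse-Z three-offset contrast, 100*(1/Z(w) - 1/Zref).

    Reported on the same %M0 scale as the other metrics.
    """
    p.validate_range(spec)
    z = float(spec.interp(p.omega))
    zref = _zref(spec, p)
    if z <= 0:
        raise InvalidInputError(f"Z(omega) = {z} is nonpositive")
    if zref <= 0:
        raise InvalidInputError(f"Zref = {zref} is nonpositive")
    value = 100.0 * (1.0 / z - 1.0 / zref)
    if clip:
        value = max(value, 0.0)
    return MetricValue("mtr_rex", value)


def arex(mtr_rex_value, t1: float) -> MetricValue:
    """Relaxation-compensated metric: MTR_Rex divided by the water T1 (s)."""
    if t1 <= 0:
        raise InvalidInputError("t1 must be > 0")
    if isinstance(mtr_rex_value, MetricValue):
        return MetricValue("arex", mtr_rex_value.value / t1,
                           mtr_rex_value.sd / t1, mtr_rex_value.n_voxels)
    return MetricValue("arex", float(mtr_rex_value) / t1)


def roi_statistics(values_per_voxel, metric_name: str = "roi") -> MetricValue:
    """Mean and sample (n-1) standard deviation over an ROI."""
    values = np.asarray(values_per_voxel, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty ROI")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return MetricValue(metric_name, float(np.mean(values)), sd, int(values.size))
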