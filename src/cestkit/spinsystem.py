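"""Multi-pool spin systems for chemical exchange saturation transfer.

A :class:`SpinSystem` is an ordered collection of proton pools, water first,
each with its own chemical shift, relaxation times, exchange rate toward
water, and relative proton concentration.  All labile pools exchange with
water only (no labile-labile exchange), the standard topology for
saturation-transfer modelling of mobile proteins and metabolites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

#: Proton gyromagnetic ratio over 2*pi, in Hz per microtesla.
GAMMA_HZ_PER_UT = 42.577

TWO_PI = 2.0 * math.pi


class InvalidInputError(ValueError):
    """Raised when domain-object parameters are unphysical or malformed."""


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ExchangePool:
    """One proton pool.

    Parameters
    ----------
    name : str
        Label, e.g. ``"water"``, ``"amine"``, ``"noe"``.
    offset : float
        Chemical shift in ppm relative to water at 0 ppm; positive offsets
        are downfield of water.
    rate : float
        Exchange rate from this pool toward water, s^-1.  Zero for water.
    fraction : float
        Proton concentration relative to water (dimensionless).  One for
        water.
    t1, t2 : float
        Longitudinal / transverse relaxation times in seconds.
    """

    name: str
    offset: float
    rate: float
    fraction: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        _check_finite(offset=self.offset, rate=self.rate,
                      fraction=self.fraction, t1=self.t1, t2=self.t2)
        if self.rate < 0:
            raise InvalidInputError(f"pool {self.name!r}: rate must be >= 0")
        if self.fraction < 0:
            raise InvalidInputError(f"pool {self.name!r}: fraction must be >= 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise InvalidInputError(f"pool {self.name!r}: t1 and t2 must be > 0")
        if self.t2 > self.t1:
            # message deliberately value-free so repeated warnings deduplicate
            warnings.warn(f"pool {self.name!r}: t2 exceeds t1", stacklevel=2)


@dataclass(frozen=True)
class SpinSystem:
    """Ordered pool collection with water first.

    The water pool must have ``fraction == 1`` and ``rate == 0``.  The Larmor
    frequency (MHz) sets the ppm-to-rad/s conversion; the default 400 MHz
    corresponds to a 9.4 T scanner.
    """

    pools: tuple[ExchangePool, ...]
    larmor_frequency: float = 400.0

    def __post_init__(self) -> None:
        if len(self.pools) < 1:
            raise InvalidInputError("SpinSystem needs at least a water pool")
        object.__setattr__(self, "pools", tuple(self.pools))
        water = self.pools[0]
        if water.fraction != 1.0 or water.rate != 0.0:
            raise InvalidInputError(
                "first pool is water and must have fraction=1, rate=0"
            )
        if self.larmor_frequency <= 0:
            raise InvalidInputError("larmor_frequency must be > 0")

    @property
    def water(self) -> ExchangePool:
        return self.pools[0]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def ppm_to_radps(self, ppm):
        """Convert an offset in ppm to angular frequency in rad/s."""
        return TWO_PI * self.larmor_frequency * np.asarray(ppm, dtype=float)

    def pool(self, name: str) -> ExchangePool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def subset(self, names) -> "SpinSystem":
        """System restricted to water plus the named labile pools."""
        keep = [self.pools[0]] + [p for p in self.pools[1:] if p.name in set(names)]
        return SpinSystem(tuple(keep), self.larmor_frequency)

    def with_offset_shift(self, shift_ppm: float) -> "SpinSystem":
        """All pool offsets translated by ``shift_ppm`` (a B0 shift)."""
        pools = tuple(replace(p, offset=p.offset + shift_ppm) for p in self.pools)
        return SpinSystem(pools, self.larmor_frequency)

    def equilibrium_state(self) -> np.ndarray:
        """Thermal-equilibrium state vector (Mx, My, Mz per pool, then 1)."""
        state = np.zeros(3 * self.n_pools + 1)
        for i, p in enumerate(self.pools):
            state[3 * i + 2] = p.fraction
        state[-1] = 1.0
        return state


def water_pool(t1: float = 1.8, t2: float = 0.1) -> ExchangePool:
    return ExchangePool("water", 0.0, 0.0, 1.0, t1, t2)
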