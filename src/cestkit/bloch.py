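"""Bloch-McConnell propagation for multi-pool saturation transfer.

The coupled magnetization dynamics of an n-pool system under off-resonant
RF irradiation form an affine linear ODE.  We work with the homogeneous
(3n+1)-dimensional form: (Mx, My, Mz) per pool plus a constant component, so
that a single matrix exponential propagates both the linear dynamics and the
longitudinal recovery term exactly over any interval of constant B1.

Pulsed trains exploit two structural facts: every pulse of a train is
identical, so one pulse+gap period is a fixed propagator raised to the
number of pulses; and the discretized Gaussian envelope is symmetric, so
only the distinct segment amplitudes need their own matrix exponential.
Matrix exponentials for batches of offsets are evaluated by
eigendecomposition with a scipy fallback for ill-conditioned cases.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .saturation import SaturationScheme, gaussian_segments
from .spinsystem import GAMMA_HZ_PER_UT, TWO_PI, InvalidInputError, SpinSystem
from .zspectrum import ZSpectrum

__all__ = [
    "build_generator",
    "build_generators",
    "propagate",
    "cw_steady_state",
    "simulate_pulse_train",
    "simulate_zspectrum",
    "train_propagators",
]


def build_generators(system: SpinSystem, b1, offset) -> np.ndarray:
    """Affine evolution generators for a batch of (b1, offset) settings.

    Parameters broadcast: ``b1`` in uT, ``offset`` in ppm.  Returns an array
    of shape (m, 3n+1, 3n+1) where n is the pool count.  Row layout per pool
    i is (Mx, My, Mz) at indices (3i, 3i+1, 3i+2); the final row/column is
    the constant component carrying the M0 recovery terms.
    """
    b1 = np.atleast_1d(np.asarray(b1, dtype=float))
    offset = np.atleast_1d(np.asarray(offset, dtype=float))
    b1, offset = np.broadcast_arrays(b1, offset)
    if np.any(b1 < 0):
        raise InvalidInputError("b1 must be >= 0")
    if not (np.all(np.isfinite(b1)) and np.all(np.isfinite(offset))):
        raise InvalidInputError("b1 and offset must be finite")

    m = b1.size
    n = system.n_pools
    dim = 3 * n + 1
    A = np.zeros((m, dim, dim))
    w1 = TWO_PI * GAMMA_HZ_PER_UT * b1  # rad/s

    for i, pool in enumerate(system.pools):
        dw = system.ppm_to_radps(pool.offset - offset)
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        A[:, x, x] -= 1.0 / pool.t2
        A[:, x, y] += dw
        A[:, y, x] -= dw
        A[:, y, y] -= 1.0 / pool.t2
        A[:, y, z] += w1
        A[:, z, y] -= w1
        A[:, z, z] -= 1.0 / pool.t1
        A[:, z, -1] += pool.fraction / pool.t1

    # exchange with water (pool 0), detailed balance via fractions
    for i, pool in enumerate(system.pools[1:], start=1):
        k_back = pool.rate                  # pool -> water
        k_fwd = pool.rate * pool.fraction   # water -> pool
        for c in range(3):
            w, p = c, 3 * i + c
            A[:, w, w] -= k_fwd
            A[:, w, p] += k_back
            A[:, p, p] -= k_back
            A[:, p, w] += k_fwd
    return A


def build_generator(system: SpinSystem, b1: float, offset: float) -> np.ndarray:
    """Single (3n+1)x(3n+1) evolution generator; see ``build_generators``."""
    return build_generators(system, [b1], [offset])[0]


import math as _math

_TAYLOR_THETA = 1.3  # scaled norm below which the degree-16 series is exact
                     # to double precision
_TAYLOR_C = tuple(1.0 / _math.factorial(k) for k in range(17))


def _taylor16(M: np.ndarray) -> np.ndarray:
    """Degree-16 Taylor approximant of exp(M), Paterson-Stockmeyer form.

    Seven batched matrix products, no linear solves; requires ||M|| below
    the Taylor radius (guaranteed by the caller's scaling).
    """
    c = _TAYLOR_C
    eye = np.broadcast_to(np.eye(M.shape[-1]), M.shape)
    M2 = M @ M
    M3 = M2 @ M
    M4 = M3 @ M
    pows = (eye, M, M2, M3)

    def block(i):
        return sum(c[4 * i + j] * pows[j]
                   for j in range(4) if 4 * i + j <= 16)

    P = block(4) @ M4 + block(3)
    P = P @ M4 + block(2)
    P = P @ M4 + block(1)
    P = P @ M4 + block(0)
    return P


def _expm_batch(A: np.ndarray, t: float) -> np.ndarray:
    """exp(A*t) for a stack of small real matrices.

    Scaling and squaring with a solve-free Taylor-16 core, batched over
    the stack; matrices are grouped by the number of squarings their norm
    requires, so a few far-off-resonance members (large precession
    frequencies) do not inflate the cost of the whole batch.
    """
    if t == 0:
        return np.broadcast_to(np.eye(A.shape[-1]), A.shape).copy()
    M = A * t
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("non-finite generator")
    norms = np.abs(M).sum(axis=-1).max(axis=-1)  # inf-norm per matrix
    s = np.maximum(0, np.ceil(np.log2(np.maximum(norms, 1e-300)
                                      / _TAYLOR_THETA))).astype(int)
    P = np.empty_like(M)
    for sv in np.unique(s):
        idx = np.nonzero(s == sv)[0]
        Q = _taylor16(M[idx] / (2.0 ** sv))
        for _ in range(sv):
            Q = Q @ Q
        P[idx] = Q
    return P


def propagate(generator: np.ndarray, duration: float, state: np.ndarray) -> np.ndarray:
    """Evolve a state under a constant generator for ``duration`` seconds.

    Exact piecewise-constant propagation: composition over subintervals
    equals a single propagation over their sum.
    """
    if duration < 0:
        raise InvalidInputError("duration must be >= 0")
    if duration == 0:
        return np.array(state, dtype=float, copy=True)
    out = scipy.linalg.expm(np.asarray(generator) * duration) @ np.asarray(state, float)
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("propagation produced non-finite state")
    return out


def cw_steady_state(system: SpinSystem, b1: float, offsets) -> np.ndarray:
    """Steady-state water Mz/M0 under CW saturation, one value per offset.

    Solves the null-space problem of the affine generator directly
    (A_lin x = -b), which is the long-duration limit of ``propagate``.
    """
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    A = build_generators(system, np.full(offsets.shape, float(b1)), offsets)
    x = np.linalg.solve(A[:, :-1, :-1], -A[:, :-1, -1:])
    return x[:, 2, 0]


def _matrix_power_batch(P: np.ndarray, n: int) -> np.ndarray:
    out = np.broadcast_to(np.eye(P.shape[-1]), P.shape).copy()
    base = P
    while n > 0:
        if n & 1:
            out = base @ out
        base = base @ base
        n >>= 1
    return out


def train_propagators(system: SpinSystem, scheme: SaturationScheme, offsets) -> np.ndarray:
    """Whole-train propagators for a batch of offsets, shape (m, 3n+1, 3n+1).

    One period is the ordered product of the discretized Gaussian segments
    followed by the RF-free gap; the train is that period raised to the
    number of pulses.
    """
    if scheme.mode != "gaussian_train":
        raise InvalidInputError("train_propagators requires a gaussian_train scheme")
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    m = offsets.size
    amps, dt = gaussian_segments(scheme)
    uniq, inverse = np.unique(np.round(amps, 12), return_inverse=True)
    u = uniq.size

    # segment propagators: one per (offset, distinct amplitude)
    b1_grid = np.repeat(uniq[None, :], m, axis=0).ravel()
    off_grid = np.repeat(offsets, u)
    A = build_generators(system, b1_grid, off_grid)
    S = _expm_batch(A, dt).reshape(m, u, *A.shape[-2:])

    pulse = S[:, inverse[0]].copy()
    for j in inverse[1:]:
        pulse = S[:, j] @ pulse

    if scheme.gap > 0:
        A0 = build_generators(system, np.zeros(m), offsets)
        gap = _expm_batch(A0, scheme.gap)
        period = gap @ pulse
    else:
        period = pulse
    return _matrix_power_batch(period, scheme.n_pulses)


def _water_z(system: SpinSystem, P: np.ndarray, initial_state=None) -> np.ndarray:
    state = system.equilibrium_state() if initial_state is None else np.asarray(initial_state, float)
    out = P @ state
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("pulse-train propagation produced non-finite state")
    return out[..., 2]


def simulate_pulse_train(system: SpinSystem, scheme: SaturationScheme,
                         offset: float, initial_state=None) -> float:
    """Water Mz/M0 after the full Gaussian pulse train at one offset."""
    P = train_propagators(system, scheme, [offset])
    return float(_water_z(system, P, initial_state)[0])


def _simulate_offsets(system: SpinSystem, scheme: SaturationScheme, offsets) -> np.ndarray:
    """Water Mz/M0 at each offset, thermal equilibrium before each."""
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if scheme.mode == "cw":
        A = build_generators(system, np.full(offsets.shape, scheme.b1), offsets)
        P = _expm_batch(A, scheme.duration)
    else:
        P = train_propagators(system, scheme, offsets)
    return _water_z(system, P)


def simulate_zspectrum(system: SpinSystem, scheme: SaturationScheme) -> ZSpectrum:
    """Simulate a full Z spectrum under the given saturation scheme.

    Each offset starts from thermal equilibrium (complete inter-offset
    relaxation, consistent with a repetition time much longer than T1).
    The reference signal z0 is the mean over the far-off-resonance
    reference offsets.
    """
    offsets = np.sort(np.asarray(scheme.offsets, dtype=float))
    if offsets.size == 0:
        raise InvalidInputError("scheme has no saturation offsets")
    refs = np.asarray(scheme.reference_offsets, dtype=float)
    z_all = _simulate_offsets(system, scheme, np.concatenate([offsets, refs]))
    z0 = float(np.mean(z_all[offsets.size:]))
    return ZSpectrum(offsets=offsets, signals=z_all[:offsets.size], z0=z0)
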