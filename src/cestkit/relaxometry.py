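"""Water relaxometry: T1 from inversion recovery, T2 from spin echo.

These fits supply the independently measured water relaxation times that
feed the "measured priors" mode of the Z-spectrum model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .spinsystem import InvalidInputError

__all__ = ["RelaxSeries", "RelaxFit", "fit_t1_ir", "fit_t2_se"]


@dataclass(frozen=True)
class RelaxSeries:
    """A relaxation measurement series.

    ``kind`` is ``"inversion_recovery"`` (times are inversion times TI) or
    ``"spin_echo"`` (times are echo times TE); signals are in arbitrary
    units.
    """

    kind: str
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.kind not in ("inversion_recovery", "spin_echo"):
            raise InvalidInputError(f"unknown series kind {self.kind!r}")
        if self.times.size < 3:
            raise InvalidInputError("need at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass(frozen=True)
class RelaxFit:
    m0: float
    time_constant: float
    residual_norm: float
    well_conditioned: bool


def _ir_model(ti, m0, t1):
    return m0 * (1.0 - 2.0 * np.exp(-ti / t1))


def fit_t1_ir(series: RelaxSeries) -> RelaxFit:
    """Least-squares fit of Mz = M0 (1 - 2 exp(-TI/T1)).

    Magnitude data (all signals non-negative) lose the sign of the
    recovering magnetization; polarity is restored by trying every
    plausible zero-crossing position and keeping the assignment with the
    smallest residual.
    """
    if series.kind != "inversion_recovery":
        raise InvalidInputError("series is not inversion recovery")
    ti, sig = series.times, series.signals
    magnitude = bool(np.all(sig >= 0))
    candidates = range(ti.size + 1) if magnitude else [None]

    best = None
    for n_flip in candidates:
        y = sig.copy()
        if n_flip is not None:
            y[:n_flip] = -y[:n_flip]
        m0_0 = max(abs(y[-1]), 1e-12)
        t1_0 = max(ti[int(np.argmin(np.abs(y)))] / np.log(2.0), ti[0])
        try:
            popt, _ = curve_fit(_ir_model, ti, y, p0=[m0_0, t1_0],
                                bounds=([0, 1e-6], [np.inf, np.inf]),
                                maxfev=5000)
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(_ir_model(ti, *popt) - y))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise ArithmeticError("inversion-recovery fit did not converge")
    resid, (m0, t1) = best
    # all TI >> T1 (flat series) or T1 beyond the sampled range is
    # unidentifiable from this design
    ok = (ti[0] / 5.0 <= t1 <= ti[-1] * 5.0)
    return RelaxFit(float(m0), float(t1), resid, bool(ok))


def fit_t2_se(series: RelaxSeries) -> RelaxFit:
    """Least-squares fit of Mz = M0 exp(-TE/T2).

    Initialized by a log-linear regression, refined by nonlinear least
    squares.
    """
    if series.kind != "spin_echo":
        raise InvalidInputError("series is not spin echo")
    te, sig = series.times, series.signals
    if np.any(sig <= 0):
        raise InvalidInputError("spin-echo signals must be > 0")
    slope, intercept = np.polyfit(te, np.log(sig), 1)
    t2_0 = -1.0 / slope if slope < 0 else te[-1] * 10.0
    m0_0 = float(np.exp(intercept))

    def model(t, m0, t2):
        return m0 * np.exp(-t / t2)

    popt, _ = curve_fit(model, te, sig, p0=[m0_0, t2_0],
                        bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=5000)
    m0, t2 = popt
    resid = float(np.linalg.norm(model(te, *popt) - sig))
    ok = (te[0] / 10.0 <= t2 <= te[-1] * 10.0)
    return RelaxFit(float(m0), float(t2), resid, bool(ok))
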