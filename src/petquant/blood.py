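"""Arterial input-function construction and plasma free fraction.

The metabolite-corrected input is the product of the measured plasma
concentration and a fitted parent-fraction model.  The input is represented
by its knots (sample times) with piecewise-linear interpolation and a
mono-exponential tail beyond the last knot, so kinetic integrals that extend
past the last blood sample remain finite and well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .curves import BloodSampleSeries

__all__ = [
    "ParentFractionModel",
    "fit_parent_fraction",
    "InputFunction",
    "build_input",
    "ProteinBindingAssay",
    "free_fraction",
]


@dataclass(frozen=True)
class ParentFractionModel:
    """Hill-type parent fraction pf(t) = 1 − a·t^b / (t^b + c).

    pf(0) = 1 by construction; a in [0, 1] is the asymptotic metabolised
    fraction, b > 0 the shape, c > 0 the (half-time)^b scale.  ``rmse`` is
    the fit residual when the model came from :func:`fit_parent_fraction`.
    """

    a: float
    b: float
    c: float
    rmse: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("a must lie in [0, 1]")
        if not (self.b > 0 and self.c > 0):
            raise ValueError("b and c must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tb = np.power(np.clip(t, 0.0, None), self.b)
        return 1.0 - self.a * tb / (tb + self.c)


def fit_parent_fraction(samples: BloodSampleSeries) -> ParentFractionModel:
    """Least-squares fit of the Hill parent-fraction model to measured fractions."""
    if samples.kind != "parent_fraction":
        raise ValueError("samples must have kind='parent_fraction'")
    t, y = samples.t, samples.value
    if len(t) < 4:
        raise ValueError("need at least 4 parent-fraction samples")
    if np.allclose(y, 1.0):
        return ParentFractionModel(0.0, 1.0, 1.0, rmse=0.0)

    def resid(p):
        a, b, logc = p
        return ParentFractionModel(a, b, np.exp(logc))(t) - y

    best = None
    for b0, c0 in ((1.0, 60.0), (2.0, 1000.0), (0.5, 30.0)):
        a0 = float(np.clip(1.0 - y[-1], 1e-3, 1.0))
        try:
            sol = least_squares(
                resid,
                x0=[a0, b0, np.log(c0)],
                bounds=([0.0, 0.05, np.log(1e-3)], [1.0, 8.0, np.log(1e8)]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ParentFractionModel(0.0, 1.0, 1.0, rmse=float("nan"), converged=False)
    a, b, logc = best.x
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return ParentFractionModel(float(a), float(b), float(np.exp(logc)), rmse=rmse,
                               converged=bool(best.status > 0))


@dataclass(frozen=True)
class InputFunction:
    """Continuous metabolite-corrected plasma input.

    Evaluation rule: zero before ``delay``; piecewise linear between the
    (delay-shifted) knots; a mono-exponential fitted to the last three knots
    extrapolates beyond the last knot.  A leading (0, 0) knot is prepended
    when the first knot is at t > 0, so the curve rises from zero.
    """

    knots_t: np.ndarray
    knots_v: np.ndarray
    delay: float = 0.0
    # tail value(t) = tail_amp * exp(-tail_rate * (t - last_knot)) for t > last knot
    tail_amp: float = field(init=False, default=0.0)
    tail_rate: float = field(init=False, default=0.0)

    def __post_init__(self):
        t = np.asarray(self.knots_t, dtype=float)
        v = np.asarray(self.knots_v, dtype=float)
        if len(t) != len(v) or len(t) < 3:
            raise ValueError("need >= 3 knots")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("input values must be non-negative")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[0.0], v])
        object.__setattr__(self, "knots_t", t)
        object.__setattr__(self, "knots_v", v)
        amp, rate = self._fit_tail(t, v)
        object.__setattr__(self, "tail_amp", amp)
        object.__setattr__(self, "tail_rate", rate)

    @staticmethod
    def _fit_tail(t, v):
        tt, vv = t[-3:], v[-3:]
        if np.any(vv <= 0):
            return float(vv[-1]), 1e-4
        slope, intercept = np.polyfit(tt, np.log(vv), 1)
        rate = -slope
        if rate <= 1e-6:  # non-decaying tail: clamp so the integral stays finite
            rate = 1e-4
        amp = float(np.exp(intercept + slope * tt[-1]))
        return amp, float(rate)

    @property
    def t_last(self) -> float:
        return float(self.knots_t[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        ts = t - self.delay
        out = np.interp(ts, self.knots_t, self.knots_v, left=0.0)
        tail = ts > self.t_last
        if np.any(tail):
            out = np.where(
                tail, self.tail_amp * np.exp(-self.tail_rate * (ts - self.t_last)), out
            )
        return out if out.ndim else float(out)

    def integral_to(self, t: float) -> float:
        """Exact ∫₀ᵗ input(s) ds (piecewise-linear segments + exponential tail)."""
        ts = t - self.delay
        if ts <= 0:
            return 0.0
        kt, kv = self.knots_t, self.knots_v
        if ts <= self.t_last:
            grid = np.concatenate([kt[kt < ts], [ts]])
            vals = np.interp(grid, kt, kv)
            return float(np.trapezoid(vals, grid))
        base = float(np.trapezoid(kv, kt))
        dt = ts - self.t_last
        base += self.tail_amp / self.tail_rate * (1.0 - np.exp(-self.tail_rate * dt))
        return base

    def auc(self, t0: float, t1: float) -> float:
        if t0 >= t1:
            raise ValueError("t0 must be < t1")
        return self.integral_to(t1) - self.integral_to(t0)


def build_input(
    plasma: BloodSampleSeries,
    pf_model: Optional[ParentFractionModel] = None,
    delay: float = 0.0,
) -> InputFunction:
    """Metabolite-corrected input: plasma(t) · pf(t) at the plasma sample times."""
    if plasma.kind not in ("plasma", "whole_blood"):
        raise ValueError("plasma series required")
    if np.any(plasma.value < 0):
        raise ValueError("negative plasma values")
    v = plasma.value.copy()
    if pf_model is not None:
        v = v * pf_model(plasma.t)
    return InputFunction(plasma.t, v, delay=delay)


@dataclass(frozen=True)
class ProteinBindingAssay:
    """Ultrafiltration counts: (free, total) replicate pairs for sample and control.

    The control (protein-free buffer) quantifies filter-membrane binding;
    the free fraction is corrected by the control recovery.
    """

    sample_free: np.ndarray
    sample_total: np.ndarray
    control_free: np.ndarray
    control_total: np.ndarray

    def __post_init__(self):
        for name in ("sample_free", "sample_total", "control_free", "control_total"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        for free, total in (
            (self.sample_free, self.sample_total),
            (self.control_free, self.control_total),
        ):
            if len(free) != len(total):
                raise ValueError("free/total replicate counts differ")
            if np.any(total <= 0):
                raise ValueError("total counts must be > 0")
            if np.any(free > total + 1e-12):
                raise ValueError("free counts exceed total counts")


def free_fraction(assay: ProteinBindingAssay) -> float:
    """Plasma free fraction f_P = C_free/C_total corrected for membrane binding.

    Per-replicate ratios are averaged first; the sample ratio is divided by
    the control ratio (membrane-binding recovery).
    """
    control = float(np.mean(assay.control_free / assay.control_total))
    if control == 0:
        raise ValueError("control recovery ratio is zero")
    fp = float(np.mean(assay.sample_free / assay.sample_total)) / control
    return min(fp, 1.0)
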