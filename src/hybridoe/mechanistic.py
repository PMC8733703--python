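"""Mechanistic half of the hybrid model.

Fed-batch mass balances for viable cell concentration X and product
titer P,

    dX/dt = mu * X - D * X
    dP/dt = v_px * X - D * P

with dilution rate D = feed flow / broth volume for continuously fed
reactors, and instantaneous bolus dilution events for shake flasks.
Also provides interpolation of model inputs between sampling points and
data-driven estimation of the specific rates mu and v_px by cubic
smoothing splines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import make_smoothing_spline

from hybridoe.datamodel import FEED_LEVEL_GLUCOSE, CultivationRun

#: Floor applied to the glutamate concentration before forming the
#: aspartate/glutamate ratio, g/L.  Prevents division blow-up when
#: glutamate is nearly exhausted.
GLUTAMATE_FLOOR: float = 1e-3


@dataclass
class StateTrajectory:
    """Integrated states on a dense time grid."""

    times: np.ndarray  # h
    X: np.ndarray  # 10^6 cells/mL
    P: np.ndarray  # g/L
    V: np.ndarray  # L
    D: np.ndarray  # h^-1


@dataclass
class RateSeries:
    """Data-derived specific rates on the observed time span."""

    times: np.ndarray  # h
    mu: np.ndarray  # h^-1, may be negative
    vpx: np.ndarray  # g/L/h per (10^6 cells/mL), may be negative


def dilution_rate(feed_flow: float, volume: float) -> float:
    """Dilution rate D = feed flow / volume (h^-1).

    Parameters
    ----------
    feed_flow : float
        Feed addition into the reactor, L/h, must be >= 0.
    volume : float
        Current broth volume, L, must be > 0.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if feed_flow < 0:
        raise ValueError(f"feed_flow must be non-negative, got {feed_flow}")
    return feed_flow / volume


def apply_bolus(
    X: float,
    P: float,
    analytes: dict[str, float],
    V: float,
    bolus_volume: float,
    feed_analytes: dict[str, float],
) -> tuple[float, float, dict[str, float], float]:
    """Instantaneous bolus feed addition.

    Cells and product are only diluted (the feed contains neither);
    analytes mix conservatively with the feed concentrations.  Returns
    ``(X', P', analytes', V')``.
    """
    if V <= 0 or bolus_volume < 0:
        raise ValueError("volumes must be positive (bolus volume non-negative)")
    Vn = V + bolus_volume
    f = V / Vn
    new_analytes = {
        name: (c * V + feed_analytes.get(name, 0.0) * bolus_volume) / Vn
        for name, c in analytes.items()
    }
    return X * f, P * f, new_analytes, Vn


def _bolus_times(run: CultivationRun, t_end: float) -> np.ndarray:
    """Daily bolus times from fed-batch onset (exclusive of t_end)."""
    t0 = run.design.batch_end
    if run.feed.mode != "bolus" or t_end <= t0:
        return np.empty(0)
    return np.arange(t0, t_end - 1e-9, 24.0)


def integrate_states(
    rate_fn: Callable[[float], tuple[float, float]],
    run: CultivationRun,
    X0: float,
    P0: float,
    rtol: float = 1e-8,
    t_end: float | None = None,
    extra_times: Sequence[float] | None = None,
) -> StateTrajectory:
    """Integrate the X/P mass balances for one run.

    ``rate_fn(t)`` returns the specific rates ``(mu, v_px)`` at time
    ``t``; feeding and dilution come from the run's feed schedule
    (continuous flow, or daily 3.3 % v/v bolus events for shake flasks).
    The output grid contains every sampling time, segment boundary and
    bolus time within the integrated span.

    Raises ``RuntimeError`` naming the time point if ``rate_fn`` returns a
    non-finite value.
    """
    if X0 < 0 or P0 < 0:
        raise ValueError("initial states must be non-negative")
    t_start = 0.0
    if t_end is None:
        t_end = float(run.samples.times[-1]) if run.samples.n_samples() else run.design.planned_duration

    def checked_rates(t: float) -> tuple[float, float]:
        mu, vpx = rate_fn(t)
        if not (np.isfinite(mu) and np.isfinite(vpx)):
            raise RuntimeError(f"rate function returned non-finite value at t={t:.3f} h")
        return mu, vpx

    bolus_ts = _bolus_times(run, t_end)
    breakpoints = {t_start, t_end}
    breakpoints.update(float(s.start_time) for s in run.design.segments if t_start < s.start_time < t_end)
    breakpoints.update(float(t) for t in bolus_ts)
    grid = set(breakpoints)
    if run.samples.n_samples():
        grid.update(float(t) for t in run.samples.times if t_start <= t <= t_end)
    if extra_times is not None:
        grid.update(float(t) for t in extra_times if t_start <= t <= t_end)
    breaks = np.array(sorted(breakpoints))
    grid = np.array(sorted(grid))

    V0 = run.working_volume
    continuous = run.feed.mode == "continuous"

    def rhs(t, y):
        X, P, V = y
        mu, vpx = checked_rates(t)
        if continuous and t >= run.design.batch_end:
            F = run.feed.flow_at(t, V0)
        else:
            F = 0.0
        D = F / V
        return [mu * X - D * X, vpx * X - D * P, F]

    times_out: list[float] = []
    X_out: list[float] = []
    P_out: list[float] = []
    V_out: list[float] = []
    D_out: list[float] = []

    X, P, V = float(X0), float(P0), float(V0)
    feed_comp_cache = run.feed.composition
    for a, b in zip(breaks[:-1], breaks[1:]):
        # bolus event at the start of a sub-interval (after recording? events
        # apply at their nominal time; sample at t reflects pre-bolus state,
        # the dense grid stores the post-bolus value from the ODE solution)
        if a in bolus_ts:
            level = run.design.segment_at(a).feed_level
            feed_analytes = feed_comp_cache.get(level, {})
            vB = run.feed.bolus_fraction * V
            X, P, _, V = apply_bolus(X, P, {}, V, vB, feed_analytes)
        t_eval = grid[(grid >= a) & (grid <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            [X, P, V],
            method="LSODA",
            rtol=rtol,
            atol=1e-10,
            t_eval=t_eval if len(t_eval) else None,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a:.2f}, {b:.2f}] h: {sol.message}")
        for i, t in enumerate(sol.t):
            if times_out and np.isclose(t, times_out[-1]):
                # boundary appears in both sub-intervals; keep the earlier
                # value (samples at bolus times are drawn before feeding)
                continue
            times_out.append(float(t))
            Xi = float(sol.y[0, i])
            Pi = float(sol.y[1, i])
            # clamp numerical undershoot only; genuinely negative P (negative
            # production rate) is reported as-is
            if -1e-9 < Xi < 0.0:
                Xi = 0.0
            if -1e-9 < Pi < 0.0:
                Pi = 0.0
            Vi = float(sol.y[2, i])
            F = run.feed.flow_at(t, V0) if (continuous and t >= run.design.batch_end) else 0.0
            X_out.append(Xi)
            P_out.append(Pi)
            V_out.append(Vi)
            D_out.append(F / Vi)
        X, P, V = float(sol.y[0, -1]), float(sol.y[1, -1]), float(sol.y[2, -1])

    return StateTrajectory(
        times=np.array(times_out),
        X=np.array(X_out),
        P=np.array(P_out),
        V=np.array(V_out),
        D=np.array(D_out),
    )


class InputInterpolator:
    """Evaluate model inputs of a run at arbitrary times.

    CPPs (temperature, feed glucose level expressed as its numeric added
    glucose, g/L) are right-continuous step functions of the design
    segments; analyte inputs are linear interpolations between sampling
    times.  The aspartate/glutamate ratio is computed after interpolation
    with a glutamate floor of ``GLUTAMATE_FLOOR``.
    """

    def __init__(self, run: CultivationRun, input_names: Sequence[str]):
        self.run = run
        self.input_names = list(input_names)
        self._t = np.asarray(run.samples.times, dtype=float)

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        """Input matrix at times ``t`` (shape ``(len(t), n_inputs)``)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < self._t[0] - 1e-9) or np.any(t_arr > self._t[-1] + 1e-9):
            raise ValueError(
                f"time outside observed span [{self._t[0]}, {self._t[-1]}] h"
            )
        cols = []
        for name in self.input_names:
            if name == "temperature":
                cols.append(self._cpp(t_arr, "temperature"))
            elif name == "feed_glucose":
                cols.append(self._cpp(t_arr, "feed_glucose"))
            elif name == "asp_glu_ratio":
                asp = self._analyte(t_arr, "aspartate")
                glu = np.maximum(self._analyte(t_arr, "glutamate"), GLUTAMATE_FLOOR)
                cols.append(asp / glu)
            else:
                cols.append(self._analyte(t_arr, name))
        out = np.column_stack(cols)
        return out if np.ndim(t) else out[0]

    def _cpp(self, t: np.ndarray, which: str) -> np.ndarray:
        d = self.run.design
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            if ti < d.batch_end:
                # batch phase: 37 C; feed level of the first fed-batch segment
                out[i] = 37.0 if which == "temperature" else FEED_LEVEL_GLUCOSE[d.segments[0].feed_level]
            else:
                seg = d.segment_at(ti)
                out[i] = seg.temperature if which == "temperature" else FEED_LEVEL_GLUCOSE[seg.feed_level]
        return out

    def _analyte(self, t: np.ndarray, name: str) -> np.ndarray:
        if name not in self.run.samples.analytes:
            raise KeyError(f"run {self.run.run_id!r} has no analyte {name!r}")
        return np.interp(t, self._t, self.run.samples.analytes[name])


def interpolate_inputs(
    run: CultivationRun, t: float | np.ndarray, input_names: Sequence[str]
) -> np.ndarray:
    """Model-input vector of ``run`` at time ``t`` (see InputInterpolator)."""
    return InputInterpolator(run, input_names)(t)


def estimate_specific_rates(
    run: CultivationRun, smoothing: float | None = None
) -> RateSeries:
    """Estimate mu(t) and v_px(t) from the sampled series by smoothing splines.

    Works on dilution-corrected quantities: with total viable cells
    ``N = X * V`` and total product ``M = P * V`` the balances reduce to
    ``dlnN/dt = mu`` and ``dM/dt = v_px * X * V`` regardless of feeding
    mode, so cubic smoothing splines are fitted to ``ln N`` and ``M`` and
    differentiated.  ``smoothing`` is the spline penalty ``lam`` (None:
    generalized cross-validation).

    Requires at least 4 sampling points and strictly positive VCC.
    """
    s = run.samples
    t = np.asarray(s.times, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 sampling points to estimate rates")
    X = np.asarray(s.vcc, dtype=float)
    P = np.asarray(s.titer, dtype=float)
    if np.any(X <= 0):
        raise ValueError("VCC must be strictly positive at every sample (log transform)")
    V = np.asarray(run.volume_at(t), dtype=float)

    lnN = np.log(X * V)
    M = P * V
    spl_n = make_smoothing_spline(t, lnN, lam=smoothing)
    spl_m = make_smoothing_spline(t, M, lam=smoothing)
    mu = spl_n.derivative()(t)
    vpx = spl_m.derivative()(t) / (np.exp(spl_n(t)))
    return RateSeries(times=t, mu=mu, vpx=vpx)
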