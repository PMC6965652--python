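"""Parametric model of a single motor-unit twitch and its least-squares fit.

A twitch evoked by a single electrical stimulus is modelled, with sarcomere
displacement standing in for force, as

    F(t) = p * t^m * exp(-k t),   t measured from force development,

where the shape constants derive from three physiological parameters:
``T_c`` (time from force development to peak), ``T_hr`` (time from force
development to half of peak during relaxation) and ``F_max`` (peak
amplitude):

    k = ln 2 / (-T_c ln(T_hr / T_c) + T_hr - T_c)
    m = k * T_c
    p = F_max * exp(-k T_c (ln T_c - 1))

so that F(T_c) = F_max and F(T_hr) = F_max / 2 hold exactly.  A latency
``delay`` from the stimulus to force development shifts the waveform; the
displacement is identically zero before it.

The reported time constants are the rise time t_r = delay + T_c (stimulus
to peak) and the half-relaxation time t_hr = T_hr - T_c (peak to half-peak).

``TwitchModel`` wraps the bounded nonlinear least-squares fit of this
waveform to a displacement trace in the usual model/results idiom:
``TwitchModel(t, d).fit()`` returns a :class:`TwitchFitResults` carrying the
estimates, their standard errors from the Jacobian, and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TwitchParameters",
    "TwitchTimes",
    "FitResult",
    "TwitchModel",
    "TwitchFitResults",
    "derive_shape_params",
    "evaluate_twitch",
    "fit_twitch",
    "twitch_times",
    "subtract_and_fit",
    "InvalidTwitchParameters",
    "TwitchFitError",
    "BelowDetectionError",
]


class InvalidTwitchParameters(ValueError):
    """Raised for nonphysical twitch parameters (e.g. T_hr <= T_c)."""


class TwitchFitError(RuntimeError):
    """Raised when the twitch fit cannot be performed or does not converge."""


class BelowDetectionError(RuntimeError):
    """Raised when a residual trace carries no detectable incremental unit."""


def derive_shape_params(T_c: float, T_hr: float, F_max: float) -> tuple[float, float, float]:
    """Shape constants (k, m, p) of the twitch waveform.

    Parameters
    ----------
    T_c : float
        Time from force development to peak, ms.  Must be > 0.
    T_hr : float
        Time from force development to half-peak during relaxation, ms.
        Must exceed ``T_c``.
    F_max : float
        Peak amplitude (px or um; the unit is carried by the caller).

    Returns
    -------
    k, m, p : float
        Decay rate (1/ms), power (unitless) and scale (amplitude * ms^-m).

    Notes
    -----
    The denominator of k equals T_c * (u - 1 - ln u) with u = T_hr/T_c > 1,
    which is strictly positive, so k > 0 for every valid parameter pair.
    """
    if not (T_c > 0 and T_hr > T_c):
        raise InvalidTwitchParameters(
            f"require T_hr > T_c > 0, got T_c={T_c!r}, T_hr={T_hr!r}"
        )
    if not F_max > 0:
        raise InvalidTwitchParameters(f"require F_max > 0, got {F_max!r}")
    k = math.log(2.0) / (-T_c * math.log(T_hr / T_c) + T_hr - T_c)
    m = k * T_c
    p = F_max * math.exp(-k * T_c * (math.log(T_c) - 1.0))
    return k, m, p


@dataclass(frozen=True)
class TwitchParameters:
    """Physiological parameters of one motor-unit twitch.

    Attributes
    ----------
    T_c : float
        Force development to peak, ms (> 0).
    T_hr : float
        Force development to half-peak during relaxation, ms (> T_c).
    F_max : float
        Peak displacement amplitude (> 0); unit given by ``amplitude_unit``.
    delay : float
        Latency from stimulus to force development, ms (>= 0).
    """

    T_c: float
    T_hr: float
    F_max: float
    delay: float = 0.0
    amplitude_unit: str = "px"

    def __post_init__(self) -> None:
        derive_shape_params(self.T_c, self.T_hr, self.F_max)  # validates
        if self.delay < 0:
            raise InvalidTwitchParameters(f"delay must be >= 0, got {self.delay!r}")

    @property
    def shape(self) -> tuple[float, float, float]:
        """(k, m, p) derived shape constants."""
        return derive_shape_params(self.T_c, self.T_hr, self.F_max)

    def times(self) -> "TwitchTimes":
        return twitch_times(self)


@dataclass(frozen=True)
class TwitchTimes:
    """Reported time constants: rise time and half-relaxation time (ms)."""

    t_r: float
    t_hr: float

    def __post_init__(self) -> None:
        if not (self.t_r > 0 and self.t_hr > 0):
            raise InvalidTwitchParameters(
                f"t_r and t_hr must be > 0, got {self.t_r!r}, {self.t_hr!r}"
            )


def twitch_times(params: TwitchParameters) -> TwitchTimes:
    """Rise time (stimulus to peak) and half-relaxation time (peak to half)."""
    return TwitchTimes(t_r=params.delay + params.T_c, t_hr=params.T_hr - params.T_c)


def evaluate_twitch(params: TwitchParameters, t: np.ndarray) -> np.ndarray:
    """Evaluate the twitch waveform at times ``t`` (ms from the stimulus).

    Zero before the latency; the normalized form
    F_max * (s/T_c)^m * exp(-k (s - T_c)) with s = t - delay is used to
    avoid overflow of p * t^m at large m.
    """
    t = np.asarray(t, dtype=float)
    k, m, _ = params.shape
    s = t - params.delay
    out = np.zeros_like(t)
    pos = s > 0
    sp = s[pos]
    out[pos] = params.F_max * np.exp(
        m * np.log(sp / params.T_c) - k * (sp - params.T_c)
    )
    return out


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting the twitch waveform to a displacement trace."""

    params: TwitchParameters
    sse: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")
        if self.n_points < 5:
            raise ValueError("need at least 5 fitted samples")

    def times(self) -> TwitchTimes:
        return twitch_times(self.params)


# fit bounds, ms; T_hr is reparameterized as T_c + delta to keep k defined
_TC_BOUNDS = (0.5, 200.0)
_DELTA_BOUNDS = (0.1, 400.0)
_DELAY_BOUNDS = (0.0, 20.0)


def _initial_guess(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Deterministic data-driven starting point (T_c, delta, F_max, delay)."""
    i_peak = int(np.argmax(d))
    f0 = float(d[i_peak])
    t_peak = float(t[i_peak])
    # latency: first time the trace exceeds 10% of peak
    above = np.nonzero(d >= 0.1 * f0)[0]
    delay0 = float(t[above[0]]) if above.size else 0.0
    delay0 = float(np.clip(delay0, *_DELAY_BOUNDS))
    tc0 = float(np.clip(t_peak - delay0, *_TC_BOUNDS))
    # half-relaxation: first half-peak crossing after the peak
    post = np.nonzero(d[i_peak:] <= 0.5 * f0)[0]
    if post.size:
        t_half = float(t[i_peak + post[0]])
        delta0 = max(t_half - t_peak, _DELTA_BOUNDS[0] * 2)
    else:
        delta0 = tc0  # relaxation not captured; start symmetric
    delta0 = float(np.clip(delta0, *_DELTA_BOUNDS))
    return np.array([tc0, delta0, max(f0, 1e-6), delay0])


class TwitchModel:
    """Least-squares fit of the twitch waveform to one displacement trace.

    Parameters
    ----------
    t : array-like
        Sample times, ms from stimulation delivery; nonnegative, increasing.
    d : array-like
        Displacement at those times (baseline-subtracted).
    amplitude_unit : str
        Unit label carried into the fitted parameters.
    """

    def __init__(self, t, d, amplitude_unit: str = "px"):
        t = np.asarray(t, dtype=float)
        d = np.asarray(d, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("t and d must be 1-D arrays of equal length")
        if t.size < 5:
            raise TwitchFitError("need at least 5 samples to fit 4 parameters")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        self.t = t
        self.d = d
        self.amplitude_unit = amplitude_unit

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        tc, delta, fmax, delay = x
        p = TwitchParameters(tc, tc + delta, fmax, delay, self.amplitude_unit)
        return evaluate_twitch(p, self.t) - self.d

    def fit(self) -> "TwitchFitResults":
        d = self.d
        if not np.any(d > 0) or float(np.max(d)) <= 0:
            raise TwitchFitError("trace has no positive displacement to fit")
        x0 = _initial_guess(self.t, d)
        lo = [_TC_BOUNDS[0], _DELTA_BOUNDS[0], 1e-9, _DELAY_BOUNDS[0]]
        hi = [_TC_BOUNDS[1], _DELTA_BOUNDS[1], np.inf, _DELAY_BOUNDS[1]]
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            self._residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        if not sol.success:
            raise TwitchFitError(f"twitch fit did not converge: {sol.message}")
        tc, delta, fmax, delay = sol.x
        params = TwitchParameters(tc, tc + delta, fmax, delay, self.amplitude_unit)
        sse = float(np.sum(sol.fun ** 2))
        return TwitchFitResults(self, params, sse, sol)


@dataclass
class TwitchFitResults:
    """Results of a :class:`TwitchModel` fit.

    Carries the fitted :class:`TwitchParameters`, the residual sum of
    squares, asymptotic standard errors from the Gauss-Newton approximation
    J'J, and the derived rise / half-relaxation times.
    """

    model: TwitchModel
    params: TwitchParameters
    sse: float
    _sol: object = field(repr=False)

    @property
    def n_points(self) -> int:
        return self.model.t.size

    @property
    def converged(self) -> bool:
        return True

    def as_fit_result(self) -> FitResult:
        return FitResult(self.params, self.sse, self.converged, self.n_points)

    def times(self) -> TwitchTimes:
        return twitch_times(self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        return evaluate_twitch(self.params, self.model.t)

    @property
    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors of (T_c, T_hr, F_max, delay)."""
        J = self._sol.jac
        n, p = J.shape
        dof = max(n - p, 1)
        s2 = self.sse / dof
        JtJ = J.T @ J
        cov_x = s2 * np.linalg.pinv(JtJ)  # in (T_c, delta, F_max, delay)
        # T_hr = T_c + delta: var = var(tc) + var(delta) + 2 cov
        se = np.sqrt(np.clip(np.diag(cov_x), 0, None))
        var_thr = cov_x[0, 0] + cov_x[1, 1] + 2 * cov_x[0, 1]
        return {
            "T_c": float(se[0]),
            "T_hr": float(np.sqrt(max(var_thr, 0.0))),
            "F_max": float(se[2]),
            "delay": float(se[3]),
        }

    def summary(self) -> str:
        tt = self.times()
        bse = self.bse
        rows = [
            ("T_c", self.params.T_c, bse["T_c"], "ms"),
            ("T_hr", self.params.T_hr, bse["T_hr"], "ms"),
            ("F_max", self.params.F_max, bse["F_max"], self.params.amplitude_unit),
            ("delay", self.params.delay, bse["delay"], "ms"),
        ]
        lines = [
            "Twitch waveform fit",
            "=" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}  unit",
            "-" * 46,
        ]
        for name, est, se, unit in rows:
            lines.append(f"{name:<8}{est:>12.4f}{se:>12.4f}  {unit}")
        lines += [
            "-" * 46,
            f"rise time t_r      {tt.t_r:10.4f} ms",
            f"half-relax t_hr    {tt.t_hr:10.4f} ms",
            f"SSE {self.sse:.6g}   n = {self.n_points}",
        ]
        return "\n".join(lines)


def fit_twitch(t, d, amplitude_unit: str = "px") -> FitResult:
    """Fit the twitch waveform to a displacement trace.

    Thin functional wrapper over :class:`TwitchModel`; see there for the
    initialization and bounds.  ``t`` is in ms from stimulation delivery.
    """
    return TwitchModel(t, d, amplitude_unit).fit().as_fit_result()


def subtract_and_fit(
    t,
    d_higher_voltage,
    previous_model: TwitchParameters,
    *,
    prestim_rms: float | None = None,
    detection_factor: float = 3.0,
    amplitude_unit: str = "px",
) -> FitResult:
    """Fit the incremental motor unit recruited by a voltage step.

    The previously fitted composite model is evaluated on the new trace's
    time grid and subtracted; the residual is fitted as a new unit.  When
    the residual peak does not exceed ``detection_factor`` times the
    pre-stimulus displacement RMS, no new unit was recruited and
    :class:`BelowDetectionError` is raised.

    Parameters
    ----------
    t, d_higher_voltage : array-like
        Time grid (ms from the stimulus) and displacement of the
        higher-voltage recording.
    previous_model : TwitchParameters
        Composite model of all units recruited at lower voltages.
    prestim_rms : float, optional
        Noise floor estimate.  If omitted it is taken from the residual at
        t < 0 when such samples exist, else from the first 10% of samples.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d_higher_voltage, dtype=float)
    residual = d - evaluate_twitch(previous_model, t)
    if prestim_rms is None:
        pre = residual[t < 0]
        if pre.size < 5:
            pre = residual[: max(5, t.size // 10)]
        prestim_rms = float(np.sqrt(np.mean(pre ** 2)))
    floor = detection_factor * prestim_rms
    peak = float(np.max(residual[t > 0])) if np.any(t > 0) else 0.0
    if peak < floor or peak <= 0:
        raise BelowDetectionError(
            f"residual peak {peak:.4g} below detection floor {floor:.4g}; "
            "no incremental unit recruited"
        )
    return fit_twitch(t, residual, amplitude_unit=amplitude_unit)
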