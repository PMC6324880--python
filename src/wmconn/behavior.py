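"""Working-memory ability from n-back learning curves.

The behavioural target is the learning plateau of a letter 3-back task:
per-session sensitivity d' = z(hit rate) - z(false-alarm rate), smoothed with
a five-session moving average, then fitted with the inverse curve
y = a - b/x (y: d' in session x; a: plateau; b: learning speed).  The
plateau a is the working-memory ability (WMA) score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class LearningCurve:
    """Per-session d' trajectory (sessions numbered from 1)."""

    sessions: np.ndarray
    dprime: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sessions = np.asarray(self.sessions, dtype=float)
        self.dprime = np.asarray(self.dprime, dtype=float)
        if self.sessions.shape != self.dprime.shape:
            raise ValueError("sessions and dprime must have equal length")
        if np.any(np.diff(self.sessions) <= 0):
            raise ValueError("sessions must be strictly increasing")


@dataclass
class PlateauFit:
    """Inverse-curve parameters: plateau ``a``, learning speed ``b``."""

    a: float
    b: float
    sse: float


def dprime(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> float:
    """Signal-detection d' with the 1/(2N) extreme-rate correction.

    Hit and false-alarm rates are clipped to [1/(2N), 1 - 1/(2N)] (N = number
    of target / non-target trials respectively) so perfect rates stay finite.
    """
    n_t = hits + misses
    n_n = false_alarms + correct_rejections
    if n_t < 1 or n_n < 1:
        raise ValueError("need at least one target and one non-target trial")
    hr = np.clip(hits / n_t, 1 / (2 * n_t), 1 - 1 / (2 * n_t))
    fr = np.clip(false_alarms / n_n, 1 / (2 * n_n), 1 - 1 / (2 * n_n))
    return float(norm.ppf(hr) - norm.ppf(fr))


def moving_average(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges.

    ``window`` must be odd and no longer than the series.  Output has the
    same length as the input; constant and linear inputs are preserved in the
    interior.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window > y.shape[0]:
        raise ValueError("window longer than the series")
    half = window // 2
    out = np.empty_like(y)
    n = y.shape[0]
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = y[i - h : i + h + 1].mean()
    return out


def fit_inverse_curve(
    curve: LearningCurve | None = None,
    y: np.ndarray | None = None,
    x: np.ndarray | None = None,
) -> PlateauFit:
    """Least-squares fit of y = a - b/x.

    Linear in the parameters, so the fit is the closed-form regression of y
    on 1/x (intercept = a, slope = -b); deterministic, no iterative
    optimisation.  When a :class:`LearningCurve` is passed its ``smoothed``
    trajectory is fitted if present, otherwise the raw d' values; smoothing
    itself is a separate, explicit step (:func:`moving_average`).
    """
    if curve is not None:
        x = curve.sessions
        y = curve.smoothed if curve.smoothed is not None else curve.dprime
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 sessions to fit the inverse curve")
    if np.all(x == x[0]):
        raise ValueError("degenerate session indices: all equal")
    X = np.column_stack([np.ones_like(x), 1.0 / x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, neg_b = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    return PlateauFit(a=a, b=-neg_b, sse=float(resid @ resid))


def plateau_from_sessions(
    dprimes: np.ndarray, window: int = 5
) -> tuple[PlateauFit, LearningCurve]:
    """Smooth per-session d' with a moving average and fit the plateau."""
    dprimes = np.asarray(dprimes, dtype=float)
    sessions = np.arange(1, dprimes.shape[0] + 1, dtype=float)
    w = min(window, dprimes.shape[0])
    if w % 2 == 0:
        w -= 1
    smoothed = moving_average(dprimes, w)
    curve = LearningCurve(sessions=sessions, dprime=dprimes, smoothed=smoothed)
    return fit_inverse_curve(curve), curve


def session_dprimes(counts: np.ndarray) -> np.ndarray:
    """d' per session from a (sessions x 4) array of
    [hits, misses, false_alarms, correct_rejections] counts."""
    counts = np.asarray(counts)
    return np.array([dprime(*row) for row in counts])
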