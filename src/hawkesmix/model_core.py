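"""Domain types and conditional-intensity evaluation.

A space-time self-exciting (Hawkes) point process on a rectangle
``S = [x_lo, x_hi] x [y_lo, y_hi]`` and half-open time window
``D = [t_lo, t_hi)`` has conditional intensity

    lambda(x, y, t | H_t) = mu(x, y) + sum_{i : t_i < t} g(x - x_i, y - y_i, t - t_i)

with a temporally constant background modelled as a sum of ``p + 1``
Gaussian-type exponent components,

    mu(x, y) = sum_j a_j exp(-alpha_mu_j (x - c_j)^2 - beta_mu_j (y - d_j)^2),

and a triggering kernel modelled as a sum of ``q + 1`` separable
Gaussian-in-space, exponential-in-time components,

    g(dx, dy, dt) = sum_j b_j exp(-alpha_g_j dx^2 - beta_g_j dy^2 - gamma_g_j dt).

All units are abstract; by convention coordinates are kilometres and times
are days.  Nothing converts units implicitly.

The module also defines the truncated intensity used to accelerate the
likelihood: with a time bound ``z``, let

    n_star = max_k #{ j : t_k - z <= t_j < t_k },

and approximate the triggering sum at event ``k`` by the sum over the
``min(n_star, k)`` immediately preceding events (a fixed-width history
window; events older than ``z`` may enter when the window is sparse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventCatalog",
    "SpatialRegion",
    "TimeWindow",
    "BackgroundParams",
    "TriggerParams",
    "ModelSpec",
    "eval_background",
    "eval_trigger",
    "trigger_total_mass",
    "conditional_intensity",
    "truncated_intensity",
    "compute_n_star",
]


def _as_1d_float(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim == 0:
        out = out.reshape(1)
    if out.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    return out


@dataclass(frozen=True)
class EventCatalog:
    """Time-sorted events (x_i, y_i, t_i).

    Invariants: the three arrays share length ``n``, times are
    nondecreasing and finite.  Ties in ``t`` are allowed and keep their
    input order; under the strict ``t_i < t`` convention equal-time events
    never trigger one another.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        x = _as_1d_float(self.x, "x")
        y = _as_1d_float(self.y, "y")
        t = _as_1d_float(self.t, "t")
        if not (len(x) == len(y) == len(t)):
            raise ValueError("x, y, t must have equal length")
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be nondecreasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)

    @property
    def n(self) -> int:
        return len(self.t)

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_unsorted(cls, x, y, t) -> "EventCatalog":
        """Build a catalog from arbitrary-order events, sorting by time.

        The sort is stable, so equal-time events keep their input order.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = np.asarray(t, dtype=float)
        order = np.argsort(t, kind="stable")
        return cls(x[order], y[order], t[order])


@dataclass(frozen=True)
class SpatialRegion:
    """Axis-aligned spatial observation rectangle [x_lo, x_hi] x [y_lo, y_hi]."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self):
        if not (self.x_lo < self.x_hi and self.y_lo < self.y_hi):
            raise ValueError("region bounds must satisfy lo < hi")

    @property
    def area(self) -> float:
        return (self.x_hi - self.x_lo) * (self.y_hi - self.y_lo)

    def contains(self, x, y) -> np.ndarray:
        return (
            (x >= self.x_lo) & (x <= self.x_hi) & (y >= self.y_lo) & (y <= self.y_hi)
        )


@dataclass(frozen=True)
class TimeWindow:
    """Half-open observation window [t_lo, t_hi)."""

    t_lo: float
    t_hi: float

    def __post_init__(self):
        if not self.t_lo < self.t_hi:
            raise ValueError("time window must satisfy t_lo < t_hi")

    @property
    def length(self) -> float:
        return self.t_hi - self.t_lo


def _check_positive(arr: np.ndarray, name: str) -> None:
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and strictly positive")


@dataclass(frozen=True)
class BackgroundParams:
    """Background kernel parameters: p + 1 Gaussian-type exponent components.

    Component j contributes ``a_j exp(-alpha_j (x - c_j)^2 - beta_j (y - d_j)^2)``;
    ``a`` is a rate amplitude (events per km^2 per day at the peak), ``alpha``
    and ``beta`` are spatial decay rates (km^-2) and (c, d) the component mean.
    """

    a: np.ndarray
    c: np.ndarray
    d: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        a = _as_1d_float(self.a, "a")
        c = _as_1d_float(self.c, "c")
        d = _as_1d_float(self.d, "d")
        alpha = _as_1d_float(self.alpha, "alpha")
        beta = _as_1d_float(self.beta, "beta")
        m = len(a)
        if not all(len(v) == m for v in (c, d, alpha, beta)):
            raise ValueError("background component arrays must share length")
        if m < 1:
            raise ValueError("need at least one background component")
        _check_positive(a, "a")
        _check_positive(alpha, "alpha")
        _check_positive(beta, "beta")
        for nm, v in (("a", a), ("c", c), ("d", d), ("alpha", alpha), ("beta", beta)):
            object.__setattr__(self, nm, v)

    @property
    def p(self) -> int:
        return len(self.a) - 1

    def total_mass_per_time(self) -> float:
        """Integral of mu over the full plane, per unit time."""
        return float(np.sum(self.a * np.pi / np.sqrt(self.alpha * self.beta)))


@dataclass(frozen=True)
class TriggerParams:
    """Triggering kernel parameters: q + 1 separable components.

    Component j contributes ``b_j exp(-alpha_j dx^2 - beta_j dy^2 - gamma_j dt)``
    for forward lags dt >= 0; ``gamma`` is the temporal decay rate (day^-1).
    """

    b: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        b = _as_1d_float(self.b, "b")
        alpha = _as_1d_float(self.alpha, "alpha")
        beta = _as_1d_float(self.beta, "beta")
        gamma = _as_1d_float(self.gamma, "gamma")
        m = len(b)
        if not all(len(v) == m for v in (alpha, beta, gamma)):
            raise ValueError("trigger component arrays must share length")
        if m < 1:
            raise ValueError("need at least one trigger component")
        for nm, v in (("b", b), ("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            _check_positive(v, nm)
            object.__setattr__(self, nm, v)

    @property
    def q(self) -> int:
        return len(self.b) - 1

    def check_subcritical(self, warn: bool = True) -> bool:
        """True when the branching ratio is below one (stationarity)."""
        mass = trigger_total_mass(self)
        ok = mass < 1.0
        if not ok and warn:
            warnings.warn(
                f"triggering mass {mass:.4f} >= 1: the process is supercritical",
                stacklevel=2,
            )
        return ok


@dataclass(frozen=True)
class ModelSpec:
    """A full intensity model plus its truncation settings.

    ``z`` is the truncation time bound used to derive ``n_star``; ``n_star``
    is the fixed history-window width of the modified truncated intensity.
    ``n_star = None`` means full history.
    """

    background: BackgroundParams
    trigger: TriggerParams
    z: float = 200.0
    n_star: int | None = None

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.n_star is not None and self.n_star < 0:
            raise ValueError("n_star must be nonnegative")


# ---------------------------------------------------------------------------
# Intensity evaluation
# ---------------------------------------------------------------------------


def eval_background(bg: BackgroundParams, x, y) -> np.ndarray | float:
    """Background intensity mu(x, y); vectorises over query points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("query coordinates must be finite")
    dx2 = (x[..., None] - bg.c) ** 2
    dy2 = (y[..., None] - bg.d) ** 2
    vals = np.sum(bg.a * np.exp(-bg.alpha * dx2 - bg.beta * dy2), axis=-1)
    return vals if vals.ndim else float(vals)


def eval_trigger(tr: TriggerParams, dx, dy, dt) -> np.ndarray | float:
    """Triggering kernel g(dx, dy, dt) for forward lags dt >= 0."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("triggering acts forward in time only (dt >= 0)")
    expo = (
        -tr.alpha * dx[..., None] ** 2
        - tr.beta * dy[..., None] ** 2
        - tr.gamma * dt[..., None]
    )
    vals = np.sum(tr.b * np.exp(expo), axis=-1)
    return vals if vals.ndim else float(vals)


def trigger_total_mass(tr: TriggerParams) -> float:
    """Branching ratio: integral of g over the plane and forward time.

    Each component integrates to ``b pi / (gamma sqrt(alpha beta))``; the
    process is subcritical (stationary) when the sum is below one.
    """
    return float(
        np.sum(tr.b * np.pi / (tr.gamma * np.sqrt(tr.alpha * tr.beta)))
    )


def conditional_intensity(model: ModelSpec, cat: EventCatalog, x, y, t) -> float:
    """Full-history conditional intensity lambda(x, y, t | H_t).

    Sums the triggering kernel over all catalog events with ``t_i < t``
    (strict inequality: an event at exactly ``t`` contributes nothing).
    """
    x = float(x)
    y = float(y)
    t = float(t)
    k = int(np.searchsorted(cat.t, t, side="left"))
    mu = eval_background(model.background, x, y)
    if k == 0:
        return float(mu)
    g = eval_trigger(
        model.trigger, x - cat.x[:k], y - cat.y[:k], t - cat.t[:k]
    )
    return float(mu + np.sum(g))


def truncated_intensity(model: ModelSpec, cat: EventCatalog, k: int) -> float:
    """Modified truncated intensity at event ``k`` (0-based index).

    Sums triggering over exactly the ``min(n_star, k)`` immediately
    preceding events; indices below zero contribute nothing, and so do
    preceding events whose timestamp equals ``t_k`` (strict inequality).
    With ``n_star = None`` or ``n_star >= k`` this equals the full
    conditional intensity at (x_k, y_k, t_k).
    """
    if not 0 <= k < cat.n:
        raise IndexError(f"event index {k} out of range for catalog of size {cat.n}")
    n_star = model.n_star if model.n_star is not None else cat.n
    lo = max(0, k - n_star)
    mu = eval_background(model.background, cat.x[k], cat.y[k])
    if lo == k:
        return float(mu)
    dt = cat.t[k] - cat.t[lo:k]
    keep = dt > 0
    if not np.any(keep):
        return float(mu)
    g = eval_trigger(
        model.trigger,
        cat.x[k] - cat.x[lo:k][keep],
        cat.y[k] - cat.y[lo:k][keep],
        dt[keep],
    )
    return float(mu + np.sum(g))


def compute_n_star(cat: EventCatalog, z: float) -> int:
    """Maximum number of events inside any trailing window [t_k - z, t_k).

    This is the fixed history-window width of the modified truncated
    intensity.  Returns 0 for an empty catalog.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    if cat.n == 0:
        return 0
    upper = np.searchsorted(cat.t, cat.t, side="left")
    lower = np.searchsorted(cat.t, cat.t - z, side="left")
    return int(np.max(upper - lower))
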