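"""Branching (cluster) simulation of space-time self-exciting processes.

The generating model is the classical immigrant/offspring construction:

* immigrants arrive as a Poisson stream, homogeneous in time with rate
  ``mu_bar``, with locations drawn from a correlated bivariate normal
  centred at (c, d) with common scale ``sigma_mu`` and correlation ``rho``;
* every event, independently and for each trigger component m, spawns a
  Poisson(theta_m) number of direct offspring with Exp(omega_m) forward
  time lags and correlated bivariate-normal spatial offsets
  (sigma_x_m, sigma_y_m, rho);
* generations iterate until extinction; subcriticality requires
  ``sum_m theta_m < 1``.

Both kernels are normalised as proper correlated bivariate normal
densities — including the ``sqrt(1 - rho^2)`` factor in the normalising
constant — so that the background integrates to exactly ``mu_bar`` per
unit time and the triggering kernel to exactly ``sum_m theta_m``.

The default experiment protocol sorts all events by time, discards the
first and last ``trim`` (default 2000) events so the retained segment
reflects the stationary regime, clips to the spatial region, truncates to
``target_n`` events and re-zeroes time.

:func:`burglary_single_kernel` and :func:`burglary_two_component_kernel`
are the reference burglary-like generating models used throughout the
package's simulation experiments (a tight fast-decaying cluster kernel on
a 20 x 20 km domain, plus a broader slower second component in the
two-component variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    EventCatalog,
    ModelSpec,
    SpatialRegion,
    TimeWindow,
)

__all__ = [
    "TriggerComponent",
    "SimKernel",
    "SimConfig",
    "burglary_single_kernel",
    "burglary_two_component_kernel",
    "burglary_region",
    "simkernel_to_model",
    "model_to_simkernel",
    "sim_kernel_masses",
    "simulate_catalog",
    "simulate_branching",
    "simulate_homogeneous",
    "simulate_residual_superposition",
]


@dataclass(frozen=True)
class TriggerComponent:
    """Natural-scale trigger component: mass, temporal rate, spatial scales."""

    theta: float
    omega: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self):
        if not (self.theta >= 0 and self.omega > 0 and self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError("require theta >= 0 and omega, sigma_x, sigma_y > 0")


@dataclass(frozen=True)
class SimKernel:
    """Natural-scale generating model: normalised correlated Gaussian kernels.

    Background: ``mu_bar`` x bivariate normal((c, d), sigma_mu, rho).
    Trigger: ``sum_m theta_m`` x [Exp(omega_m) density in time] x
    [bivariate normal(0, (sigma_x_m, sigma_y_m), rho) in space].
    """

    mu_bar: float
    sigma_mu: float
    c: float
    d: float
    rho: float = 0.0
    components: tuple = ()

    def __post_init__(self):
        if not (self.mu_bar > 0 and self.sigma_mu > 0):
            raise ValueError("mu_bar and sigma_mu must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be below 1")
        comps = tuple(self.components)
        total = sum(c.theta for c in comps)
        if not 0 <= total < 1:
            raise ValueError(
                f"total trigger mass {total:.3f} must lie in [0, 1) for stationarity"
            )
        object.__setattr__(self, "components", comps)


def burglary_region() -> SpatialRegion:
    """The 20 x 20 km reference simulation domain."""
    return SpatialRegion(0.0, 20.0, 0.0, 20.0)


def burglary_single_kernel(rho: float = 0.0) -> SimKernel:
    """Single-component reference model: one tight, fast-decaying cluster kernel."""
    return SimKernel(
        mu_bar=5.71,
        sigma_mu=4.5,
        c=10.0,
        d=10.0,
        rho=rho,
        components=(TriggerComponent(theta=0.2, omega=0.1, sigma_x=0.01, sigma_y=0.1),),
    )


def burglary_two_component_kernel(rho: float = 0.0) -> SimKernel:
    """Two-component reference model: the single kernel plus a broader, faster one."""
    return SimKernel(
        mu_bar=5.71,
        sigma_mu=4.5,
        c=10.0,
        d=10.0,
        rho=rho,
        components=(
            TriggerComponent(theta=0.2, omega=0.1, sigma_x=0.01, sigma_y=0.1),
            TriggerComponent(theta=0.3, omega=0.2, sigma_x=0.2, sigma_y=0.05),
        ),
    )


def sim_kernel_masses(k: SimKernel) -> tuple[float, float]:
    """(background mass per unit time, total trigger mass), in closed form.

    Integrates each kernel analytically: a quadratic exponent
    ``-u' Q u / 2`` integrates to ``2 pi / sqrt(det Q)`` over the plane and
    the temporal factor ``omega e^{-omega t}`` to one over forward time.
    """
    one_m_r2 = 1.0 - k.rho**2

    def gauss_plane_integral(sx: float, sy: float) -> float:
        # inverse covariance of the correlated bivariate normal
        q_xx = 1.0 / (sx**2 * one_m_r2)
        q_yy = 1.0 / (sy**2 * one_m_r2)
        q_xy = -k.rho / (sx * sy * one_m_r2)
        det_q = q_xx * q_yy - q_xy**2
        return 2.0 * math.pi / math.sqrt(det_q)

    bg_amp = k.mu_bar / (2.0 * math.pi * k.sigma_mu**2 * math.sqrt(one_m_r2))
    bg_mass = bg_amp * gauss_plane_integral(k.sigma_mu, k.sigma_mu)
    trig_mass = 0.0
    for comp in k.components:
        amp = comp.theta * comp.omega / (
            2.0 * math.pi * comp.sigma_x * comp.sigma_y * math.sqrt(one_m_r2)
        )
        trig_mass += amp * gauss_plane_integral(comp.sigma_x, comp.sigma_y) / comp.omega
    return float(bg_mass), float(trig_mass)


def simkernel_to_model(k: SimKernel, z: float = 200.0) -> ModelSpec:
    """Exact raw-parameter equivalent of a rho = 0 generating kernel.

    ``b = theta omega / (2 pi sigma_x sigma_y)``, ``alpha = 1/(2 sigma_x^2)``,
    ``beta = 1/(2 sigma_y^2)``, ``gamma = omega``; likewise for the
    background.  The fitted family has no correlation term, so this mapping
    is only exact at rho = 0.
    """
    from .model_core import BackgroundParams, TriggerParams

    if k.rho != 0.0:
        raise ValueError("raw Gaussian-exponent form is exact only for rho = 0")
    bg = BackgroundParams(
        a=[k.mu_bar / (2 * np.pi * k.sigma_mu**2)],
        c=[k.c],
        d=[k.d],
        alpha=[1.0 / (2 * k.sigma_mu**2)],
        beta=[1.0 / (2 * k.sigma_mu**2)],
    )
    tr = TriggerParams(
        b=[c.theta * c.omega / (2 * np.pi * c.sigma_x * c.sigma_y) for c in k.components],
        alpha=[1.0 / (2 * c.sigma_x**2) for c in k.components],
        beta=[1.0 / (2 * c.sigma_y**2) for c in k.components],
        gamma=[c.omega for c in k.components],
    )
    return ModelSpec(background=bg, trigger=tr, z=z)


def model_to_simkernel_components(model: ModelSpec):
    """Branching representation of a fitted raw-parameter model.

    Returns (background components, trigger components) where background
    components are (rate per unit time, cx, cy, sx, sy) tuples and trigger
    components are :class:`TriggerComponent`.
    """
    bg = model.background
    tr = model.trigger
    bg_comps = [
        (
            float(bg.a[j] * np.pi / np.sqrt(bg.alpha[j] * bg.beta[j])),
            float(bg.c[j]),
            float(bg.d[j]),
            float(1.0 / np.sqrt(2 * bg.alpha[j])),
            float(1.0 / np.sqrt(2 * bg.beta[j])),
        )
        for j in range(bg.p + 1)
    ]
    trig_comps = [
        TriggerComponent(
            theta=float(tr.b[j] * np.pi / (tr.gamma[j] * np.sqrt(tr.alpha[j] * tr.beta[j]))),
            omega=float(tr.gamma[j]),
            sigma_x=float(1.0 / np.sqrt(2 * tr.alpha[j])),
            sigma_y=float(1.0 / np.sqrt(2 * tr.beta[j])),
        )
        for j in range(tr.q + 1)
    ]
    return bg_comps, trig_comps


def model_to_simkernel(model: ModelSpec) -> SimKernel:
    """SimKernel equivalent of a single-background-component fitted model."""
    bg_comps, trig_comps = model_to_simkernel_components(model)
    if len(bg_comps) != 1:
        raise ValueError("model_to_simkernel requires a single background component")
    rate, cx, cy, sx, sy = bg_comps[0]
    if not math.isclose(sx, sy, rel_tol=1e-9):
        # SimKernel carries one sigma_mu; keep the geometric mean
        sx = sy = math.sqrt(sx * sy)
    return SimKernel(
        mu_bar=rate, sigma_mu=sx, c=cx, d=cy, rho=0.0, components=tuple(trig_comps)
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation run settings.

    ``target_n`` is the post-trim, post-clip catalog size; the immigrant
    time span is extended automatically until it is reached.  ``trim``
    events are discarded at each end of the time-sorted sequence (burn-in
    and burn-out); set ``trim=0`` to disable.
    """

    kernel: object  # SimKernel or ModelSpec
    region: SpatialRegion
    target_n: int
    trim: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.target_n <= 0:
            raise ValueError("target_n must be positive")
        if self.trim < 0:
            raise ValueError("trim must be nonnegative")
        if self.trim > 0 and self.target_n <= 2 * self.trim:
            raise ValueError("target_n must exceed 2 * trim when trimming is enabled")


def _kernel_pieces(kernel) -> tuple[list, list, float]:
    """Normalise SimKernel / ModelSpec to branching pieces + rho."""
    if isinstance(kernel, SimKernel):
        bg_comps = [(kernel.mu_bar, kernel.c, kernel.d, kernel.sigma_mu, kernel.sigma_mu)]
        return bg_comps, list(kernel.components), kernel.rho
    if isinstance(kernel, ModelSpec):
        bg_comps, trig_comps = model_to_simkernel_components(kernel)
        return bg_comps, trig_comps, 0.0
    raise TypeError("kernel must be a SimKernel or a ModelSpec")


def _correlated_offsets(rng, m, sx, sy, rho):
    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    return sx * u, sy * (rho * u + math.sqrt(1.0 - rho**2) * v)


def simulate_branching(
    kernel, t_span: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw branching realisation over immigrant span [0, t_span].

    Returns time-sorted ``(t, x, y, parent, generation)`` where
    ``parent = -1`` marks immigrants and otherwise indexes the direct
    ancestor in the returned (sorted) arrays.  Offspring may fall after
    ``t_span`` or outside any spatial region; no clipping happens here.
    """
    bg_comps, trig_comps, rho = _kernel_pieces(kernel)
    total_mass = sum(c.theta for c in trig_comps)
    if total_mass >= 1:
        raise ValueError(f"supercritical kernel: trigger mass {total_mass:.3f} >= 1")

    ts, xs, ys, parents, gens = [], [], [], [], []
    for rate, cx, cy, sx, sy in bg_comps:
        m = rng.poisson(rate * t_span)
        dx, dy = _correlated_offsets(rng, m, sx, sy, rho)
        ts.append(rng.uniform(0.0, t_span, m))
        xs.append(cx + dx)
        ys.append(cy + dy)
        parents.append(np.full(m, -1, dtype=np.int64))
        gens.append(np.zeros(m, dtype=np.int64))

    cur_t = np.concatenate(ts)
    cur_x = np.concatenate(xs)
    cur_y = np.concatenate(ys)
    current = np.arange(len(cur_t))  # global indices of the current generation
    n_total = len(cur_t)
    gen = 0
    while len(current):
        gen += 1
        new_t, new_x, new_y, new_parent = [], [], [], []
        for comp in trig_comps:
            counts = rng.poisson(comp.theta, len(current))
            par_local = np.repeat(np.arange(len(current)), counts)
            m = len(par_local)
            if m == 0:
                continue
            lag = rng.exponential(1.0 / comp.omega, m)
            dx, dy = _correlated_offsets(rng, m, comp.sigma_x, comp.sigma_y, rho)
            new_t.append(cur_t[par_local] + lag)
            new_x.append(cur_x[par_local] + dx)
            new_y.append(cur_y[par_local] + dy)
            new_parent.append(current[par_local])
        if not new_t:
            break
        cur_t = np.concatenate(new_t)
        cur_x = np.concatenate(new_x)
        cur_y = np.concatenate(new_y)
        npar = np.concatenate(new_parent)
        ts.append(cur_t)
        xs.append(cur_x)
        ys.append(cur_y)
        parents.append(npar)
        gens.append(np.full(len(cur_t), gen, dtype=np.int64))
        current = np.arange(n_total, n_total + len(cur_t))
        n_total += len(cur_t)

    t = np.concatenate(ts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    parent = np.concatenate(parents)
    genv = np.concatenate(gens)
    order = np.argsort(t, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_parent = np.where(parent >= 0, rank[np.maximum(parent, 0)], -1)
    return t[order], x[order], y[order], new_parent[order], genv[order]


def simulate_catalog(cfg: SimConfig, return_duration: bool = False):
    """Simulate a catalog per the burn-in protocol.

    Branching realisation -> global time sort -> discard the first and last
    ``trim`` events -> clip to ``region`` -> truncate to ``target_n``
    events -> re-zero time at the first retained event.  The immigrant time
    span is extended (with fresh random substreams) until the post-trim,
    post-clip catalog reaches ``target_n``.  Bit-reproducible for a fixed
    seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    bg_comps, trig_comps, _ = _kernel_pieces(cfg.kernel)
    bg_rate = sum(c[0] for c in bg_comps)
    mass = sum(c.theta for c in trig_comps)
    if mass >= 1:
        raise ValueError(f"supercritical kernel: trigger mass {mass:.3f} >= 1")
    # rough in-region acceptance probability, refined by the extension loop
    needed = (cfg.target_n / 0.9 + 2 * cfg.trim) * 1.15
    t_span = needed * (1.0 - mass) / bg_rate

    for attempt, child in enumerate(ss.spawn(12)):
        rng = np.random.default_rng(child)
        t, x, y, parent, gen = simulate_branching(cfg.kernel, t_span, rng)
        if cfg.trim > 0:
            if len(t) <= 2 * cfg.trim:
                t_span *= 1.6
                continue
            sl = slice(cfg.trim, len(t) - cfg.trim)
            t, x, y = t[sl], x[sl], y[sl]
        keep = cfg.region.contains(x, y)
        t, x, y = t[keep], x[keep], y[keep]
        if len(t) >= cfg.target_n:
            t, x, y = t[: cfg.target_n], x[: cfg.target_n], y[: cfg.target_n]
            t0 = t[0]
            cat = EventCatalog(x, y, t - t0)
            if return_duration:
                return cat, float(t[-1] - t0)
            return cat
        t_span *= 1.4
    raise RuntimeError("failed to reach target_n after extending the time span")


def simulate_homogeneous(
    rate: float,
    region: SpatialRegion,
    window: TimeWindow,
    seed: int | np.random.Generator = 0,
) -> EventCatalog:
    """Homogeneous Poisson catalog with intensity ``rate`` on S x D."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = rng.poisson(rate * region.area * window.length)
    t = np.sort(rng.uniform(window.t_lo, window.t_hi, m))
    x = rng.uniform(region.x_lo, region.x_hi, m)
    y = rng.uniform(region.y_lo, region.y_hi, m)
    return EventCatalog(x, y, t)


def simulate_residual_superposition(
    model: ModelSpec,
    cat: EventCatalog,
    k: float,
    region: SpatialRegion,
    window: TimeWindow,
    seed: int | np.random.Generator = 0,
) -> EventCatalog:
    """Inhomogeneous Poisson points with intensity ``max(k - lambda_hat, 0)``.

    Simulated by thinning a dominating homogeneous process of rate ``k``:
    a candidate at (x, y, t) is kept with probability
    ``max(k - lambda_hat(x, y, t), 0) / k`` where ``lambda_hat`` is the
    model's conditional intensity given the observed catalog history.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cand = simulate_homogeneous(k, region, window, rng)
    if cand.n == 0:
        return cand
    lam = _intensity_at_points(model, cat, cand.x, cand.y, cand.t)
    accept = rng.uniform(size=cand.n) < np.maximum(k - lam, 0.0) / k
    return EventCatalog(cand.x[accept], cand.y[accept], cand.t[accept])


def _intensity_at_points(
    model: ModelSpec, cat: EventCatalog, x: np.ndarray, y: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Vectorised full-history conditional intensity at arbitrary points."""
    from .model_core import eval_background

    lam = np.asarray(eval_background(model.background, x, y), dtype=float).copy()
    if cat.n == 0:
        return lam
    tr = model.trigger
    # chunk over query points to bound the (points x events) workspace
    chunk = max(1, int(4e6 // max(cat.n, 1)))
    for lo in range(0, len(t), chunk):
        hi = min(lo + chunk, len(t))
        dt = t[lo:hi, None] - cat.t[None, :]
        mask = dt > 0
        dx2 = (x[lo:hi, None] - cat.x[None, :]) ** 2
        dy2 = (y[lo:hi, None] - cat.y[None, :]) ** 2
        acc = np.zeros(hi - lo)
        for j in range(tr.q + 1):
            e = np.exp(-tr.alpha[j] * dx2 - tr.beta[j] * dy2 - tr.gamma[j] * np.where(mask, dt, 0.0))
            acc += tr.b[j] * np.sum(np.where(mask, e, 0.0), axis=1)
        lam[lo:hi] += acc
    return lam
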