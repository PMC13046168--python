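"""Residual diagnostics: thinning, super-thinning, Ripley K / centered L.

A correctly specified conditional intensity can be reduced to a
homogeneous Poisson process by random thinning.  Plain thinning at rate
``b = inf lambda_hat`` discards most points; *super-thinning* instead picks
an intermediate rate ``k``, thins where the fitted intensity exceeds ``k``
(keep probability ``min(k / lambda_hat_i, 1)``) and superposes simulated
points with intensity ``max(k - lambda_hat, 0)`` where it falls below.
Under the true model the combined residual process is homogeneous Poisson
with rate ``k``.

Spatial homogeneity of the residuals is then summarised by the
edge-corrected Ripley K function

    K_hat(d) = |S| n^{-2} sum_i sum_{j != i} w(s_i, s_j)^{-1} 1{d_ij < d},

where ``w`` is the fraction of the circumference of the circle centred at
``s_i`` with radius ``d_ij`` lying inside S, and by the centered L
function ``L(d) - d = sqrt(K_hat(d) / pi) - d`` (zero in expectation for
homogeneous Poisson).  Monte-Carlo envelopes come from simulated
homogeneous catalogs at the same rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .likelihood import (
    background_compensator,
    build_history_pairs,
    trigger_compensator,
    trigger_history_sums,
)
from .model_core import (
    EventCatalog,
    ModelSpec,
    SpatialRegion,
    TimeWindow,
    eval_background,
)
from .simulate import simulate_homogeneous, simulate_residual_superposition

__all__ = [
    "KLResult",
    "ThinningResult",
    "default_distance_grid",
    "intensity_at_events",
    "thin",
    "superthin_rate",
    "super_thin",
    "ripley_K",
    "centered_L",
    "mc_envelope",
    "superthin_diagnostic",
    "temporal_uniformity",
]

_N_CIRCLE = 512  # points per circle for the numeric circumference fraction


@dataclass(frozen=True)
class KLResult:
    """Distance grid with K, L, centered L and Monte-Carlo envelope bands.

    ``env_lo``/``env_hi`` are the pointwise 2.5%/97.5% quantiles of the
    centered L function over ``M`` homogeneous Poisson replicates and
    ``mean_L`` their mean.  When produced by :func:`superthin_diagnostic`,
    ``st_lo``/``st_hi``/``st_mean`` additionally describe the band over
    repeated super-thinnings of the data themselves.
    """

    distances: np.ndarray
    K: np.ndarray
    L: np.ndarray
    centered_L: np.ndarray
    env_lo: np.ndarray
    env_hi: np.ndarray
    mean_L: np.ndarray
    M: int
    st_lo: np.ndarray | None = None
    st_hi: np.ndarray | None = None
    st_mean: np.ndarray | None = None


@dataclass(frozen=True)
class ThinningResult:
    """Super-thinning output: retained, superposed and combined catalogs."""

    retained: EventCatalog
    superposed: EventCatalog
    combined: EventCatalog
    rate_k: float
    seed: int


def default_distance_grid(region: SpatialRegion, m: int = 50) -> np.ndarray:
    """m distances from 0 to a quarter of the shorter region side."""
    d_max = min(region.x_hi - region.x_lo, region.y_hi - region.y_lo) / 4.0
    return np.linspace(0.0, d_max, m)


def intensity_at_events(model: ModelSpec, cat: EventCatalog) -> np.ndarray:
    """Fitted (truncated) conditional intensity at every event of the catalog."""
    pairs = build_history_pairs(cat, model.n_star)
    g = trigger_history_sums(model.trigger, cat, model.n_star, pairs=pairs)
    return np.asarray(
        eval_background(model.background, cat.x, cat.y) + g @ model.trigger.b
    )


def thin(
    cat: EventCatalog,
    intensity_at_events_: np.ndarray,
    b: float,
    seed: int | np.random.Generator = 0,
) -> EventCatalog:
    """Keep each event independently with probability min(b / lambda_i, 1)."""
    if b < 0:
        raise ValueError("b must be nonnegative")
    lam = np.asarray(intensity_at_events_, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("intensities must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.uniform(size=cat.n) < np.minimum(b / lam, 1.0)
    return EventCatalog(cat.x[keep], cat.y[keep], cat.t[keep])


def superthin_rate(
    model: ModelSpec, cat: EventCatalog, region: SpatialRegion, window: TimeWindow
) -> float:
    """Mean fitted intensity over S x D, k = (1/|S||D|) * integral of lambda_hat.

    The closed-form compensators make this exact — no numerical
    integration.
    """
    total = background_compensator(model.background, region, window)
    total += trigger_compensator(model.trigger, cat, region, window)
    return float(total / (region.area * window.length))


def super_thin(
    model: ModelSpec,
    cat: EventCatalog,
    region: SpatialRegion,
    window: TimeWindow,
    k: float | None = None,
    seed: int = 0,
    intensities: np.ndarray | None = None,
) -> ThinningResult:
    """Super-thin the catalog at rate ``k`` (default: the mean intensity).

    Thins with ``b = k`` and superposes simulated points with intensity
    ``max(k - lambda_hat, 0)``; the combined process is homogeneous Poisson
    at rate ``k`` when the model is correct.  ``intensities`` may carry
    precomputed fitted intensities at the events (they do not depend on the
    thinning seed).
    """
    if k is None:
        k = superthin_rate(model, cat, region, window)
    if k <= 0:
        raise ValueError("k must be positive")
    ss = np.random.SeedSequence(seed)
    rng_thin, rng_sup = (np.random.default_rng(s) for s in ss.spawn(2))
    lam = intensities if intensities is not None else intensity_at_events(model, cat)
    retained = thin(cat, lam, k, rng_thin)
    superposed = simulate_residual_superposition(model, cat, k, region, window, rng_sup)
    combined = EventCatalog.from_unsorted(
        np.concatenate([retained.x, superposed.x]),
        np.concatenate([retained.y, superposed.y]),
        np.concatenate([retained.t, superposed.t]),
    )
    return ThinningResult(
        retained=retained, superposed=superposed, combined=combined, rate_k=float(k), seed=seed
    )


@njit(cache=True)
def _pair_weights(px, py, r, x_lo, x_hi, y_lo, y_hi, cos_tab, sin_tab):
    """Circumference fraction inside the rectangle, per (center, radius) pair.

    Exact 1.0 shortcut when the circle lies fully inside; otherwise the
    fraction of the tabulated evenly spaced circle points falling in the
    rectangle, floored at one point.
    """
    out = np.empty(len(px))
    n_circle = len(cos_tab)
    for p in range(len(px)):
        rad = r[p]
        if (
            px[p] - x_lo >= rad
            and x_hi - px[p] >= rad
            and py[p] - y_lo >= rad
            and y_hi - py[p] >= rad
        ):
            out[p] = 1.0
            continue
        inside = 0
        for a in range(n_circle):
            qx = px[p] + rad * cos_tab[a]
            qy = py[p] + rad * sin_tab[a]
            if x_lo <= qx <= x_hi and y_lo <= qy <= y_hi:
                inside += 1
        if inside == 0:
            inside = 1
        out[p] = inside / n_circle
    return out


_ANGLES = 2.0 * np.pi * np.arange(_N_CIRCLE) / _N_CIRCLE
_COS_TAB = np.cos(_ANGLES)
_SIN_TAB = np.sin(_ANGLES)


def ripley_K(
    cat: EventCatalog, region: SpatialRegion, distances: np.ndarray
) -> np.ndarray:
    """Edge-corrected Ripley K on the catalog's spatial projection.

    Uses the ``n^{-2}`` normalisation and the circumference-fraction edge
    correction evaluated at the first point of each ordered pair.
    """
    distances = np.asarray(distances, dtype=float)
    n = cat.n
    if n < 2:
        raise ValueError("ripley_K requires at least 2 points")
    d_max = float(np.max(distances))
    dx = cat.x[:, None] - cat.x[None, :]
    dy = cat.y[:, None] - cat.y[None, :]
    dist = np.sqrt(dx**2 + dy**2)
    ii, jj = np.nonzero((dist < d_max) & ~np.eye(n, dtype=bool))
    if len(ii) == 0:
        return np.zeros_like(distances)
    dij = dist[ii, jj]
    w = _pair_weights(
        cat.x[ii],
        cat.y[ii],
        dij,
        region.x_lo,
        region.x_hi,
        region.y_lo,
        region.y_hi,
        _COS_TAB,
        _SIN_TAB,
    )
    order = np.argsort(dij)
    d_sorted = dij[order]
    cum = np.concatenate([[0.0], np.cumsum(1.0 / w[order])])
    counts = cum[np.searchsorted(d_sorted, distances, side="left")]
    return region.area / n**2 * counts


def centered_L(K: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """sqrt(K / pi) - d: zero in expectation for homogeneous Poisson."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("K must be nonnegative")
    return np.sqrt(K / np.pi) - np.asarray(distances, dtype=float)


def _centered_L_of(cat: EventCatalog, region: SpatialRegion, distances) -> np.ndarray:
    if cat.n < 2:
        return np.zeros_like(np.asarray(distances, dtype=float)) - np.asarray(distances)
    return centered_L(ripley_K(cat, region, distances), distances)


def mc_envelope(
    k: float,
    region: SpatialRegion,
    window: TimeWindow,
    M: int,
    distances: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise 95% envelope of centered L under homogeneous Poisson(k).

    Returns (env_lo, env_hi, mean_L): the 2.5%/97.5% quantiles and mean of
    the centered L function over M simulated catalogs.
    """
    if M < 20:
        raise ValueError("need at least 20 Monte-Carlo replicates")
    ss = np.random.SeedSequence(seed)
    curves = np.empty((M, len(distances)))
    for m, child in enumerate(ss.spawn(M)):
        rng = np.random.default_rng(child)
        sim = simulate_homogeneous(k, region, window, rng)
        curves[m] = _centered_L_of(sim, region, distances)
    env_lo = np.quantile(curves, 0.025, axis=0)
    env_hi = np.quantile(curves, 0.975, axis=0)
    return env_lo, env_hi, curves.mean(axis=0)


def superthin_diagnostic(
    model: ModelSpec,
    cat: EventCatalog,
    region: SpatialRegion,
    window: TimeWindow,
    M: int = 100,
    distances: np.ndarray | None = None,
    seed: int = 0,
    M_envelope: int | None = None,
) -> KLResult:
    """Full residual diagnostic: repeated super-thinning plus Poisson envelope.

    Super-thins the catalog M times (the band of the resulting centered L
    curves is ``st_lo``/``st_hi``, their mean ``st_mean`` and ``centered_L``
    the first replicate's curve) and computes the 95% envelope from
    ``M_envelope`` (default M) homogeneous Poisson catalogs at the same
    rate k.
    """
    if M_envelope is None:
        M_envelope = M
    if distances is None:
        distances = default_distance_grid(region)
    distances = np.asarray(distances, dtype=float)
    k = superthin_rate(model, cat, region, window)
    lam = intensity_at_events(model, cat)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(M + 1)
    curves = np.empty((M, len(distances)))
    K0 = np.zeros_like(distances)
    for m in range(M):
        st = super_thin(
            model,
            cat,
            region,
            window,
            k=k,
            seed=int(children[m].generate_state(1)[0] % 2**31),
            intensities=lam,
        )
        if m == 0 and st.combined.n >= 2:
            K0 = ripley_K(st.combined, region, distances)
        curves[m] = _centered_L_of(st.combined, region, distances)
    env_lo, env_hi, mean_l = mc_envelope(
        k,
        region,
        window,
        M_envelope,
        distances,
        seed=int(children[M].generate_state(1)[0] % 2**31),
    )
    return KLResult(
        distances=distances,
        K=K0,
        L=np.sqrt(K0 / np.pi),
        centered_L=curves[0],
        env_lo=env_lo,
        env_hi=env_hi,
        mean_L=mean_l,
        M=M,
        st_lo=np.quantile(curves, 0.025, axis=0),
        st_hi=np.quantile(curves, 0.975, axis=0),
        st_mean=curves.mean(axis=0),
    )


def temporal_uniformity(cat: EventCatalog, window: TimeWindow) -> float:
    """Kolmogorov-Smirnov p-value of event times against Uniform(D).

    Convenience check of temporal homogeneity of the residual process.
    """
    from scipy.stats import kstest

    u = (cat.t - window.t_lo) / window.length
    return float(kstest(u, "uniform").pvalue)
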