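"""Forward simulation of growth, critical weight and maturity.

A larva starts its final instar at mass ``m0`` in the nonfeeding state
and gains mass at rate ``alpha`` (g/h) whenever feeding.  When mass
first reaches the critical weight ``w_c`` a hormone-degradation phase of
duration G ~ Gamma(shape j, scale mu) begins; switching and growth
continue throughout G, and age and mass are recorded when it ends.

Two sampling engines produce the same distribution:

``event``
    exact exponential sojourns, vectorised across replicates (all
    replicates alternate in lockstep, so the loop is over bouts, not
    events).
``clock``
    an exact distributional decomposition: the time to accumulate the
    required feeding hours is ``tau + Gamma(K, 1/lambda_n)`` with
    ``K - 1 ~ Poisson(lambda_f * tau)``, and feeding time inside the
    degradation window is drawn from the analytic occupation-time
    distribution by inverse CDF.  Cost is independent of the switching
    rates, which keeps fast-switching limits tractable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .alpha_growth import AlphaDistribution, sample_alpha
from .telegraph import (
    FEEDING,
    NONFEEDING,
    InvalidParameterError,
    SwitchRates,
    _occupation_terms,
    expected_feeding_fraction,
    sample_occupation_times,
    stationary_feeding_fraction,
)

__all__ = [
    "DevelopmentParams",
    "MaturitySample",
    "JointSummary",
    "sample_degradation_durations",
    "simulate_feeding_times",
    "simulate_instar4_gain",
    "simulate_maturity",
    "samples_to_frame",
    "summarize_joint",
    "energy_distance_test",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DevelopmentParams:
    """Critical weight and hormone-degradation settings.

    Defaults follow the fitted-model runs: w_c = 7 g and a degradation
    phase of j = 48 unit steps of mean mu = 1 h (duration gamma
    distributed with mean mu * j ~ 48 h).
    """

    w_c: float = 7.0
    j: int = 48
    mu: float = 1.0
    max_horizon_h: float = 5000.0

    def __post_init__(self) -> None:
        if self.w_c <= 0:
            raise InvalidParameterError("w_c must be > 0")
        if int(self.j) != self.j or self.j < 1:
            raise InvalidParameterError("j must be an integer >= 1")
        if self.mu <= 0:
            raise InvalidParameterError("mu must be > 0")
        if self.max_horizon_h <= 0:
            raise InvalidParameterError("max_horizon_h must be > 0")


class MaturitySample(NamedTuple):
    replicate: int
    m0_g: float
    alpha_g_per_h: float
    age_h: float
    mass_g: float
    reached_wc: bool


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_degradation_durations(
    dev: DevelopmentParams,
    n: int,
    seed=None,
    stepwise: bool = False,
) -> np.ndarray:
    """Durations of the growth-cessation phase, hours.

    The default draws Gamma(shape j, scale mu) directly; ``stepwise``
    sums j exponential steps of mean mu instead (identical distribution,
    kept as a validation mode).
    """
    rng = _as_rng(seed)
    if stepwise:
        return rng.exponential(dev.mu, size=(n, int(dev.j))).sum(axis=1)
    return rng.gamma(shape=float(dev.j), scale=dev.mu, size=n)


def simulate_feeding_times(
    rates: SwitchRates, z_h: float, n: int, seed=None
) -> np.ndarray:
    """n independent total feeding times in a window of z_h hours,
    starting nonfeeding (model-fit assessment against observed trials)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    return sample_occupation_times(rates, z_h, n, start_state=NONFEEDING, seed=seed)


# ---------------------------------------------------------------------------
# occupation-time sampling via the analytic distribution
# ---------------------------------------------------------------------------


def _occupation_quantile_sample(
    rates: SwitchRates,
    z: np.ndarray,
    start_feeding: np.ndarray,
    rng: np.random.Generator,
    n_grid: int = 513,
    chunk: int = 20_000,
) -> np.ndarray:
    """Inverse-CDF draws of feeding time for per-replicate windows ``z``.

    Works per start state on the occupation time of the *other* state
    ``v`` (atom at v = 0 handled exactly); the continuous part is sampled
    on an adaptive grid placed around the transient mean with a width of
    many asymptotic standard deviations, falling back to the full (0, z)
    range for short windows.
    """
    lf, ln = rates.lambda_f, rates.lambda_n
    r = lf + ln
    out = np.empty(z.size)
    for feeding_start in (False, True):
        sel = np.flatnonzero(start_feeding == feeding_start)
        if sel.size == 0:
            continue
        # exit rate of the start state, and of the other state
        b = lf if feeding_start else ln
        a = ln if feeding_start else lf
        for lo_i in range(0, sel.size, chunk):
            idx = sel[lo_i : lo_i + chunk]
            zc = z[idx]
            atom = np.exp(-b * zc)  # never leave the start state
            u01 = rng.uniform(size=idx.size)
            take_atom = u01 < atom
            # transient mean of the other-state occupation v over the window;
            # the other state's stationary share is (exit rate of start)/r
            relax = -np.expm1(-r * zc) / (r * zc)
            mean_v = zc * (b / r) * (1.0 - relax)
            sd_v = np.sqrt(2.0 * lf * ln / r**3 * zc) + 2.0 / r
            lo = np.maximum(mean_v - 12.0 * sd_v, zc * 1e-9)
            hi = np.minimum(mean_v + 12.0 * sd_v, zc * (1.0 - 1e-9))
            full = (hi - lo) > 0.6 * zc
            lo = np.where(full, zc * 1e-9, lo)
            hi = np.where(full, zc * (1.0 - 1e-9), hi)
            frac = np.linspace(0.0, 1.0, n_grid)
            grid = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
            logf = _occupation_terms(
                a, b, grid, zc[:, None] - grid, need_derivs=False
            )
            dens = np.exp(logf - logf.max(axis=1, keepdims=True))
            dx = (hi - lo) / (n_grid - 1)
            cdf = np.concatenate(
                [
                    np.zeros((idx.size, 1)),
                    np.cumsum((dens[:, 1:] + dens[:, :-1]) / 2.0, axis=1),
                ],
                axis=1,
            )
            total = cdf[:, -1:]
            cdf = cdf / total
            uu = rng.uniform(size=idx.size)
            pos = np.empty(idx.size, dtype=np.int64)
            for k in range(idx.size):  # searchsorted per row; cheap vs density eval
                pos[k] = np.searchsorted(cdf[k], uu[k])
            pos = np.clip(pos, 1, n_grid - 1)
            c_lo = np.take_along_axis(cdf, (pos - 1)[:, None], axis=1)[:, 0]
            c_hi = np.take_along_axis(cdf, pos[:, None], axis=1)[:, 0]
            g_lo = np.take_along_axis(grid, (pos - 1)[:, None], axis=1)[:, 0]
            g_hi = np.take_along_axis(grid, pos[:, None], axis=1)[:, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(c_hi > c_lo, (uu - c_lo) / (c_hi - c_lo), 0.5)
            v = g_lo + t * (g_hi - g_lo)
            v = np.where(take_atom, 0.0, v)
            # v is occupation of the non-start state
            out[idx] = zc - v if feeding_start else v
    return out


# ---------------------------------------------------------------------------
# 4th-instar mass gain
# ---------------------------------------------------------------------------


def simulate_instar4_gain(
    rates: SwitchRates,
    alpha_dist: AlphaDistribution,
    durations_h: Sequence[float],
    n: int,
    seed=None,
    method: str = "auto",
) -> np.ndarray:
    """Simulated total mass gains (g) over a full instar.

    Each replicate draws an instar duration from the empirical pool
    (with replacement), simulates switching over it from a nonfeeding
    start, draws alpha (truncated at 0) and returns alpha x feeding
    time.
    """
    pool = np.asarray(durations_h, dtype=float)
    if pool.size == 0:
        raise InvalidParameterError("empty duration pool")
    if np.any(pool <= 0):
        raise InvalidParameterError("durations must be positive")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = _as_rng(seed)
    d = rng.choice(pool, size=n, replace=True)
    alpha = sample_alpha(alpha_dist, n, rng)
    method = _resolve_method(method, rates, float(d.mean()), n)
    if method == "event":
        w = sample_occupation_times(rates, d, start_state=NONFEEDING, seed=rng)
    else:  # clock: draw from the analytic occupation distribution
        w = _occupation_quantile_sample(rates, d, np.zeros(n, dtype=bool), rng)
    return alpha * w


def _resolve_method(method: str, rates: SwitchRates, span_h: float, n: int) -> str:
    """'event' = exact sojourn loop, 'clock' = distributional shortcut."""
    if method in ("event", "clock"):
        return method
    if method != "auto":
        raise InvalidParameterError(f"unknown method {method!r}")
    lf, ln = rates.lambda_f, rates.lambda_n
    bouts_per_h = 2.0 * lf * ln / (lf + ln)
    return "event" if n * span_h * bouts_per_h <= 4e7 else "clock"


# ---------------------------------------------------------------------------
# full joint model
# ---------------------------------------------------------------------------


def simulate_maturity(
    rates: SwitchRates,
    alpha_dist: AlphaDistribution,
    m0_dist: Tuple[float, float],
    dev: DevelopmentParams,
    n: int,
    seed=None,
    method: str = "auto",
    stepwise_degradation: bool = False,
) -> List[MaturitySample]:
    """Joint (age, mass) at maturity for ``n`` replicates.

    ``m0_dist`` is the (mean, sd) of the normal initial-mass
    distribution, truncated at > 0.  Replicates that do not reach the
    critical weight within ``dev.max_horizon_h`` are returned with
    ``reached_wc=False`` (age set to the horizon, mass NaN) and should
    be excluded from summaries.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = _as_rng(seed)
    m0_mean, m0_sd = m0_dist
    m0 = rng.normal(m0_mean, m0_sd, size=n)
    bad = m0 <= 0
    while np.any(bad):
        m0[bad] = rng.normal(m0_mean, m0_sd, size=int(bad.sum()))
        bad = m0 <= 0
    alpha = sample_alpha(alpha_dist, n, rng)
    G = sample_degradation_durations(dev, n, seed=rng, stepwise=stepwise_degradation)

    if alpha_dist.mean_g_per_h <= 0 and m0_mean < dev.w_c:
        warnings.warn(
            "alpha mean <= 0 with m0 below critical weight: replicates will censor",
            RuntimeWarning,
        )

    span_guess = (
        max(dev.w_c - m0_mean, 0.0)
        / max(alpha_dist.mean_g_per_h * stationary_feeding_fraction(rates), 1e-12)
        + dev.j * dev.mu
    )
    method = _resolve_method(method, rates, min(span_guess, dev.max_horizon_h), n)
    if method == "event":
        age, mass, reached = _maturity_event(rates, alpha, m0, dev, G, rng)
    else:
        age, mass, reached = _maturity_clock(rates, alpha, m0, dev, G, rng)
    if not np.any(reached):
        warnings.warn("no replicate reached the critical weight", RuntimeWarning)
    return [
        MaturitySample(i, float(m0[i]), float(alpha[i]), float(age[i]), float(mass[i]), bool(reached[i]))
        for i in range(n)
    ]


def _maturity_clock(rates, alpha, m0, dev, G, rng):
    lf, ln = rates.lambda_f, rates.lambda_n
    n = alpha.size
    with np.errstate(divide="ignore"):
        tau_req = np.where(m0 >= dev.w_c, 0.0, (dev.w_c - m0) / alpha)
    grow = (tau_req > 0) & np.isfinite(tau_req)
    above = tau_req == 0.0
    age_wc = np.full(n, np.inf)
    age_wc[above] = 0.0
    if np.any(grow):
        k = 1 + rng.poisson(lf * tau_req[grow])
        nonfeed = rng.gamma(shape=k.astype(float), scale=1.0 / ln)
        age_wc[grow] = tau_req[grow] + nonfeed
    reached = age_wc <= dev.max_horizon_h
    age = np.full(n, dev.max_horizon_h)
    mass = np.full(n, np.nan)
    if np.any(reached):
        idx = np.flatnonzero(reached)
        w_g = _occupation_quantile_sample(rates, G[idx], grow[idx], rng)
        age[idx] = age_wc[idx] + G[idx]
        mass[idx] = m0[idx] + alpha[idx] * (tau_req[idx] + w_g)
    return age, mass, reached


def _maturity_event(rates, alpha, m0, dev, G, rng):
    lf, ln = rates.lambda_f, rates.lambda_n
    n = alpha.size
    with np.errstate(divide="ignore"):
        tau_req = np.where(m0 >= dev.w_c, 0.0, (dev.w_c - m0) / alpha)
    t = np.zeros(n)
    wfeed = np.zeros(n)
    t_cross = np.where(tau_req == 0.0, 0.0, np.inf)
    deadline = np.where(tau_req == 0.0, G, np.inf)
    age = np.full(n, dev.max_horizon_h)
    mass = np.full(n, np.nan)
    reached = np.zeros(n, dtype=bool)
    active = np.arange(n)
    feeding = False  # lockstep alternation, everyone starts nonfeeding
    while active.size:
        rate = lf if feeding else ln
        d = rng.exponential(1.0 / rate, size=active.size)
        if feeding:
            w_new = wfeed[active] + d
            crossing = ~np.isfinite(t_cross[active]) & (w_new >= tau_req[active])
            if np.any(crossing):
                ci = active[crossing]
                tc = t[ci] + (tau_req[ci] - wfeed[ci])
                t_cross[ci] = tc
                deadline[ci] = tc + G[ci]
            wfeed[active] = w_new
        t[active] += d
        done = deadline[active] <= t[active]
        if np.any(done):
            di = active[done]
            overshoot = t[di] - deadline[di]
            w_final = wfeed[di] - (overshoot if feeding else 0.0)
            age[di] = deadline[di]
            mass[di] = m0[di] + alpha[di] * w_final
            reached[di] = True
        censor = (t[active] >= dev.max_horizon_h) & ~np.isfinite(deadline[active])
        active = active[~done & ~censor]
        feeding = not feeding
    return age, mass, reached


def samples_to_frame(samples: Sequence[MaturitySample]):
    """Samples as a pandas DataFrame in the CSV column layout."""
    import pandas as pd

    return pd.DataFrame(samples, columns=MaturitySample._fields)


# ---------------------------------------------------------------------------
# joint summaries
# ---------------------------------------------------------------------------


@dataclass
class JointSummary:
    n_used: int
    n_censored: int
    marginals: dict
    levels: Tuple[float, ...]
    contours: Optional[dict]  # level -> list of polygons (age, mass) lists
    kde_bandwidth: Optional[Tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_censored": self.n_censored,
            "marginals": self.marginals,
            "levels": list(self.levels),
            "contours": self.contours,
            "kde_bandwidth": list(self.kde_bandwidth) if self.kde_bandwidth else None,
        }


_QUANTS = (0.05, 0.25, 0.5, 0.75, 0.95)


def _marginal_stats(v: np.ndarray) -> dict:
    qs = np.quantile(v, _QUANTS)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        **{f"q{int(q * 100):02d}": float(x) for q, x in zip(_QUANTS, qs)},
    }


def summarize_joint(
    samples: Sequence[MaturitySample],
    levels: Iterable[float] = (0.5, 0.9),
    grid_size: int = 128,
) -> JointSummary:
    """Marginal statistics and highest-density-region contours.

    Contour thresholds are quantiles of the KDE density evaluated at the
    samples themselves, so a level-0.9 region is the smallest estimated
    region holding ~90% of the mass.  Degenerate geometry (samples on a
    line) skips the contours with a warning.
    """
    levels = tuple(sorted(levels))
    arr = np.array(
        [(s.age_h, s.mass_g) for s in samples if s.reached_wc], dtype=float
    )
    arr = arr[np.isfinite(arr).all(axis=1)]
    n_used = arr.shape[0]
    if n_used < 100:
        raise InvalidParameterError(
            f"need >= 100 uncensored samples for a joint summary, got {n_used}"
        )
    marginals = {
        "age_h": _marginal_stats(arr[:, 0]),
        "mass_g": _marginal_stats(arr[:, 1]),
    }
    contours = None
    bw = None
    cov = np.cov(arr.T)
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-12 * max(eig[-1], 1e-300):
        warnings.warn(
            "singular sample covariance (degenerate geometry); contours skipped",
            RuntimeWarning,
        )
        return JointSummary(
            n_used=n_used,
            n_censored=len(samples) - n_used,
            marginals=marginals,
            levels=levels,
            contours=None,
        )
    try:
        kde = stats.gaussian_kde(arr.T)
        dens_at_samples = kde(arr.T)
        thresholds = {lev: float(np.quantile(dens_at_samples, 1.0 - lev)) for lev in levels}
        sd = arr.std(axis=0, ddof=1)
        bw = tuple(float(s) * kde.factor for s in sd)
        pad = 4.0
        x = np.linspace(arr[:, 0].min() - pad * bw[0], arr[:, 0].max() + pad * bw[0], grid_size)
        y = np.linspace(arr[:, 1].min() - pad * bw[1], arr[:, 1].max() + pad * bw[1], grid_size)
        xx, yy = np.meshgrid(x, y)
        zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        from contourpy import contour_generator

        gen = contour_generator(xx, yy, zz)
        contours = {}
        for lev in levels:
            polys = gen.lines(thresholds[lev])
            contours[str(lev)] = [np.asarray(p).tolist() for p in polys]
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular sample covariance (degenerate geometry); contours skipped",
            RuntimeWarning,
        )
    return JointSummary(
        n_used=n_used,
        n_censored=len(samples) - n_used,
        marginals=marginals,
        levels=levels,
        contours=contours,
        kde_bandwidth=bw,
    )


# ---------------------------------------------------------------------------
# two-sample comparison for validation runs
# ---------------------------------------------------------------------------


def energy_distance_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 199,
    seed=None,
) -> Tuple[float, float]:
    """Two-sample energy-distance permutation test for 2-D samples.

    Returns ``(statistic, p_value)``.  The statistic is
    ``2 E|X-Y| - E|X-X'| - E|Y-Y'|`` with Euclidean distances; the
    p-value is the permutation tail probability with the +1 correction.
    """
    from scipy.spatial.distance import cdist

    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[0], y.shape[0]
    if nx < 2 or ny < 2:
        raise InvalidParameterError("need >= 2 points per sample")
    pooled = np.vstack([x, y])
    dist = cdist(pooled, pooled)
    rng = _as_rng(seed)

    def estat(ix, iy):
        dxy = dist[np.ix_(ix, iy)].mean()
        dxx = dist[np.ix_(ix, ix)].sum() / (len(ix) * (len(ix) - 1))
        dyy = dist[np.ix_(iy, iy)].sum() / (len(iy) * (len(iy) - 1))
        return 2.0 * dxy - dxx - dyy

    ix0 = np.arange(nx)
    iy0 = np.arange(nx, nx + ny)
    observed = estat(ix0, iy0)
    count = 0
    idx = np.arange(nx + ny)
    for _ in range(n_permutations):
        rng.shuffle(idx)
        if estat(idx[:nx], idx[nx:]) >= observed:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return float(observed), float(p)
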