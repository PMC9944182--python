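"""Two-state (feeding/nonfeeding) switching process.

Event-driven simulation of alternating exponential bouts, the 5-s
minimum-bout observation filter, and the exact mixed distribution of the
total time spent feeding within a fixed observation window.

Conventions
-----------
* Bout logs are kept in **seconds** (observations are recorded to the
  nearest second); all rates, windows and densities are in **hours**.
  The conversion lives in a single constant, :data:`SECONDS_PER_HOUR`.
* Unless stated otherwise the process starts in the **nonfeeding** state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Tuple

import numpy as np
from scipy import special

SECONDS_PER_HOUR = 3600.0

FEEDING = "feeding"
NONFEEDING = "nonfeeding"
STATES = (FEEDING, NONFEEDING)

__all__ = [
    "SECONDS_PER_HOUR",
    "FEEDING",
    "NONFEEDING",
    "SwitchRates",
    "Bout",
    "BoutSequence",
    "OccupancyParams",
    "InvalidParameterError",
    "simulate_bouts",
    "total_feeding_time",
    "apply_min_bout_filter",
    "occupation_log_density",
    "occupation_cdf_grid",
    "sample_occupation_times",
    "expected_feeding_fraction",
    "stationary_feeding_fraction",
]


class InvalidParameterError(ValueError):
    """Raised for non-positive rates, windows or other bad model inputs."""


@dataclass(frozen=True)
class SwitchRates:
    """Switching rates of the two-state process, in switches per hour.

    ``lambda_f`` is the rate of leaving the feeding state, ``lambda_n``
    the rate of leaving the nonfeeding state.
    """

    lambda_f: float
    lambda_n: float

    def __post_init__(self) -> None:
        for name in ("lambda_f", "lambda_n"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )


class Bout(NamedTuple):
    state: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BoutSequence:
    """One individual's ordered alternation of bouts over ``[0, Z]``.

    Bout endpoints are in seconds from trial start; ``trial_length_h``
    is the window length Z in hours.  Bouts are contiguous,
    non-overlapping, strictly alternating in state and cover the window.
    """

    trial_length_h: float
    bouts: List[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.trial_length_h <= 0:
            raise InvalidParameterError("trial_length_h must be > 0")
        if not self.bouts:
            raise InvalidParameterError("BoutSequence needs at least one bout")
        z_s = self.trial_length_h * SECONDS_PER_HOUR
        prev_end = 0.0
        prev_state = None
        for i, b in enumerate(self.bouts):
            if b.state not in STATES:
                raise InvalidParameterError(f"bout {i}: unknown state {b.state!r}")
            if b.state == prev_state:
                raise InvalidParameterError(f"bout {i}: states must alternate")
            if abs(b.start_s - prev_end) > 1e-6:
                raise InvalidParameterError(
                    f"bout {i}: starts at {b.start_s}, expected {prev_end}"
                )
            if b.end_s < b.start_s:
                raise InvalidParameterError(f"bout {i}: negative duration")
            prev_end = b.end_s
            prev_state = b.state
        if abs(prev_end - z_s) > 1e-6:
            raise InvalidParameterError(
                f"last bout ends at {prev_end} s, expected {z_s} s"
            )

    @property
    def trial_length_s(self) -> float:
        return self.trial_length_h * SECONDS_PER_HOUR

    def feeding_time_h(self) -> float:
        return total_feeding_time(self)


@dataclass(frozen=True)
class OccupancyParams:
    """Total feeding time ``x`` within a window of length ``z``, hours."""

    x: float
    z: float

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.z:
            raise InvalidParameterError(f"need 0 <= x <= z, got x={self.x}, z={self.z}")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_bouts(
    rates: SwitchRates,
    z_h: float,
    start_state: str = NONFEEDING,
    seed=None,
) -> BoutSequence:
    """Simulate one trial of exact exponential sojourns, truncated at Z.

    ``seed`` may be an int or a ``numpy.random.Generator``; the same seed
    yields an identical bout list.
    """
    if z_h <= 0:
        raise InvalidParameterError(f"z_h must be > 0, got {z_h}")
    if start_state not in STATES:
        raise InvalidParameterError(f"unknown start_state {start_state!r}")
    rng = _as_rng(seed)
    z_s = z_h * SECONDS_PER_HOUR
    rate_s = {
        FEEDING: rates.lambda_f / SECONDS_PER_HOUR,
        NONFEEDING: rates.lambda_n / SECONDS_PER_HOUR,
    }
    bouts: List[Bout] = []
    t = 0.0
    state = start_state
    while t < z_s:
        dur = rng.exponential(1.0 / rate_s[state])
        end = min(t + dur, z_s)
        bouts.append(Bout(state, t, end))
        t = t + dur
        state = FEEDING if state == NONFEEDING else NONFEEDING
    return BoutSequence(trial_length_h=z_h, bouts=bouts)


def total_feeding_time(seq: BoutSequence) -> float:
    """Total feeding time in the sequence, in hours."""
    tot_s = sum(b.duration_s for b in seq.bouts if b.state == FEEDING)
    return tot_s / SECONDS_PER_HOUR


def apply_min_bout_filter(seq: BoutSequence, min_seconds: float = 5.0) -> BoutSequence:
    """Absorb interior bouts shorter than ``min_seconds`` into their context.

    A short bout is disregarded and the surrounding state maintained: its
    duration is merged with the (same-state) neighbours on either side.
    The scan runs left to right and repeats until no interior bout is
    shorter than the threshold, so cascading merges resolve
    deterministically.  The first and last bouts are never absorbed (there
    is no single surrounding state to maintain) and total duration is
    preserved exactly.
    """
    durs = [(b.state, b.duration_s) for b in seq.bouts]
    changed = True
    while changed:
        changed = False
        i = 1
        while i < len(durs) - 1:
            state, d = durs[i]
            if d < min_seconds:
                left_state, left_d = durs[i - 1]
                _, right_d = durs[i + 1]
                durs[i - 1 : i + 2] = [(left_state, left_d + d + right_d)]
                changed = True
                i = max(i - 1, 1)
            else:
                i += 1
    bouts = []
    t = 0.0
    for state, d in durs:
        bouts.append(Bout(state, t, t + d))
        t += d
    # rebuild endpoints exactly against the window to avoid float drift
    bouts[-1] = Bout(bouts[-1].state, bouts[-1].start_s, seq.trial_length_s)
    return BoutSequence(trial_length_h=seq.trial_length_h, bouts=bouts)


# ---------------------------------------------------------------------------
# occupation-time distribution
# ---------------------------------------------------------------------------

_SMALL_Q = 1e-4


def _bessel_ratio_terms(q: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return u = I1/I0 and its first two derivatives in q, stably.

    Uses exponentially scaled Bessel functions; small q falls back to the
    series to dodge cancellation in u''.
    """
    q = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = special.i1e(q) / special.i0e(q)
        up = 1.0 - u / q - u * u
        upp = -up / q + u / (q * q) - 2.0 * u * up
    small = q < _SMALL_Q
    if np.any(small):
        qs = np.where(small, q, 1.0)
        u = np.where(small, qs / 2.0 - qs**3 / 16.0, u)
        up = np.where(small, 0.5 - 3.0 * qs**2 / 16.0, up)
        upp = np.where(small, -3.0 * qs / 8.0, upp)
    return u, up, upp


def _occupation_terms(a, b, x, y, need_derivs: bool = True):
    """Log-density and its (a, b) derivatives at interior points 0 < x < Z.

    ``a`` = exit rate from the state whose occupation is *not* measured
    at start... concretely, for a nonfeeding start measuring feeding time
    x (y = Z - x): a = lambda_f, b = lambda_n.  All inputs broadcast; the
    returned arrays have the broadcast shape.

    Returns ``logf`` or ``(logf, la, lb, laa, lab, lbb)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = 2.0 * np.sqrt(a * b * x * y)
    u, up, upp = _bessel_ratio_terms(q)
    i0e = special.i0e(q)
    half_x = q / (2.0 * x)
    abar = b + half_x * u
    logf = -a * x - b * y + q + np.log(i0e) + np.log(abar)
    if not need_derivs:
        return logf
    aq = (u + q * up) / (2.0 * x)
    aqq = (2.0 * up + q * upp) / (2.0 * x)
    g1 = u + aq / abar
    dg1dq = up + (aqq * abar - aq * aq) / (abar * abar)
    dg1db = -aq / (abar * abar)
    q_a = q / (2.0 * a)
    q_b = q / (2.0 * b)
    q_aa = -q / (4.0 * a * a)
    q_ab = q / (4.0 * a * b)
    q_bb = -q / (4.0 * b * b)
    la = -x + g1 * q_a
    lb = -y + g1 * q_b + 1.0 / abar
    laa = dg1dq * q_a * q_a + g1 * q_aa
    lab = dg1dq * q_a * q_b + dg1db * q_a + g1 * q_ab
    lbb = (dg1dq * q_b + dg1db) * q_b + g1 * q_bb - (aq * q_b + 1.0) / (abar * abar)
    return logf, la, lb, laa, lab, lbb


_EDGE_NUDGE = 1e-12


def occupation_log_density(
    x,
    z,
    rates: SwitchRates,
    start_state: str = NONFEEDING,
):
    """Log of the mixed distribution of total feeding time in ``[0, z]``.

    For a nonfeeding start the distribution has a point mass
    ``exp(-lambda_n * z)`` at ``x = 0`` (the process never leaves the
    initial state) and a continuous Bessel-form density on ``(0, z)``;
    ``x == z`` is evaluated as the continuous limit (no atom there).  A
    feeding start mirrors this: atom at ``x = z``, continuous limit at 0.

    ``x`` may be a scalar or array; returns log probability for atom
    points and log density elsewhere.
    """
    if start_state not in STATES:
        raise InvalidParameterError(f"unknown start_state {start_state!r}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    z = float(z)
    if z <= 0:
        raise InvalidParameterError("z must be > 0")
    if np.any(x < 0) or np.any(x > z):
        raise InvalidParameterError("x must lie in [0, z]")

    if start_state == NONFEEDING:
        t_other, a, b = x, rates.lambda_f, rates.lambda_n
    else:
        # symmetric role swap: measure the nonfeeding occupation z - x
        t_other, a, b = z - x, rates.lambda_n, rates.lambda_f

    out = np.empty_like(t_other)
    at_atom = t_other == 0.0
    out[at_atom] = -b * z
    interior = ~at_atom
    ti = t_other[interior]
    # exact far edge hits the 0/0 in sqrt(y/x); evaluate the finite limit
    ti = np.where(ti >= z * (1.0 - _EDGE_NUDGE), z * (1.0 - _EDGE_NUDGE), ti)
    out[interior] = _occupation_terms(a, b, ti, z - ti, need_derivs=False)
    return float(out[0]) if scalar else out


def occupation_cdf_grid(
    z: float,
    rates: SwitchRates,
    start_state: str = NONFEEDING,
    n_grid: int = 20001,
):
    """Numeric CDF of total feeding time on a uniform grid over ``[0, z]``.

    Returns ``(grid, cdf)`` where the CDF includes the start-state atom.
    Intended as the analytic side of simulation cross-checks.
    """
    grid = np.linspace(0.0, z, n_grid)
    inner = grid[1:-1]
    logf = occupation_log_density(inner, z, rates, start_state)
    f = np.exp(np.asarray(logf))
    # endpoint densities via the continuous limits
    f0 = np.exp(occupation_log_density(z * _EDGE_NUDGE, z, rates, start_state))
    f1 = np.exp(occupation_log_density(z * (1 - _EDGE_NUDGE), z, rates, start_state))
    dens = np.concatenate([[f0], f, [f1]])
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0) * (z / (n_grid - 1))])
    if start_state == NONFEEDING:
        cdf = cdf + np.exp(-rates.lambda_n * z)  # atom at 0
    # atom at z (feeding start) enters only at the right endpoint
    return grid, cdf


def sample_occupation_times(
    rates: SwitchRates,
    z_h,
    n: int | None = None,
    start_state: str = NONFEEDING,
    seed=None,
) -> np.ndarray:
    """Draw total feeding times by event simulation, vectorised over trials.

    ``z_h`` may be a scalar (with ``n`` replicates) or an array of
    per-replicate window lengths.  All replicates alternate in lockstep
    (everyone completes one bout per round), which keeps the loop over
    rounds rather than over events.
    """
    rng = _as_rng(seed)
    z = np.asarray(z_h, dtype=float)
    if z.ndim == 0:
        if n is None:
            raise InvalidParameterError("n is required with a scalar window")
        z = np.full(n, float(z))
    if np.any(z <= 0):
        raise InvalidParameterError("window lengths must be > 0")
    m = z.size
    t = np.zeros(m)
    w = np.zeros(m)
    active = np.arange(m)
    state = start_state
    rate = {FEEDING: rates.lambda_f, NONFEEDING: rates.lambda_n}
    while active.size:
        d = rng.exponential(1.0 / rate[state], size=active.size)
        if state == FEEDING:
            w[active] += np.minimum(d, z[active] - t[active])
        t[active] += d
        active = active[t[active] < z[active]]
        state = FEEDING if state == NONFEEDING else NONFEEDING
    return w


# ---------------------------------------------------------------------------
# expected occupancy
# ---------------------------------------------------------------------------


def stationary_feeding_fraction(rates: SwitchRates) -> float:
    """Long-run fraction of time spent feeding, lambda_n / (lambda_n + lambda_f)."""
    return rates.lambda_n / (rates.lambda_n + rates.lambda_f)


def expected_feeding_fraction(
    rates: SwitchRates, t_h: float, start_state: str = NONFEEDING
) -> float:
    """E[feeding time in [0, t]] / t for the given start state.

    Transient two-state solution: with r = lambda_n + lambda_f and
    pi = lambda_n / r, a nonfeeding start gives
    ``pi * (1 - (1 - exp(-r t)) / (r t))``.
    """
    if start_state not in STATES:
        raise InvalidParameterError(f"unknown start_state {start_state!r}")
    if t_h <= 0:
        raise InvalidParameterError("t_h must be > 0")
    r = rates.lambda_n + rates.lambda_f
    pi = rates.lambda_n / r
    rt = r * t_h
    relax = -np.expm1(-rt) / rt  # (1 - e^{-rt})/(rt), stable for small rt
    if start_state == NONFEEDING:
        return float(pi * (1.0 - relax))
    return float(pi + (1.0 - pi) * relax)
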