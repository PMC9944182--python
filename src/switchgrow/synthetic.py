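"""Synthetic feeding-trial logs, mass records and validation tables.

Generators mirror the observation protocol the analysis assumes: 1-h
trials watched from a nonfeeding start with switch times rounded to the
nearest second and bouts under 5 s disregarded; molt-to-pretrial mass
records ~24 +/- 2 h apart on a quarter-hour grid; and out-of-sample
style tables (instar-duration pools, initial masses, age/mass at
wandering) for end-to-end pipeline runs without any download.

Default group parameters are the fitted point estimates for each
diet x instar cell, so synthetic runs live in the realistic regime.
Molt-mass and duration-pool distributions are *synthetic conventions*
(plausible placeholders, configurable), not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .alpha_growth import AlphaDistribution, sample_alpha
from .maturity import DevelopmentParams, simulate_maturity
from .telegraph import (
    FEEDING,
    NONFEEDING,
    SECONDS_PER_HOUR,
    Bout,
    BoutSequence,
    InvalidParameterError,
    SwitchRates,
    apply_min_bout_filter,
    expected_feeding_fraction,
    simulate_bouts,
)

__all__ = [
    "GroupTruth",
    "DEFAULT_TRUTHS",
    "default_truths",
    "generate_trials",
    "generate_mass_records",
    "generate_outofsample",
]

DIETS = ("diet", "tobacco", "devilsclaw")


@dataclass(frozen=True)
class GroupTruth:
    """Generating parameters for one diet x instar cell."""

    diet: str
    instar: int
    rates: SwitchRates
    alpha: AlphaDistribution
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")


def default_truths() -> Dict[Tuple[str, int], GroupTruth]:
    """Fitted point estimates per cell, with the study's group sizes."""
    spec = {
        # (diet, instar): (lambda_f, lambda_n, alpha_mean, alpha_sd, n)
        ("diet", 4): (10.25, 4.93, 0.04, 0.02, 18),
        ("tobacco", 4): (16.21, 10.19, 0.05, 0.01, 19),
        ("devilsclaw", 4): (56.22, 24.36, 0.04, 0.01, 11),
        ("diet", 5): (16.85, 11.05, 0.15, 0.04, 17),
        ("tobacco", 5): (10.7, 12.63, 0.11, 0.03, 10),
        ("devilsclaw", 5): (59.43, 37.99, 0.14, 0.03, 11),
    }
    return {
        key: GroupTruth(
            diet=key[0],
            instar=key[1],
            rates=SwitchRates(v[0], v[1]),
            alpha=AlphaDistribution(v[2], v[3], diet=key[0], instar=key[1]),
            n_individuals=v[4],
        )
        for key, v in spec.items()
    }


DEFAULT_TRUTHS = default_truths()

# synthetic conventions for molt mass (g), by instar; truncated > 0
MOLT_MASS_DEFAULTS = {4: (0.35, 0.08), 5: (1.8, 0.4)}


def _round_bouts_to_seconds(seq: BoutSequence) -> BoutSequence:
    """Round switch times to the nearest second, dropping collapsed bouts."""
    z_s = round(seq.trial_length_s)
    edges = [round(b.start_s) for b in seq.bouts] + [z_s]
    bouts: List[Bout] = []
    for b, (s, e) in zip(seq.bouts, zip(edges[:-1], edges[1:])):
        if e <= s:
            continue
        if bouts and bouts[-1].state == b.state:
            bouts[-1] = Bout(b.state, bouts[-1].start_s, float(e))
        else:
            bouts.append(Bout(b.state, float(s), float(e)))
    # rounding can orphan the window edges; stretch the neighbours
    if bouts[0].start_s != 0.0:
        bouts[0] = Bout(bouts[0].state, 0.0, bouts[0].end_s)
    if bouts[-1].end_s != z_s:
        bouts[-1] = Bout(bouts[-1].state, bouts[-1].start_s, float(z_s))
    return BoutSequence(trial_length_h=seq.trial_length_h, bouts=bouts)


def generate_trials(
    truth: GroupTruth,
    z_h: float = 1.0,
    min_bout_s: float = 5.0,
    seed=None,
    round_seconds: bool = True,
) -> pd.DataFrame:
    """Bout-log rows for one group's feeding trials.

    Each individual is simulated from a nonfeeding start, switch times
    are rounded to the nearest second (optional) and the minimum-bout
    rule applied (``min_bout_s=0`` disables it).  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(truth.n_individuals):
        seq = simulate_bouts(truth.rates, z_h, start_state=NONFEEDING, seed=rng)
        if round_seconds:
            seq = _round_bouts_to_seconds(seq)
        if min_bout_s > 0:
            seq = apply_min_bout_filter(seq, min_bout_s)
        ind = f"{truth.diet}-{truth.instar}-{i + 1:03d}"
        for b in seq.bouts:
            rows.append(
                {
                    "individual_id": ind,
                    "diet": truth.diet,
                    "instar": truth.instar,
                    "state": b.state,
                    "start_s": int(round(b.start_s)) if round_seconds else b.start_s,
                    "end_s": int(round(b.end_s)) if round_seconds else b.end_s,
                    "trial_length_s": int(round(z_h * SECONDS_PER_HOUR)),
                }
            )
    return pd.DataFrame(rows)


def generate_mass_records(
    truth: GroupTruth,
    seed=None,
    noise_cv: float = 0.02,
    molt_mass: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Mass-record rows consistent with the group's alpha and rates.

    Elapsed time ~ Uniform(22, 26) h rounded to the quarter hour; the
    mass increment is alpha_i x expected feeding hours over that window,
    with optional lognormal measurement noise (CV default 2%) on both
    masses.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_individuals
    elapsed = np.round(rng.uniform(22.0, 26.0, size=n) * 4.0) / 4.0
    alpha_i = sample_alpha(truth.alpha, n, rng)
    mu, sd = molt_mass or MOLT_MASS_DEFAULTS.get(truth.instar, (1.0, 0.2))
    molt = rng.normal(mu, sd, size=n)
    bad = molt <= 0
    while np.any(bad):
        molt[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = molt <= 0
    frac = np.array(
        [expected_feeding_fraction(truth.rates, e) for e in elapsed]
    )
    pretrial = molt + alpha_i * frac * elapsed
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        scale = np.exp(-(sigma**2) / 2.0)  # unit-mean lognormal
        molt = molt * rng.lognormal(0.0, sigma, size=n) * scale
        pretrial = pretrial * rng.lognormal(0.0, sigma, size=n) * scale
    return pd.DataFrame(
        {
            "individual_id": [f"{truth.diet}-{truth.instar}-{i + 1:03d}" for i in range(n)],
            "diet": truth.diet,
            "instar": truth.instar,
            "mass_molt_g": molt,
            "mass_pretrial_g": pretrial,
            "elapsed_h": elapsed,
        }
    )


def generate_outofsample(
    dev: DevelopmentParams,
    truth: GroupTruth,
    m0_dist: Tuple[float, float],
    n: int,
    seed=None,
    duration_pool_lognorm: Tuple[float, float] = (4.5, 0.25),
    lambda_f_factor: float = 1.0,
    lambda_n_factor: float = 1.0,
    alpha_factor: float = 1.0,
) -> Dict[str, pd.DataFrame]:
    """Out-of-sample-style validation tables.

    Returns a dict with ``durations`` (4th-instar duration pool, h),
    ``initial_masses`` (start-of-5th-instar masses, g) and ``wandering``
    (age/mass at wandering from the joint model).  The ``*_factor``
    arguments perturb the generating parameters of the wandering arm
    only — emulating a strain/era gap between training data and
    out-of-sample records — so a validation comparison against
    unperturbed predictions degrades as the factors move away from 1.
    Scaling only ``lambda_f`` shifts the feeding share; scaling both
    rates together keeps the share and merely tightens the occupation
    variance.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu_ln, sd_ln = duration_pool_lognorm
    durations = pd.DataFrame({"duration_h": rng.lognormal(mu_ln, sd_ln, size=n)})
    m0 = rng.normal(m0_dist[0], m0_dist[1], size=n)
    bad = m0 <= 0
    while np.any(bad):
        m0[bad] = rng.normal(m0_dist[0], m0_dist[1], size=int(bad.sum()))
        bad = m0 <= 0
    initial = pd.DataFrame({"m0_g": m0})
    pert_rates = SwitchRates(
        truth.rates.lambda_f * lambda_f_factor,
        truth.rates.lambda_n * lambda_n_factor,
    )
    pert_alpha = AlphaDistribution(
        truth.alpha.mean_g_per_h * alpha_factor,
        truth.alpha.sd_g_per_h * alpha_factor,
        diet=truth.diet,
        instar=truth.instar,
    )
    samples = simulate_maturity(
        pert_rates, pert_alpha, m0_dist, dev, n, seed=rng, method="auto"
    )
    wander = pd.DataFrame(
        {
            "age_h": [s.age_h for s in samples if s.reached_wc],
            "mass_g": [s.mass_g for s in samples if s.reached_wc],
            "diet": truth.diet,
        }
    )
    return {"durations": durations, "initial_masses": initial, "wandering": wander}
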