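"""CSV dialects and run configuration.

Bout logs are one row per bout: ``individual_id, diet, instar, state,
start_s, end_s, trial_length_s`` (UTF-8, header required, times in
integer seconds).  Mass records, rate tables, alpha tables and
simulation outputs each have a fixed column set documented on their
reader/writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .alpha_growth import AlphaDistribution, MassRecord
from .inference import RateEstimate, TrialObservation
from .telegraph import (
    SECONDS_PER_HOUR,
    Bout,
    BoutSequence,
    InvalidParameterError,
    SwitchRates,
    total_feeding_time,
)

__all__ = [
    "BoutLogError",
    "read_bout_log",
    "trials_from_bout_log",
    "bout_durations",
    "read_mass_records",
    "write_rate_table",
    "read_rate_table",
    "write_alpha_table",
    "RunConfig",
    "load_config",
]

BOUT_COLUMNS = [
    "individual_id",
    "diet",
    "instar",
    "state",
    "start_s",
    "end_s",
    "trial_length_s",
]

MASS_COLUMNS = [
    "individual_id",
    "diet",
    "instar",
    "mass_molt_g",
    "mass_pretrial_g",
    "elapsed_h",
]


class BoutLogError(InvalidParameterError):
    """Bout-log validation failure; the message names the offending rows."""


GroupKey = Tuple[str, int]


def read_bout_log(path) -> Dict[GroupKey, Dict[str, BoutSequence]]:
    """Read and validate a bout-log CSV.

    Returns ``{(diet, instar): {individual_id: BoutSequence}}``.
    Overlaps, gaps, non-alternating states and windows not covering
    ``[0, trial_length_s]`` raise :class:`BoutLogError` naming the 1-based
    data row numbers involved.
    """
    df = pd.read_csv(path)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise BoutLogError(f"{path}: missing columns {missing}")
    out: Dict[GroupKey, Dict[str, BoutSequence]] = {}
    for (diet, instar, ind), sub in df.groupby(
        ["diet", "instar", "individual_id"], sort=False
    ):
        sub = sub.sort_values("start_s")
        rows = (sub.index + 2).tolist()  # header is line 1
        z_s = sub["trial_length_s"].iloc[0]
        if (sub["trial_length_s"] != z_s).any():
            raise BoutLogError(
                f"individual {ind}: inconsistent trial_length_s (rows {rows})"
            )
        bouts = [
            Bout(r.state, float(r.start_s), float(r.end_s))
            for r in sub.itertuples()
        ]
        try:
            seq = BoutSequence(
                trial_length_h=float(z_s) / SECONDS_PER_HOUR, bouts=bouts
            )
        except InvalidParameterError as exc:
            raise BoutLogError(
                f"individual {ind} (rows {rows[0]}-{rows[-1]}): {exc}"
            ) from exc
        out.setdefault((str(diet), int(instar)), {})[str(ind)] = seq
    if not out:
        raise BoutLogError(f"{path}: no bout rows")
    return out


def adapt_bout_log(
    df: pd.DataFrame,
    column_map: Dict[str, str],
    state_map: Optional[Dict[str, str]] = None,
    trial_length_s: Optional[float] = None,
) -> pd.DataFrame:
    """Adapter point for externally deposited bout tables.

    ``column_map`` maps dialect column names to the external ones;
    ``state_map`` translates external state labels to
    ``feeding``/``nonfeeding``.  A missing ``trial_length_s`` column can
    be filled with a constant.  The result conforms to the bout-log
    dialect and can be written out or validated via
    :func:`read_bout_log`.
    """
    out = pd.DataFrame({k: df[v] for k, v in column_map.items()})
    if state_map:
        out["state"] = out["state"].map(state_map)
    if "trial_length_s" not in out.columns:
        if trial_length_s is None:
            raise InvalidParameterError(
                "trial_length_s column or constant required"
            )
        out["trial_length_s"] = trial_length_s
    missing = [c for c in BOUT_COLUMNS if c not in out.columns]
    if missing:
        raise InvalidParameterError(f"adapted table missing columns {missing}")
    return out[BOUT_COLUMNS]


def trials_from_bout_log(
    bouts: Dict[GroupKey, Dict[str, BoutSequence]],
) -> Dict[GroupKey, List[TrialObservation]]:
    """Total feeding time per individual, grouped for fitting."""
    out: Dict[GroupKey, List[TrialObservation]] = {}
    for (diet, instar), individuals in bouts.items():
        out[(diet, instar)] = [
            TrialObservation(
                individual_id=ind,
                diet=diet,
                instar=instar,
                x_h=total_feeding_time(seq),
                z_h=seq.trial_length_h,
            )
            for ind, seq in individuals.items()
        ]
    return out


def bout_durations(
    bouts: Dict[GroupKey, Dict[str, BoutSequence]],
    group: GroupKey,
    state: str,
):
    """(durations_s, censored) for one group/state, for exponential checks.

    A bout touching either edge of the window is flagged censored (its
    true length is truncated by the observation window).
    """
    durs: List[float] = []
    cens: List[bool] = []
    for seq in bouts[group].values():
        z_s = seq.trial_length_s
        for b in seq.bouts:
            if b.state != state:
                continue
            durs.append(b.duration_s)
            cens.append(b.start_s <= 0.0 or b.end_s >= z_s)
    return durs, cens


def read_mass_records(path) -> List[MassRecord]:
    df = pd.read_csv(path)
    missing = [c for c in MASS_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    return [
        MassRecord(
            individual_id=str(r.individual_id),
            diet=str(r.diet),
            instar=int(r.instar),
            mass_molt_g=float(r.mass_molt_g),
            mass_pretrial_g=float(r.mass_pretrial_g),
            elapsed_h=float(r.elapsed_h),
        )
        for r in df.itertuples()
    ]


def write_rate_table(
    estimates: Dict[GroupKey, RateEstimate], path, seed=None
) -> pd.DataFrame:
    rows = []
    for (diet, instar), est in sorted(estimates.items()):
        rows.append(
            {
                "group": f"{diet}:{instar}",
                "diet": diet,
                "instar": instar,
                "lambda_f": est.point.lambda_f,
                "lambda_f_lo": est.ci_f[0] if est.ci_f else None,
                "lambda_f_hi": est.ci_f[1] if est.ci_f else None,
                "lambda_n": est.point.lambda_n,
                "lambda_n_lo": est.ci_n[0] if est.ci_n else None,
                "lambda_n_hi": est.ci_n[1] if est.ci_n else None,
                "level": est.level,
                "n_boot": est.n_boot,
                "n_trials": est.n_trials,
                "n_failed_replicates": est.n_failed,
                "seed": seed,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_rate_table(path) -> Dict[GroupKey, SwitchRates]:
    df = pd.read_csv(path)
    return {
        (str(r.diet), int(r.instar)): SwitchRates(float(r.lambda_f), float(r.lambda_n))
        for r in df.itertuples()
    }


def write_alpha_table(
    dists: Dict[GroupKey, AlphaDistribution], path
) -> pd.DataFrame:
    rows = [
        {
            "group": f"{diet}:{instar}",
            "diet": diet,
            "instar": instar,
            "alpha_mean": d.mean_g_per_h,
            "alpha_sd": d.sd_g_per_h,
            "n": d.n,
        }
        for (diet, instar), d in sorted(dists.items())
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values."""

    trials: Optional[str] = None
    masses: Optional[str] = None
    out_dir: str = "."
    z_h: float = 1.0
    min_bout_s: float = 5.0
    n_boot: int = 10_000
    level: float = 0.90
    n_sim: int = 100_000
    seed: int = 0
    w_c: float = 7.0
    j: int = 48
    mu: float = 1.0
    max_horizon_h: float = 5000.0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> RunConfig:
    """YAML or JSON config with keys mirroring :class:`RunConfig`."""
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    ) or {}
    return RunConfig.from_mapping(data)
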