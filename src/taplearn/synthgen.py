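"""Synthetic finger-tapping cohorts with known ground truth.

The generator emulates a two-session sequential finger-tapping study:
on day one a subject performs ``n_train`` 30-second trials whose expected
number of correct sequences follows the power-law-of-practice curve
``Y = I + C * (1 - R**(t-1))``; after an offline delay (30 minutes or
24 hours) three retest trials probe overnight consolidation.  Cohorts are
balanced over binary design factors (piano experience, age group,
intelligence, gender), and the mean consolidation gain of each design cell
is configured through additive factor effects, so every downstream
statistic has a known target.

All randomness is derived from a single master seed through per-subject
``SeedSequence`` substreams: appending subjects to a design never perturbs
the data of earlier subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .curvefit import CurveParams, learning_curve
from .errors import DesignError, TapLearnError

__all__ = [
    "FactorSpec",
    "CANONICAL_FACTORS",
    "ConsolidationEffectSpec",
    "GroupHyper",
    "GroupHyperParams",
    "generate_design",
    "draw_subject_params",
    "simulate_day1",
    "simulate_day2",
    "scenario_cohort",
    "save_cohort",
    "group_label",
]

# Observation noise on a single 30 s trial, in correct sequences.
DEFAULT_NOISE_SD = 1.5
# Subject-level spread of the overnight gain, chosen so that the
# within-cell standard deviation of the raw consolidation score
# (gain noise plus the day-1 and day-2 trial-mean noise, each sd/sqrt(3))
# equals 2.0 sequences: gain_sd**2 + 2/3 * noise_sd**2 = 2.0**2.
DEFAULT_GAIN_NOISE_SD = float(np.sqrt(4.0 - 2.0 / 3.0 * DEFAULT_NOISE_SD**2))
# Mean overnight gain shared by all cells before factor effects.
DEFAULT_BASELINE_GAIN = 3.0
# Age-related reduction of the mean gain, and the experience term that
# cancels it for players (the compensation pattern).
DEFAULT_AGE_EFFECT = -2.0

N_DAY2_TRIALS = 3

# Substream stage codes: one independent stream per subject and stage.
_STAGE_DESIGN, _STAGE_PARAMS, _STAGE_DAY1, _STAGE_DAY2 = 0, 1, 2, 3


@dataclass(frozen=True)
class FactorSpec:
    """A binary between-subject design factor."""

    name: str
    levels: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.levels) != 2 or len(set(self.levels)) != 2:
            raise DesignError(
                f"factor {self.name!r} must have exactly two distinct levels, "
                f"got {self.levels!r}"
            )

    def indicator(self, level: str) -> int:
        """1 for the second level, 0 for the first."""
        if level not in self.levels:
            raise DesignError(f"unknown level {level!r} for factor {self.name!r}")
        return int(level == self.levels[1])


CANONICAL_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("piano", ("non-player", "player")),
    FactorSpec("age_group", ("younger", "older")),
    FactorSpec("intelligence", ("control", "high")),
    FactorSpec("gender", ("female", "male")),
)

# Age bands in years.  Age 30 belongs to the older group.
DEFAULT_AGE_BANDS: dict[str, tuple[float, float]] = {
    "younger": (18.0, 30.0),  # half-open: draws are < 30
    "older": (30.0, 70.0),
}
# Lifetime hours of piano practice per experience level.
DEFAULT_HOUR_BANDS: dict[str, tuple[float, float]] = {
    "non-player": (0.0, 50.0),
    "player": (500.0, 5000.0),
}


def _subject_rng(seed: int, subject_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), int(subject_index), int(stage)))
    )


def group_label(row: Mapping[str, str], factors: Sequence[FactorSpec]) -> str:
    """Design-cell label: factor levels joined with '|' in factor order."""
    return "|".join(str(row[f.name]) for f in factors)


# ---------------------------------------------------------------------------
# Design generation
# ---------------------------------------------------------------------------

def generate_design(
    n_per_cell: int,
    factors: Sequence[FactorSpec] = CANONICAL_FACTORS,
    seed: int = 0,
    *,
    delay: str = "24h",
    age_bands: Mapping[str, tuple[float, float]] | None = None,
    hour_bands: Mapping[str, tuple[float, float]] | None = None,
    index_offset: int = 0,
) -> pd.DataFrame:
    """Balanced factorial subject table: ``n_per_cell`` subjects per cell.

    Continuous covariates are drawn within the cell's band: ``age_years``
    uniform in the age-group band (younger < 30, older >= 30) and
    ``piano_hours`` uniform in the experience band (players >= 500 h,
    non-players <= 50 h).  ``index_offset`` shifts the subject substream
    indices, allowing independent designs under one master seed.
    """
    if n_per_cell < 1:
        raise ValueError(f"n_per_cell must be >= 1, got {n_per_cell}")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise DesignError("factor names must be unique")
    age_bands = dict(DEFAULT_AGE_BANDS if age_bands is None else age_bands)
    hour_bands = dict(DEFAULT_HOUR_BANDS if hour_bands is None else hour_bands)

    rows = []
    idx = index_offset
    # replicate-major order: growing n_per_cell appends whole blocks, so
    # existing subjects keep their substreams (and hence their data)
    for _ in range(n_per_cell):
        for cell in itertools.product(*(f.levels for f in factors)):
            levels = dict(zip(names, cell))
            rng = _subject_rng(seed, idx, _STAGE_DESIGN)
            row = {"subject_id": f"S{idx + 1:04d}", **levels}
            if "age_group" in levels:
                lo, hi = age_bands[levels["age_group"]]
                row["age_years"] = float(rng.uniform(lo, hi))
            else:
                row["age_years"] = float(rng.uniform(18.0, 30.0))
            if "piano" in levels:
                lo, hi = hour_bands[levels["piano"]]
                row["piano_hours"] = float(rng.uniform(lo, hi))
            else:
                row["piano_hours"] = 0.0
            row["delay"] = delay
            rows.append(row)
            idx += 1
    df = pd.DataFrame(rows)
    return df[_ordered_columns(df)]


def _ordered_columns(df: pd.DataFrame) -> list[str]:
    # canonical CSV column order, with any extra factors after subject_id
    preferred = ["subject_id", "piano", "age_group", "age_years",
                 "intelligence", "gender", "piano_hours", "delay"]
    extra = [c for c in df.columns if c not in preferred]
    return ["subject_id"] + extra + [c for c in preferred[1:] if c in df.columns]


# ---------------------------------------------------------------------------
# Ground-truth parameters
# ---------------------------------------------------------------------------

@dataclass
class GroupHyper:
    """Population distribution of the learning-curve parameters in one cell."""

    mu_I: float
    mu_C: float
    mu_R: float
    sigma_I: float = 2.0
    sigma_C: float = 2.0
    sigma_R: float = 0.08
    sigma_obs: float = DEFAULT_NOISE_SD


@dataclass
class GroupHyperParams:
    """Per-group hyperparameters keyed by design-cell label."""

    groups: dict[str, GroupHyper]

    def __getitem__(self, group: str) -> GroupHyper:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"no hyperparameters defined for group {group!r}") from None


def default_group_hypers(
    factors: Sequence[FactorSpec], *, flat: bool = False
) -> GroupHyperParams:
    """Cell-wise hyperparameters encoding the study's online-learning pattern.

    Players start higher (mu_I + 6) and approach their plateau faster
    (mu_R - 0.15); the high-intelligence group starts higher (mu_I + 3);
    mean day-one improvement mu_C is shared.  With ``flat=True`` every
    cell gets identical hyperparameters (the null configuration).
    """
    by_name = {f.name: f for f in factors}
    groups: dict[str, GroupHyper] = {}
    for cell in itertools.product(*(f.levels for f in factors)):
        levels = dict(zip((f.name for f in factors), cell))
        label = group_label(levels, factors)
        if flat:
            groups[label] = GroupHyper(mu_I=10.0, mu_C=8.0, mu_R=0.6)
            continue
        mu_I, mu_R = 8.0, 0.65
        if "piano" in by_name and by_name["piano"].indicator(levels["piano"]):
            mu_I += 6.0
            mu_R -= 0.15
        if "intelligence" in by_name and by_name["intelligence"].indicator(
            levels["intelligence"]
        ):
            mu_I += 3.0
        groups[label] = GroupHyper(mu_I=mu_I, mu_C=8.0, mu_R=mu_R)
    return GroupHyperParams(groups)


def _truncated_normal_draw(
    mu: float,
    sigma: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> float:
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return float(mu)
    for _ in range(max_tries):
        x = rng.normal(mu, sigma)
        if lo < x < hi:
            return float(x)
    raise TapLearnError(
        f"rejection sampling failed for N({mu}, {sigma}) on ({lo}, {hi})"
    )


def draw_subject_params(
    hypers: GroupHyperParams,
    group: str,
    rng: np.random.Generator | int,
) -> CurveParams:
    """Sample one subject's (I, C, R) from the group's normal populations.

    I and C are truncated to be non-negative and R to (0, 1) by rejection;
    a zero sigma degenerates to the mean exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h = hypers[group]
    return CurveParams(
        I=_truncated_normal_draw(h.mu_I, h.sigma_I, 0.0, np.inf, rng),
        C=_truncated_normal_draw(h.mu_C, h.sigma_C, 0.0, np.inf, rng),
        R=_truncated_normal_draw(h.mu_R, h.sigma_R, 0.0, 1.0, rng),
    )


# ---------------------------------------------------------------------------
# Consolidation effects
# ---------------------------------------------------------------------------

@dataclass
class ConsolidationEffectSpec:
    """Additive model of the mean overnight gain over design cells.

    ``main_effects[name]`` shifts the mean gain of subjects at the factor's
    *second* level; ``interactions[(f, g)]`` shifts subjects at the second
    level of both factors.  The per-cell mean is therefore a lookup
    reproducible from the additive terms.  ``gain_noise_sd`` is the
    between-subject spread of the gain around its cell mean.
    """

    baseline_gain: float = DEFAULT_BASELINE_GAIN
    main_effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    gain_noise_sd: float = DEFAULT_GAIN_NOISE_SD

    def __post_init__(self) -> None:
        if self.gain_noise_sd < 0:
            raise ValueError("gain_noise_sd must be >= 0")

    def cell_gain(
        self, levels: Mapping[str, str], factors: Sequence[FactorSpec]
    ) -> float:
        by_name = {f.name: f for f in factors}
        gain = self.baseline_gain
        for name, effect in self.main_effects.items():
            if name not in by_name:
                raise KeyError(f"effect references unknown factor {name!r}")
            gain += effect * by_name[name].indicator(levels[name])
        for (a, b), effect in self.interactions.items():
            for name in (a, b):
                if name not in by_name:
                    raise KeyError(f"effect references unknown factor {name!r}")
            gain += (
                effect
                * by_name[a].indicator(levels[a])
                * by_name[b].indicator(levels[b])
            )
        return float(gain)

    def gain_table(self, factors: Sequence[FactorSpec]) -> dict[str, float]:
        """Mean gain for every design cell."""
        table = {}
        for cell in itertools.product(*(f.levels for f in factors)):
            levels = dict(zip((f.name for f in factors), cell))
            table[group_label(levels, factors)] = self.cell_gain(levels, factors)
        return table


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def simulate_day1(
    params: CurveParams,
    n_train: int,
    noise_sd: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Day-one training trials: power-law curve plus Gaussian noise.

    Counts are treated as continuous; values are clipped at zero.  At least
    three trials are required for the three curve parameters to be
    identifiable downstream.
    """
    if n_train < 3:
        raise ValueError(f"n_train must be >= 3, got {n_train}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = np.arange(1, n_train + 1)
    y = learning_curve(params.I, params.C, params.R, t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_train)
    return np.clip(y, 0.0, None)


def day1_endpoint(params: CurveParams, n_train: int) -> float:
    """Noise-free mean of the last three day-one curve values."""
    t = np.arange(n_train - 2, n_train + 1)
    return float(np.mean(learning_curve(params.I, params.C, params.R, t)))


def simulate_day2(
    params: CurveParams,
    gain: ConsolidationEffectSpec,
    subject: Mapping[str, str],
    noise_sd: float,
    rng: np.random.Generator | int,
    *,
    factors: Sequence[FactorSpec] = CANONICAL_FACTORS,
    n_train: int = 12,
    return_realized_gain: bool = False,
):
    """Three retest trials after the offline delay.

    The subject's day-two level is their noise-free day-one endpoint (mean
    of the last three curve values) plus an overnight gain drawn once per
    subject as ``cell_gain + N(0, gain_noise_sd)``; each trial then adds
    independent observation noise and is clipped at zero.  Anchoring day
    two at the day-one endpoint rather than the asymptote I + C makes the
    generative gain coincide exactly with the last3-based consolidation
    score in the noise-free limit.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cell = gain.cell_gain(subject, factors)
    realized = cell + (
        rng.normal(0.0, gain.gain_noise_sd) if gain.gain_noise_sd > 0 else 0.0
    )
    base = day1_endpoint(params, n_train) + realized
    y = np.full(N_DAY2_TRIALS, base)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=N_DAY2_TRIALS)
    y = np.clip(y, 0.0, None)
    if return_realized_gain:
        return y, float(realized)
    return y


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("main", "control1", "control2", "null")


def _main_gain_spec(**kw) -> ConsolidationEffectSpec:
    """Compensation pattern: only older non-players lose gain."""
    age = kw.pop("age_effect", DEFAULT_AGE_EFFECT)
    return ConsolidationEffectSpec(
        main_effects={"age_group": age},
        interactions={("piano", "age_group"): -age},
        **kw,
    )


def _control1_design(seed: int) -> pd.DataFrame:
    """Four recruited groups (20/20/14/13) with a 30-minute delay.

    Group sizes and female counts follow the recruited samples; the
    intelligence split emulates a median split, alternating within group.
    """
    specs = [  # (age_group, piano, n, n_female, age band)
        ("younger", "player", 20, 10, (18.0, 28.0)),
        ("younger", "non-player", 20, 10, (18.0, 29.0)),
        ("older", "player", 14, 5, (55.0, 70.0)),
        ("older", "non-player", 13, 5, (55.0, 66.0)),
    ]
    rows = []
    idx = 0
    for age_group, piano, n, n_female, band in specs:
        for j in range(n):
            rng = _subject_rng(seed, idx, _STAGE_DESIGN)
            rows.append(
                {
                    "subject_id": f"S{idx + 1:04d}",
                    "piano": piano,
                    "age_group": age_group,
                    "intelligence": "high" if j % 2 else "control",
                    "gender": "female" if j < n_female else "male",
                    "age_years": float(rng.uniform(*band)),
                    "piano_hours": float(
                        rng.uniform(*DEFAULT_HOUR_BANDS[piano])
                    ),
                    "delay": "30min",
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    return df[_ordered_columns(df)]


def _control2_design(seed: int) -> pd.DataFrame:
    """Young subjects only, short training, crossed with the delay factor.

    30-minute arm: n = 30 with 12 players; 24-hour arm: n = 37 with 17
    players.  Gender and the intelligence median split alternate within
    each delay-by-experience group.
    """
    specs = [  # (delay, piano, n)
        ("30min", "player", 12),
        ("30min", "non-player", 18),
        ("24h", "player", 17),
        ("24h", "non-player", 20),
    ]
    rows = []
    idx = 0
    for delay, piano, n in specs:
        for j in range(n):
            rng = _subject_rng(seed, idx, _STAGE_DESIGN)
            rows.append(
                {
                    "subject_id": f"S{idx + 1:04d}",
                    "piano": piano,
                    "age_group": "younger",
                    "intelligence": "high" if j % 2 else "control",
                    "gender": "female" if j % 2 == 0 else "male",
                    "age_years": float(rng.uniform(18.0, 30.0)),
                    "piano_hours": float(
                        rng.uniform(*DEFAULT_HOUR_BANDS[piano])
                    ),
                    "delay": delay,
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    return df[_ordered_columns(df)]


def scenario_cohort(
    name: str,
    overrides: Mapping[str, object] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one named study scenario.

    - ``main``: 128 subjects, 8 per cell of the 2^4 design, 12 training and
      3 retest trials, 24 h delay; older non-players' mean gain is reduced
      by 2.0 sequences while every other cell shares the younger gain.
    - ``control1``: the four recruited groups (20/20/14/13), 30-minute
      delay, age effect on the gain but no experience effect.
    - ``control2``: young subjects, 6 training trials, both delays, no
      experience effect.
    - ``null``: the main design with identical learning populations in
      every cell and all factor effects on the gain set to zero.

    Returns (subject factors, trial table, ground-truth record); the
    record stores every parameter used, including each subject's drawn
    curve parameters and realized overnight gain.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    ov = dict(overrides or {})
    noise_sd = float(ov.pop("noise_sd", DEFAULT_NOISE_SD))
    gain_kw = {
        k: ov.pop(k)
        for k in ("baseline_gain", "gain_noise_sd")
        if k in ov
    }

    factors = CANONICAL_FACTORS
    if name == "main":
        n_per_cell = int(ov.pop("n_per_cell", 8))
        n_train = int(ov.pop("n_train", 12))
        design = generate_design(n_per_cell, factors, seed, delay="24h")
        gains = _main_gain_spec(
            age_effect=float(ov.pop("age_effect", DEFAULT_AGE_EFFECT)), **gain_kw
        )
        hypers = default_group_hypers(factors)
    elif name == "null":
        n_per_cell = int(ov.pop("n_per_cell", 8))
        n_train = int(ov.pop("n_train", 12))
        design = generate_design(n_per_cell, factors, seed, delay="24h")
        gains = ConsolidationEffectSpec(**gain_kw)
        hypers = default_group_hypers(factors, flat=True)
    elif name == "control1":
        n_train = int(ov.pop("n_train", 12))
        design = _control1_design(seed)
        gains = ConsolidationEffectSpec(
            main_effects={"age_group": float(ov.pop("age_effect", -2.5))},
            **gain_kw,
        )
        hypers = default_group_hypers(factors)
    else:  # control2
        n_train = int(ov.pop("n_train", 6))
        design = _control2_design(seed)
        gains = ConsolidationEffectSpec(**gain_kw)
        hypers = default_group_hypers(factors)
    if ov:
        raise ValueError(f"unrecognized overrides: {sorted(ov)}")

    trial_rows = []
    subjects_truth = {}
    for idx, row in design.reset_index(drop=True).iterrows():
        glabel = group_label(row, factors)
        params = draw_subject_params(
            hypers, glabel, _subject_rng(seed, idx, _STAGE_PARAMS)
        )
        y1 = simulate_day1(
            params, n_train, noise_sd, _subject_rng(seed, idx, _STAGE_DAY1)
        )
        y2, realized = simulate_day2(
            params,
            gains,
            row,
            noise_sd,
            _subject_rng(seed, idx, _STAGE_DAY2),
            factors=factors,
            n_train=n_train,
            return_realized_gain=True,
        )
        sid = row["subject_id"]
        for t, v in enumerate(y1, start=1):
            trial_rows.append((sid, "day1", t, float(v)))
        for t, v in enumerate(y2, start=1):
            trial_rows.append((sid, "day2", t, float(v)))
        subjects_truth[sid] = {
            "group": glabel,
            "I": params.I,
            "C": params.C,
            "R": params.R,
            "cell_gain": gains.cell_gain(row, factors),
            "realized_gain": realized,
        }

    trials = pd.DataFrame(
        trial_rows, columns=["subject_id", "session", "trial", "correct_sequences"]
    )
    truth = {
        "scenario": name,
        "seed": int(seed),
        "n_train": n_train,
        "n_day2": N_DAY2_TRIALS,
        "noise_sd": noise_sd,
        "gain_spec": {
            "baseline_gain": gains.baseline_gain,
            "main_effects": dict(gains.main_effects),
            "interactions": {f"{a}:{b}": v for (a, b), v in gains.interactions.items()},
            "gain_noise_sd": gains.gain_noise_sd,
        },
        "cell_gains": gains.gain_table(factors),
        "hypers": {g: asdict(h) for g, h in hypers.groups.items()},
        "subjects": subjects_truth,
    }
    return design, trials, truth


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_cohort(
    out_dir: str | Path,
    factors: pd.DataFrame,
    trials: pd.DataFrame,
    ground_truth: dict | None = None,
) -> dict[str, Path]:
    """Write factors.csv, trials.csv and (optionally) ground_truth.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "factors": out / "factors.csv",
        "trials": out / "trials.csv",
    }
    factors.to_csv(paths["factors"], index=False)
    trials.to_csv(paths["trials"], index=False)
    if ground_truth is not None:
        paths["ground_truth"] = out / "ground_truth.yaml"
        with open(paths["ground_truth"], "w") as fh:
            yaml.safe_dump(ground_truth, fh, sort_keys=True)
    return paths
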