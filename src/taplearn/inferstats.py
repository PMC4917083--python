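"""Consolidation scores and the downstream inferential statistics.

Implements the full set of between-subject analyses used on the
finger-tapping data: the overnight consolidation score (retest mean minus
end-of-training mean) with its variance-stabilizing square-root
transform, effect-coded factorial ANOVA with two-way interactions and
pooled-error simple effects, one-sample t-tests, Pearson correlations,
and the Fisher r-to-z comparison of two independent correlations.

The factorial ANOVA uses effect (+1/-1) coding and partial
(Type-III-style) sums of squares: each effect's SS is the increase in
residual SS when its column is dropped from the full model.  On balanced
designs this coincides with the classical sequential decomposition and
the effect SS plus residual SS add up to the total SS; on unbalanced
designs (the 30-minute control cohort) it is the conventional choice
that reduces to the balanced answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DesignError

__all__ = [
    "ConsolidationScore",
    "TestResult",
    "signed_sqrt",
    "consolidation_score",
    "consolidation_scores",
    "factorial_anova",
    "simple_effects",
    "one_sample_t",
    "pearson_r",
    "fisher_z_compare",
    "curve_param_anovas",
]


@dataclass(frozen=True)
class TestResult:
    """Scalar test outcome: the statistic, its df (if any), p and tail."""

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    tail: str = "two"
    name: str = ""


@dataclass(frozen=True)
class ConsolidationScore:
    """Overnight gain of one subject, raw and square-root transformed."""

    subject_id: str
    raw: float
    transformed: float
    selection_mode: str


def signed_sqrt(x):
    """Signed square root: ``sign(x) * sqrt(|x|)``.

    Monotone and defined for negative scores, so it can be applied to
    subjects whose performance dropped overnight while still compressing
    the positive skew of the gains.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.sqrt(np.abs(x))
    return float(out) if out.ndim == 0 else out


def consolidation_score(
    day1: Sequence[float],
    day2: Sequence[float],
    mode: str = "last3",
    subject_id: str = "",
) -> ConsolidationScore:
    """Overnight consolidation: mean(day-2 trials) - mean(3 day-1 trials).

    ``mode`` selects the day-1 reference: the final three trials in index
    order ("last3", the primary measure) or the three highest-valued
    trials ("best3", the fatigue control).  Day 2 must have exactly three
    trials; day-1 values must be given in trial order.
    """
    day1 = np.asarray(day1, dtype=float)
    day2 = np.asarray(day2, dtype=float)
    if day1.size < 3:
        raise ValueError(f"day1 needs >= 3 trials, got {day1.size}")
    if day2.size != 3:
        raise ValueError(f"day2 needs exactly 3 trials, got {day2.size}")
    if mode == "last3":
        ref = day1[-3:]
    elif mode == "best3":
        ref = np.sort(day1)[-3:]
    else:
        raise ValueError(f"mode must be 'last3' or 'best3', got {mode!r}")
    raw = float(day2.mean() - ref.mean())
    return ConsolidationScore(subject_id, raw, signed_sqrt(raw), mode)


def consolidation_scores(
    trials: pd.DataFrame,
    mode: str = "last3",
    transform: str = "signed_root",
) -> pd.DataFrame:
    """Per-subject consolidation scores for a long trial table.

    ``transform="signed_root"`` applies the signed square root per
    subject; ``"shift_root"`` instead shifts all raw scores by the cohort
    minimum (if negative) before taking the root, the alternative
    convention for handling overnight losses.
    """
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        d1 = sub[sub["session"] == "day1"].sort_values("trial")
        d2 = sub[sub["session"] == "day2"].sort_values("trial")
        sc = consolidation_score(
            d1["correct_sequences"].to_numpy(),
            d2["correct_sequences"].to_numpy(),
            mode,
            subject_id=str(sid),
        )
        rows.append({"subject_id": sc.subject_id, "raw": sc.raw,
                     "transformed": sc.transformed})
    out = pd.DataFrame(rows)
    if transform == "shift_root":
        shift = max(0.0, -float(out["raw"].min()))
        out["transformed"] = np.sqrt(out["raw"] + shift)
    elif transform != "signed_root":
        raise ValueError(f"unknown transform {transform!r}")
    return out


# ---------------------------------------------------------------------------
# Factorial ANOVA
# ---------------------------------------------------------------------------

def _infer_factor_columns(factors: pd.DataFrame) -> list[str]:
    cols = []
    for c in factors.columns:
        if c == "subject_id":
            continue
        col = factors[c]
        if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)) \
                and col.nunique() == 2:
            cols.append(c)
    return cols


def _effect_columns(
    factors: pd.DataFrame, factor_names: Sequence[str], interaction_order: int
) -> tuple[np.ndarray, list[str]]:
    mains = {}
    for name in factor_names:
        levels = sorted(factors[name].unique())
        if len(levels) != 2:
            raise DesignError(
                f"factor {name!r} has {len(levels)} levels; exactly 2 required"
            )
        mains[name] = np.where(factors[name].to_numpy() == levels[1], 1.0, -1.0)
    cols, labels = [], []
    for order in range(1, interaction_order + 1):
        for combo in itertools.combinations(factor_names, order):
            col = np.ones(len(factors))
            for name in combo:
                col = col * mains[name]
            cols.append(col)
            labels.append(":".join(combo))
    return np.column_stack(cols), labels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def factorial_anova(
    response,
    factors: pd.DataFrame,
    interaction_order: int = 2,
    factor_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Effect-coded factorial ANOVA with interactions up to the given order.

    Returns a table with one row per effect (label, ss, df_num, df_den,
    F, p) and a final residual row.  ``response`` is one value per row of
    ``factors``; binary factors are detected automatically unless
    ``factor_names`` is given.
    """
    y = np.asarray(response, dtype=float)
    factors = factors.reset_index(drop=True)
    if len(y) != len(factors):
        raise ValueError("response length does not match factors")
    if factor_names is None:
        factor_names = _infer_factor_columns(factors)
    if not factor_names:
        raise DesignError("no binary factors found")
    E, labels = _effect_columns(factors, factor_names, interaction_order)
    X = np.column_stack([np.ones(len(y)), E])
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased effects via near-zero R diagonal of a pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [labels[i - 1] for i in range(1, p) if diag[i] < 1e-8 * diag.max()]
        raise DesignError(f"rank-deficient design; aliased effects: {aliased}")
    df_den = len(y) - p
    if df_den < 1:
        raise DesignError("no residual degrees of freedom")
    rss_full = _rss(X, y)
    ms_res = rss_full / df_den

    rows = []
    for j, label in enumerate(labels):
        Xr = np.delete(X, j + 1, axis=1)
        ss = _rss(Xr, y) - rss_full
        ss = max(ss, 0.0)
        F = (ss / 1.0) / ms_res if ms_res > 0 else (np.inf if ss > 0 else 0.0)
        pval = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
        rows.append({"effect": label, "ss": ss, "df_num": 1, "df_den": df_den,
                     "F": F, "p": pval})
    rows.append({"effect": "Residual", "ss": rss_full, "df_num": df_den,
                 "df_den": np.nan, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def simple_effects(
    response,
    factors: pd.DataFrame,
    target: str,
    within: str,
    interaction_order: int = 2,
    factor_names: Sequence[str] | None = None,
    pooled_error: bool = True,
) -> pd.DataFrame:
    """Effect of ``target`` tested separately at each level of ``within``.

    The default tests the difference between the two target-level means
    inside a ``within`` level against the pooled residual mean square of
    the full factorial model, so the denominator df equals the full
    model's residual df.  ``pooled_error=False`` instead runs a Welch
    t-test within each level (reported as F = t^2 with Welch df).
    """
    if target == within:
        raise ValueError("target and within must be different factors")
    y = np.asarray(response, dtype=float)
    factors = factors.reset_index(drop=True)
    full = factorial_anova(y, factors, interaction_order, factor_names)
    resid = full[full["effect"] == "Residual"].iloc[0]
    ms_res = resid["ss"] / resid["df_num"]
    df_den = float(resid["df_num"])

    t_levels = sorted(factors[target].unique())
    if len(t_levels) != 2:
        raise DesignError(f"target factor {target!r} must have 2 levels")
    rows = []
    for level in sorted(factors[within].unique()):
        sel = factors[within] == level
        ya = y[sel.to_numpy() & (factors[target] == t_levels[0]).to_numpy()]
        yb = y[sel.to_numpy() & (factors[target] == t_levels[1]).to_numpy()]
        if len(ya) == 0 or len(yb) == 0:
            raise DesignError(
                f"no observations for {target!r} within {within}={level!r}"
            )
        diff = yb.mean() - ya.mean()
        if pooled_error:
            ss = diff**2 / (1.0 / len(ya) + 1.0 / len(yb))
            F = ss / ms_res if ms_res > 0 else (np.inf if ss > 0 else 0.0)
            pval = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
            rows.append({"within_level": level, "diff": diff, "F": F,
                         "df_num": 1, "df_den": df_den, "p": pval})
        else:
            t, pval = stats.ttest_ind(yb, ya, equal_var=False)
            va, vb = ya.var(ddof=1) / len(ya), yb.var(ddof=1) / len(yb)
            df_w = (va + vb) ** 2 / (
                va**2 / (len(ya) - 1) + vb**2 / (len(yb) - 1)
            )
            rows.append({"within_level": level, "diff": diff, "F": float(t) ** 2,
                         "df_num": 1, "df_den": df_w, "p": float(pval)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scalar tests
# ---------------------------------------------------------------------------

def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("one-sample t-test needs n >= 2")
    if np.allclose(x.std(ddof=1), 0.0):
        raise DegenerateInputError("one-sample t-test undefined at zero variance")
    res = stats.ttest_1samp(x, mu0)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        df=float(x.size - 1), tail="two", name="one_sample_t",
    )


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with a two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateInputError("correlation needs n >= 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise DegenerateInputError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        df=float(x.size - 2), tail="two", name="pearson_r",
    )


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int, tail: str = "two"
) -> TestResult:
    """Compare two independent correlations via the Fisher z-transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value
    comes from the standard normal.  One-tailed tests use the observed
    direction of the difference.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError(f"correlations must satisfy |r| < 1, got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("Fisher comparison needs n >= 4 in both samples")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    if tail == "two":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(abs(z)) if z != 0 else 0.5
    return TestResult(
        statistic=float(z), p=float(p), df=None, tail=tail,
        name="fisher_z_compare",
    )


# ---------------------------------------------------------------------------
# Curve-parameter analyses
# ---------------------------------------------------------------------------

def curve_param_anovas(
    estimates: pd.DataFrame,
    factors: pd.DataFrame,
    n_train: int = 12,
    interaction_order: int = 2,
    factor_names: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Factorial ANOVAs on the fitted curve parameters.

    Runs one ANOVA each on initial performance I, learning rate R, and
    the model-implied day-one improvement from trial 1 to trial
    ``n_train``, ``C * (1 - R**(n_train-1))``.  ``estimates`` must hold
    one (subject_id, I, C, R) row per subject in ``factors``.
    """
    merged = factors.merge(estimates, on="subject_id", how="left", validate="1:1")
    if merged[["I", "C", "R"]].isna().any().any():
        missing = merged.loc[merged["I"].isna(), "subject_id"].tolist()
        raise KeyError(f"no curve estimates for subjects: {missing}")
    improvement = merged["C"] * (1.0 - merged["R"] ** (n_train - 1))
    outcomes = {
        "I": merged["I"].to_numpy(),
        "R": merged["R"].to_numpy(),
        "improvement": improvement.to_numpy(),
    }
    return {
        name: factorial_anova(vals, factors, interaction_order, factor_names)
        for name, vals in outcomes.items()
    }
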