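"""Behavioral statistics for the categorization experiment.

Everything operates on trial logs in the schema of
:mod:`facecontrast.behavior`: learning curves over training sessions,
pooled per-condition accuracies with exact binomial tests, the
targets x distractors pairwise percent-correct matrix, split-half
reliability with the Spearman-Brown correction, Pearson correlations
between matrices, and a cell-permutation test for the behavior-model
correlation.  Correction trials are excluded from every accuracy
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedCorrelationError",
    "DegenerateTestError",
    "PairwiseMatrix",
    "PermutationResult",
    "learning_curves",
    "condition_accuracy",
    "pairwise_matrix",
    "matrix_correlation",
    "split_half_reliability",
    "spearman_brown",
    "permutation_test",
    "compare_samples",
]


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (constant input or too few common cells)."""


class DegenerateTestError(ValueError):
    """The requested test statistic is undefined for these data."""


@dataclass(frozen=True)
class PairwiseMatrix:
    """Targets x distractors percent-correct grid with per-cell counts.

    ``percent_correct`` lies in [0, 100] and is NaN wherever
    ``n_trials`` is zero.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    percent_correct: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.row_labels), len(self.col_labels))
        if self.percent_correct.shape != shape or self.n_trials.shape != shape:
            raise ValueError("grid shapes do not match labels")


@dataclass(frozen=True)
class PermutationResult:
    observed_r: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int


def _noncorrection(trials: pd.DataFrame) -> pd.DataFrame:
    return trials.loc[~trials["correction_trial"].astype(bool)]


def _new_test_trials(trials: pd.DataFrame) -> pd.DataFrame:
    sub = _noncorrection(trials)
    return sub.loc[sub["pair_novelty"] == "new"]


# ---------------------------------------------------------------------------
# training


def learning_curves(trials: pd.DataFrame, group_col: str | None = None) -> pd.DataFrame:
    """Per-phase session accuracy curves averaged across animals.

    Returns a tidy frame with columns ``group, phase, session, accuracy,
    sem, n_rats`` where ``session`` indexes sessions within the phase
    (0-based), ``accuracy`` is the across-rat mean of per-rat session
    accuracy on non-correction trials and ``sem`` the standard error
    across rats.  ``group_col`` (e.g. ``"stim_order"``) splits the
    cohort; otherwise a single group ``"all"`` is reported.
    """
    sub = _noncorrection(trials)
    sub = sub.loc[sub["phase_or_protocol"].str.startswith("phase")]
    if sub.empty:
        raise ValueError("no training trials")
    sub = sub.copy()
    if group_col is None:
        sub["__group"] = "all"
    else:
        sub["__group"] = sub[group_col]
    # per-rat session order within each phase
    per = (
        sub.groupby(["__group", "rat_id", "phase_or_protocol", "session_index"])["chose_target"]
        .mean()
        .reset_index(name="accuracy")
    )
    per["session"] = per.groupby(["rat_id", "phase_or_protocol"]).cumcount()
    agg = (
        per.groupby(["__group", "phase_or_protocol", "session"])["accuracy"]
        .agg(
            accuracy="mean",
            sem=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
            n_rats="count",
        )
        .reset_index()
        .rename(columns={"__group": "group", "phase_or_protocol": "phase"})
    )
    return agg


# ---------------------------------------------------------------------------
# generalization


def condition_accuracy(
    trials: pd.DataFrame, condition_map: Mapping[tuple[str, str], str]
) -> pd.DataFrame:
    """Pooled accuracy per hypothesis condition with exact binomial tests.

    Pools new-pair, non-correction test trials of all animals within
    each condition; reports the proportion correct, a two-sided exact
    binomial p-value against 0.5 (outcomes with pmf <= the observed pmf)
    and the Clopper-Pearson 95% CI.  Conditions without trials are
    omitted with a warning.
    """
    sub = _new_test_trials(trials)
    conditions = sorted(set(condition_map.values()))
    key = list(zip(sub["target_id"], sub["distractor_id"]))
    labels = pd.Series([condition_map.get(k) for k in key], index=sub.index)
    rows = []
    for cond in conditions:
        grp = sub.loc[labels == cond]
        if grp.empty:
            warnings.warn(f"condition {cond!r} has no trials; omitted", stacklevel=2)
            continue
        n = int(len(grp))
        k = int(grp["chose_target"].sum())
        test = stats.binomtest(k, n, 0.5, alternative="two-sided")
        ci = test.proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {
                "condition": cond,
                "n_trials": n,
                "n_correct": k,
                "accuracy": k / n,
                "p_value": float(test.pvalue),
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return pd.DataFrame(rows)


def pairwise_matrix(
    trials: pd.DataFrame,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    rounds: Sequence[int] | None = None,
) -> PairwiseMatrix:
    """Pooled percent-correct per test pair (rows targets, cols distractors).

    Each cell is 100 x correct / total over the new-pair non-correction
    trials of all animals (optionally restricted to ``rounds``); cells
    without trials are NaN.
    """
    sub = _new_test_trials(trials)
    if rounds is not None:
        sub = sub.loc[sub["round"].isin(list(rounds))]
    shape = (len(row_labels), len(col_labels))
    correct = np.zeros(shape)
    total = np.zeros(shape, dtype=int)
    ri = {t: i for i, t in enumerate(row_labels)}
    ci = {d: j for j, d in enumerate(col_labels)}
    grouped = sub.groupby(["target_id", "distractor_id"])["chose_target"].agg(["sum", "count"])
    for (t, d), row in grouped.iterrows():
        if t in ri and d in ci:
            correct[ri[t], ci[d]] = row["sum"]
            total[ri[t], ci[d]] = row["count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * correct / np.maximum(total, 1), np.nan)
    return PairwiseMatrix(
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
        percent_correct=pct,
        n_trials=total,
    )


def _grid(x) -> np.ndarray:
    if isinstance(x, PairwiseMatrix):
        return np.asarray(x.percent_correct, dtype=float)
    if hasattr(x, "values") and not isinstance(x, np.ndarray):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _common_cells(a, b) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = _grid(a), _grid(b)
    if ga.shape != gb.shape:
        raise ValueError(f"grid shapes differ: {ga.shape} vs {gb.shape}")
    mask = np.isfinite(ga) & np.isfinite(gb)
    if mask.sum() < 3:
        raise UndefinedCorrelationError("fewer than 3 common defined cells")
    return ga[mask], gb[mask]


def matrix_correlation(a, b) -> float:
    """Pearson correlation over the common defined cells of two grids."""
    x, y = _common_cells(a, b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input grid")
    return float(stats.pearsonr(x, y).statistic)


def split_half_reliability(matrix_round1, matrix_round2) -> float:
    """Correlation of the pairwise matrix between the two test rounds."""
    return matrix_correlation(matrix_round1, matrix_round2)


def spearman_brown(r: float) -> float:
    """Predicted full-length reliability ``2r / (1 + r)`` of a split half."""
    if r <= -1.0:
        raise ValueError("Spearman-Brown correction undefined for r <= -1")
    return 2.0 * r / (1.0 + r)


def permutation_test(
    behavior,
    model,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Cell-permutation null for the behavior-model Pearson correlation.

    The behavior grid's defined cells are shuffled as one flat vector
    (cells move freely across rows and columns) and re-correlated with
    the fixed model grid; ``p = #{null r >= observed} / n_perm`` with no
    smoothing term.
    """
    x, y = _common_cells(behavior, model)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input grid")
    n = x.size
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    observed = float(np.mean(zx * zy))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean(zx[rng.permutation(n)] * zy)
    p = float(np.count_nonzero(null >= observed) / n_perm)
    return PermutationResult(
        observed_r=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=p,
        n_perm=int(n_perm),
        seed=int(seed),
    )


def compare_samples(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateTestError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), int(x.size + y.size - 2), float(res.pvalue)
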