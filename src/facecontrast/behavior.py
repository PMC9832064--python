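"""Touchscreen-experiment simulator and decision-model fitting.

Simulates a two-alternative forced-choice face/non-face categorization
experiment: five cumulative training phases run to a session-accuracy
criterion (80% for two consecutive 100-trial sessions, or a relaxed
75% x 4 variant), with correction trials after errors; then three test
protocols, run in two rounds of three counterbalanced blocks, mixing
one third trained ("old") pairs under real reward with two thirds new
pairs rewarded randomly on 80% of trials.

Choices come from a standard 2AFC psychometric model with a lapse rate:
on a new pair with feature-strength difference ``delta`` (target minus
distractor mean strength),

    P(correct) = lambda / 2 + (1 - lambda) * logistic(sensitivity * delta)

while trained pairs use a fixed asymptotic accuracy ``p_old`` under the
same lapse.  ``recover_parameters`` fits (sensitivity, lapse) back from
trial logs by maximum likelihood, which closes the loop between the
generative model and the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .stimuli import StimulusSet
from .template import ModelMatrix

__all__ = [
    "SimulationTruncatedError",
    "BoundaryEstimateWarning",
    "DecisionModel",
    "RecoveredParams",
    "TRIAL_COLUMNS",
    "CRITERIA",
    "PROTOCOL_GROUPS",
    "simulate_training",
    "simulate_testing",
    "simulate_experiment",
    "recover_parameters",
]

#: criterion name -> (session accuracy threshold, consecutive sessions)
CRITERIA: dict[str, tuple[float, int]] = {"strict": (0.80, 2), "relaxed": (0.75, 4)}

#: test protocol -> nominal CF groups of the distractors it samples
PROTOCOL_GROUPS: dict[str, tuple[int, int]] = {
    "test1": (1, 6),
    "test2": (1, 12),
    "test3": (6, 12),
}

TRIAL_COLUMNS = [
    "rat_id",
    "round",
    "session_index",
    "phase_or_protocol",
    "block_index",
    "target_id",
    "distractor_id",
    "target_side",
    "chose_target",
    "rewarded",
    "correction_trial",
    "pair_novelty",
]


class SimulationTruncatedError(RuntimeError):
    """A simulated animal failed to reach criterion within the session cap."""


class BoundaryEstimateWarning(UserWarning):
    """A fitted parameter landed on the boundary of its allowed range."""


@dataclass(frozen=True)
class DecisionModel:
    """2AFC psychometric decision model with lapse and side bias.

    Parameters
    ----------
    sensitivity
        Slope per unit feature-strength difference (logistic link).
    lapse
        Fraction of trials answered at random regardless of stimulus;
        ``lapse = 1`` forces chance performance everywhere.
    side_bias
        Additive bias (logit units, scaled by 2) toward the left screen;
        0 means unbiased.
    p_old
        Asymptotic (lapse-free) accuracy on trained pairs.
    """

    sensitivity: float = 4.0
    lapse: float = 0.25
    side_bias: float = 0.0
    p_old: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0,1]")
        if not -1.0 <= self.side_bias <= 1.0:
            raise ValueError("side_bias must lie in [-1,1]")
        if not 0.5 <= self.p_old <= 1.0:
            raise ValueError("p_old must lie in [0.5,1]")

    def p_correct_new(self, delta: float | np.ndarray) -> float | np.ndarray:
        """P(choose target) on a new pair with strength difference ``delta``."""
        return self.lapse / 2.0 + (1.0 - self.lapse) * expit(self.sensitivity * np.asarray(delta))

    def p_correct_old(self) -> float:
        """P(choose target) on a trained pair."""
        return self.lapse / 2.0 + (1.0 - self.lapse) * self.p_old

    def p_choose_target(self, p_correct: float, target_side: str) -> float:
        """Apply the side bias to an unbiased P(choose target)."""
        if self.side_bias == 0.0:
            return p_correct
        p = np.clip(p_correct, 1e-9, 1 - 1e-9)
        shift = 2.0 * self.side_bias * (1.0 if target_side == "left" else -1.0)
        return float(expit(logit(p) + shift))


def _choose(rng: np.random.Generator, model: DecisionModel, p_correct: float, side: str) -> bool:
    return bool(rng.random() < model.p_choose_target(p_correct, side))


def _side(rng: np.random.Generator) -> str:
    return "left" if rng.random() < 0.5 else "right"


# ---------------------------------------------------------------------------
# training


def simulate_training(
    stimulus_set: StimulusSet,
    model: DecisionModel,
    criterion: str = "strict",
    seed: int | np.random.Generator = 0,
    rat_id: str = "rat1",
    session_trials: int = 100,
    max_sessions_per_phase: int = 150,
    reverse_order: bool = False,
) -> pd.DataFrame:
    """Simulate the five cumulative training phases to criterion.

    Phase ``p`` presents all combinations of the first ``p`` training
    targets and distractors (in reversed introduction order when
    ``reverse_order``).  Sessions contain ``session_trials``
    non-correction trials; after each error the same pair and side are
    repeated (flagged as correction trials) until answered correctly.
    The phase advances once the non-correction session accuracy meets
    the criterion for the required number of consecutive sessions.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(CRITERIA)}")
    threshold, needed = CRITERIA[criterion]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    targets = list(stimulus_set.train_targets)
    distractors = list(stimulus_set.train_distractors)
    if reverse_order:
        targets, distractors = targets[::-1], distractors[::-1]

    rows: list[dict] = []
    session_index = 0
    p_corr = model.p_correct_old()
    for phase in range(1, 6):
        pairs = [(t.id, d.id) for t in targets[:phase] for d in distractors[:phase]]
        streak = 0
        sessions_in_phase = 0
        while streak < needed:
            if sessions_in_phase >= max_sessions_per_phase:
                raise SimulationTruncatedError(
                    f"{rat_id}: phase {phase} did not reach criterion within "
                    f"{max_sessions_per_phase} sessions"
                )
            n_correct = 0
            for _ in range(session_trials):
                tid, did = pairs[rng.integers(len(pairs))]
                side = _side(rng)
                correct = _choose(rng, model, p_corr, side)
                n_correct += correct
                rows.append(
                    {
                        "rat_id": rat_id,
                        "round": 1,
                        "session_index": session_index,
                        "phase_or_protocol": f"phase{phase}",
                        "block_index": 0,
                        "target_id": tid,
                        "distractor_id": did,
                        "target_side": side,
                        "chose_target": correct,
                        "rewarded": correct,
                        "correction_trial": False,
                        "pair_novelty": "old",
                    }
                )
                # correction trials: repeat the failed pair and side until correct
                tries = 0
                while not correct and tries < 1000:
                    correct = _choose(rng, model, p_corr, side)
                    tries += 1
                    rows.append(
                        {
                            "rat_id": rat_id,
                            "round": 1,
                            "session_index": session_index,
                            "phase_or_protocol": f"phase{phase}",
                            "block_index": 0,
                            "target_id": tid,
                            "distractor_id": did,
                            "target_side": side,
                            "chose_target": correct,
                            "rewarded": correct,
                            "correction_trial": True,
                            "pair_novelty": "old",
                        }
                    )
            accuracy = n_correct / session_trials
            streak = streak + 1 if accuracy >= threshold else 0
            session_index += 1
            sessions_in_phase += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# testing


def simulate_testing(
    stimulus_set: StimulusSet,
    model: DecisionModel,
    seed: int | np.random.Generator = 0,
    rat_id: str = "rat1",
    protocol_order: Sequence[str] = ("test1", "test2", "test3"),
    session_trials: int = 100,
    old_fraction: float = 1.0 / 3.0,
    random_reward_p: float = 0.8,
) -> pd.DataFrame:
    """Simulate the two rounds of the three test protocols.

    Each round runs three blocks; each block runs one 100-trial session
    per protocol in ``protocol_order``.  A third of trials present a
    trained pair under real reward; the rest present a new pair (one of
    the 10 test targets against a distractor from the protocol's two CF
    groups) rewarded with probability ``random_reward_p`` independent of
    the choice.
    """
    if set(protocol_order) != set(PROTOCOL_GROUPS):
        raise ValueError(f"protocol_order must permute {sorted(PROTOCOL_GROUPS)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fsm = stimulus_set.feature_strength_matrix()
    delta = {
        (t, d): float(fsm.values[i, j])
        for i, t in enumerate(fsm.row_labels)
        for j, d in enumerate(fsm.col_labels)
    }
    old_pairs = [
        (t.id, d.id)
        for t in stimulus_set.train_targets
        for d in stimulus_set.train_distractors
    ]
    targets = list(stimulus_set.test_targets)
    by_group: dict[int, list] = {}
    for d in stimulus_set.test_distractors:
        by_group.setdefault(int(d.cf_group), []).append(d)

    p_old = model.p_correct_old()
    rows: list[dict] = []
    session_index = 0
    for rnd in (1, 2):
        for block in (1, 2, 3):
            for protocol in protocol_order:
                pool = by_group[PROTOCOL_GROUPS[protocol][0]] + by_group[
                    PROTOCOL_GROUPS[protocol][1]
                ]
                for _ in range(session_trials):
                    side = _side(rng)
                    if rng.random() < old_fraction:
                        tid, did = old_pairs[rng.integers(len(old_pairs))]
                        correct = _choose(rng, model, p_old, side)
                        rewarded = correct
                        novelty = "old"
                    else:
                        tid = targets[rng.integers(len(targets))].id
                        did = pool[rng.integers(len(pool))].id
                        if (tid, did) not in delta:
                            raise ValueError(f"missing feature profile for pair ({tid}, {did})")
                        correct = _choose(rng, model, model.p_correct_new(delta[(tid, did)]), side)
                        rewarded = bool(rng.random() < random_reward_p)
                        novelty = "new"
                    rows.append(
                        {
                            "rat_id": rat_id,
                            "round": rnd,
                            "session_index": session_index,
                            "phase_or_protocol": protocol,
                            "block_index": block,
                            "target_id": tid,
                            "distractor_id": did,
                            "target_side": side,
                            "chose_target": correct,
                            "rewarded": rewarded,
                            "correction_trial": False,
                            "pair_novelty": novelty,
                        }
                    )
                session_index += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_experiment(
    stimulus_set: StimulusSet,
    model: DecisionModel,
    n_rats: int = 8,
    criterion: str = "strict",
    seed: int = 0,
    include_training: bool = True,
    session_trials: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: training plus testing for ``n_rats`` animals.

    The second half of the cohort receives the training stimuli in
    reversed order, and test-protocol order rotates across animals
    (counterbalancing).  A ``stim_order`` column records the group.
    Returns ``(training_trials, testing_trials)``; the former is empty
    when ``include_training`` is False.
    """
    ss = np.random.SeedSequence(seed)
    orders = [
        ("test1", "test2", "test3"),
        ("test2", "test3", "test1"),
        ("test3", "test1", "test2"),
    ]
    train_frames, test_frames = [], []
    for i, child in enumerate(ss.spawn(n_rats)):
        rng = np.random.default_rng(child)
        rat = f"rat{i + 1}"
        reversed_order = i >= (n_rats + 1) // 2
        group = "reversed" if reversed_order else "forward"
        if include_training:
            tr = simulate_training(
                stimulus_set,
                model,
                criterion=criterion,
                seed=rng,
                rat_id=rat,
                session_trials=session_trials,
                reverse_order=reversed_order,
            )
            tr["stim_order"] = group
            train_frames.append(tr)
        te = simulate_testing(
            stimulus_set,
            model,
            seed=rng,
            rat_id=rat,
            protocol_order=orders[i % 3],
            session_trials=session_trials,
        )
        te["stim_order"] = group
        test_frames.append(te)
    empty = pd.DataFrame(columns=TRIAL_COLUMNS + ["stim_order"])
    train = pd.concat(train_frames, ignore_index=True) if train_frames else empty
    test = pd.concat(test_frames, ignore_index=True)
    return train, test


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass(frozen=True)
class RecoveredParams:
    sensitivity: float
    lapse: float
    log_likelihood: float
    n_trials: int
    converged: bool


def recover_parameters(
    trials: pd.DataFrame,
    model_matrix: ModelMatrix,
    fix_sensitivity: float | None = None,
) -> RecoveredParams:
    """Maximum-likelihood fit of (sensitivity, lapse) to new-pair trials.

    Correction trials and old pairs are excluded.  ``fix_sensitivity``
    pins the slope (useful for likelihood-ratio tests against a flat
    psychometric function).  Emits :class:`BoundaryEstimateWarning` if
    an estimate lands on its bound (typical of degenerate all-correct /
    all-incorrect data).
    """
    mask = (trials["pair_novelty"] == "new") & (~trials["correction_trial"])
    sub = trials.loc[mask]
    if sub.empty:
        raise ValueError("no new-pair non-correction trials to fit")
    lut = {
        (t, d): model_matrix.values[i, j]
        for i, t in enumerate(model_matrix.row_labels)
        for j, d in enumerate(model_matrix.col_labels)
    }
    try:
        delta = np.array([lut[(t, d)] for t, d in zip(sub["target_id"], sub["distractor_id"])])
    except KeyError as exc:
        raise ValueError(f"pair missing from model matrix: {exc}") from exc
    correct = sub["chose_target"].to_numpy(dtype=float)

    def nll(theta: np.ndarray) -> float:
        if fix_sensitivity is None:
            k, lam = theta
        else:
            k, lam = fix_sensitivity, theta[0]
        p = lam / 2.0 + (1.0 - lam) * expit(k * delta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(correct * np.log(p) + (1 - correct) * np.log1p(-p)))

    if fix_sensitivity is None:
        starts = [(1.0, 0.2), (4.0, 0.2), (10.0, 0.5), (0.5, 0.05)]
        bounds = [(0.0, 200.0), (0.0, 0.999)]
        x0s = [np.array(s) for s in starts]
    else:
        bounds = [(0.0, 0.999)]
        x0s = [np.array([lam]) for lam in (0.05, 0.3, 0.7)]
    best = None
    for x0 in x0s:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if fix_sensitivity is None:
        k_hat, lam_hat = float(best.x[0]), float(best.x[1])
    else:
        k_hat, lam_hat = float(fix_sensitivity), float(best.x[0])
    if fix_sensitivity is None and (k_hat >= 199.0 or lam_hat >= 0.998):
        warnings.warn(
            "parameter estimate at boundary; data may be degenerate",
            BoundaryEstimateWarning,
            stacklevel=2,
        )
    return RecoveredParams(
        sensitivity=k_hat,
        lapse=lam_hat,
        log_likelihood=-float(best.fun),
        n_trials=int(len(sub)),
        converged=bool(best.success),
    )
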