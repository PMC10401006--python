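"""Outcome measures of the experiment.

Diagnostic error is the absolute distance (percentage points) between a
clinician's risk estimate and the vignette's correct value.  Accuracy is
the negated error min-max normalized to [0, 1]; with the default fixed
bounds (negated error spans [-100, 0]) this is exactly 1 - error/100, so
the percent forms satisfy accuracy + error = 100.

Aggregation follows the trial-level strategy: each trial's clinician mean
is one observation, which respects the statistical non-independence of
networked clinicians.  Quartile/decile bins are assigned from round-1
accuracy only, pooled across trials within a condition by default
(per-trial binning is available), with bin 1 = least accurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import TrialRecord
from .errors import (
    InvalidBoundsError,
    InvalidInputError,
    InvalidParametersError,
    MissingDataError,
)

logger = logging.getLogger(__name__)

#: Fixed normalization bounds on negated error: -100 (worst) to 0 (perfect).
DEFAULT_BOUNDS = (-100.0, 0.0)


def absolute_error(estimate: float, truth: float) -> float:
    """|estimate - truth| in percentage points; both inputs must be in [0, 100]."""
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if np.any((est < 0) | (est > 100)) or np.any((tru < 0) | (tru > 100)):
        raise InvalidInputError("estimate and truth must lie in [0, 100]")
    out = np.abs(est - tru)
    return float(out) if out.ndim == 0 else out


def accuracy_from_error(error, bounds=DEFAULT_BOUNDS, as_percent: bool = False):
    """Min-max-normalized negated error.

    accuracy = (-error - min_negerr) / (max_negerr - min_negerr); with the
    default fixed bounds this reduces to 1 - error/100 (strictly decreasing
    in error).  ``as_percent`` rescales to 0-100.
    """
    lo, hi = bounds
    if hi == lo:
        raise InvalidBoundsError("degenerate normalization bounds (max == min)")
    err = np.asarray(error, dtype=float)
    acc = (-err - lo) / (hi - lo)
    if as_percent:
        acc = 100.0 * acc
    return float(acc) if acc.ndim == 0 else acc


def observed_bounds(errors: Iterable[float]) -> tuple:
    """Per-dataset (min, max) of negated error, for observed-min/max mode."""
    neg = -np.asarray(list(errors), dtype=float)
    lo, hi = float(neg.min()), float(neg.max())
    if lo == hi:
        raise InvalidBoundsError("all errors identical; observed bounds degenerate")
    return lo, hi


def build_panel(trials: Iterable[TrialRecord], bounds=DEFAULT_BOUNDS) -> pd.DataFrame:
    """Long per-response frame with error and accuracy columns attached."""
    rows = []
    for t in trials:
        cfg = t.config
        for r in t.responses:
            rows.append(
                (
                    t.trial_id,
                    cfg.vignette_id,
                    cfg.condition,
                    r.clinician_id,
                    r.round,
                    r.estimate,
                    r.recommendation,
                    cfg.truth,
                    cfg.correct_option,
                )
            )
    panel = pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "vignette_id",
            "condition",
            "clinician_id",
            "round",
            "estimate",
            "recommendation",
            "truth",
            "correct_option",
        ],
    )
    panel["error"] = np.abs(panel["estimate"] - panel["truth"])
    panel["accuracy"] = accuracy_from_error(panel["error"].to_numpy(), bounds)
    panel["correct"] = panel["recommendation"] == panel["correct_option"]
    return panel


def trial_mean_accuracy(trial: TrialRecord, round: int, bounds=DEFAULT_BOUNDS) -> float:
    """Mean clinician accuracy for one trial at one round (trial-level unit)."""
    est = trial.estimates(round)
    if len(est) < trial.config.n_clinicians:
        raise MissingDataError(
            f"trial {trial.trial_id} round {round}: "
            f"{len(est)}/{trial.config.n_clinicians} responses"
        )
    errors = np.abs(np.array(list(est.values())) - trial.config.truth)
    return float(np.mean(accuracy_from_error(errors, bounds)))


def correct_rate(trial: TrialRecord, round: int) -> float:
    """Fraction of clinicians choosing the correct option at one round."""
    recs = trial.recommendations(round)
    vals = np.array([r == trial.config.correct_option for r in recs.values()])
    return float(vals.mean())


@dataclass(frozen=True)
class SwitchRates:
    """Recommendation switch rates between round 1 and the final round.

    Rates are NaN (undefined) when the eligible set is empty, never zero.
    """

    incorrect_to_correct: float
    correct_to_incorrect: float
    n_initially_incorrect: int
    n_initially_correct: int


def switch_rate(trial: TrialRecord, final_round: Optional[int] = None) -> SwitchRates:
    """Fraction switching to/from the correct recommendation (rounds 1 -> final)."""
    final_round = final_round or trial.config.n_rounds
    first = trial.recommendations(1)
    last = trial.recommendations(final_round)
    if not first or not last:
        raise MissingDataError(f"trial {trial.trial_id}: missing rounds for switch rate")
    correct = trial.config.correct_option
    init_wrong = [c for c, r in first.items() if r != correct]
    init_right = [c for c, r in first.items() if r == correct]
    i2c = (
        float(np.mean([last[c] == correct for c in init_wrong]))
        if init_wrong
        else float("nan")
    )
    c2i = (
        float(np.mean([last[c] != correct for c in init_right]))
        if init_right
        else float("nan")
    )
    return SwitchRates(i2c, c2i, len(init_wrong), len(init_right))


def clinician_table(
    panel: pd.DataFrame,
    n_quartiles: int = 4,
    n_deciles: Optional[int] = 10,
    binning: str = "pooled",
) -> pd.DataFrame:
    """Per-clinician wide table: round-1/final accuracy, revision, bins.

    Clinicians missing any round are excluded (completers-only analysis);
    the exclusion count is logged and kept in ``frame.attrs['n_excluded']``.
    ``n_deciles=None`` skips the decile column (small panels).
    """
    last_round = int(panel["round"].max())
    n_rounds = panel["round"].nunique()
    counts = panel.groupby(["trial_id", "clinician_id"])["round"].nunique()
    complete = counts[counts == n_rounds].index
    n_excluded = int(len(counts) - len(complete))
    if n_excluded:
        logger.info("excluding %d clinicians with incomplete rounds", n_excluded)

    wide_rows = []
    sub = panel.set_index(["trial_id", "clinician_id"]).loc[complete].reset_index()
    piv_est = sub.pivot_table(
        index=["trial_id", "clinician_id"], columns="round", values="estimate"
    )
    piv_acc = sub.pivot_table(
        index=["trial_id", "clinician_id"], columns="round", values="accuracy"
    )
    piv_cor = sub.pivot_table(
        index=["trial_id", "clinician_id"], columns="round", values="correct"
    )
    meta = (
        sub.groupby(["trial_id", "clinician_id"])[["condition", "vignette_id"]]
        .first()
    )
    out = meta.copy()
    for r in (1, 2, last_round):
        out[f"acc_r{r}"] = piv_acc[r]
        out[f"est_r{r}"] = piv_est[r]
        out[f"correct_r{r}"] = piv_cor[r].astype(bool)
    out["revision_magnitude"] = np.abs(out[f"est_r{last_round}"] - out["est_r1"])
    out["acc_change_12"] = 100.0 * (out["acc_r2"] - out["acc_r1"])
    out[f"acc_change_1{last_round}"] = 100.0 * (
        out[f"acc_r{last_round}"] - out["acc_r1"]
    )
    out = out.reset_index()

    out["quartile"] = bin_by_initial_accuracy(out, n_quartiles, binning=binning)
    if n_deciles is not None:
        out["decile"] = bin_by_initial_accuracy(out, n_deciles, binning=binning)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["final_round"] = last_round
    return out


def bin_by_initial_accuracy(
    clin: pd.DataFrame, k: int, binning: str = "pooled"
) -> pd.Series:
    """Equal-frequency bins on round-1 accuracy; bin 1 = least accurate.

    ``pooled`` bins within condition across that condition's trials;
    ``per-trial`` bins within each trial.  Ties are broken by the stable key
    (accuracy, trial_id, clinician_id); bin sizes differ by at most one,
    with larger bins at the low-accuracy end.
    """
    if binning not in ("pooled", "per-trial"):
        raise InvalidParametersError(f"unknown binning scope {binning!r}")
    group_cols = ["condition"] if binning == "pooled" else ["trial_id"]
    bins = pd.Series(index=clin.index, dtype=int)
    for _, grp in clin.groupby(group_cols, sort=False):
        n = len(grp)
        if n < k:
            raise InvalidParametersError(
                f"{n} clinicians cannot fill {k} bins in group"
            )
        order = grp.sort_values(
            ["acc_r1", "trial_id", "clinician_id"], kind="mergesort"
        ).index
        assigned = np.arange(n) * k // n + 1
        bins.loc[order] = assigned
    return bins


def change_in_accuracy(
    panel: pd.DataFrame,
    from_round: int,
    to_round: int,
    mask: Optional[pd.Series] = None,
) -> float:
    """Mean accuracy at ``to_round`` minus mean at ``from_round``, in pp (0-100)."""
    rounds = set(panel["round"].unique())
    if from_round not in rounds or to_round not in rounds:
        raise InvalidParametersError(
            f"rounds ({from_round}, {to_round}) not both present in panel"
        )
    sub = panel if mask is None else panel[mask]
    a_from = sub.loc[sub["round"] == from_round, "accuracy"].mean()
    a_to = sub.loc[sub["round"] == to_round, "accuracy"].mean()
    return float(100.0 * (a_to - a_from))


def revision_magnitude(panel: pd.DataFrame, trial_id: str, clinician_id: str) -> float:
    """|final-round estimate - round-1 estimate| for one clinician, in pp."""
    sub = panel[
        (panel["trial_id"] == trial_id) & (panel["clinician_id"] == clinician_id)
    ]
    last = int(panel["round"].max())
    first = sub.loc[sub["round"] == 1, "estimate"]
    final = sub.loc[sub["round"] == last, "estimate"]
    if first.empty or final.empty:
        raise MissingDataError(
            f"clinician {clinician_id} in trial {trial_id} missing round 1 or {last}"
        )
    return float(abs(final.iloc[0] - first.iloc[0]))


def trial_summaries(trials: Iterable[TrialRecord], bounds=DEFAULT_BOUNDS) -> pd.DataFrame:
    """One row per trial: per-round mean accuracy and correct rate, plus changes."""
    rows = []
    for t in trials:
        n_rounds = t.config.n_rounds
        accs = {r: trial_mean_accuracy(t, r, bounds) for r in range(1, n_rounds + 1)}
        rates = {r: correct_rate(t, r) for r in range(1, n_rounds + 1)}
        row = {
            "trial_id": t.trial_id,
            "vignette_id": t.config.vignette_id,
            "condition": t.config.condition,
        }
        for r in range(1, n_rounds + 1):
            row[f"mean_accuracy_r{r}"] = accs[r]
            row[f"correct_rate_r{r}"] = rates[r]
        row["acc_change_12"] = 100.0 * (accs[2] - accs[1])
        row[f"acc_change_1{n_rounds}"] = 100.0 * (accs[n_rounds] - accs[1])
        row[f"rate_change_1{n_rounds}"] = rates[n_rounds] - rates[1]
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate_quartile_summary(
    trials: Iterable[TrialRecord],
    binning: str = "pooled",
    bounds=DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Condition x quartile summary of accuracy and correct-rate outcomes.

    One row per condition and initial-accuracy quartile (1 = least accurate),
    averaged across trials at the individual level.  Accuracy columns are on
    the 0-100 percent scale; treatment-rate columns are fractions.
    """
    panel = build_panel(trials, bounds)
    clin = clinician_table(panel, n_deciles=None, binning=binning)
    final = clin.attrs["final_round"]
    rows = []
    for (cond, q), grp in clin.groupby(["condition", "quartile"], sort=True):
        rows.append(
            {
                "condition": cond,
                "quartile": int(q),
                "initial_accuracy": 100.0 * grp["acc_r1"].mean(),
                "final_accuracy": 100.0 * grp[f"acc_r{final}"].mean(),
                "accuracy_change": grp[f"acc_change_1{final}"].mean(),
                "initial_correct_rate": grp["correct_r1"].mean(),
                "final_correct_rate": grp[f"correct_r{final}"].mean(),
                "correct_rate_change": (
                    grp[f"correct_r{final}"].mean() - grp["correct_r1"].mean()
                ),
            }
        )
    return pd.DataFrame(rows)
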