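"""Behavioural measures: ratio-dependent accuracy, Weber fraction, congruency cost.

The approximate number system predicts that two-alternative numerosity
comparison accuracy depends only on the numerical ratio of the two sets.
The standard single-parameter model assumes log-Gaussian internal noise:

    p_correct(r) = Phi( |ln r| / (sqrt(2) * w) )

with r = min(N)/max(N) in (0, 1), Phi the standard normal CDF and w the
Weber fraction. Smaller w means finer number acuity. The fit is weighted
least squares of observed accuracies against this curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


def weber_accuracy(ratio, w: float, lapse: float = 0.0):
    """Predicted comparison accuracy at numerical ratio(s) ``ratio``."""
    r = np.asarray(ratio, dtype=float)
    p = stats.norm.cdf(np.abs(np.log(r)) / (np.sqrt(2.0) * w))
    return 0.5 * lapse + (1.0 - lapse) * p


def _trial_fields(trial):
    """Accept (pair, correct) tuples or objcts with .pair/.correct."""
    if isinstance(trial, tuple):
        pair, correct = trial
    else:
        pair, correct = trial.pair, trial.correct
    return pair, bool(correct)


def accuracy_by_ratio(trials: Sequence) -> pd.DataFrame:
    """Partition trials by exact numerosity ratio and tally accuracy.

    Returns a DataFrame with columns ``ratio`` (float in (0,1)), ``ratio_label``
    ("p:q"), ``n_trials`` and ``accuracy``, sorted by descending ratio
    (easiest last).
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    counts: dict[tuple[int, int], list[int]] = {}
    for trial in trials:
        pair, correct = _trial_fields(trial)
        n_lo = min(pair.left.numerosity, pair.right.numerosity)
        n_hi = max(pair.left.numerosity, pair.right.numerosity)
        f = Fraction(n_lo, n_hi)
        key = (f.numerator, f.denominator)
        cell = counts.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(correct)
    rows = [
        {
            "ratio": p / q,
            "ratio_label": f"{p}:{q}",
            "n_trials": n,
            "accuracy": k / n,
        }
        for (p, q), (n, k) in counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("ratio", ascending=True)
        .reset_index(drop=True)
    )


@dataclass
class PsychometricResult:
    """Weber-fraction fit of an accuracy-by-ratio table."""

    w: float
    table: pd.DataFrame
    residuals: np.ndarray
    rmse: float
    reliable: bool
    condition: str = ""
    lapse: float = 0.0

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("Weber fraction must be positive")


def fit_weber(acc_table: pd.DataFrame, lapse: float = 0.0,
              condition: str = "", min_ratios: int = 3,
              min_trials: int = 20) -> PsychometricResult:
    """Least-squares Weber-fraction estimate from an accuracy table.

    Requires at least ``min_ratios`` distinct ratios with ``min_trials``
    trials each. Degenerate tables (all cells at chance, or all at ceiling)
    are fitted anyway but flagged ``reliable=False``.
    """
    table = acc_table.sort_values("ratio").reset_index(drop=True)
    if len(table) < min_ratios:
        raise ValueError(f"need >= {min_ratios} distinct ratios, got {len(table)}")
    if (table["n_trials"] < min_trials).any():
        raise ValueError(f"every ratio needs >= {min_trials} trials")
    r = table["ratio"].to_numpy()
    acc = table["accuracy"].to_numpy()
    n = table["n_trials"].to_numpy().astype(float)
    if not ((r > 0) & (r < 1)).all():
        raise ValueError("ratios must lie in (0, 1)")

    def loss(log_w):
        pred = weber_accuracy(r, np.exp(log_w), lapse)
        return float(np.sum(n * (acc - pred) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-4), np.log(10.0)),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    w = float(np.exp(res.x))
    residuals = acc - weber_accuracy(r, w, lapse)
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    at_chance = np.all(np.abs(acc - 0.5) < 0.05)
    at_ceiling = np.all(acc > 0.995)
    at_bound = w < 2e-4 or w > 9.0
    return PsychometricResult(
        w=w, table=table, residuals=residuals, rmse=rmse,
        reliable=not (at_chance or at_ceiling or at_bound),
        condition=condition, lapse=lapse,
    )


def learning_trajectory(trajectory, bank, train_pairs, eval_pairs,
                        feedback_fraction: float = 0.25,
                        readout_seed: int = 0, readout_kwargs: dict | None = None
                        ) -> pd.DataFrame:
    """Weber fraction at every unsupervised-learning checkpoint.

    The read-out is retrained from scratch with an *identical* protocol
    (same pairs, same feedback subset, same update order, via a fixed seed)
    at every checkpoint, so acuity differences reflect only the generative
    layer. Evaluation pairs must be disjoint from the read-out training
    pairs; no leakage check is possible here, keep them separate upstream.
    """
    from . import network as net

    readout_kwargs = readout_kwargs or {}
    rows = []
    for epoch, layer in zip(trajectory.epochs, trajectory.snapshots):
        head = net.train_readout(
            train_pairs, bank, layer, feedback_fraction=feedback_fraction,
            rng=np.random.default_rng(readout_seed), **readout_kwargs,
        )
        outcomes = net.evaluate_pairs(eval_pairs, bank, layer, head)
        result = fit_weber(accuracy_by_ratio(outcomes),
                           condition=f"epoch={epoch}")
        rows.append({"epoch": epoch, "w": result.w,
                     "reliable": result.reliable, "rmse": result.rmse})
    return pd.DataFrame(rows)


def congruency_cost(results_by_condition: Mapping[str, pd.DataFrame]
                    ) -> pd.DataFrame:
    """Per-ratio accuracy difference congruent minus incongruent.

    ``results_by_condition`` maps the labels ``"congruent"`` and
    ``"incongruent"`` to accuracy-by-ratio tables on matched ratio sets.
    Positive cost = the incongruent cues hurt performance.
    """
    try:
        cong = results_by_condition["congruent"]
        incong = results_by_condition["incongruent"]
    except KeyError as err:
        raise ValueError(f"missing condition {err}") from err
    c = cong.set_index("ratio_label")
    i = incong.set_index("ratio_label")
    missing = sorted(set(c.index) ^ set(i.index))
    if missing:
        raise ValueError(f"unmatched ratio cells: {missing}")
    out = pd.DataFrame(
        {
            "ratio": c["ratio"],
            "acc_congruent": c["accuracy"],
            "acc_incongruent": i["accuracy"],
            "n_congruent": c["n_trials"],
            "n_incongruent": i["n_trials"],
        }
    )
    out["cost"] = out["acc_congruent"] - out["acc_incongruent"]
    out = out.sort_values("ratio").reset_index(names="ratio_label")
    out.attrs["mean_cost"] = float(out["cost"].mean())
    return out
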