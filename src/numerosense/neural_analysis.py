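"""Neuron-level coding analyses of the generative hidden layer.

Two complementary characterizations of how hidden units respond to probe
images crossing numerosity with cumulative area:

* **summation coding** (numerosity-sensitive units): per-unit ordinary least
  squares of activation on standardized log2(numerosity) and log2(area);
  a unit is sensitive when the numerosity coefficient is large, the area
  coefficient small and the fit good. The coefficient sign separates
  monotonically increasing from decreasing profiles.
* **numerosity selectivity**: per-unit two-factor ANOVA (numerosity x area,
  with interaction); a unit is selective when the numerosity main effect is
  significant while the area main effect (and interaction) are not. Its
  preferred numerosity is the level with maximal mean activation, and
  tuning curves of units preferring the same level are pooled after
  per-unit min-max normalization.

Selection is per-neuron with no correction across neurons, matching the
convention of the electrophysiology analyses these procedures mirror.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: summation-coding thresholds: |B_numerosity| >= THETA_N, |B_area| <= THETA_A,
#: R^2 >= THETA_R2 (standardized coefficients).
THETA_N = 0.10
THETA_A = 0.05
THETA_R2 = 0.50
ANOVA_ALPHA = 0.01


@dataclass
class TuningTable:
    """Per-neuron responses over a complete numerosity x area factorial probe.

    Holds both per-image activations (for regression / ANOVA) and the cell
    means over the factorial grid (for tuning curves).
    """

    activations: np.ndarray       # (M images, U neurons), in [0, 1]
    numerosity: np.ndarray        # (M,) int
    area: np.ndarray              # (M,) int
    n_levels: np.ndarray          # sorted unique numerosities
    a_levels: np.ndarray          # sorted unique areas
    cell_mean: np.ndarray         # (U, nN, nA)
    cell_var: np.ndarray          # (U, nN, nA)
    cell_count: np.ndarray        # (nN, nA)

    @classmethod
    def from_responses(cls, activations, numerosity, area,
                       min_per_cell: int = 1) -> "TuningTable":
        acts = np.atleast_2d(np.asarray(activations, dtype=float))
        num = np.asarray(numerosity, dtype=int)
        ar = np.asarray(area, dtype=int)
        if len(acts) != len(num) or len(num) != len(ar):
            raise ValueError("activations, numerosity and area lengths differ")
        n_levels = np.unique(num)
        a_levels = np.unique(ar)
        u = acts.shape[1]
        cell_mean = np.empty((u, len(n_levels), len(a_levels)))
        cell_var = np.empty_like(cell_mean)
        cell_count = np.zeros((len(n_levels), len(a_levels)), dtype=int)
        missing = []
        for i, nl in enumerate(n_levels):
            for j, al in enumerate(a_levels):
                sel = (num == nl) & (ar == al)
                cnt = int(sel.sum())
                cell_count[i, j] = cnt
                if cnt < min_per_cell:
                    missing.append((int(nl), int(al)))
                    continue
                cell_mean[:, i, j] = acts[sel].mean(axis=0)
                cell_var[:, i, j] = acts[sel].var(axis=0)
        if missing:
            raise ValueError(
                f"incomplete factorial design; missing/short cells "
                f"(numerosity, area): {missing}"
            )
        return cls(acts, num, ar, n_levels, a_levels,
                   cell_mean, cell_var, cell_count)

    @property
    def n_neurons(self) -> int:
        return self.activations.shape[1]

    def marginal_curves(self) -> np.ndarray:
        """(U, nN) mean activation per numerosity, averaged over area levels."""
        return self.cell_mean.mean(axis=2)


def probe_corpus(n_levels, a_levels, replicates: int,
                 rng: np.random.Generator, side: int = 30) -> list:
    """Factorial probe stimulus set: every (numerosity, area) cell replicated."""
    from .stimuli import generate_image

    images = []
    for n in n_levels:
        for a in a_levels:
            if a < n:
                raise ValueError(f"area level {a} infeasible for numerosity {n}")
            for _ in range(replicates):
                images.append(generate_image(n, area_target=int(a), rng=rng,
                                             side=side))
    return images


def build_tuning_table(bank, layer, probe_images,
                       min_per_cell: int = 20) -> TuningTable:
    """Encode a factorial probe set and tabulate per-neuron cell statistics."""
    from .network import corpus_features

    acts = layer.hidden_probs(corpus_features(probe_images, bank))
    num = np.array([im.numerosity for im in probe_images])
    area = np.array([im.cumulative_area for im in probe_images])
    return TuningTable.from_responses(acts, num, area,
                                      min_per_cell=min_per_cell)


# ---------------------------------------------------------------------------
# summation coding (regression)
# ---------------------------------------------------------------------------

def _zscore(x):
    s = x.std()
    if s == 0:
        raise ValueError("zero-variance regressor")
    return (x - x.mean()) / s


def classify_summation(table: TuningTable, theta_n: float = THETA_N,
                       theta_a: float = THETA_A,
                       theta_r2: float = THETA_R2) -> pd.DataFrame:
    """Per-neuron standardized regression on log2(N) and log2(A).

    Returns one row per neuron with columns ``b_numerosity``, ``b_area``,
    ``r2``, ``coding_class`` in {"sensitive+", "sensitive-", "none"} and a
    ``flag`` column ("zero_variance" for flat units).
    """
    x = np.column_stack([
        _zscore(np.log2(table.numerosity.astype(float))),
        _zscore(np.log2(table.area.astype(float))),
    ])
    y = table.activations
    y_mean = y.mean(axis=0)
    y_std = y.std(axis=0)
    flat = y_std < 1e-12
    y_z = np.zeros_like(y)
    y_z[:, ~flat] = (y[:, ~flat] - y_mean[~flat]) / y_std[~flat]

    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, y_z, rcond=None)
    pred = design @ coef
    sse = ((y_z - pred) ** 2).sum(axis=0)
    sst = (y_z ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse / sst
    r2[flat] = 0.0

    b_num, b_area = coef[1], coef[2]
    sensitive = (~flat & (np.abs(b_num) >= theta_n)
                 & (np.abs(b_area) <= theta_a) & (r2 >= theta_r2))
    coding = np.where(
        sensitive, np.where(b_num > 0, "sensitive+", "sensitive-"), "none"
    )
    return pd.DataFrame(
        {
            "neuron": np.arange(table.n_neurons),
            "b_numerosity": b_num,
            "b_area": b_area,
            "r2": r2,
            "coding_class": coding,
            "flag": np.where(flat, "zero_variance", ""),
        }
    )


# ---------------------------------------------------------------------------
# numerosity selectivity (two-factor ANOVA)
# ---------------------------------------------------------------------------

def two_way_anova(table: TuningTable) -> pd.DataFrame:
    """Balanced two-factor ANOVA with interaction, vectorized over neurons.

    Requires a balanced design with >= 2 replicates per cell (otherwise
    there is no error term). Returns F statistics and p values for the
    numerosity main effect, the area main effect and their interaction.
    """
    counts = table.cell_count
    r = int(counts.flat[0])
    if (counts != r).any():
        raise ValueError("two-way ANOVA requires a balanced design")
    if r < 2:
        raise ValueError("need >= 2 replicates per cell for the F denominator")
    a, b = len(table.n_levels), len(table.a_levels)
    y = table.activations                       # (M, U)
    cm = table.cell_mean                        # (U, a, b)
    grand = cm.mean(axis=(1, 2))                # (U,)
    row = cm.mean(axis=2)                       # (U, a)
    col = cm.mean(axis=1)                       # (U, b)

    ss_n = r * b * ((row - grand[:, None]) ** 2).sum(axis=1)
    ss_a = r * a * ((col - grand[:, None]) ** 2).sum(axis=1)
    inter = cm - row[:, :, None] - col[:, None, :] + grand[:, None, None]
    ss_int = r * (inter ** 2).sum(axis=(1, 2))
    # within-cell error from the stored per-cell variances (biased, * n)
    ss_err = (table.cell_var * r).sum(axis=(1, 2))

    df_n, df_a = a - 1, b - 1
    df_int = df_n * df_a
    df_err = a * b * (r - 1)
    mse = ss_err / df_err
    with np.errstate(invalid="ignore", divide="ignore"):
        f_n = (ss_n / df_n) / mse
        f_a = (ss_a / df_a) / mse
        f_int = (ss_int / df_int) / mse
    out = pd.DataFrame(
        {
            "neuron": np.arange(table.n_neurons),
            "F_numerosity": f_n,
            "F_area": f_a,
            "F_interaction": f_int,
            "p_numerosity": stats.f.sf(f_n, df_n, df_err),
            "p_area": stats.f.sf(f_a, df_a, df_err),
            "p_interaction": stats.f.sf(f_int, df_int, df_err),
        }
    )
    # (near-)constant units have no meaningful F ratio
    degenerate = (~np.isfinite(mse)) | (y.std(axis=0) < 1e-12)
    for colname in ("p_numerosity", "p_area", "p_interaction"):
        out.loc[degenerate, colname] = np.nan
    return out


def classify_selective(table: TuningTable,
                       alpha: float = ANOVA_ALPHA) -> pd.DataFrame:
    """Numerosity-selective units by two-factor ANOVA.

    Selective = significant numerosity main effect at ``alpha``, while both
    the area main effect and the interaction are non-significant. The
    preferred numerosity is the level maximizing the area-averaged tuning
    curve.
    """
    anova = two_way_anova(table)
    curves = table.marginal_curves()
    preferred = table.n_levels[np.argmax(curves, axis=1)]
    valid = anova[["p_numerosity", "p_area", "p_interaction"]].notna().all(axis=1)
    selective = (
        valid
        & (anova["p_numerosity"] < alpha)
        & (anova["p_area"] >= alpha)
        & (anova["p_interaction"] >= alpha)
    )
    out = anova.copy()
    out["coding_class"] = np.where(selective, "selective", "none")
    out["preferred_numerosity"] = np.where(selective, preferred, -1)
    out["flag"] = np.where(valid, "", "zero_variance")
    return out


# ---------------------------------------------------------------------------
# tuning-curve pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledCurves:
    """Average tuning curves of numerosity-selective units."""

    by_preferred: pd.DataFrame    # preferred, numerosity, response, n_neurons
    by_distance: pd.DataFrame     # distance, response, n_neurons
    preferred_counts: pd.Series   # preferred level -> unit count
    n_selective: int


def pool_tuning_curves(profiles: pd.DataFrame,
                       table: TuningTable) -> PooledCurves:
    """Pool normalized tuning curves by preferred numerosity.

    Each selective unit's area-averaged curve is min-max normalized to
    [0, 1] (so it peaks at exactly 1.0 at its preferred level), then curves
    sharing a preferred numerosity are averaged. A second view aligns every
    curve on the numerical distance from its preferred level.
    """
    sel = profiles[profiles["coding_class"] == "selective"]
    counts = pd.Series(0, index=pd.Index(table.n_levels, name="preferred"),
                       dtype=int)
    if len(sel) == 0:
        warnings.warn("no numerosity-selective units: empty pooled curves")
        empty_p = pd.DataFrame(
            columns=["preferred", "numerosity", "response", "n_neurons"]
        )
        empty_d = pd.DataFrame(columns=["distance", "response", "n_neurons"])
        return PooledCurves(empty_p, empty_d, counts, 0)

    curves = table.marginal_curves()[sel["neuron"].to_numpy()]
    lo = curves.min(axis=1, keepdims=True)
    hi = curves.max(axis=1, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    norm = (curves - lo) / span
    preferred = sel["preferred_numerosity"].to_numpy()

    rows_p, rows_d = [], {}
    for level in table.n_levels:
        mask = preferred == level
        if not mask.any():
            continue
        mean_curve = norm[mask].mean(axis=0)
        for nl, resp in zip(table.n_levels, mean_curve):
            rows_p.append({"preferred": int(level), "numerosity": int(nl),
                           "response": float(resp), "n_neurons": int(mask.sum())})
    for curve, pref in zip(norm, preferred):
        for nl, resp in zip(table.n_levels, curve):
            d = int(nl - pref)
            rows_d.setdefault(d, []).append(resp)
    by_distance = pd.DataFrame(
        [
            {"distance": d, "response": float(np.mean(v)),
             "n_neurons": len(v)}
            for d, v in sorted(rows_d.items())
        ]
    )
    counts.update(pd.Series(preferred).value_counts())
    return PooledCurves(pd.DataFrame(rows_p), by_distance,
                        counts.astype(int), int(len(sel)))
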