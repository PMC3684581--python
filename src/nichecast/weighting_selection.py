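"""Prevalence weighting and forward variable selection.

When only presences are known, models are fitted against a large random
background sample. Left unweighted, 380 presences against 100,000
background rows would amount to assuming a species prevalence of ~0.004.
The weighting scheme here fixes the *class totals*: presence rows share a
total weight of ``phi`` and background rows a total of ``1 - phi``, so the
ratio of class totals is ``phi / (1 - phi)`` — at ``phi = 0.5`` the two
classes weigh the same, at 0.9 the presence class weighs 9 times more.

Forward selection adds one predictor at a time (highest explained
deviance first), drops candidates correlated at ``|r| >= r_max`` with
anything already selected, and stops when the new term is not significant
or AIC does not decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import CellId, EnvGrid, PresenceSet

logger = logging.getLogger("nichecast")

__all__ = [
    "class_weights",
    "effective_prevalence",
    "TrainingTable",
    "build_training_table",
    "SelectionResult",
    "forward_select",
]


def class_weights(n_presence: int, n_background: int, phi: float) -> tuple[float, float]:
    """Per-row weights making class totals proportional to prevalence.

    Returns ``(w_presence, w_background)`` with ``w_p = phi / n_presence``
    and ``w_b = (1 - phi) / n_background``; all weights sum to 1 and the
    class-total ratio is ``phi / (1 - phi)``.
    """
    if n_presence < 1 or n_background < 1:
        raise ValueError("row counts must be >= 1")
    if not (0.0 < phi < 1.0):
        raise ValueError(f"phi must be in (0, 1), got {phi}")
    return phi / n_presence, (1.0 - phi) / n_background


def effective_prevalence(n_presence: int, n_background: int) -> float:
    """Prevalence implied by equal row weights.

    Implemented as ``n_presence / n_background``, the printed arithmetic
    for the motivating example (380/100,000 ≈ 0.004); at that scale this
    is indistinguishable from the proportion ``n_p / (n_p + n_b)``.
    """
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    return n_presence / n_background


# ---------------------------------------------------------------------------
# Training table
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Presence + background rows with labels, weights and predictors."""

    cells: list[CellId]
    y: np.ndarray          # 1 presence, 0 background
    w: np.ndarray          # strictly positive row weights
    X: pd.DataFrame        # predictor values, one column per variable
    phi: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.cells)
        if not (len(self.y) == len(self.w) == len(self.X) == n):
            raise ValueError("cells, y, w and X must have equal length")
        if (self.w <= 0).any():
            raise ValueError("weights must be strictly positive")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("predictors must be finite")
        if not (self.y == 1).any() or not (self.y == 0).any():
            raise ValueError("table needs at least one row of each label")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def n_presence(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_background(self) -> int:
        return int((self.y == 0).sum())

    def subset_variables(self, variables: Sequence[str]) -> "TrainingTable":
        return TrainingTable(
            cells=self.cells, y=self.y, w=self.w,
            X=self.X[list(variables)].copy(), phi=self.phi,
        )

    def normalized_weights(self) -> np.ndarray:
        """Weights rescaled to sum to the row count (AIC convention)."""
        return self.w * (len(self.w) / self.w.sum())


def build_training_table(
    grid: EnvGrid,
    presences: PresenceSet,
    background: Iterable[CellId],
    phi: float = 0.5,
    variables: Sequence[str] | None = None,
) -> TrainingTable:
    """Assemble the weighted presence/background table from a grid."""
    pres = presences.sorted_cells()
    bg = sorted(background)
    w_p, w_b = class_weights(len(pres), len(bg), phi)
    cells = pres + bg
    y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(bg), dtype=int)])
    w = np.concatenate([np.full(len(pres), w_p), np.full(len(bg), w_b)])
    X = grid.values_at(cells, variables).reset_index(drop=True)
    return TrainingTable(cells=cells, y=y, w=w, X=X, phi=phi)


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    selected: list[str]
    trace: pd.DataFrame  # columns: step, variable, deviance, aic, p_value, removed_candidates, accepted

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)


def _fit_step(table: TrainingTable, variables: Sequence[str], fit_family: str):
    """Deviance/AIC/df of one weighted fit of the selection family."""
    from .sdm_engines import _forward_fit_stats

    return _forward_fit_stats(table, variables, fit_family)


def forward_select(
    table: TrainingTable,
    candidates: Sequence[str],
    r_max: float = 0.8,
    alpha: float = 0.05,
    fit_family: str = "gam_k3",
) -> SelectionResult:
    """Forward stepwise predictor selection with a collinearity filter.

    Step 1 keeps the single predictor with the highest explained deviance.
    Before every later step, candidates with ``|Pearson r| >= r_max``
    against any selected predictor are removed (correlations computed over
    the table's rows, unweighted). Addition stops when the chi-square test
    on the deviance drop of the new term exceeds ``alpha`` or AIC does not
    decrease. Ties on deviance resolve to the earlier candidate. The trace
    records every step, including the rejected final candidate and the
    collinear removals.
    """
    candidates = [c for c in candidates if c in table.X.columns]
    if not candidates:
        raise ValueError("no valid candidates")

    selected: list[str] = []
    remaining = list(candidates)
    dev_prev, aic_prev, _ = _fit_step(table, [], fit_family)  # null model
    rows = []
    step = 0
    while remaining:
        step += 1
        # collinearity filter against the already selected variables
        removed = []
        if selected:
            keep = []
            for c in remaining:
                r = max(
                    abs(float(np.corrcoef(table.X[c], table.X[s])[0, 1]))
                    for s in selected
                )
                (removed if r >= r_max else keep).append(c)
            remaining = keep
            if removed:
                logger.info("forward_select step %d: removed collinear %s", step, removed)
        if not remaining:
            rows.append({
                "step": step, "variable": "", "deviance": np.nan, "aic": np.nan,
                "p_value": np.nan, "removed_candidates": ";".join(removed),
                "accepted": False,
            })
            break

        best_var, best = None, None
        for c in remaining:  # first-in-order wins ties (strict improvement required)
            dev, aic, df = _fit_step(table, selected + [c], fit_family)
            if best is None or dev < best[0]:
                best_var, best = c, (dev, aic, df)
        dev_new, aic_new, df_new = best
        df_old = _fit_step(table, selected, fit_family)[2] if selected else 1
        d_df = df_new - df_old  # params added by the new term
        drop = max(dev_prev - dev_new, 0.0)
        p_value = float(stats.chi2.sf(drop, d_df)) if d_df > 0 else 1.0
        accepted = (p_value <= alpha) and (aic_new < aic_prev)
        rows.append({
            "step": step, "variable": best_var, "deviance": dev_new, "aic": aic_new,
            "p_value": p_value, "removed_candidates": ";".join(removed),
            "accepted": accepted,
        })
        if not accepted:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        dev_prev, aic_prev = dev_new, aic_new

    trace = pd.DataFrame(
        rows, columns=["step", "variable", "deviance", "aic", "p_value",
                       "removed_candidates", "accepted"],
    )
    return SelectionResult(selected=selected, trace=trace)
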