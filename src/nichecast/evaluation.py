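"""Classification performance under the repeated-split protocol.

Models are scored with AUC (threshold-free), plus sensitivity and
specificity at the MST threshold — the cut-off maximizing their sum. The
cross-validation protocol fits on 80% of the presences together with a
random pseudo-absence sample of the same size, and tests on the remaining
20% of presences with a disjoint pseudo-absence sample, repeated 10
times; keeping the pseudo-absence samples small avoids the AUC inflation
a huge background sample would induce. Families whose mean AUC falls
below 0.9 are dropped before any consensus is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .geo_io import CellId, EnvGrid, PresenceSet
from .sdm_engines import MahalanobisModel, SuitabilityModel
from .weighting_selection import TrainingTable, build_training_table

logger = logging.getLogger("nichecast")

__all__ = ["auc", "mst_threshold", "EvalReport", "cv_evaluate", "retain_models"]


def auc(scores_presence: Sequence[float], scores_absence: Sequence[float]) -> float:
    """Mann–Whitney concordance: P(presence outscores absence) + ½·P(tie)."""
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if len(sp) == 0 or len(sa) == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(len(sp)), np.zeros(len(sa))])
    return float(roc_auc_score(y, np.concatenate([sp, sa])))


def mst_threshold(scores: Sequence[float], labels: Sequence[int]
                  ) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Scans 0, the midpoints of consecutive sorted unique scores, and 1
    (cells scoring >= threshold are classified presences); ties resolve to
    the lowest threshold. Returns ``(threshold, sensitivity,
    specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_p, n_a = int((labels == 1).sum()), int((labels == 0).sum())
    if n_p == 0 or n_a == 0:
        raise ValueError("need both labels to compute sensitivity and specificity")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best = None
    for t in candidates:
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / n_p)
        spec = float((~pred & (labels == 0)).sum() / n_a)
        if best is None or sens + spec > best[1] + best[2] + 1e-15:
            best = (float(t), sens, spec)
    return best


@dataclass
class EvalReport:
    """Per-repeat and summary classification performance of one model."""

    family: str
    phi: float
    repeats: pd.DataFrame  # columns: repeat, auc, sensitivity, specificity, threshold

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def mean_auc(self) -> float:
        return float(self.repeats["auc"].mean())

    def summary(self) -> dict[str, float]:
        """Mean ± sample SD of each index across repeats."""
        out = {"family": self.family, "phi": self.phi, "n_repeats": self.n_repeats}
        for col in ("auc", "sensitivity", "specificity", "threshold"):
            out[f"{col}_mean"] = float(self.repeats[col].mean())
            out[f"{col}_sd"] = float(self.repeats[col].std(ddof=1))
        return out

    def summary_row(self) -> dict[str, str]:
        """Table-style 'mean±sd' strings (AUC / Sensitivity / Specificity)."""
        s = self.summary()
        return {
            "model": self.family, "prevalence": f"{self.phi:.0%}",
            "AUC": f"{s['auc_mean']:.3f}±{s['auc_sd']:.3f}",
            "Sensitivity": f"{s['sensitivity_mean']:.3f}±{s['sensitivity_sd']:.3f}",
            "Specificity": f"{s['specificity_mean']:.3f}±{s['specificity_sd']:.3f}",
        }


def draw_split(presence_cells: Sequence[CellId], grid: EnvGrid,
               train_frac: float, rng: np.random.Generator
               ) -> tuple[list[CellId], list[CellId], list[CellId], list[CellId]]:
    """One repeat's (train presences, test presences, train pseudo-absences,
    test pseudo-absences).

    Pseudo-absences are random valid cells excluding every presence cell;
    the train and test draws are disjoint, each the size of its presence
    split.
    """
    cells = sorted(presence_cells)
    perm = rng.permutation(len(cells))
    n_train = int(round(train_frac * len(cells)))
    train_p = [cells[i] for i in perm[:n_train]]
    test_p = [cells[i] for i in perm[n_train:]]

    pool = sorted(set(map(tuple, grid.valid_cells())) - set(cells))
    need = len(train_p) + len(test_p)
    if need > len(pool):
        raise ValueError("not enough non-presence cells for pseudo-absence draws")
    idx = rng.choice(len(pool), size=need, replace=False)
    pa = [pool[i] for i in idx]
    return train_p, test_p, pa[: len(train_p)], pa[len(train_p):]


def cv_evaluate(fit_fn: Callable[[TrainingTable], SuitabilityModel],
                presences: PresenceSet, grid: EnvGrid, phi: float = 0.5,
                n_repeats: int = 10, train_frac: float = 0.8,
                seed: int = 0, family: str = "model",
                variables: Sequence[str] | None = None) -> EvalReport:
    """Repeated-split evaluation of one model family.

    Each repeat splits the presences ``train_frac``/rest, fits
    ``fit_fn`` on the training presences plus an equal-sized pseudo-absence
    sample (weighted to prevalence ``phi``), and computes AUC and the MST
    triple on the held-out presences against a disjoint pseudo-absence
    sample. Deterministic under ``seed``.
    """
    if len(presences) < 10:
        raise ValueError("need at least 10 presences for the 80/20 protocol")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        train_p, test_p, train_a, test_a = draw_split(
            presences.cells, grid, train_frac, rng
        )
        table = build_training_table(
            grid, PresenceSet(frozenset(train_p), presences.taxon),
            train_a, phi=phi, variables=variables,
        )
        model = fit_fn(table)
        X_test = grid.values_at(test_p + test_a, variables=list(model.variables) or None)
        scores = model.predict_rows(X_test.reset_index(drop=True))
        if isinstance(model, MahalanobisModel):
            scores = np.clip(scores, 0.0, 1.0)
        labels = np.array([1] * len(test_p) + [0] * len(test_a))
        t, sens, spec = mst_threshold(scores, labels)
        rows.append({
            "repeat": rep, "auc": auc(scores[labels == 1], scores[labels == 0]),
            "sensitivity": sens, "specificity": spec, "threshold": t,
        })
    return EvalReport(family=family, phi=phi, repeats=pd.DataFrame(rows))


def retain_models(reports: Mapping[str, "EvalReport | float"],
                  auc_min: float = 0.9) -> list[str]:
    """Families whose mean AUC is >= ``auc_min`` (inclusive), input order.

    Warns when nothing qualifies; the caller is expected to fall back to
    the single best model in that case.
    """
    means = {
        fam: (r.mean_auc if isinstance(r, EvalReport) else float(r))
        for fam, r in reports.items()
    }
    kept = [fam for fam, m in means.items() if m >= auc_min]
    if not kept:
        logger.warning(
            "no family reaches AUC >= %.3f (best: %s); falling back to best single model",
            auc_min, max(means, key=means.get) if means else None,
        )
    return kept
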