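"""Outlying Mean Index (OMI) niche analysis.

The OMI framework asks how far a taxon's *niche position* — the mean
environmental conditions of its occupied cells — sits from the average
available environment, measured in SD units of a reference cell sample.
The ordination diagonalizes the weighted outer-product matrix of the
taxa's marginality vectors, ``M = Σ_k w_k m_k m_kᵀ`` with weights
proportional to presence counts, yielding axes that best separate the
taxa's occupancies along combinations of environmental gradients. Per
taxon and axis we report niche position (mean score), niche breadth (SD
of scores), the OMI statistic ``‖m‖²``, a one-tailed bootstrap test of
specialization against random cell sets of the same size, and Welch
t-tests comparing two taxa along the main axis and each raw gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import CellId, EnvGrid, PresenceSet

__all__ = [
    "standardize_env", "marginality", "omi_ordination", "omi_statistic",
    "specialization_test", "clade_comparison", "OMIResult", "run_omi",
]


def standardize_env(
    grid: EnvGrid,
    reference_cells: Iterable[CellId] | None = None,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Z-table over all valid cells, centered/scaled by a reference sample.

    The reference cell set (default: every valid cell) plays the role of
    the globally sampled background: its per-variable mean and SD define
    the standardization, so marginality is expressed in SD units of the
    available environment. A constant variable is an error.
    """
    X = grid.table(variables)
    ref = X.loc[list(reference_cells)] if reference_cells is not None else X
    mean, sd = ref.mean(), ref.std(ddof=1)
    bad = sd[sd <= 0].index.tolist()
    if bad:
        raise ValueError(f"constant variables cannot be standardized: {bad}")
    return (X - mean) / sd


def marginality(Z: pd.DataFrame, presence_cells: Iterable[CellId]) -> np.ndarray:
    """Niche-position vector: mean of Z rows over the occupied cells."""
    cells = sorted(set(presence_cells))
    if not cells:
        raise ValueError("presence set is empty")
    return Z.loc[cells].to_numpy(dtype=float).mean(axis=0)


def omi_statistic(Z: pd.DataFrame, presence_cells: Iterable[CellId]) -> float:
    """OMI: squared distance of the niche position from the reference mean."""
    m = marginality(Z, presence_cells)
    return float(m @ m)


def omi_ordination(
    Z: pd.DataFrame, presence_sets: Sequence[PresenceSet]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigen-decomposition of the weighted marginality outer-product matrix.

    Taxon weights are proportional to presence counts. Returns
    ``(axes, eigenvalues)``: axes is a variables × axes frame of unit-norm
    loading vectors in descending eigenvalue order; the eigenvalue sum
    equals ``Σ_k w_k ‖m_k‖²`` (trace identity). Cell scores on an axis are
    ``Z · axis``.
    """
    if not presence_sets:
        raise ValueError("need at least one taxon")
    counts = np.array([len(p) for p in presence_sets], dtype=float)
    w = counts / counts.sum()
    V = Z.shape[1]
    M = np.zeros((V, V))
    for wk, pset in zip(w, presence_sets):
        m = marginality(Z, pset.cells)
        M += wk * np.outer(m, m)
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    axes = pd.DataFrame(
        eigvec[:, order], index=Z.columns,
        columns=[f"OMI{i + 1}" for i in range(V)],
    )
    return axes, eigval


def specialization_test(
    Z: pd.DataFrame,
    presence_cells: Iterable[CellId],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    reference_cells: Iterable[CellId] | None = None,
) -> float:
    """One-tailed bootstrap test of niche specialization.

    Compares the observed OMI statistic with that of ``n_boot`` random
    cell sets of the same size drawn (without replacement) from the
    reference cells; ``p = (1 + #{boot ≥ observed}) / (n_boot + 1)``.
    The test is exact under exchangeability because the null draw matches
    the bootstrap draw.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = sorted(set(presence_cells))
    observed = omi_statistic(Z, cells)
    ref = Z.loc[list(reference_cells)] if reference_cells is not None else Z
    vals = ref.to_numpy(dtype=float)
    n, R = len(cells), len(vals)
    if n > R:
        raise ValueError("presence set larger than reference pool")
    count = 0
    for _ in range(n_boot):
        idx = rng.choice(R, size=n, replace=False)
        m = vals[idx].mean(axis=0)
        if m @ m >= observed:
            count += 1
    return (1 + count) / (n_boot + 1)


def _welch_one_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Welch t and one-sided p in the direction of the observed ordering."""
    t, p_two = stats.ttest_ind(a, b, equal_var=False)
    direction = "greater" if np.mean(a) >= np.mean(b) else "less"
    p_one = p_two / 2.0 if t != 0 else 0.5
    return float(t), float(p_one), direction


def clade_comparison(
    Z: pd.DataFrame,
    axes: pd.DataFrame,
    cells_1: Iterable[CellId],
    cells_2: Iterable[CellId],
    axis: str = "OMI1",
) -> pd.DataFrame:
    """Welch t-tests between two taxa along the main axis and each gradient.

    One row per tested gradient (the leading ordination axis first, then
    every raw environmental variable), with the two group means, the
    Welch t statistic, the one-sided p in the direction of the observed
    ordering, and that direction ("greater" = taxon 1 mean higher).
    """
    c1, c2 = sorted(set(cells_1)), sorted(set(cells_2))
    Z1, Z2 = Z.loc[c1], Z.loc[c2]
    rows = []
    s1 = Z1.to_numpy() @ axes[axis].to_numpy()
    s2 = Z2.to_numpy() @ axes[axis].to_numpy()
    for name, a, b in [(axis, s1, s2)] + [
        (v, Z1[v].to_numpy(), Z2[v].to_numpy()) for v in Z.columns
    ]:
        t, p, direction = _welch_one_sided(a, b)
        rows.append({
            "gradient": name, "mean_1": float(np.mean(a)), "mean_2": float(np.mean(b)),
            "t": t, "p_one_sided": p, "direction_taxon1": direction,
        })
    return pd.DataFrame(rows)


@dataclass
class OMIResult:
    """Full output of the OMI analysis for a set of taxa."""

    axes: pd.DataFrame                 # loadings, variables × axes (unit-norm)
    eigenvalues: np.ndarray
    pct_variance: np.ndarray           # % of eigenvalue total per axis
    niche_position: pd.DataFrame       # taxa × axes (mean axis score)
    niche_breadth: pd.DataFrame        # taxa × axes (SD of axis scores)
    omi_stat: dict[str, float]
    specialization_p: dict[str, float]
    pairwise: pd.DataFrame | None = None

    def to_csvs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        loadings = self.axes.copy()
        loadings.insert(0, "variable", loadings.index)
        eig = pd.DataFrame({
            "axis": self.axes.columns, "eigenvalue": self.eigenvalues,
            "pct_variance": self.pct_variance,
        })
        taxa = pd.DataFrame({
            "taxon": list(self.omi_stat),
            "omi": [self.omi_stat[t] for t in self.omi_stat],
            "specialization_p": [self.specialization_p[t] for t in self.omi_stat],
        })
        for name, df in [("omi_loadings", loadings), ("omi_eigenvalues", eig),
                         ("omi_taxa", taxa),
                         ("omi_niche_position", self.niche_position),
                         ("omi_niche_breadth", self.niche_breadth)]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=name.endswith(("position", "breadth")))
            written.append(p)
        if self.pairwise is not None:
            p = outdir / "omi_pairwise_tests.csv"
            self.pairwise.to_csv(p, index=False)
            written.append(p)
        return written


def run_omi(
    grid: EnvGrid,
    presence_sets: Sequence[PresenceSet],
    reference_cells: Iterable[CellId] | None = None,
    variables: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> OMIResult:
    """End-to-end OMI analysis: ordination, positions/breadths, tests."""
    Z = standardize_env(grid, reference_cells, variables)
    axes, eigval = omi_ordination(Z, presence_sets)
    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)

    rng = np.random.default_rng(seed)
    pos, brd, omi, spec = {}, {}, {}, {}
    for pset in presence_sets:
        cells = pset.sorted_cells()
        scores = Z.loc[cells].to_numpy() @ axes.to_numpy()
        pos[pset.taxon] = scores.mean(axis=0)
        brd[pset.taxon] = scores.std(axis=0, ddof=1)
        omi[pset.taxon] = omi_statistic(Z, cells)
        spec[pset.taxon] = specialization_test(
            Z, cells, n_boot=n_boot, seed=rng, reference_cells=reference_cells
        )

    pairwise = None
    if len(presence_sets) == 2:
        pairwise = clade_comparison(
            Z, axes, presence_sets[0].cells, presence_sets[1].cells
        )
    taxa = [p.taxon for p in presence_sets]
    return OMIResult(
        axes=axes, eigenvalues=eigval, pct_variance=pct,
        niche_position=pd.DataFrame(pos, index=axes.columns).T,
        niche_breadth=pd.DataFrame(brd, index=axes.columns).T,
        omi_stat=omi, specialization_p=spec, pairwise=pairwise,
    )
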