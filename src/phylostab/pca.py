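"""PCA of the support matrix and per-strategy dispersion (stability) scoring.

The decomposition is an eigendecomposition of the column covariance
(denominator n-1) after centering and, by default, unit-variance scaling
with zero-variance columns dropped. Component signs are fixed by making
the largest-magnitude loading positive, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import SupportTree

__all__ = [
    "PCAResult",
    "StabilityReport",
    "run_pca",
    "variable_contributions",
    "group_dispersion",
    "total_tree_length",
    "summarize_tree_stats",
    "plot_scores",
]


@dataclass
class PCAResult:
    """Eigenvalues, per-tree scores, orthonormal loadings and contributions.

    ``column_ids`` names the retained variables (after dropping
    zero-variance columns under standardization); ``dropped`` lists the
    removed ones. ``contributions[j, k] = 100 * loadings[j, k]**2``.
    """

    eigenvalues: np.ndarray          # (r,) descending, >= 0
    scores: np.ndarray               # (n, r)
    loadings: np.ndarray             # (p_retained, r) orthonormal columns
    contributions: np.ndarray        # (p_retained, r) percentages
    explained: np.ndarray            # (r,) fractions summing to 1
    column_ids: list[str]
    dropped: list[str]
    row_ids: list[str]
    standardized: bool

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _matrix_parts(m):
    """Accept a BipartitionSupportMatrix or a bare 2-D array."""
    if hasattr(m, "values") and hasattr(m, "column_encodings"):
        return (
            np.asarray(m.values, dtype=float),
            m.column_encodings(),
            list(m.tree_ids),
        )
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValidationError("PCA input must be 2-D")
    return (
        x,
        [f"var{j}" for j in range(x.shape[1])],
        [f"row{i}" for i in range(x.shape[0])],
    )


def run_pca(m, standardize: bool = True) -> PCAResult:
    """Principal components of the (trees x splits) support matrix.

    Columns are mean-centered; with ``standardize`` they are scaled to
    unit variance and zero-variance columns are dropped (and reported).
    Eigenvalues equal the variances of the scores with denominator n-1.
    """
    x, column_ids, row_ids = _matrix_parts(m)
    n, p = x.shape
    if n < 2:
        raise DataError(f"PCA needs >=2 rows, got {n}")
    if np.isnan(x).any():
        raise DataError(
            "matrix contains missing entries (NaN); impute or rebuild with a fill"
        )

    dropped: list[str] = []
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0.0
        dropped = [c for c, k in zip(column_ids, keep) if not k]
        if not keep.any():
            raise DataError("all columns have zero variance under standardize")
        x = x[:, keep]
        column_ids = [c for c, k in zip(column_ids, keep) if k]
        x = (x - x.mean(axis=0)) / sd[keep]
    else:
        x = x - x.mean(axis=0)

    cov = x.T @ x / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # reproducible sign: largest-|loading| entry of each component positive
    for k in range(eigvecs.shape[1]):
        jmax = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[jmax, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]

    scores = x @ eigvecs
    contributions = 100.0 * eigvecs**2
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)

    return PCAResult(
        eigenvalues=eigvals,
        scores=scores,
        loadings=eigvecs,
        contributions=contributions,
        explained=explained,
        column_ids=column_ids,
        dropped=dropped,
        row_ids=row_ids,
        standardized=standardize,
    )


def variable_contributions(p: PCAResult, k: int) -> list[tuple[str, float]]:
    """Variables ranked by contribution (percent) to component ``k``.

    Descending by contribution; ties broken by original column order.
    """
    if not 0 <= k < p.n_components:
        raise ValidationError(
            f"component {k} out of range (have {p.n_components})"
        )
    ranked = sorted(
        enumerate(p.contributions[:, k]), key=lambda jv: (-jv[1], jv[0])
    )
    return [(p.column_ids[j], float(v)) for j, v in ranked]


@dataclass
class StabilityReport:
    """Per-strategy dispersion in the leading K-component subspace.

    Dispersion is the mean pairwise Euclidean distance among a strategy's
    score points (0 for a single tree); smaller = denser = more stable.
    Rank 1 is the most stable strategy.
    """

    dispersion: dict
    rank: dict
    centroids: dict
    n_components: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for strat in sorted(self.dispersion, key=lambda s: self.rank[s]):
            row = {
                "strategy": strat,
                "rank": self.rank[strat],
                "dispersion": self.dispersion[strat],
            }
            for k, c in enumerate(self.centroids[strat], 1):
                row[f"centroid_pc{k}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


def group_dispersion(
    p: PCAResult, strategies: Sequence[str], n_components: int = 2
) -> StabilityReport:
    """Score per-strategy tightness of the PCA score clouds."""
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > p.n_components:
        raise ValidationError(
            f"n_components {n_components} exceeds available {p.n_components}"
        )
    if len(strategies) != p.scores.shape[0]:
        raise ValidationError("one strategy label required per score row")

    pts = p.scores[:, :n_components]
    by_strategy: dict[str, list[int]] = {}
    for i, s in enumerate(strategies):
        by_strategy.setdefault(s, []).append(i)

    dispersion: dict[str, float] = {}
    centroids: dict[str, tuple] = {}
    for strat, idx in by_strategy.items():
        sub = pts[idx]
        centroids[strat] = tuple(float(c) for c in sub.mean(axis=0))
        if len(idx) < 2:
            dispersion[strat] = 0.0
        else:
            dists = [
                float(np.linalg.norm(sub[a] - sub[b]))
                for a, b in combinations(range(len(idx)), 2)
            ]
            dispersion[strat] = float(np.mean(dists))

    ordered = sorted(dispersion, key=lambda s: (dispersion[s], s))
    rank = {s: r for r, s in enumerate(ordered, 1)}
    return StabilityReport(
        dispersion=dispersion,
        rank=rank,
        centroids=centroids,
        n_components=n_components,
    )


def total_tree_length(tree: SupportTree, strict: bool = True) -> float:
    """Sum of all branch lengths of the tree."""
    total = 0.0
    for node in tree.postorder():
        if node is tree.root:
            continue
        if node.length is None:
            if strict:
                raise DataError(
                    "edge without a branch length "
                    f"(above {'leaf ' + repr(node.label) if node.is_leaf() else 'an internal node'})"
                )
            continue
        if node.length < 0:
            raise DataError(f"negative branch length {node.length}")
        total += node.length
    return total


def summarize_tree_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-strategy summary of per-tree statistics.

    ``stats`` needs a ``strategy`` column plus one or more numeric columns
    (e.g. ``total_length``, ``log_likelihood``). Output has one row per
    (strategy, metric) with n, mean, min, q1, median, q3, max; quartiles
    use linear interpolation.
    """
    if "strategy" not in stats.columns:
        raise ValidationError("stats table needs a 'strategy' column")
    metrics = [c for c in stats.columns if c != "strategy"]
    if not metrics:
        raise ValidationError("stats table needs at least one metric column")
    rows = []
    for strat, grp in stats.groupby("strategy", sort=True):
        for metric in metrics:
            v = grp[metric].dropna().to_numpy(dtype=float)
            if v.size == 0:
                continue
            rows.append(
                {
                    "strategy": strat,
                    "metric": metric,
                    "n": int(v.size),
                    "mean": float(v.mean()),
                    "min": float(v.min()),
                    "q1": float(np.quantile(v, 0.25)),
                    "median": float(np.quantile(v, 0.5)),
                    "q3": float(np.quantile(v, 0.75)),
                    "max": float(v.max()),
                }
            )
    return pd.DataFrame(
        rows, columns=["strategy", "metric", "n", "mean", "min", "q1", "median", "q3", "max"]
    )


def plot_scores(p: PCAResult, strategies: Sequence[str], path, top: int = 20):
    """PC1/PC2 scatter colored by strategy with the top contributing splits."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if p.n_components < 2:
        raise ValidationError("need >=2 components to plot PC1/PC2")
    fig, (ax, ax2) = plt.subplots(
        1, 2, figsize=(11, 5), gridspec_kw={"width_ratios": [2, 1]}
    )
    for strat in sorted(set(strategies)):
        idx = [i for i, s in enumerate(strategies) if s == strat]
        ax.scatter(p.scores[idx, 0], p.scores[idx, 1], label=strat, alpha=0.8)
    ax.set_xlabel(f"PC1 ({100 * p.explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * p.explained[1]:.1f}%)")
    ax.legend(fontsize=8)

    combined = p.contributions[:, 0] * p.explained[0] + (
        p.contributions[:, 1] * p.explained[1]
    )
    order = np.argsort(-combined)[:top]
    labels = [p.column_ids[j][:40] for j in order]
    ax2.barh(range(len(order))[::-1], combined[order])
    ax2.set_yticks(range(len(order))[::-1], labels, fontsize=6)
    ax2.set_xlabel("contribution to PC1+PC2 (weighted %)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
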