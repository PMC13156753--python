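"""Precision-recall benchmarking at extreme class imbalance.

Implements the evaluation machinery used to compare presentation
predictors: the precision-recall curve, non-interpolated average precision
(AP), PPV@top-k, and a resampling protocol that repeatedly draws a fixed
number of positives together with ``neg_ratio`` times as many negatives
(default 1000:1, matching the prevalence of eluted ligands among
combinatorially possible peptides of their source proteins) and reports the
across-iteration mean and standard deviation of each metric plus a
pointwise precision band on a fixed recall grid.

Tie handling is canonical everywhere: items are ranked by score descending
with ties broken by stable input index.  Breaking ties by label would
inflate every metric and is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: PPV is reported at these depths by default.
DEFAULT_PPV_KS = (10, 20, 50, 100)

#: Number of recall grid points for the pointwise precision band.
PR_GRID_POINTS = 200


@dataclass(frozen=True)
class ScoredSet:
    """Predictor scores aligned with 0/1 presentation labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class BenchmarkResult:
    """Resampled benchmark summary: AP and PPV@k means with spread."""

    ap_mean: float
    ap_sd: float
    ppv_at_k: dict[int, tuple[float, float]]
    pr_recall_grid: np.ndarray
    pr_precision_mean: np.ndarray
    pr_precision_sd: np.ndarray
    n_iterations: int
    n_pos: int
    neg_ratio: int
    seed: int
    n_neg_per_iteration: int = 0
    ap_values: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "ap_mean": self.ap_mean,
            "ap_sd": self.ap_sd,
            "ppv_at_k": {str(k): {"mean": m, "sd": s} for k, (m, s) in self.ppv_at_k.items()},
            "pr_band": {
                "recall": self.pr_recall_grid.tolist(),
                "precision_mean": self.pr_precision_mean.tolist(),
                "precision_sd": self.pr_precision_sd.tolist(),
            },
            "n_iterations": self.n_iterations,
            "n_pos": self.n_pos,
            "neg_ratio": self.neg_ratio,
            "seed": self.seed,
            "n_neg_per_iteration": self.n_neg_per_iteration,
        }


def _canonical_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorting by score descending, ties by stable input index."""
    return np.argsort(-scores, kind="stable")


def average_precision(scored: ScoredSet, interpolated: bool = False) -> float:
    """Non-interpolated average precision.

    The mean, over positives in canonical descending-score order, of the
    precision at each positive's rank — the standard proxy for the area
    under the precision-recall curve.  With ``interpolated=True`` each
    precision is replaced by the maximum precision at any equal-or-deeper
    recall before averaging.
    """
    labels = scored.labels[_canonical_order(scored.scores)]
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    ranks = np.arange(1, len(labels) + 1)
    cum_pos = np.cumsum(labels)
    precision_at_rank = cum_pos / ranks
    prec_at_positives = precision_at_rank[labels == 1]
    if interpolated:
        prec_at_positives = np.maximum.accumulate(prec_at_positives[::-1])[::-1]
    return float(prec_at_positives.mean())


def ppv_at_k(scored: ScoredSet, k: int) -> float:
    """Fraction of positives among the k top-scoring items (canonical ties).

    The expected wet-lab hit rate when synthesizing and testing the k
    highest-ranked pHLA pairs.
    """
    if not 1 <= k <= len(scored):
        raise ValueError(f"k={k} outside 1..{len(scored)}")
    order = _canonical_order(scored.scores)
    return float(scored.labels[order[:k]].mean())


def pr_curve(scored: ScoredSet) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every rank in canonical order."""
    labels = scored.labels[_canonical_order(scored.scores)]
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("PR curve requires at least one positive and one negative")
    cum_pos = np.cumsum(labels)
    ranks = np.arange(1, len(labels) + 1)
    return cum_pos / n_pos, cum_pos / ranks


def _precision_on_grid(scored: ScoredSet, grid: np.ndarray) -> np.ndarray:
    recall, precision = pr_curve(scored)
    # precision at the first rank attaining each grid recall level
    idx = np.searchsorted(recall, grid, side="left")
    idx = np.clip(idx, 0, len(precision) - 1)
    return precision[idx]


def resample_benchmark(
    pool: ScoredSet,
    n_iter: int = 100,
    n_pos: int = 500,
    neg_ratio: int = 1000,
    seed: int = 0,
    ppv_ks: tuple[int, ...] = DEFAULT_PPV_KS,
) -> BenchmarkResult:
    """Resampled PR benchmark at fixed class imbalance.

    Each iteration draws ``n_pos`` positives and ``n_pos * neg_ratio``
    negatives from the pool uniformly without replacement (within the
    iteration), then computes AP and PPV at each k.  Means and standard
    deviations are across iterations; the PR band is the pointwise mean
    +/- sd of precision on a fixed recall grid.  Deterministic for a fixed
    seed.
    """
    pos_idx = np.flatnonzero(pool.labels == 1)
    neg_idx = np.flatnonzero(pool.labels == 0)
    n_neg = n_pos * neg_ratio
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        raise ValueError(
            f"pool too small: need {n_pos} positives and {n_neg} negatives, "
            f"have {len(pos_idx)} and {len(neg_idx)}"
        )
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, PR_GRID_POINTS)
    aps = np.empty(n_iter)
    ppvs = {k: np.empty(n_iter) for k in ppv_ks}
    band = np.empty((n_iter, PR_GRID_POINTS))
    neg_drawn = 0
    for it in range(n_iter):
        take_pos = rng.choice(pos_idx, size=n_pos, replace=False)
        take_neg = rng.choice(neg_idx, size=n_neg, replace=False)
        neg_drawn = len(take_neg)
        take = np.concatenate([take_pos, take_neg])
        sample = ScoredSet(pool.scores[take], pool.labels[take])
        aps[it] = average_precision(sample)
        for k in ppv_ks:
            ppvs[k][it] = ppv_at_k(sample, k)
        band[it] = _precision_on_grid(sample, grid)
    return BenchmarkResult(
        ap_mean=float(aps.mean()),
        ap_sd=float(aps.std(ddof=1)) if n_iter > 1 else 0.0,
        ppv_at_k={
            k: (float(v.mean()), float(v.std(ddof=1)) if n_iter > 1 else 0.0)
            for k, v in ppvs.items()
        },
        pr_recall_grid=grid,
        pr_precision_mean=band.mean(axis=0),
        pr_precision_sd=band.std(axis=0, ddof=1) if n_iter > 1 else np.zeros_like(grid),
        n_iterations=n_iter,
        n_pos=n_pos,
        neg_ratio=neg_ratio,
        seed=seed,
        n_neg_per_iteration=neg_drawn,
        ap_values=aps,
    )
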