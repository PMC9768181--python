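"""Global additive surrogate of per-individual effect estimates.

To propose new treatment-interaction terms, the per-individual lnOR (or
tau) estimates of a black-box ensemble are explained with a generalized
additive model with pairwise interactions: piecewise-constant shape
functions over binned features, fitted by cyclic boosting of depth-1
bin-mean updates, followed by greedy addition of the pairwise terms that
most reduce residual variance on the level grid.  Features ranked by mean
absolute contribution give the importance ordering a modeler scans for
heterogeneity dimensions missing from the current constrained model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model_spec import ModelSpec

__all__ = ["FeatureBinning", "SurrogateModel", "fit_surrogate", "rank_candidate_terms"]


@dataclass
class FeatureBinning:
    """How one feature is mapped to bin indices 0..n_bins-1."""

    kind: str  # "quantile" | "levels"
    edges: np.ndarray | None = None
    levels: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1 if self.kind == "quantile" else len(self.levels)

    def index(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        if self.kind == "quantile":
            return np.searchsorted(self.edges, v.astype(float), side="right")
        idx = np.searchsorted(self.levels, v)
        idx = np.clip(idx, 0, len(self.levels) - 1)
        return idx

    @classmethod
    def from_values(cls, values: np.ndarray, max_bins: int) -> "FeatureBinning":
        uniq = np.unique(values)
        if len(uniq) <= max_bins:
            return cls("levels", levels=uniq)
        qs = np.quantile(values.astype(float), np.linspace(0, 1, max_bins + 1)[1:-1])
        return cls("quantile", edges=np.unique(qs))


@dataclass
class SurrogateModel:
    """Fitted additive surrogate: intercept + shapes + pairwise grids.

    Shape functions are mean-centered over the training population, so the
    intercept is the training-target mean and each term's importance is the
    population mean of its absolute contribution.
    """

    intercept: float
    binnings: dict[str, FeatureBinning]
    shapes: dict[str, np.ndarray]
    pair_shapes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    importances: dict = field(default_factory=dict)
    fidelity_r2: float = 0.0

    def contributions(self, data: pd.DataFrame) -> dict:
        out = {}
        idx = {f: self.binnings[f].index(data[f].to_numpy()) for f in self.shapes}
        for f, shape in self.shapes.items():
            out[f] = shape[idx[f]]
        for (fa, fb), grid in self.pair_shapes.items():
            out[(fa, fb)] = grid[idx[fa], idx[fb]]
        return out

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(data), self.intercept)
        for contrib in self.contributions(data).values():
            pred = pred + contrib
        return pred


def _bin_means(idx: np.ndarray, resid: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=resid, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means


def fit_surrogate(
    target: np.ndarray,
    covariates: pd.DataFrame,
    n_pairs: int = 5,
    rounds: int = 500,
    learning_rate: float = 0.1,
    seed: int = 0,
    max_bins: int = 16,
) -> SurrogateModel:
    """Fit the additive surrogate by cyclic boosting.

    Each round sweeps the features in a fixed order, adding
    ``learning_rate`` times the per-bin residual mean to the feature's
    shape.  Pairwise terms are then added greedily: the pair with the
    largest residual-variance reduction on its level grid is fitted (full
    grid means) and removed from the candidate set, ``n_pairs`` times.
    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    y = np.asarray(target, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("target must be finite (drop capped individuals first)")
    if len(y) != len(covariates):
        raise ValueError("target/covariates length mismatch")
    feats = list(covariates.columns)
    binnings = {
        f: FeatureBinning.from_values(covariates[f].to_numpy(), max_bins)
        for f in feats
    }
    idx = {f: binnings[f].index(covariates[f].to_numpy()) for f in feats}
    n = len(y)

    intercept = float(y.mean())
    resid = y - intercept
    var0 = float(np.var(y))
    shapes = {f: np.zeros(binnings[f].n_bins) for f in feats}
    if var0 == 0.0:
        warnings.warn("constant target: R^2 undefined, reported as 0", stacklevel=2)
        return SurrogateModel(intercept, binnings, shapes,
                              importances={f: 0.0 for f in feats}, fidelity_r2=0.0)

    for _round in range(rounds):
        for f in feats:
            update = learning_rate * _bin_means(idx[f], resid, binnings[f].n_bins)
            shapes[f] += update
            resid -= update[idx[f]]

    pair_shapes: dict[tuple[str, str], np.ndarray] = {}
    candidates = list(combinations(feats, 2))
    for _ in range(min(n_pairs, len(candidates))):
        best, best_red, best_grid = None, 0.0, None
        for fa, fb in candidates:
            na, nb = binnings[fa].n_bins, binnings[fb].n_bins
            flat = idx[fa] * nb + idx[fb]
            counts = np.bincount(flat, minlength=na * nb)
            sums = np.bincount(flat, weights=resid, minlength=na * nb)
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            reduction = float((counts * means * means).sum())
            if reduction > best_red:
                best, best_red = (fa, fb), reduction
                best_grid = means.reshape(na, nb)
        if best is None:
            break
        fa, fb = best
        pair_shapes[best] = best_grid
        resid -= best_grid[idx[fa], idx[fb]]
        candidates.remove(best)

    # center every term over the training population; fold means into intercept
    importances: dict = {}
    for f in feats:
        counts = np.bincount(idx[f], minlength=binnings[f].n_bins)
        m = float((counts * shapes[f]).sum() / n)
        shapes[f] -= m
        intercept += m
        importances[f] = float((counts * np.abs(shapes[f])).sum() / n)
    for (fa, fb), grid in pair_shapes.items():
        na, nb = binnings[fa].n_bins, binnings[fb].n_bins
        counts = np.bincount(idx[fa] * nb + idx[fb], minlength=na * nb).reshape(na, nb)
        m = float((counts * grid).sum() / n)
        grid -= m
        intercept += m
        importances[(fa, fb)] = float((counts * np.abs(grid)).sum() / n)

    r2 = 1.0 - float(np.var(resid)) / var0
    return SurrogateModel(
        intercept=intercept,
        binnings=binnings,
        shapes=shapes,
        pair_shapes=pair_shapes,
        importances=importances,
        fidelity_r2=r2,
    )


def _shape_direction(shape: np.ndarray) -> str:
    """Monotone direction flag via the Spearman sign of bin index vs value."""
    if len(shape) < 2 or np.allclose(shape, shape[0]):
        return "flat"
    from scipy.stats import spearmanr

    rho = spearmanr(np.arange(len(shape)), shape).statistic
    if np.isnan(rho) or rho == 0:
        return "flat"
    return "increasing" if rho > 0 else "decreasing"


def rank_candidate_terms(
    surrogate: SurrogateModel, current_spec: ModelSpec
) -> pd.DataFrame:
    """Features ranked as candidate treatment-interaction terms.

    Excludes the treatment itself and features that already interact with
    the treatment in the current specification; annotates each candidate
    with its importance and the empirical monotone direction of its shape.
    """
    treated_with = {
        v
        for t in current_spec.terms
        if t.is_interaction and current_spec.treatment in t.variables
        for v in t.variables
        if v != current_spec.treatment
    }
    rows = []
    for f, imp in sorted(
        ((f, surrogate.importances.get(f, 0.0)) for f in surrogate.shapes),
        key=lambda kv: -kv[1],
    ):
        if f == current_spec.treatment or f in treated_with:
            continue
        rows.append(
            {
                "feature": f,
                "importance": imp,
                "direction": _shape_direction(surrogate.shapes[f]),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "importance", "direction"])
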