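"""Heterogeneous treatment effects for an ordinal treatment.

The treatment convention is a one-level increase of an ordinal exposure
(e.g. physical-activity category), capped at the top level: individuals
already at the highest level have a treatment effect of exactly zero.

Three estimation surfaces live here:

* an S-learner on a fitted constrained GLM — tau_i is the difference of
  inverse-link predictions with the treatment shifted up one level;
* a two-component consensus ensemble that zeroes out estimates whose
  average is not sufficiently far from zero relative to the components'
  disagreement;
* log-odds-ratio extraction that converts component outcome-probability
  predictions into lnOR per individual, the quantity on which a logit-link
  GLM's treatment coefficients live — this makes black-box components
  directly comparable to the constrained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import CodedDesign, ModelSpec, build_design
from .solver import FittedGLMQC, predict

__all__ = [
    "TreatmentPlan",
    "ComponentPredictions",
    "HTEResult",
    "tau_slearner",
    "ensemble_consensus",
    "component_prob_at",
    "lnor_from_components",
    "pct_positive",
    "PROB_CLIP",
]

PROB_CLIP = 1e-6  # probabilities clipped to [PROB_CLIP, 1-PROB_CLIP] for lnOR


@dataclass(frozen=True)
class TreatmentPlan:
    """One-level-increase treatment for an ordinal exposure with K levels."""

    treatment: str
    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("treatment needs >= 2 levels")

    def shifted(self, w_obs: np.ndarray) -> np.ndarray:
        return np.minimum(np.asarray(w_obs) + 1, self.n_levels)

    def cap_mask(self, w_obs: np.ndarray) -> np.ndarray:
        return np.asarray(w_obs) == self.n_levels


@dataclass
class HTEResult:
    """Per-individual treatment-effect estimates for one outcome."""

    tau: np.ndarray
    cap_mask: np.ndarray
    source: str = ""
    lnor: np.ndarray | None = None  # NaN at capped individuals (binary outcomes)

    def __post_init__(self) -> None:
        if np.any(self.tau[self.cap_mask] != 0.0):
            raise ValueError("capped individuals must have tau == 0")


@dataclass
class ComponentPredictions:
    """Outcome-probability predictions of one ensemble component.

    ``kind="posterior-draw"`` holds per-level draws (e.g. posterior samples
    of a Bayesian tree ensemble): ``draws[level]`` is an (n, S) array and
    the probability at a level is the mean over draws.

    ``kind="constant-effect"`` holds a fitted probability at the observed
    treatment level plus a per-individual effect that is constant across
    levels given the covariates (e.g. a causal forest); probabilities at
    other levels are the first-order extrapolation
    ``y_hat_obs + extrapolation_sign * (w - w_obs) * tau_hat``
    (default sign -1).
    """

    kind: str
    w_obs: np.ndarray
    y_hat_obs: np.ndarray | None = None
    tau_hat: np.ndarray | None = None
    draws: dict[int, np.ndarray] = field(default_factory=dict)
    extrapolation_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.kind not in ("posterior-draw", "constant-effect"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        self.w_obs = np.asarray(self.w_obs, dtype=np.int64)
        if self.kind == "constant-effect":
            if self.y_hat_obs is None or self.tau_hat is None:
                raise ValueError("constant-effect needs y_hat_obs and tau_hat")
            self.y_hat_obs = np.asarray(self.y_hat_obs, dtype=float)
            self.tau_hat = np.asarray(self.tau_hat, dtype=float)
        else:
            if not self.draws:
                raise ValueError("posterior-draw needs draws")
            sizes = {v.shape for v in self.draws.values()}
            if len(sizes) != 1:
                raise ValueError("draw arrays must share one shape")


def tau_slearner(
    model: FittedGLMQC,
    data: pd.DataFrame,
    spec: ModelSpec,
    plan: TreatmentPlan | None = None,
) -> HTEResult:
    """S-learner HTE from a single fitted outcome model.

    tau_i = g^-1(eta_i at w = w_obs+1) - g^-1(eta_i at w = w_obs), all other
    covariates held fixed; zero at the cap.  For a logit link the lnOR is
    the difference of the two linear predictors.
    """
    tvar = spec.variable(spec.treatment)
    if plan is None:
        plan = TreatmentPlan(spec.treatment, tvar.n_levels)
    w_obs = tvar.level_index(data[spec.treatment])
    cap = plan.cap_mask(w_obs)
    w_new = plan.shifted(w_obs)

    data_s = data.copy()
    data_s[spec.treatment] = [tvar.levels[k - 1] for k in w_new]
    d0 = build_design(data, spec)
    d1 = build_design(data_s, spec)
    eta0 = predict(model, d0, scale="link")
    eta1 = predict(model, d1, scale="link")
    r0 = predict(model, d0, scale="response")
    r1 = predict(model, d1, scale="response")
    tau = r1 - r0
    tau[cap] = 0.0
    lnor = None
    if model.link == "logit":
        lnor = eta1 - eta0
        lnor[cap] = np.nan
    return HTEResult(tau=tau, cap_mask=cap, source="glmqc_slearner", lnor=lnor)


def ensemble_consensus(
    tau_a: np.ndarray, tau_b: np.ndarray, q: float = np.sqrt(2.0)
) -> np.ndarray:
    """Two-component consensus combination.

    With avg_i = (a_i + b_i)/2 and sigma_i = |a_i - b_i|/2 (the standard
    deviation of the two-component mean), the output is 0 where
    |avg_i| <= q * sigma_i and avg_i elsewhere: estimates the components
    do not agree on are zeroed rather than averaged.
    """
    a = np.asarray(tau_a, dtype=float)
    b = np.asarray(tau_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("component vectors must have equal length")
    if q < 0:
        raise ValueError("q must be >= 0")
    avg = 0.5 * (a + b)
    sigma = 0.5 * np.abs(a - b)
    return np.where(np.abs(avg) <= q * sigma, 0.0, avg)


def component_prob_at(pred: ComponentPredictions, w: int | np.ndarray) -> np.ndarray:
    """Outcome probability of a component at treatment level(s) ``w``.

    Posterior-draw components average their draws at the requested level;
    constant-effect components extrapolate linearly from the observed-level
    fit.  The result is clipped to [PROB_CLIP, 1-PROB_CLIP].
    """
    if pred.kind == "posterior-draw":
        if np.ndim(w) == 0:
            if int(w) not in pred.draws:
                raise KeyError(f"no draws stored for level {w}")
            p = pred.draws[int(w)].mean(axis=1)
        else:
            w = np.asarray(w, dtype=np.int64)
            missing = sorted(set(w.tolist()) - set(pred.draws))
            if missing:
                raise KeyError(f"no draws stored for level(s) {missing}")
            means = {lv: d.mean(axis=1) for lv, d in pred.draws.items()}
            p = np.empty(len(w))
            for lv in np.unique(w):
                m = w == lv
                p[m] = means[int(lv)][m]
    else:
        p = pred.y_hat_obs + pred.extrapolation_sign * (
            np.asarray(w) - pred.w_obs
        ) * pred.tau_hat
    if np.isnan(p).any():
        raise ValueError("NaN in component probabilities")
    return np.clip(p, PROB_CLIP, 1 - PROB_CLIP)


def lnor_from_components(
    pred_a: ComponentPredictions,
    pred_b: ComponentPredictions,
    plan: TreatmentPlan,
) -> np.ndarray:
    """Ensemble log odds ratio of treated vs control per individual.

    The two components' probabilities are averaged with equal weight at the
    control (observed) and treated (one-up) levels, then
    lnOR_i = ln[ p_s/(1-p_s) / (p_0/(1-p_0)) ].  Capped individuals are
    excluded (NaN) before any averaging.
    """
    if not np.array_equal(pred_a.w_obs, pred_b.w_obs):
        raise ValueError("components disagree on observed treatment levels")
    w0 = pred_a.w_obs
    cap = plan.cap_mask(w0)
    ws = plan.shifted(w0)
    p0 = 0.5 * component_prob_at(pred_a, w0) + 0.5 * component_prob_at(pred_b, w0)
    ps = 0.5 * component_prob_at(pred_a, ws) + 0.5 * component_prob_at(pred_b, ws)
    lnor = np.log(ps / (1 - ps)) - np.log(p0 / (1 - p0))
    lnor[cap] = np.nan
    return lnor


def pct_positive(values: np.ndarray) -> float:
    """Percentage of strictly positive entries (a confounding diagnostic).

    For a treatment expected to be protective, a large share of positive
    effect estimates suggests confounding or misspecification.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.count_nonzero(v > 0)) / v.size
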