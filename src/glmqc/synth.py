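"""Confounded synthetic health-survey populations with known ground truth.

Emulates the structure of an individual-level health survey: demographic,
behavioral and socioeconomic covariates; an ordinal 4-level physical-activity
exposure whose assignment is confounded (healthier individuals exercise
more, via a proportional-odds propensity model calibrated to target
marginals); and binary disease outcomes drawn from a known logistic
structural model with monotone main effects and activity x covariate
interactions.  Because the structural model is known, every individual's
exact treatment effect under the one-level-increase convention is available
as an oracle for recovery and targeting tests.

The default treatment marginals are (18%, 45%, 10%, 27%) for
inactive / insufficiently active / active / very active.  All other
marginals and effect magnitudes are synthetic: they mirror the qualitative
epidemiology (risk rises with age, BMI and smoking; activity is protective,
more so at older ages and for smokers) with invented magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .model_spec import ConstraintCase, ModelSpec, SpecError, TermSpec, VariableSpec

__all__ = [
    "TrueCurve",
    "TrueSurface",
    "OutcomeModel",
    "SynthConfig",
    "SynthPopulation",
    "generate",
    "naive_vs_adjusted_gap",
    "default_config",
    "structural_spec",
    "no_interaction_spec",
    "unconstrain",
    "variable_registry",
]

TREATMENT = "activity"
K_TREATMENT = 4
DEFAULT_MARGINALS = (0.18, 0.45, 0.10, 0.27)

AGE_EDGES = [18.0, 35.0, 50.0, 65.0, 200.0]
BMI_EDGES = [0.0, 22.5, 27.5, 32.5, 100.0]


def variable_registry() -> dict[str, VariableSpec]:
    """Variable definitions shared by the generator and the model specs."""
    return {
        "activity": VariableSpec("activity", "ordinal", levels=[1, 2, 3, 4]),
        "age": VariableSpec("age", "continuous-discretized", bin_edges=AGE_EDGES),
        "bmi": VariableSpec("bmi", "continuous-discretized", bin_edges=BMI_EDGES),
        "smoking": VariableSpec("smoking", "binary"),
        "secondhand": VariableSpec("secondhand", "binary"),
        "alcohol": VariableSpec("alcohol", "ordinal", levels=[1, 2, 3]),
        "fruitveg": VariableSpec("fruitveg", "ordinal", levels=[1, 2, 3]),
        "trust": VariableSpec("trust", "ordinal", levels=[1, 2, 3]),
        "gender": VariableSpec("gender", "binary"),
        "region": VariableSpec("region", "categorical", levels=[1, 2, 3, 4, 5]),
    }


# ---------------------------------------------------------------------------
# structural outcome model
# ---------------------------------------------------------------------------


@dataclass
class TrueCurve:
    """A main-effect curve on the logit scale with its constraint annotation."""

    values: np.ndarray
    case: ConstraintCase

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        c = self.case
        v = self.values
        if c.is_monotone:
            d = np.diff(v)
            ok = np.all(d >= 0) if c.monotonicity == "increasing" else np.all(d <= 0)
            if not ok:
                raise SpecError("declared curve violates its own monotonicity")
        if c.sign == "positive" and np.any(v < 0):
            raise SpecError("declared curve violates its own positive sign")
        if c.sign == "negative" and np.any(v > 0):
            raise SpecError("declared curve violates its own negative sign")


@dataclass
class TrueSurface:
    """An interaction surface gamma(level_a, level_b) on the logit scale.

    For monotone cases the constrained quantity is the double increment
    gamma(a+1,b+1) - gamma(a+1,b) - gamma(a,b+1) + gamma(a,b).
    """

    values: np.ndarray  # (K_a, K_b) grid including the reference row/column
    case: ConstraintCase

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.case.is_monotone:
            dd = np.diff(np.diff(self.values, axis=0), axis=1)
            ok = np.all(dd >= 0) if self.case.sign == "positive" else np.all(dd <= 0)
            if not ok:
                raise SpecError("declared surface violates its double-increment sign")


@dataclass
class OutcomeModel:
    """Logistic structural model for one binary disease outcome."""

    name: str
    intercept: float
    curves: dict[str, TrueCurve]
    surfaces: dict[tuple[str, str], TrueSurface] = field(default_factory=dict)

    def eta_at_levels(
        self, levels: dict[str, np.ndarray], w: np.ndarray
    ) -> np.ndarray:
        """Linear predictor with the treatment forced to level vector ``w``."""
        lev = dict(levels)
        lev[TREATMENT] = np.asarray(w)
        eta = np.full(len(lev[TREATMENT]), self.intercept, dtype=float)
        for var, curve in self.curves.items():
            eta += curve.values[lev[var] - 1]
        for (va, vb), surf in self.surfaces.items():
            eta += surf.values[lev[va] - 1, lev[vb] - 1]
        return eta


def _ramp_surface(ka: int, kb: int, slope: float) -> np.ndarray:
    """Bilinear surface slope*(a-1)*(b-1): constant double increment."""
    a = np.arange(ka)[:, None]
    b = np.arange(kb)[None, :]
    return slope * a * b


def default_outcomes() -> list[OutcomeModel]:
    """Two disease outcomes mimicking diabetes- and IHD-like structure."""
    inc_pos = ConstraintCase("increasing", "positive")
    dec_neg = ConstraintCase("decreasing", "negative")
    diabetes = OutcomeModel(
        name="diabetes",
        intercept=-2.8,
        curves={
            "age": TrueCurve([0.0, 0.6, 1.1, 1.5], inc_pos),
            "bmi": TrueCurve([0.0, 0.4, 0.8, 1.2], inc_pos),
            "smoking": TrueCurve([0.0, 0.4], inc_pos),
            "secondhand": TrueCurve([0.0, 0.2], inc_pos),
            "activity": TrueCurve([0.0, -0.35, -0.6, -0.8], dec_neg),
        },
        surfaces={
            ("activity", "age"): TrueSurface(_ramp_surface(4, 4, -0.12), dec_neg),
            ("activity", "smoking"): TrueSurface(_ramp_surface(4, 2, -0.25), dec_neg),
        },
    )
    ihd = OutcomeModel(
        name="ihd",
        intercept=-3.0,
        curves={
            "age": TrueCurve([0.0, 0.7, 1.3, 1.8], inc_pos),
            "bmi": TrueCurve([0.0, 0.3, 0.6, 0.9], inc_pos),
            "smoking": TrueCurve([0.0, 0.5], inc_pos),
            "secondhand": TrueCurve([0.0, 0.25], inc_pos),
            "activity": TrueCurve([0.0, -0.3, -0.5, -0.65], dec_neg),
        },
        surfaces={
            ("activity", "age"): TrueSurface(_ramp_surface(4, 4, -0.15), dec_neg),
        },
    )
    return [diabetes, ihd]


# ---------------------------------------------------------------------------
# configuration and population containers
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    n: int = 10_000
    seed: int = 0
    treatment_marginals: tuple = DEFAULT_MARGINALS
    confounding: float = 0.5  # strength of the healthiness -> activity link
    age_bmi_corr: float = 1.0  # 0 disables the age -> BMI drift
    outcomes: list[OutcomeModel] = field(default_factory=default_outcomes)

    def __post_init__(self) -> None:
        m = np.asarray(self.treatment_marginals, dtype=float)
        if len(m) != K_TREATMENT or not np.isclose(m.sum(), 1.0):
            raise SpecError("treatment_marginals must be 4 shares summing to 1")
        if np.any(m <= 0):
            raise SpecError("treatment_marginals must be positive")


@dataclass
class SynthPopulation:
    data: pd.DataFrame
    truth: dict[str, dict[str, np.ndarray]]
    config: SynthConfig

    @property
    def n(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _calibrate_cutpoints(
    s: np.ndarray, gamma: float, cum_targets: np.ndarray
) -> np.ndarray:
    """Proportional-odds intercepts hitting the cumulative marginals.

    Solves mean_i expit(c_k - gamma*s_i) = target_k by bisection for each
    cut point k.
    """
    cuts = []
    for t in cum_targets:
        f = lambda c: float(expit(c - gamma * s).mean() - t)  # noqa: E731
        try:
            cuts.append(brentq(f, -50.0, 50.0, xtol=1e-12))
        except ValueError as exc:
            achieved = [float(expit(c - gamma * s).mean()) for c in (-50, 50)]
            raise RuntimeError(
                f"marginal calibration infeasible for target {t}; "
                f"achievable range {achieved}"
            ) from exc
    c = np.asarray(cuts)
    if np.any(np.diff(c) <= 0):
        raise RuntimeError("calibrated cut points not increasing")
    return c


def generate(config: SynthConfig) -> SynthPopulation:
    """Draw a full synthetic population with exact per-individual truth.

    Deterministic given the config (covariates, treatment and outcomes all
    come from one seeded generator in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    reg = variable_registry()

    age = np.clip(rng.normal(45.0, 16.0, n), 18.0, 89.0)
    gender = rng.binomial(1, 0.5, n)
    bmi = np.clip(
        26.0 + 0.08 * config.age_bmi_corr * (age - 45.0) + rng.normal(0.0, 4.0, n),
        16.0,
        45.0,
    )
    smoking = rng.binomial(1, 0.30, n)
    secondhand = rng.binomial(1, 0.25, n)
    alcohol = rng.choice([1, 2, 3], n, p=[0.7, 0.2, 0.1])
    fruitveg = rng.choice([1, 2, 3], n, p=[0.3, 0.5, 0.2])
    trust = rng.choice([1, 2, 3], n, p=[0.4, 0.4, 0.2])
    education = rng.choice([0, 5, 8, 11, 16], n, p=[0.15, 0.35, 0.2, 0.15, 0.15])
    income = rng.uniform(0.0, 1.0, n)
    region = rng.choice([1, 2, 3, 4, 5], n)

    # healthiness score drives activity upward when confounding > 0
    health = _zscore(
        -0.5 * _zscore(age) - 0.5 * _zscore(bmi) - 0.6 * smoking + 0.4 * _zscore(income)
    )
    cum_targets = np.cumsum(config.treatment_marginals)[:-1]
    cuts = _calibrate_cutpoints(-health, config.confounding, cum_targets)
    # P(w <= k | health): higher health -> lower cumulative prob -> higher w
    cdf = expit(cuts[None, :] - config.confounding * health[:, None])
    u = rng.uniform(0.0, 1.0, n)
    w = 1 + (u[:, None] > cdf).sum(axis=1)

    levels = {
        "age": reg["age"].level_index(age),
        "bmi": reg["bmi"].level_index(bmi),
        "smoking": reg["smoking"].level_index(smoking),
        "secondhand": reg["secondhand"].level_index(secondhand),
        "alcohol": alcohol.astype(np.int64),
        "fruitveg": fruitveg.astype(np.int64),
        "trust": trust.astype(np.int64),
        "gender": reg["gender"].level_index(gender),
        "region": region.astype(np.int64),
    }

    data = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "bmi": bmi,
            "smoking": smoking,
            "secondhand": secondhand,
            "alcohol": alcohol,
            "fruitveg": fruitveg,
            "trust": trust,
            "education": education,
            "income": income,
            "region": region,
            TREATMENT: w,
        }
    )

    truth: dict[str, dict[str, np.ndarray]] = {}
    for om in config.outcomes:
        eta = np.column_stack(
            [om.eta_at_levels(levels, np.full(n, k)) for k in range(1, K_TREATMENT + 1)]
        )
        prob = expit(eta)
        y = rng.binomial(1, prob[np.arange(n), w - 1])
        data[om.name] = y
        cap = w == K_TREATMENT
        w_up = np.minimum(w + 1, K_TREATMENT)
        tau = prob[np.arange(n), w_up - 1] - prob[np.arange(n), w - 1]
        tau[cap] = 0.0
        lnor = eta[np.arange(n), w_up - 1] - eta[np.arange(n), w - 1]
        lnor[cap] = np.nan
        truth[om.name] = {"tau": tau, "lnor": lnor, "prob": prob, "eta": eta}

    return SynthPopulation(data=data, truth=truth, config=config)


def naive_vs_adjusted_gap(pop: SynthPopulation, outcome: str) -> pd.DataFrame:
    """Naive adjacent-level outcome contrasts minus the true ATE per pair.

    The naive contrast compares observed disease rates between adjacent
    activity groups; under confounding (healthier people exercise more) it
    overstates the benefit of activity relative to the true average effect.
    """
    w = pop.data[TREATMENT].to_numpy()
    y = pop.data[outcome].to_numpy()
    prob = pop.truth[outcome]["prob"]
    rows = []
    for k in range(1, K_TREATMENT):
        in_k, in_k1 = w == k, w == k + 1
        if in_k.sum() == 0 or in_k1.sum() == 0:
            raise ValueError(f"empty treatment stratum in pair ({k},{k + 1})")
        naive = float(y[in_k1].mean() - y[in_k].mean())
        true_ate = float((prob[:, k] - prob[:, k - 1]).mean())
        rows.append(
            {"pair": f"{k}->{k + 1}", "naive": naive, "true_ate": true_ate,
             "gap": naive - true_ate}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model specifications over the synthetic population
# ---------------------------------------------------------------------------


def default_config(n: int = 10_000, seed: int = 0, confounding: float = 0.5,
                   **kw) -> SynthConfig:
    return SynthConfig(n=n, seed=seed, confounding=confounding, **kw)


def structural_spec(outcome_model: OutcomeModel) -> ModelSpec:
    """The correctly specified constrained model for a structural outcome.

    Terms and qualitative constraints match the generating model exactly,
    so its fitted effect curves should converge to the true ones.
    """
    reg = variable_registry()
    variables = [reg[v] for v in outcome_model.curves]
    terms = [
        TermSpec((v,), curve.case) for v, curve in outcome_model.curves.items()
    ]
    for (va, vb), surf in outcome_model.surfaces.items():
        terms.append(TermSpec((va, vb), surf.case))
    return ModelSpec(
        outcome=outcome_model.name,
        family="binomial",
        treatment=TREATMENT,
        variables=variables,
        terms=terms,
    )


def no_interaction_spec(outcome_model: OutcomeModel) -> ModelSpec:
    """Main-effects-only benchmark (no treatment-interaction heterogeneity)."""
    spec = structural_spec(outcome_model)
    return ModelSpec(
        outcome=spec.outcome,
        family=spec.family,
        treatment=spec.treatment,
        variables=spec.variables,
        terms=[t for t in spec.terms if not t.is_interaction],
    )


def unconstrain(spec: ModelSpec) -> ModelSpec:
    """Same terms with every qualitative constraint removed."""
    return ModelSpec(
        outcome=spec.outcome,
        family=spec.family,
        treatment=spec.treatment,
        variables=spec.variables,
        terms=[TermSpec(t.variables, ConstraintCase()) for t in spec.terms],
        intercept=spec.intercept,
    )
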