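import numpy as np
import pandas as pd
import pytest

from glmqc import synth
from glmqc.model_spec import ConstraintCase, ModelSpec, TermSpec, VariableSpec

#: the six monotone constraint cases
MONOTONE_CASES = [
    ConstraintCase("increasing", "positive"),
    ConstraintCase("increasing", "negative"),
    ConstraintCase("decreasing", "positive"),
    ConstraintCase("decreasing", "negative"),
    ConstraintCase("increasing", "unrestricted"),
    ConstraintCase("decreasing", "unrestricted"),
]


@pytest.fixture(scope="session")
def small_pop():
    """A confounded synthetic population shared across tests."""
    return synth.generate(synth.default_config(n=4000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def feasible_steps(case: ConstraintCase, width: int, rng) -> np.ndarray:
    """Random step coefficients satisfying a case's sign bounds."""
    bounds = case.step_bounds(width)
    z = rng.exponential(1.0, width)
    z[bounds == -1] *= -1
    z[bounds == 0] = rng.normal(0.0, 1.0, (bounds == 0).sum())
    return z


def simple_binary_spec(family="gaussian", sign="unrestricted"):
    """Outcome on a single binary treatment, optionally sign-constrained."""
    return ModelSpec(
        outcome="y",
        family=family,
        treatment="t",
        variables=[VariableSpec("t", "binary")],
        terms=[TermSpec(("t",), ConstraintCase("none", sign))],
    )


def binary_frame(n, rng, effect=1.0, family="gaussian"):
    t = rng.integers(0, 2, n)
    if family == "gaussian":
        y = effect * t + rng.normal(0, 1, n)
    else:
        p = 1 / (1 + np.exp(-(-0.5 + effect * t)))
        y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"t": t, "y": y})
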