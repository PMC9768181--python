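"""Declarative model specification and qualitative-constraint coding.

A qualitatively constrained GLM models the link-transformed mean as an
additive function of discretized/ordinal covariates and selected two-way
interactions, where the modeler may require each effect curve to be
monotone (non-decreasing / non-increasing over the ordered levels) and/or
to have a fixed sign relative to a reference level.

The constraints are imposed by reparameterization: each coded variable is
rewritten in *incremental* (cumulative step) coding, so that the effect at
level ``l`` is the running sum of per-step coefficients.  Sign bounds on
the step coefficients then imply monotonicity of the recovered curve, and
the original dummy-style coefficients are recovered as ``beta = A @ zeta``
with a triangular coding matrix ``A``.  Two-way interactions use the
Kronecker product ``A_j (x) A_k`` of the per-variable coding matrices, so
the bounded quantity is the double increment of the interaction surface.

Six meaningful monotone constraint cases exist (plus sign-only dummy
constraints and the unconstrained case):

====  ============  ============  =============  ==================
case  monotonicity  sign          reference end  step bounds
====  ============  ============  =============  ==================
1     increasing    positive      first level    all >= 0
2     increasing    negative      last level     all <= 0
3     decreasing    positive      last level     all >= 0
4     decreasing    negative      first level    all <= 0
5     increasing    unrestricted  first level    >= 0 for k > 1
6     decreasing    unrestricted  first level    <= 0 for k > 1
====  ============  ============  =============  ==================

In cases 5 and 6 the first step is free, so the curve is monotone over
levels 2..K and its overall sign is unrestricted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "ConstraintCase",
    "TermSpec",
    "ModelSpec",
    "TermBlock",
    "CodedDesign",
    "SpecError",
    "DataError",
    "discretize",
    "encode_incremental",
    "encode_dummy",
    "coding_matrix",
    "build_design",
    "recover_coefficients",
    "effect_curve",
    "effect_surface",
]

VARIABLE_KINDS = (
    "binary",
    "categorical",
    "ordinal",
    "continuous-linear",
    "continuous-discretized",
)

#: sign bound codes per design column: +1 => coefficient >= 0,
#: -1 => coefficient <= 0, 0 => free.
GE, LE, FREE = 1, -1, 0


class SpecError(ValueError):
    """Invalid model specification."""


class DataError(ValueError):
    """Data does not conform to the model specification."""


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintCase:
    """Qualitative constraint on one term's effect.

    ``monotonicity`` in {"increasing", "decreasing", "none"};
    ``sign`` in {"positive", "negative", "unrestricted"}.
    """

    monotonicity: str = "none"
    sign: str = "unrestricted"

    def __post_init__(self) -> None:
        if self.monotonicity not in ("increasing", "decreasing", "none"):
            raise SpecError(f"bad monotonicity {self.monotonicity!r}")
        if self.sign not in ("positive", "negative", "unrestricted"):
            raise SpecError(f"bad sign {self.sign!r}")

    @property
    def is_monotone(self) -> bool:
        return self.monotonicity != "none"

    @property
    def is_unconstrained(self) -> bool:
        return self.monotonicity == "none" and self.sign == "unrestricted"

    @property
    def reference_end(self) -> str:
        """Which end of the level axis the monotone coding accumulates from."""
        if not self.is_monotone:
            raise SpecError("reference_end only defined for monotone cases")
        if (self.monotonicity, self.sign) in (
            ("increasing", "negative"),
            ("decreasing", "positive"),
        ):
            return "last"
        return "first"

    def step_bounds(self, width: int) -> np.ndarray:
        """Per-step sign bound codes for an incremental coding of this case."""
        if not self.is_monotone:
            raise SpecError("step_bounds only defined for monotone cases")
        sign = {"positive": GE, "negative": LE}.get(self.sign)
        if sign is None:
            # cases 5/6: first step free, remaining steps enforce monotonicity
            sign = GE if self.monotonicity == "increasing" else LE
            b = np.full(width, sign, dtype=np.int8)
            b[0] = FREE
            return b
        return np.full(width, sign, dtype=np.int8)


@dataclass
class VariableSpec:
    """One survey variable and how it enters the design.

    ``bin_edges`` (continuous-discretized only) are strictly increasing cut
    points defining half-open bins ``[lo, hi)``; ``levels`` are the ordered
    category labels for coded variables; ``transform`` is an optional named
    univariate transform for continuous-linear variables ("identity" or
    "min_cap" with ``transform_param`` = cap value).
    """

    name: str
    kind: str
    bin_edges: list[float] | None = None
    levels: list | None = None
    reference_level: object | None = None
    transform: str = "identity"
    transform_param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise SpecError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "continuous-discretized":
            if self.bin_edges is None or len(self.bin_edges) < 3:
                raise SpecError(f"{self.name}: need >= 3 bin edges")
            edges = np.asarray(self.bin_edges, dtype=float)
            if not np.all(np.diff(edges) > 0):
                raise SpecError(f"{self.name}: bin_edges must be strictly increasing")
            if self.levels is None:
                self.levels = list(range(1, len(edges)))
        elif self.kind in ("binary", "categorical", "ordinal"):
            if self.levels is None:
                if self.kind == "binary":
                    self.levels = [0, 1]
                else:
                    raise SpecError(f"{self.name}: levels required for {self.kind}")
            if self.kind == "binary" and len(self.levels) != 2:
                raise SpecError(f"{self.name}: binary variable needs 2 levels")
        if self.kind != "continuous-linear":
            if self.n_levels < 2:
                raise SpecError(f"{self.name}: K >= 2 required")
            if self.reference_level is None:
                self.reference_level = self.levels[0]
            if self.reference_level not in self.levels:
                raise SpecError(
                    f"{self.name}: reference {self.reference_level!r} not in levels"
                )
        if self.transform not in ("identity", "min_cap"):
            raise SpecError(f"{self.name}: unknown transform {self.transform!r}")
        if self.transform == "min_cap" and self.transform_param is None:
            raise SpecError(f"{self.name}: min_cap needs transform_param")

    @property
    def is_coded(self) -> bool:
        return self.kind != "continuous-linear"

    @property
    def n_levels(self) -> int:
        return len(self.levels) if self.levels is not None else 1

    def level_index(self, values: pd.Series | np.ndarray) -> np.ndarray:
        """Map raw data values to integer levels 1..K."""
        if self.kind == "continuous-discretized":
            return discretize(np.asarray(values, dtype=float), self)
        lut = {lv: i + 1 for i, lv in enumerate(self.levels)}
        out = np.empty(len(values), dtype=np.int64)
        vals = np.asarray(values)
        for i, v in enumerate(vals):
            try:
                out[i] = lut[v.item() if isinstance(v, np.generic) else v]
            except KeyError:
                raise DataError(
                    f"variable {self.name!r}: unseen level {v!r} at row {i}"
                ) from None
        return out

    def linear_column(self, values: pd.Series | np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.transform == "min_cap":
            v = np.minimum(v, float(self.transform_param))
        return v


@dataclass(frozen=True)
class TermSpec:
    """A main effect (1 variable) or two-way interaction (2 variables)."""

    variables: tuple
    constraint: ConstraintCase = field(default_factory=ConstraintCase)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) not in (1, 2):
            raise SpecError("a term has one or two variables")
        if len(self.variables) == 2 and self.variables[0] == self.variables[1]:
            raise SpecError("interaction variables must be distinct")

    @property
    def is_interaction(self) -> bool:
        return len(self.variables) == 2

    @property
    def name(self) -> str:
        return "*".join(self.variables)


@dataclass
class ModelSpec:
    """Full declarative model: outcome, family, treatment, variables, terms."""

    outcome: str
    family: str
    treatment: str
    variables: list[VariableSpec]
    terms: list[TermSpec]
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise SpecError(f"unknown family {self.family!r}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SpecError("duplicate variable names")
        self._vars = {v.name: v for v in self.variables}
        for t in self.terms:
            for vn in t.variables:
                if vn not in self._vars:
                    raise SpecError(f"term {t.name}: undeclared variable {vn!r}")
        if not any(self.treatment in t.variables for t in self.terms):
            raise SpecError(f"treatment {self.treatment!r} appears in no term")

    @property
    def link(self) -> str:
        return "logit" if self.family == "binomial" else "identity"

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._vars[name]
        except KeyError:
            raise SpecError(f"no variable {name!r} in spec") from None

    def term_for(self, *variables: str) -> TermSpec:
        key = set(variables)
        for t in self.terms:
            if set(t.variables) == key:
                return t
        raise SpecError(f"no term over {sorted(key)} in spec")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "treatment": self.treatment,
            "intercept": self.intercept,
            "variables": [
                {
                    k: v
                    for k, v in {
                        "name": vs.name,
                        "kind": vs.kind,
                        "bin_edges": vs.bin_edges,
                        "levels": vs.levels,
                        "reference_level": vs.reference_level,
                        "transform": vs.transform,
                        "transform_param": vs.transform_param,
                    }.items()
                    if v is not None and v != "identity"
                }
                for vs in self.variables
            ],
            "terms": [
                {
                    "variables": list(t.variables),
                    "monotonicity": t.constraint.monotonicity,
                    "sign": t.constraint.sign,
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        variables = [VariableSpec(**v) for v in d["variables"]]
        terms = [
            TermSpec(
                tuple(t["variables"]),
                ConstraintCase(
                    t.get("monotonicity", "none"), t.get("sign", "unrestricted")
                ),
            )
            for t in d["terms"]
        ]
        return cls(
            outcome=d["outcome"],
            family=d["family"],
            treatment=d["treatment"],
            variables=variables,
            terms=terms,
            intercept=d.get("intercept", True),
        )

    @classmethod
    def from_file(cls, path) -> "ModelSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# coding primitives
# ---------------------------------------------------------------------------


def discretize(values: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Map continuous values to bin levels 1..K using half-open bins [lo, hi).

    Values outside the outer edges are clamped into the end bins (with a
    warning); non-finite values are rejected with their row indices.
    """
    if spec.kind != "continuous-discretized":
        raise SpecError(f"{spec.name}: discretize needs continuous-discretized")
    v = np.asarray(values, dtype=float)
    bad = ~np.isfinite(v)
    if bad.any():
        raise DataError(
            f"variable {spec.name!r}: non-finite values at rows "
            f"{np.flatnonzero(bad)[:10].tolist()}"
        )
    edges = np.asarray(spec.bin_edges, dtype=float)
    K = len(edges) - 1
    out_of_range = (v < edges[0]) | (v >= edges[-1])
    if out_of_range.any():
        warnings.warn(
            f"variable {spec.name!r}: {int(out_of_range.sum())} value(s) outside "
            f"[{edges[0]}, {edges[-1]}) clamped into end bins",
            stacklevel=2,
        )
    lev = np.searchsorted(edges, v, side="right")
    return np.clip(lev, 1, K).astype(np.int64)


def encode_incremental(
    levels: np.ndarray, K: int, case: ConstraintCase
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative step coding of ordinal levels for a monotone constraint case.

    Column ``k`` (of K-1) indicates that the observation has crossed step
    ``k`` moving away from the case's reference end.  Returns the n x (K-1)
    coded matrix and the per-column sign bound codes.
    """
    if K < 2:
        raise SpecError("incremental coding needs K >= 2")
    if not case.is_monotone:
        raise SpecError("incremental coding needs a monotone case")
    lev = np.asarray(levels, dtype=np.int64)
    if lev.min(initial=1) < 1 or lev.max(initial=K) > K:
        raise DataError(f"levels outside 1..{K}")
    steps = np.arange(1, K)
    if case.reference_end == "first":
        Z = (lev[:, None] > steps[None, :]).astype(float)
    else:
        Z = (lev[:, None] <= steps[None, :]).astype(float)
    return Z, case.step_bounds(K - 1)


def encode_dummy(
    levels: np.ndarray, K: int, reference: int, sign: str = "unrestricted"
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot-minus-reference indicators with a shared sign bound.

    ``reference`` is the 1-based reference level; the K-1 columns correspond
    to the non-reference levels in ascending order.
    """
    if K < 2:
        raise SpecError("dummy coding needs K >= 2")
    if not (1 <= reference <= K):
        raise SpecError(f"reference {reference} outside 1..{K}")
    lev = np.asarray(levels, dtype=np.int64)
    if lev.min(initial=1) < 1 or lev.max(initial=K) > K:
        raise DataError(f"levels outside 1..{K}")
    others = [k for k in range(1, K + 1) if k != reference]
    Z = (lev[:, None] == np.asarray(others)[None, :]).astype(float)
    bound = {"positive": GE, "negative": LE, "unrestricted": FREE}[sign]
    return Z, np.full(K - 1, bound, dtype=np.int8)


def coding_matrix(K: int, case: ConstraintCase | None) -> np.ndarray:
    """Coding matrix A mapping working (step) to original (dummy) coefficients.

    Lower-triangular of ones when steps accumulate from the first level,
    upper-triangular when from the last; identity for dummy coding.
    """
    if case is None or not case.is_monotone:
        return np.eye(K - 1)
    if case.reference_end == "first":
        return np.tril(np.ones((K - 1, K - 1)))
    return np.triu(np.ones((K - 1, K - 1)))


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


@dataclass
class TermBlock:
    """One term's slice of the coded design."""

    term: TermSpec
    index: int
    sl: slice
    A: np.ndarray
    column_names: list[str]
    coding: str  # "incremental" | "dummy" | "linear" | "interaction"
    shape: tuple  # (K,) for mains, (K_a, K_b) for interactions; (1,) linear
    ref_position: int | None = None  # 0-based reference level index (dummy coding)

    @property
    def width(self) -> int:
        return self.sl.stop - self.sl.start


@dataclass
class CodedDesign:
    """Reparametrized design matrix with per-column bounds and coding blocks."""

    X: np.ndarray
    bounds: np.ndarray
    blocks: list[TermBlock]
    column_names: list[str]
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def block_for(self, *variables: str) -> TermBlock:
        key = set(variables)
        for b in self.blocks:
            if set(b.term.variables) == key:
                return b
        raise SpecError(f"no block over {sorted(key)}")


def _main_block(
    data: pd.DataFrame, vspec: VariableSpec, case: ConstraintCase
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], str]:
    """Coded columns, bounds, A, names, coding-kind for one variable/case."""
    name = vspec.name
    if vspec.kind == "continuous-linear":
        if case.is_monotone:
            raise SpecError(
                f"{name}: shape constraints need a coded variable, not linear"
            )
        col = vspec.linear_column(data[name].to_numpy())[:, None]
        bound = {"positive": GE, "negative": LE, "unrestricted": FREE}[case.sign]
        return col, np.array([bound], dtype=np.int8), np.eye(1), [name], "linear"
    lev = vspec.level_index(data[name])
    K = vspec.n_levels
    if case.is_monotone:
        if vspec.kind == "categorical":
            raise SpecError(f"{name}: categorical variables admit no monotonicity")
        Z, bounds = encode_incremental(lev, K, case)
        A = coding_matrix(K, case)
        if case.reference_end == "first":
            names = [f"{name}:ge{k + 1}" for k in range(1, K)]
        else:
            names = [f"{name}:le{k}" for k in range(1, K)]
        return Z, bounds, A, names, "incremental"
    ref = vspec.levels.index(vspec.reference_level) + 1
    Z, bounds = encode_dummy(lev, K, ref, case.sign)
    names = [f"{name}:{lv}" for lv in vspec.levels if lv != vspec.reference_level]
    return Z, bounds, np.eye(K - 1), names, "dummy"


def build_design(data: pd.DataFrame, spec: ModelSpec) -> CodedDesign:
    """Assemble the reparametrized design for ``spec`` from raw survey data.

    Main-effect blocks are coded per their constraint case; interaction
    blocks are all pairwise products of the two per-variable codings, with
    coding matrix ``A_j (x) A_k`` and per-cell bounds from the interaction's
    constraint case.
    """
    if len(data) == 0:
        raise DataError("empty data table")
    used = sorted({v for t in spec.terms for v in t.variables})
    for vn in used:
        if vn not in data.columns:
            raise DataError(f"missing column {vn!r}")
        na = data[vn].isna()
        if na.to_numpy().any():
            raise DataError(
                f"column {vn!r}: NA at row {int(np.flatnonzero(na)[0])}"
            )

    cols: list[np.ndarray] = []
    bounds: list[np.ndarray] = []
    blocks: list[TermBlock] = []
    names: list[str] = []
    start = 0
    for ti, term in enumerate(spec.terms):
        case = term.constraint
        ref_pos = None
        if not term.is_interaction:
            vs = spec.variable(term.variables[0])
            Z, b, A, cnames, ckind = _main_block(data, vs, case)
            shape = (vs.n_levels,) if vs.is_coded else (1,)
            if ckind == "dummy":
                ref_pos = vs.levels.index(vs.reference_level)
        else:
            if case.is_monotone and case.sign == "unrestricted":
                raise SpecError(
                    f"term {term.name}: monotone interactions need a declared sign"
                )
            va, vb = (spec.variable(v) for v in term.variables)
            sub_case = case if case.is_monotone else ConstraintCase("none", case.sign)
            Za, _, Aa, na_, _ = _main_block(data, va, _axis_case(va, sub_case))
            Zb, _, Ab, nb_, _ = _main_block(data, vb, _axis_case(vb, sub_case))
            Z = (Za[:, :, None] * Zb[:, None, :]).reshape(len(data), -1)
            A = np.kron(Aa, Ab)
            bound = {"positive": GE, "negative": LE, "unrestricted": FREE}[case.sign]
            b = np.full(Z.shape[1], bound, dtype=np.int8)
            cnames = [f"{x}*{y}" for x in na_ for y in nb_]
            ckind = "interaction"
            shape = (
                va.n_levels if va.is_coded else 1,
                vb.n_levels if vb.is_coded else 1,
            )
        cols.append(Z)
        bounds.append(b)
        names.extend(cnames)
        blocks.append(
            TermBlock(
                term, ti, slice(start, start + Z.shape[1]), A, cnames, ckind, shape,
                ref_pos,
            )
        )
        start += Z.shape[1]
    X = np.hstack(cols)
    assert len(names) == X.shape[1]
    return CodedDesign(X, np.concatenate(bounds), blocks, names, spec)


def _axis_case(vspec: VariableSpec, case: ConstraintCase) -> ConstraintCase:
    """Constraint case applied to one axis of an interaction block."""
    if vspec.kind == "continuous-linear" or not case.is_monotone:
        # linear axis or sign-only interaction: plain column / dummy coding
        return ConstraintCase("none", "unrestricted")
    return case


# ---------------------------------------------------------------------------
# coefficient recovery and effect curves
# ---------------------------------------------------------------------------


def recover_coefficients(working: np.ndarray, design: CodedDesign) -> dict[str, np.ndarray]:
    """Original-scale coefficients per term: ``beta_j = A_j @ zeta_j``.

    For interactions ``gamma_jk = (A_j (x) A_k) @ eta_jk``.  The inverse map
    ``zeta = A^{-1} beta`` round-trips exactly (A is unit-triangular).
    """
    working = np.asarray(working, dtype=float)
    if working.shape != (design.p,):
        raise SpecError(
            f"working vector length {working.shape} != design width {design.p}"
        )
    return {b.term.name: b.A @ working[b.sl] for b in design.blocks}


def effect_curve(block: TermBlock, working: np.ndarray) -> np.ndarray:
    """Per-level effect values e(1..K), zero at the coding reference level.

    ``working`` is the term's step/dummy coefficient vector (length K-1).
    For monotone codings the curve is the cumulative sum of steps away from
    the reference end.
    """
    if block.term.is_interaction:
        raise SpecError("effect_curve is for main terms; use effect_surface")
    zeta = np.asarray(working, dtype=float)
    if zeta.shape != (block.width,):
        raise SpecError("coefficient length mismatch")
    if block.coding == "linear":
        return zeta.copy()
    beta = block.A @ zeta
    K = block.shape[0]
    case = block.term.constraint
    if block.coding == "incremental":
        if case.reference_end == "first":
            return np.concatenate([[0.0], beta])
        return np.concatenate([beta, [0.0]])
    # dummy coding: insert zero at the user-declared reference position
    curve = np.zeros(K)
    idx = [i for i in range(K) if i != block.ref_position]
    curve[idx] = beta
    return curve


def effect_surface(block: TermBlock, working: np.ndarray) -> np.ndarray:
    """Interaction effect surface gamma reshaped to the (K_a-ish, K_b-ish) grid."""
    if not block.term.is_interaction:
        raise SpecError("effect_surface is for interaction terms")
    eta = np.asarray(working, dtype=float)
    gamma = block.A @ eta
    ka = block.shape[0] - 1 if block.shape[0] > 1 else 1
    kb = block.shape[1] - 1 if block.shape[1] > 1 else 1
    return gamma.reshape(ka, kb)
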