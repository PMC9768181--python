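"""CSV/JSON/YAML readers and writers, validation, and run manifests.

File contracts:

* survey data — CSV, UTF-8, comma-separated, header mandatory, one row per
  individual;
* model files — JSON holding the model specification together with the
  fitted coefficients (working and original scale), bounds and diagnostics;
* component predictions — CSV, either constant-effect
  (``id,w_obs,y_hat_obs,tau_hat``) or posterior-draw (``id,draw,level,p``);
* HTE files — CSV ``id,tau[,lnor],capped``.

All writers go through a write-to-temp-then-rename step so a failure never
leaves a partial output file, and every CLI run drops a manifest JSON next
to its outputs recording command, inputs, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hte import ComponentPredictions, pct_positive
from .model_spec import DataError, ModelSpec
from .solver import FittedGLMQC
from .targeting import TargetingConfig, captured_fraction, select

log = logging.getLogger("glmqc")

__all__ = [
    "read_survey_csv",
    "load_config",
    "atomic_write_text",
    "write_json",
    "save_model",
    "load_model",
    "read_component_csv",
    "write_hte_csv",
    "read_hte_csv",
    "RunManifest",
    "compare_report",
    "report_to_markdown",
]


def read_survey_csv(path, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Read and validate an individual-level survey CSV.

    With a spec, the columns every term uses must exist, contain no NA, and
    coded variables must only show declared levels.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"{path}: empty file")
    log.info("read %d rows x %d columns from %s", len(df), df.shape[1], path)
    if spec is not None:
        used = sorted({v for t in spec.terms for v in t.variables})
        for col in used:
            if col not in df.columns:
                raise DataError(f"{path}: missing column {col!r}")
            na = df[col].isna()
            if na.any():
                raise DataError(
                    f"{path}: NA in column {col!r} at row {int(np.flatnonzero(na)[0])}"
                )
            vs = spec.variable(col)
            if vs.is_coded and vs.kind != "continuous-discretized":
                vs.level_index(df[col])  # raises on unseen levels
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON config file (YAML is a JSON superset)."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (no partial outputs)."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, allow_nan=True))


def save_model(model: FittedGLMQC, spec: ModelSpec, path) -> None:
    """Serialize a fitted model with its specification to one JSON file."""
    write_json({"spec": spec.to_dict(), "model": model.to_dict()}, path)


def load_model(path) -> tuple[FittedGLMQC, ModelSpec]:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    return FittedGLMQC.from_dict(d["model"]), ModelSpec.from_dict(d["spec"])


def read_component_csv(path) -> ComponentPredictions:
    """Read a component-prediction CSV, auto-detecting its kind."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"id", "w_obs", "y_hat_obs", "tau_hat"} <= cols:
        df = df.sort_values("id", kind="stable")
        return ComponentPredictions(
            kind="constant-effect",
            w_obs=df["w_obs"].to_numpy(),
            y_hat_obs=df["y_hat_obs"].to_numpy(),
            tau_hat=df["tau_hat"].to_numpy(),
        )
    if {"id", "draw", "level", "p"} <= cols:
        draws: dict[int, np.ndarray] = {}
        w_obs = None
        for lv, sub in df.groupby("level"):
            piv = sub.pivot(index="id", columns="draw", values="p").sort_index()
            draws[int(lv)] = piv.to_numpy()
        if "w_obs" in cols:
            w_obs = (
                df.drop_duplicates("id").sort_values("id")["w_obs"].to_numpy()
            )
        else:
            raise DataError(f"{path}: posterior-draw CSV needs a w_obs column")
        return ComponentPredictions(kind="posterior-draw", w_obs=w_obs, draws=draws)
    raise DataError(
        f"{path}: unrecognized component CSV columns {sorted(cols)}"
    )


def write_hte_csv(path, tau: np.ndarray, cap_mask: np.ndarray,
                  lnor: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"id": np.arange(len(tau)), "tau": tau})
    if lnor is not None:
        df["lnor"] = lnor
    df["capped"] = cap_mask.astype(int)
    atomic_write_text(path, df.to_csv(index=False))


def read_hte_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "tau" not in df.columns:
        raise DataError(f"{path}: no 'tau' column")
    return df


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    arguments: dict
    inputs: dict = field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    version: str = __version__
    timestamp: str = ""

    @staticmethod
    def fingerprint(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, out_path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        write_json(asdict(self), str(out_path) + ".manifest.json")


def compare_report(
    models: dict[str, dict],
    truth: np.ndarray,
    fractions=(0.25,),
    costs=None,
    seed: int = 0,
    n_random: int = 100,
) -> dict:
    """Multi-model targeting comparison (machine-readable table).

    ``models[name]`` holds ``{"tau": per-individual effect estimates,
    "spec": ModelSpec or None}``.  For each model: term and constraint
    summary, captured benefit at each budget fraction (against ``truth``
    benefits = -tau_true), and the % positive diagnostic.
    """
    if not models:
        raise ValueError("need at least one model")
    truth = np.asarray(truth, dtype=float)
    lengths = {len(m["tau"]) for m in models.values()} | {len(truth)}
    if len(lengths) != 1:
        raise DataError("models and truth cover different populations")
    rng = np.random.default_rng(seed)
    out: dict = {"fractions": list(map(float, fractions)), "models": []}
    for name, m in models.items():
        tau = np.asarray(m["tau"], dtype=float)
        spec: ModelSpec | None = m.get("spec")
        entry = {
            "name": name,
            "terms": [t.name for t in spec.terms] if spec else None,
            "constraints": (
                [
                    f"{t.name}: {t.constraint.monotonicity}/{t.constraint.sign}"
                    for t in spec.terms
                ]
                if spec
                else None
            ),
            "pct_tau_positive": pct_positive(tau),
            "benefit": {},
        }
        for f in fractions:
            sel = select(-tau, TargetingConfig(budget_fraction=f, costs=costs))
            entry["benefit"][str(f)] = captured_fraction(truth, sel)
        out["models"].append(entry)
    baselines: dict = {"perfect": {}, "random": {}}
    n = len(truth)
    for f in fractions:
        sel = select(truth, TargetingConfig(budget_fraction=f, costs=costs))
        baselines["perfect"][str(f)] = captured_fraction(truth, sel)
        caps = [
            captured_fraction(
                truth,
                select(rng.random(n), TargetingConfig(budget_fraction=f, costs=costs)),
            )
            for _ in range(n_random)
        ]
        baselines["random"][str(f)] = float(np.mean(caps))
    out["baselines"] = baselines
    return out


def report_to_markdown(report: dict) -> str:
    """Render a compare_report dict as a Markdown table."""
    fr = report["fractions"]
    head = ["model", "terms"] + [f"benefit@{f:g}" for f in fr] + ["% tau>0"]
    lines = ["| " + " | ".join(head) + " |",
             "|" + "---|" * len(head)]
    for m in report["models"]:
        terms = ", ".join(m["terms"]) if m["terms"] else "-"
        row = [m["name"], terms]
        row += [f"{m['benefit'][str(f)]:.1%}" for f in fr]
        row += [f"{m['pct_tau_positive']:.1f}%"]
        lines.append("| " + " | ".join(row) + " |")
    for base in ("perfect", "random"):
        row = [base, "-"] + [
            f"{report['baselines'][base][str(f)]:.1%}" for f in fr
        ] + ["-"]
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"
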