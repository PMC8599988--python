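"""File formats: timing CSVs (milliseconds) and surrogate model JSON (seconds).

All user-facing files carry times in milliseconds; conversion to the
package's internal seconds happens here and nowhere else.  The model file
stores coefficients in seconds (the unit the regression runs in) and is
versioned; only ``units: "s"`` is accepted.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .model import TimingPair
from .surrogate import PolynomialSurrogate, polynomial_features

__all__ = [
    "InputError",
    "ModelFormatError",
    "load_timings",
    "save_model",
    "load_model",
    "default_surrogate",
]

MODEL_SCHEMA = 1
DEFAULT_MODEL_RESOURCE = "surrogate_order8.json"


class InputError(ValueError):
    """Malformed timing input file."""


class ModelFormatError(ValueError):
    """Model file does not match the expected schema."""


def load_timings(path) -> list[TimingPair]:
    """Read timing pairs from a CSV with columns tce_ms, tfe_ms.

    Values are converted to seconds.  Rows with missing or non-positive
    values are rejected with their 1-based file line numbers (header is
    line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file, expected header tce_ms,tfe_ms") from exc
    missing = [c for c in ("tce_ms", "tfe_ms") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    bad_lines = []
    pairs: list[TimingPair] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header occupies line 1
        tce, tfe = row["tce_ms"], row["tfe_ms"]
        if not (np.isfinite(tce) and np.isfinite(tfe) and tce > 0 and tfe > 0):
            bad_lines.append(line_no)
            continue
        pairs.append(TimingPair(t_ce=float(tce) * 1e-3, t_fe=float(tfe) * 1e-3))
    if bad_lines:
        raise InputError(
            f"{path}: non-positive or missing timing values on line(s) {bad_lines}"
        )
    return pairs


def save_model(model: PolynomialSurrogate, path) -> None:
    """Serialize a fitted surrogate to versioned JSON (coefficients in seconds)."""
    meta = {}
    for attr in ("rmse_test_", "r_squared_test_", "seed_", "train_fraction_"):
        if hasattr(model, attr):
            meta[attr.rstrip("_")] = getattr(model, attr)
    spec = getattr(model, "grid_spec_", None)
    if spec is not None:
        meta["grid_spec"] = {"start": spec.start, "stop": spec.stop, "spacing": spec.spacing}
    doc = {
        "schema": MODEL_SCHEMA,
        "units": "s",
        "order": int(model.order),
        "coefficients": [
            [int(i), int(j), float(c)] for (i, j), c in zip(model.powers_, model.coef_)
        ],
        "metadata": meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def _model_from_doc(doc: dict, source: str) -> PolynomialSurrogate:
    if doc.get("schema") != MODEL_SCHEMA:
        raise ModelFormatError(f"{source}: unsupported schema {doc.get('schema')!r}")
    if doc.get("units") != "s":
        raise ModelFormatError(f"{source}: units must be 's', got {doc.get('units')!r}")
    order = doc.get("order")
    coeffs = doc.get("coefficients")
    if not isinstance(order, int) or order < 1 or not isinstance(coeffs, list):
        raise ModelFormatError(f"{source}: malformed order/coefficients")
    model = PolynomialSurrogate(order=order)
    _, powers = polynomial_features(np.zeros((1, 2)), order)
    by_exponent = {}
    for entry in coeffs:
        try:
            i, j, value = entry
        except (TypeError, ValueError) as exc:
            raise ModelFormatError(f"{source}: bad coefficient entry {entry!r}") from exc
        by_exponent[(int(i), int(j))] = float(value)
    try:
        model.coef_ = np.array([by_exponent[(i, j)] for i, j in powers])
    except KeyError as exc:
        raise ModelFormatError(f"{source}: missing coefficient for exponents {exc}") from exc
    model.powers_ = powers
    model.n_features_in_ = 2
    meta = doc.get("metadata", {})
    env = meta.get("grid_spec")
    if env is not None:
        model.envelope_ = ((env["start"], env["stop"]), (env["start"], env["stop"]))
    else:
        model.envelope_ = ((-np.inf, np.inf), (-np.inf, np.inf))
    for key in ("rmse_test", "r_squared_test", "seed", "train_fraction"):
        if key in meta:
            setattr(model, key + "_", meta[key])
    return model


def load_model(path) -> PolynomialSurrogate:
    """Load a surrogate saved by :func:`save_model`; validates schema and units."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError(f"{path}: expected a JSON object")
    return _model_from_doc(doc, str(path))


def default_surrogate() -> PolynomialSurrogate:
    """The packaged eighth-order surrogate, refit on the default grid."""
    text = resources.files("stridetime").joinpath("data", DEFAULT_MODEL_RESOURCE).read_text()
    return _model_from_doc(json.loads(text), DEFAULT_MODEL_RESOURCE)
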