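"""Regression calibration mapping pad RGB color to free-chlorine concentration.

Three nested model families are supported, mirroring the progression from a
proof-of-concept fit to the selected model:

* ``linear_sum`` — concentration on the channel sum R+G+B (the chemistry
  makes lighter pads, hence larger sums, correspond to lower chlorine);
* ``multiple_rg`` — concentration on R and G individually (the blue channel
  carried no significant weight in the original deployment);
* ``polynomial_sq`` — concentration on R, G, B and their squares, the family
  selected by backward stepwise AIC.

Fits are ordinary least squares via statsmodels.  Predictions are raw linear
predictor evaluations and may be negative; clamping negatives into the lowest
tier is a classification-stage rule, not a regression one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .reference import PUBLISHED_COEFFICIENTS

FAMILY_TERMS: dict[str, tuple[str, ...]] = {
    "linear_sum": ("sum",),
    "multiple_rg": ("r", "g"),
    "polynomial_sq": ("r", "g", "b_chan", "r2", "g2", "b2"),
}

#: How each design term is computed from mean pad channels.
_TERM_FUNCS = {
    "sum": lambda r, g, b: r + g + b,
    "r": lambda r, g, b: r,
    "g": lambda r, g, b: g,
    "b_chan": lambda r, g, b: b,
    "r2": lambda r, g, b: r**2,
    "g2": lambda r, g, b: g**2,
    "b2": lambda r, g, b: b**2,
}


class CalibrationError(ValueError):
    """Degenerate calibration input (rank deficiency, too few rows, ...)."""


@dataclass
class FittedModel:
    """An OLS calibration fit: family, surviving terms, coefficients, diagnostics."""

    family: str
    terms: tuple[str, ...]
    coef: dict[str, float]          # per-term coefficients
    intercept: float
    adj_r2: float                   # NaN when residual df is 0 (flagged exact fit)
    aic: float
    n: int
    pvalues: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    notes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "terms": list(self.terms),
            "coef": self.coef,
            "intercept": self.intercept,
            "adj_r2": None if np.isnan(self.adj_r2) else self.adj_r2,
            "aic": self.aic,
            "n": self.n,
            "pvalues": self.pvalues,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            family=d["family"],
            terms=tuple(d["terms"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            intercept=float(d["intercept"]),
            adj_r2=float("nan") if d.get("adj_r2") is None else float(d["adj_r2"]),
            aic=float(d.get("aic", float("nan"))),
            n=int(d.get("n", 0)),
            pvalues={k: float(v) for k, v in d.get("pvalues", {}).items()},
            notes=dict(d.get("notes", {})),
        )


def published_model(family: str = "polynomial_sq") -> FittedModel:
    """The built-in published calibration ("paper-2022") for a family.

    These coefficients were fit to the original deployment's photographs; on
    synthetic scenes a freshly trained model should be used instead.  In the
    polynomial family the predictor-to-channel binding (R, G, B order) is an
    assumption recorded in the model notes.
    """
    coefs = dict(PUBLISHED_COEFFICIENTS[family])
    intercept = coefs.pop("b")
    notes = {"source": "paper-2022 published coefficients"}
    if family == "polynomial_sq":
        notes["channel_binding"] = (
            "predictors assumed bound to channels in (R, G, B) order, by analogy "
            "with the multiple linear family; not verifiable from the published fit"
        )
    return FittedModel(
        family=family,
        terms=FAMILY_TERMS[family],
        coef=coefs,
        intercept=intercept,
        adj_r2=float("nan"),
        aic=float("nan"),
        n=0,
        notes=notes,
    )


def _design(rows: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    r, g, b = (rows[c].to_numpy(dtype=float) for c in ("r", "g", "b"))
    return np.column_stack([_TERM_FUNCS[t](r, g, b) for t in terms])


def _fit_ols(rows: pd.DataFrame, family: str, terms: Sequence[str]) -> FittedModel:
    terms = tuple(terms)
    min_rows = len(terms) + 1
    if len(rows) < min_rows:
        raise CalibrationError(f"{family}: need at least {min_rows} rows, got {len(rows)}")
    y = rows["concentration"].to_numpy(dtype=float)
    X = _design(rows, terms)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise CalibrationError(f"{family}: design matrix is rank deficient (collinear terms)")
    res = sm.OLS(y, Xc).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aic = float(res.aic)  # -inf for an exact fit; handled by stepwise tie-breaking
        adj_r2 = float(res.rsquared_adj) if res.df_resid > 0 else float("nan")
    if res.df_resid == 0:
        warnings.warn("exact interpolation: adjusted R^2 undefined", RuntimeWarning, stacklevel=3)
    coef = {t: float(res.params[i + 1]) for i, t in enumerate(terms)}
    pvalues = {t: float(res.pvalues[i + 1]) for i, t in enumerate(terms)}
    return FittedModel(
        family=family,
        terms=terms,
        coef=coef,
        intercept=float(res.params[0]),
        adj_r2=adj_r2,
        aic=aic,
        n=len(rows),
        pvalues=pvalues,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def fit_linear_sum(rows: pd.DataFrame) -> FittedModel:
    """OLS of concentration on the RGB channel sum."""
    return _fit_ols(rows, "linear_sum", FAMILY_TERMS["linear_sum"])


def fit_multiple_rg(rows: pd.DataFrame) -> FittedModel:
    """OLS of concentration on R and G, with per-term p-values reported."""
    return _fit_ols(rows, "multiple_rg", FAMILY_TERMS["multiple_rg"])


def fit_polynomial_sq(rows: pd.DataFrame) -> FittedModel:
    """OLS of concentration on R, G, B and their squares."""
    return _fit_ols(rows, "polynomial_sq", FAMILY_TERMS["polynomial_sq"])


FIT_FUNCS = {
    "linear_sum": fit_linear_sum,
    "multiple_rg": fit_multiple_rg,
    "polynomial_sq": fit_polynomial_sq,
}


def backward_stepwise_aic(
    rows: pd.DataFrame,
    full_terms: Sequence[str] = FAMILY_TERMS["polynomial_sq"],
) -> tuple[FittedModel, list[dict]]:
    """Greedy backward elimination minimizing AIC.

    Starting from the full term set, repeatedly drop the single term whose
    removal lowers AIC the most; stop when no removal lowers it.  Exact ties
    (which arise for noiseless exact fits, where AIC degenerates) break
    toward the smaller model.  The intercept is never removed.  Returns the
    surviving model and a removal trace (one record per iteration with the
    candidate AICs).
    """
    terms = list(full_terms)
    current = _fit_ols(rows, "polynomial_sq", terms)
    trace: list[dict] = []
    while len(terms) > 1:
        candidates: dict[str, float] = {}
        for t in terms:
            reduced = [u for u in terms if u != t]
            try:
                candidates[t] = _fit_ols(rows, "polynomial_sq", reduced).aic
            except CalibrationError:
                continue
        if not candidates:
            break
        drop = min(candidates, key=candidates.get)
        trace.append({"current_aic": current.aic, "candidates": candidates, "dropped": None})
        if candidates[drop] <= current.aic:
            trace[-1]["dropped"] = drop
            terms.remove(drop)
            current = _fit_ols(rows, "polynomial_sq", terms)
        else:
            break
    return current, trace


def _sample_rgb(sample) -> tuple[float, float, float]:
    if isinstance(sample, Mapping):
        return float(sample["r"]), float(sample["g"]), float(sample["b"])
    if hasattr(sample, "mean_r"):
        return float(sample.mean_r), float(sample.mean_g), float(sample.mean_b)
    r, g, b = sample
    return float(r), float(g), float(b)


def predict_concentration(model: FittedModel, sample) -> float:
    """Evaluate the model's linear predictor at a pad color (mg/L, may be negative).

    ``sample`` may be an (R, G, B) triple, a mapping with keys r/g/b, or a
    PadSample-like object with ``mean_r``/``mean_g``/``mean_b`` attributes.
    """
    r, g, b = _sample_rgb(sample)
    for v in (r, g, b):
        if not 0.0 <= v <= 255.0:
            raise ValueError(f"channel value {v} outside [0, 255]")
    value = model.intercept
    for t in model.terms:
        if t not in model.coef:
            raise CalibrationError(f"model missing coefficient for term {t!r}")
        value += model.coef[t] * _TERM_FUNCS[t](r, g, b)
    return float(value)


def residual_diagnostics(model: FittedModel) -> dict:
    """Residual report: residual/fitted pairs, Shapiro-Wilk, adjusted R^2, AIC."""
    if model.residuals is None or len(model.residuals) < 3:
        raise CalibrationError("need a fitted model with at least 3 residuals")
    resid = np.asarray(model.residuals, dtype=float)
    report = {
        "residuals": resid,
        "fitted": np.asarray(model.fitted, dtype=float),
        "adj_r2": model.adj_r2,
        "aic": model.aic,
        "n": model.n,
    }
    if np.allclose(resid, 0.0):
        report.update(shapiro_w=float("nan"), shapiro_p=float("nan"), degenerate=True)
        return report
    w, p = sps.shapiro(resid)
    report.update(shapiro_w=float(w), shapiro_p=float(p), degenerate=False)
    return report
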