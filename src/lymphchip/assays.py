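"""Comparative-Ct qPCR quantification and 4PL ELISA standard curves.

Relative gene expression uses the comparative Ct method: per sample,
dCt = Ct_target - Ct_housekeeping; per group, ddCt = mean dCt(group) -
mean dCt(control); fold change = 2^(-ddCt), assuming an amplification
efficiency of 2 per cycle.  ELISA standard curves use the
four-parameter logistic model

    y = d + (a - d) / (1 + (x / c)^b),

with a/d the lower/upper asymptotes, c the inflection concentration and
b the Hill slope; inverse prediction maps measured optical densities
back to concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .device_model import ValidationError

__all__ = [
    "StandardCurve",
    "relative_expression",
    "fit_4pl",
    "logistic4",
    "inverse_4pl",
    "AssayError",
]

CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


class AssayError(ValueError):
    """Assay-specific computation failure (degenerate fit, out-of-range OD)."""


# --------------------------------------------------------------------------
# comparative Ct


def relative_expression(
    table: pd.DataFrame,
    housekeeping: str = "GAPDH",
    control_group: str = "control",
) -> pd.DataFrame:
    """Fold changes 2^(-ddCt) per gene x group, normalized to GAPDH-like
    housekeeping and a control group.

    ``table`` needs columns (sample_id, group, gene, replicate, ct).
    Samples lacking a housekeeping measurement are dropped with a
    warning.  Returns a tidy frame with columns (gene, group, n, ddct,
    fold, fold_sd_low, fold_sd_high, per_replicate_folds); the control
    group's fold is exactly 1 by construction.
    """
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValidationError("all Ct values must be > 0")
    if housekeeping not in set(table["gene"]):
        raise ValidationError(f"housekeeping gene {housekeeping!r} absent from table")
    if control_group not in set(table["group"]):
        raise ValidationError(f"control group {control_group!r} absent from table")

    hk = (
        table[table["gene"] == housekeeping]
        .set_index(["sample_id", "replicate"])["ct"]
        .rename("ct_hk")
    )
    tgt = table[table["gene"] != housekeeping].copy()
    tgt = tgt.join(hk, on=["sample_id", "replicate"])
    n_missing = int(tgt["ct_hk"].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} measurements lacking a housekeeping Ct", stacklevel=2
        )
        tgt = tgt.dropna(subset=["ct_hk"])
    tgt["dct"] = tgt["ct"] - tgt["ct_hk"]

    records = []
    for gene, sub in tgt.groupby("gene", sort=True):
        ctrl = sub[sub["group"] == control_group]
        if ctrl.empty:
            raise ValidationError(f"gene {gene!r} has no control-group measurements")
        dct_ctrl = ctrl["dct"].mean()
        for group, g in sub.groupby("group", sort=True):
            ddct = g["dct"].mean() - dct_ctrl
            rep_folds = np.power(2.0, -(g["dct"].to_numpy() - dct_ctrl))
            records.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": len(g),
                    "ddct": ddct,
                    "fold": 2.0 ** (-ddct),
                    "fold_sem": float(np.std(rep_folds, ddof=1) / math.sqrt(len(g)))
                    if len(g) > 1
                    else 0.0,
                    "per_replicate_folds": rep_folds,
                }
            )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# four-parameter logistic


@dataclass(frozen=True)
class StandardCurve:
    """Fitted 4PL standard curve."""

    a: float  # response at zero concentration (lower asymptote for b > 0)
    d: float  # response at infinite concentration
    c: float  # inflection (EC50) concentration
    b: float  # Hill slope
    residuals: np.ndarray = field(repr=False, default=None)
    concentration_range: tuple[float, float] = (0.0, math.inf)

    def __call__(self, x):
        return logistic4(x, self.a, self.d, self.c, self.b)

    def inverse(self, od: float) -> float:
        return inverse_4pl(self, od)


def logistic4(x, a: float, d: float, c: float, b: float):
    """4PL response y = d + (a - d) / (1 + (x/c)^b); array-friendly in x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / c) ** b, np.inf if b < 0 else 0.0)
    return d + (a - d) / (1.0 + ratio)


def fit_4pl(
    concentrations,
    responses,
    n_starts: int = 8,
    seed: int = 0,
) -> StandardCurve:
    """Least-squares 4PL fit with multi-start heuristic initialisation.

    Initials: asymptotes from the response extremes, c from the
    concentration nearest mid-response, b = +/-1; additional starts
    jitter (c, b) with a seeded generator.  Requires >= 5 distinct
    concentrations.  Raises :class:`AssayError` when no start converges
    to a finite solution.
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.shape != y.shape:
        raise ValidationError("concentrations and responses must have equal length")
    if np.unique(x).size < 5:
        raise ValidationError("at least 5 distinct concentrations are required")
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if np.any(x < 0):
        raise ValidationError("concentrations must be >= 0")

    y_lo, y_hi = float(y.min()), float(y.max())
    if y_hi - y_lo < 1e-12:
        raise AssayError("degenerate data: responses are constant, 4PL is unidentifiable")
    mid = 0.5 * (y_lo + y_hi)
    pos = x[x > 0]
    c0 = float(pos[np.argmin(np.abs(y[x > 0] - mid))]) if pos.size else 1.0

    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    # parameterize as (a, d, log_c, b)
    def residual(p):
        a, d, logc, b = p
        return logistic4(x, a, d, math.exp(logc), b) - y

    rng = np.random.default_rng(seed)
    spans = y_hi - y_lo
    starts = []
    base_b = 1.0 if increasing else 1.0  # sign handled via a/d ordering
    if increasing:
        starts.append((y_lo, y_hi, math.log(c0), base_b))
    else:
        starts.append((y_hi, y_lo, math.log(c0), base_b))
    for _ in range(n_starts - 1):
        jc = math.log(c0) + rng.normal(0, 0.7)
        jb = abs(base_b * math.exp(rng.normal(0, 0.5)))
        if increasing:
            starts.append((y_lo - 0.05 * spans, y_hi + 0.05 * spans, jc, jb))
        else:
            starts.append((y_hi + 0.05 * spans, y_lo - 0.05 * spans, jc, jb))

    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise AssayError(
            "4PL fit failed to converge from any start; "
            f"data range y=[{y_lo:g},{y_hi:g}], x=[{x.min():g},{x.max():g}]"
        )
    a, d, logc, b = best.x
    return StandardCurve(
        a=float(a),
        d=float(d),
        c=float(math.exp(logc)),
        b=float(b),
        residuals=best.fun,
        concentration_range=(float(x[x > 0].min()) if (x > 0).any() else 0.0, float(x.max())),
    )


def inverse_4pl(curve: StandardCurve, od: float) -> float:
    """Invert the 4PL: concentration producing optical density ``od``.

    x = c * ((a - od)/(od - d))^(1/b).  Raises :class:`AssayError` when
    ``od`` lies outside the open interval between the asymptotes.
    """
    lo, hi = sorted((curve.a, curve.d))
    if not lo < od < hi:
        raise AssayError(
            f"OD {od:g} outside the invertible range ({lo:g}, {hi:g}) of the standard curve"
        )
    ratio = (curve.a - od) / (od - curve.d)
    return curve.c * ratio ** (1.0 / curve.b)
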