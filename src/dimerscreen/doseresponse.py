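"""Dose-response normalization and four-parameter logistic pharmacology.

Assay signals are normalized to the reference-ligand scale: 0% is the mean
of the vehicle (negative) controls and 100% the mean of the reference-ligand
(positive) controls.  Curves are then fit with the variable-slope 4PL model
on log10 concentration,

    y(x) = bottom + (top - bottom) / (1 + 10^(hill * (log10 EC50 - log10 x)))

so ``top`` is the fitted maximal response (E_max, in % of reference),
``ec50`` the midpoint in molar, and ``hill`` the slope — positive for
agonist curves, negative for inhibition (descending) curves.  The fitted
curve always equals ``(bottom + top)/2`` at the fitted EC50.

Positive-allosteric-modulator potentiation is quantified on fitted tops:
``100 × (top_modulated − top_baseline) / top_baseline`` per modulator
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DataError, DegenerateControlsError

#: 2-fold dilution series, 0.0625-32 µM, in molar.
DEFAULT_DILUTION_M = tuple(0.0625e-6 * 2.0**k for k in range(10))


def four_pl(
    x: np.ndarray | float, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray | float:
    """Variable-slope four-parameter logistic evaluated at concentration ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(ec50) - np.log10(x))))


@dataclass
class FourPLFit:
    """Fitted 4PL parameters on the %-of-reference response scale."""

    bottom: float
    top: float
    ec50: float
    hill: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    rss: float = float("nan")
    n_points: int = 0

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


@dataclass
class PotentiationResult:
    """Percent change of the fitted top caused by a co-applied modulator."""

    modulator_conc: float
    baseline_top: float
    modulated_top: float
    potentiation_pct: float


def normalize_to_reference(raw: pd.DataFrame, mode: str = "subtractive") -> pd.DataFrame:
    """Convert raw signals to percent of the reference-ligand response.

    ``raw`` is a long table with columns ``compound_id, conc_molar,
    replicate, value, role`` where control rows carry role ``pos``/``neg``.
    Sample rows get a ``response`` column; in the default subtractive mode

        response% = 100 (x - mean(neg)) / (mean(pos) - mean(neg))

    while ``mode="ratio"`` divides by the positive-control mean only.
    """
    required = {"value", "role"}
    if not required.issubset(raw.columns):
        raise DataError("dose-response table needs 'value' and 'role' columns")
    pos = raw.loc[raw["role"] == "pos", "value"].to_numpy(dtype=float)
    neg = raw.loc[raw["role"] == "neg", "value"].to_numpy(dtype=float)
    if pos.size < 1 or neg.size < 1:
        raise DataError("need at least one pos and one neg control row")
    mean_pos, mean_neg = pos.mean(), neg.mean()
    if mean_pos == mean_neg:
        raise DegenerateControlsError("positive and negative control means coincide")
    out = raw[raw["role"] == "sample"].copy()
    x = out["value"].to_numpy(dtype=float)
    if mode == "subtractive":
        out["response"] = 100.0 * (x - mean_neg) / (mean_pos - mean_neg)
    elif mode == "ratio":
        if mean_pos == 0:
            raise DegenerateControlsError("positive control mean is zero")
        out["response"] = 100.0 * x / mean_pos
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out.reset_index(drop=True)


def _extract_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        conc_col = "conc_molar" if "conc_molar" in curve.columns else "concentration"
        resp_col = "response" if "response" in curve.columns else "value"
        x = curve[conc_col].to_numpy(dtype=float)
        y = curve[resp_col].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in curve)
    if np.any(x <= 0):
        raise DataError("concentrations must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise DataError("responses must be finite")
    return x, y


def fit_4pl(
    curve,
    direction: str | None = None,
    maxfev: int = 20000,
) -> FourPLFit:
    """Least-squares 4PL fit of a normalized dose-response curve.

    ``curve`` is either a DataFrame with ``conc_molar`` and ``response``
    columns (replicates as individual rows, unweighted) or an ``(x, y)``
    pair.  ``direction`` may constrain the Hill slope sign
    (``"ascending"``/``"descending"``); the default infers the sign from
    the data for initialization only.

    Initialization comes from data quantiles: the extreme per-concentration
    means seed bottom/top and the concentration whose mean is nearest the
    midpoint seeds EC50.  Non-convergence and flat (span-less) curves are
    returned with ``converged=False`` rather than raised.
    """
    x, y = _extract_xy(curve)
    if np.unique(x).size < 4:
        raise DataError("need at least 4 distinct concentrations")

    # per-concentration means for initialization
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    gm = np.array([ys[xs == u].mean() for u in uniq])
    b0, t0 = float(gm.min()), float(gm.max())
    span = t0 - b0
    scale = max(abs(b0), abs(t0), 1.0)

    slope_sign = np.sign(np.corrcoef(np.log10(xs), ys)[0, 1]) if span > 0 else 0.0
    if direction == "ascending":
        slope_sign = 1.0
    elif direction == "descending":
        slope_sign = -1.0
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    if slope_sign == 0.0 or not np.isfinite(slope_sign):
        slope_sign = 1.0
    if slope_sign < 0:
        # descending: top is the low-concentration plateau
        b0, t0 = t0, b0

    mid = (b0 + t0) / 2.0
    log_ec50_0 = float(np.log10(uniq[np.argmin(np.abs(gm - mid))]))
    p0 = [b0, t0, log_ec50_0, slope_sign * 1.0]

    def model(logx, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))

    if direction is None:
        bounds = (-np.inf, np.inf)
    elif direction == "ascending":
        bounds = ([-np.inf, -np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf, np.inf])
    else:
        bounds = ([-np.inf, -np.inf, -np.inf, -np.inf], [np.inf, np.inf, np.inf, 0.0])

    converged = True
    try:
        popt, pcov = curve_fit(
            model,
            np.log10(x),
            y,
            p0=p0,
            bounds=bounds,
            maxfev=maxfev,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, ValueError):
        popt = np.array(p0, dtype=float)
        pcov = np.full((4, 4), np.nan)
        converged = False

    bottom, top, log_ec50, hill = (float(v) for v in popt)
    resid = y - model(np.log10(x), *popt)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    # a span-less fit cannot place the midpoint: flag it
    if abs(top - bottom) < 1e-8 * scale or not np.all(np.isfinite(popt)):
        converged = False
    se = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        "ec50": float(perr[2] * np.log(10.0) * 10.0**log_ec50),
        "hill": float(perr[3]),
    }
    return FourPLFit(
        bottom=bottom,
        top=top,
        ec50=float(10.0**log_ec50),
        hill=hill,
        se=se,
        converged=converged,
        rss=rss,
        n_points=int(y.size),
    )


def fit_inhibition(curve, maxfev: int = 20000) -> FourPLFit:
    """4PL fit constrained to a descending response (IC50 curve).

    The fitted ``ec50`` is the IC50; ``top`` is the low-concentration
    plateau and the Hill slope is non-positive.
    """
    return fit_4pl(curve, direction="descending", maxfev=maxfev)


def potentiation_analysis(
    baseline_curve,
    modulated_curves: Mapping[float, object],
    direction: str | None = None,
) -> list[PotentiationResult]:
    """Percent potentiation of the fitted top per modulator concentration.

    All curves must already be normalized on the same control scale.
    """
    base = fit_4pl(baseline_curve, direction=direction)
    if base.top <= 0:
        raise DataError("baseline fitted top <= 0; potentiation undefined")
    out = []
    for conc in sorted(modulated_curves):
        fit = fit_4pl(modulated_curves[conc], direction=direction)
        out.append(
            PotentiationResult(
                modulator_conc=float(conc),
                baseline_top=base.top,
                modulated_top=fit.top,
                potentiation_pct=100.0 * (fit.top - base.top) / base.top,
            )
        )
    return out
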