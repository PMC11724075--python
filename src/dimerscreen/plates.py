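"""Plate-level statistics for a primary dimerization screen.

Raw luminescence plates carry systematic row, column and edge artifacts on
top of the biological signal.  The standard robust treatment is Tukey median
polish per plate (an additive decomposition ``value = grand + row + col +
residual`` obtained by alternately sweeping row and column medians), followed
by conversion of the residuals to B-scores: residual divided by ``1.4826 ×
MAD`` of the plate's sample-well residuals.  Because the scale is per plate,
B-scores are directly comparable across plates and the screen-wide top-N
triage can rank all sample wells together.

Confirmation-screen hits are then called on raw signal against a threshold of
``mean(negative controls) + 3 × SD`` with the sample standard deviation
(``ddof=1``); a well is a hit only if its signal is strictly above the
threshold.

Control wells never enter the polish nor the MAD and never receive a B-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    DegeneratePlateError,
    EmptySelectionError,
    InsufficientControlsError,
)

#: Consistency constant making the MAD an unbiased scale estimate under normality.
MAD_SCALE = 1.4826

SAMPLE, POS, NEG, EMPTY = "sample", "pos", "neg", "empty"


@dataclass
class PlateGrid:
    """One plate of raw well signals with per-well roles and compound ids.

    ``values``, ``roles`` and ``compound_ids`` are same-shape 2-D arrays;
    roles take values ``sample``/``pos``/``neg``/``empty`` and every sample
    well must carry a non-empty compound id.
    """

    plate_id: str
    values: np.ndarray
    roles: np.ndarray
    compound_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        if self.values.ndim != 2:
            raise DataError("plate values must be a 2-D matrix")
        if self.roles.shape != self.values.shape or self.compound_ids.shape != self.values.shape:
            raise DataError("values, roles and compound_ids must share one shape")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DataError("plate values must be finite and non-negative")
        sample = self.sample_mask
        ids = self.compound_ids[sample]
        if any(not i for i in ids):
            raise DataError("every sample well needs a compound id")

    @property
    def sample_mask(self) -> np.ndarray:
        return self.roles == SAMPLE

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MedianPolishDecomposition:
    """Additive grand/row/column effects plus residuals from median polish."""

    grand_effect: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_sweeps: int
    converged: bool

    def fitted(self) -> np.ndarray:
        """Grand + row + column effects, broadcast to the plate shape."""
        return (
            self.grand_effect
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


@dataclass
class BScorePlate:
    """B-scores for one plate; control wells carry NaN."""

    plate_id: str
    b_scores: np.ndarray
    robust_scale: float
    source: MedianPolishDecomposition


@dataclass
class HitCall:
    compound_id: str
    confirmation_signal: float
    threshold: float
    is_hit: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_hit = self.confirmation_signal > self.threshold


def median_polish(
    values: np.ndarray,
    max_sweeps: int = 10,
    tol: float | None = None,
    mask: np.ndarray | None = None,
) -> MedianPolishDecomposition:
    """Tukey median polish of a plate matrix.

    Rows are swept first, then columns, for at most ``max_sweeps`` full
    sweeps or until the largest median removed in a sweep drops below
    ``tol`` (default ``1e-6 ×`` the plate median absolute value).

    Parameters
    ----------
    values
        2-D matrix of raw signals, at least 2×2.
    mask
        Optional boolean matrix; ``False`` wells (e.g. controls) are
        excluded from every median and get NaN residuals.

    Notes
    -----
    Residuals are recomputed at the end as ``values − fitted`` so the
    decomposition identity holds to machine precision on included wells.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DataError("median polish needs a matrix of at least 2x2")
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise DataError("mask shape must match values")
    if not np.all(np.isfinite(arr[mask])):
        raise DataError("plate contains non-finite entries")

    work = np.where(mask, arr, np.nan)
    if tol is None:
        tol = 1e-6 * max(float(np.nanmedian(np.abs(work))), 1.0)

    n_rows, n_cols = arr.shape
    grand = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    resid = work.copy()
    n_sweeps = 0
    converged = False
    with warnings.catch_warnings():
        # fully-masked rows/columns legitimately produce all-NaN slices
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for _ in range(max_sweeps):
            rm = np.nan_to_num(np.nanmedian(resid, axis=1))
            resid -= rm[:, None]
            row_eff += rm
            shift = np.median(row_eff)
            row_eff -= shift
            grand += shift

            cm = np.nan_to_num(np.nanmedian(resid, axis=0))
            resid -= cm[None, :]
            col_eff += cm
            shift = np.median(col_eff)
            col_eff -= shift
            grand += shift

            n_sweeps += 1
            if max(np.abs(rm).max(initial=0.0), np.abs(cm).max(initial=0.0)) < tol:
                converged = True
                break

    fitted = grand + row_eff[:, None] + col_eff[None, :]
    resid = np.where(mask, arr - fitted, np.nan)
    return MedianPolishDecomposition(
        grand_effect=float(grand),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        n_sweeps=n_sweeps,
        converged=converged,
    )


def b_score(plate: PlateGrid, polish: MedianPolishDecomposition | None = None) -> BScorePlate:
    """B-scores of a plate's sample wells.

    ``b = residual / (1.4826 × MAD)`` with the MAD taken about the median of
    the sample-well residuals.  Control wells are excluded from the polish
    (when computed here) and from the MAD, and carry NaN in the output.
    """
    sample = plate.sample_mask
    if polish is None:
        polish = median_polish(plate.values, mask=sample)
    resid = polish.residuals
    sample_res = resid[sample]
    sample_res = sample_res[np.isfinite(sample_res)]
    if sample_res.size == 0:
        raise DataError("plate has no polished sample wells")
    mad = float(np.median(np.abs(sample_res - np.median(sample_res))))
    robust_scale = MAD_SCALE * mad
    if robust_scale == 0.0:
        raise DegeneratePlateError(
            f"plate {plate.plate_id!r}: all sample residuals identical, B-scores undefined"
        )
    scores = np.where(sample, resid / robust_scale, np.nan)
    return BScorePlate(
        plate_id=plate.plate_id,
        b_scores=scores,
        robust_scale=robust_scale,
        source=polish,
    )


def score_table(plates: Sequence[PlateGrid], scored: Sequence[BScorePlate]) -> pd.DataFrame:
    """Long-format table of all sample-well B-scores across plates."""
    rows = []
    for plate, sc in zip(plates, scored, strict=True):
        ii, jj = np.nonzero(plate.sample_mask)
        for i, j in zip(ii, jj):
            rows.append(
                {
                    "compound_id": plate.compound_ids[i, j],
                    "plate_id": plate.plate_id,
                    "row": int(i),
                    "col": int(j),
                    "b_score": float(sc.b_scores[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["compound_id", "plate_id", "row", "col", "b_score"])


def select_top_hits(
    scored_plates: Sequence[BScorePlate],
    n: int,
    plates: Sequence[PlateGrid] | None = None,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank all sample wells by B-score and return the top ``n``.

    Ties at the selection boundary are broken by ascending compound id so the
    triage is reproducible.  Provide either the source ``plates`` (to build
    the score table) or a prebuilt ``table``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table is None:
        if plates is None:
            raise ValueError("either plates or table is required")
        table = score_table(plates, scored_plates)
    if table.empty:
        raise EmptySelectionError("no scored sample wells to select from")
    if not np.all(np.isfinite(table["b_score"].to_numpy())):
        raise DataError("every sample well must carry a finite B-score")
    ordered = table.sort_values(
        ["b_score", "compound_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(min(n, len(ordered))).reset_index(drop=True)


def confirmation_threshold(neg_controls: Iterable[float]) -> float:
    """Hit threshold: mean of the negative controls plus three sample SDs."""
    vals = np.asarray(list(neg_controls), dtype=float)
    if vals.size < 2:
        raise InsufficientControlsError("need at least 2 negative-control values")
    if not np.all(np.isfinite(vals)):
        raise DataError("negative controls must be finite")
    return float(vals.mean() + 3.0 * vals.std(ddof=1))


def call_hits(
    confirm: Iterable[tuple[str, float]], threshold: float
) -> list[HitCall]:
    """Call hits on confirmation signals: strictly above threshold wins.

    Output order equals input order.
    """
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    return [HitCall(cid, float(sig), float(threshold)) for cid, sig in confirm]
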