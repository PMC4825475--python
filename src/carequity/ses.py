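"""Composite socio-economic status (SES) index for survey respondents.

The index combines four items — occupation, education, area
socio-economic cluster (SEC) and housing — each brought onto an ordered
1–5 scale.  The first three are integer survey codes grouped monotonely
into five categories; the housing item is ln(rooms * SEC), linearly
rescaled onto [1, 5] using the dataset's own minimum and maximum so the
four items share a range.  The composite score is the equally-weighted
(arithmetic) mean of the four item values, and respondents are split at
the empirical 33.3% and 66.7% score quantiles into low / middle / high
tertiles.  Internal consistency of the four items is summarized by
Cronbach's alpha (raw and standardized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinningMap",
    "DEFAULT_BINNING",
    "RoomsCalibration",
    "SesItems",
    "SesMetadata",
    "categorize_item",
    "rooms_item",
    "calibrate_rooms",
    "ses_score",
    "tertile_cutoffs",
    "assign_tertile",
    "cronbach_alpha",
    "assign_ses",
]

TERTILE_LABELS = ("low", "middle", "high")


@dataclass(frozen=True)
class BinningMap:
    """Monotone grouping of raw survey codes into ordered categories 1-5.

    The default groups the 11 occupation codes, 7 education codes and 10
    SEC clusters into near-even bands; any override must stay total over
    the declared code range and order-preserving.
    """

    occupation: Mapping[int, int]
    education: Mapping[int, int]
    sec: Mapping[int, int]

    _RANGES = {"occupation": (1, 11), "education": (0, 6), "sec": (1, 10)}

    def __post_init__(self) -> None:
        for item, (lo, hi) in self._RANGES.items():
            mapping = getattr(self, item)
            codes = sorted(mapping)
            if codes != list(range(lo, hi + 1)):
                raise ValueError(
                    f"{item} map must cover every raw code {lo}..{hi}, got {codes}"
                )
            cats = [mapping[c] for c in codes]
            if any(not 1 <= c <= 5 for c in cats):
                raise ValueError(f"{item} categories must lie in 1..5")
            if any(b < a for a, b in zip(cats, cats[1:])):
                raise ValueError(f"{item} map is not order-preserving: {cats}")

    def item(self, name: str) -> Mapping[int, int]:
        if name not in self._RANGES:
            raise KeyError(f"unknown SES item {name!r}")
        return getattr(self, name)


DEFAULT_BINNING = BinningMap(
    occupation={1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 3, 7: 4, 8: 4, 9: 4, 10: 5, 11: 5},
    education={0: 1, 1: 1, 2: 2, 3: 3, 4: 4, 5: 4, 6: 5},
    sec={1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 4, 8: 4, 9: 5, 10: 5},
)


def categorize_item(raw_code: int, mapping: Mapping[int, int], item: str = "item") -> int:
    """Map a raw survey code to its ordered 1-5 category."""
    try:
        return int(mapping[int(raw_code)])
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"raw code {raw_code!r} is out of range for SES item {item!r}"
        ) from None


@dataclass(frozen=True)
class RoomsCalibration:
    """Dataset min/max of ln(rooms * SEC), stored with a run for reproducibility."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(
                f"degenerate rooms calibration: min={self.min} must be < max={self.max}"
            )


def calibrate_rooms(rooms: np.ndarray, sec_raw: np.ndarray) -> RoomsCalibration:
    rooms = np.asarray(rooms, dtype=float)
    sec_raw = np.asarray(sec_raw, dtype=float)
    if np.any(rooms <= 0) or np.any(sec_raw < 1):
        raise ValueError("rooms must be positive and SEC clusters >= 1")
    ln = np.log(rooms * sec_raw)
    return RoomsCalibration(float(ln.min()), float(ln.max()))


def rooms_item(rooms: float, sec_raw: int, calib: RoomsCalibration):
    """Housing item: ln(rooms * SEC) min-max rescaled onto [1, 5].

    Accepts scalars or arrays; values outside the calibration range are
    clipped to the [1, 5] endpoints.
    """
    rooms = np.asarray(rooms, dtype=float)
    sec = np.asarray(sec_raw, dtype=float)
    if np.any(rooms <= 0):
        raise ValueError("number of rooms must be positive")
    if np.any(sec < 1):
        raise ValueError("SEC cluster must be >= 1")
    value = 1.0 + 4.0 * (np.log(rooms * sec) - calib.min) / (calib.max - calib.min)
    out = np.clip(value, 1.0, 5.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SesItems:
    """The four 1-5 item values of one respondent."""

    occupation_cat: int
    education_cat: int
    sec_cat: int
    rooms_item: float

    def __post_init__(self) -> None:
        for name in ("occupation_cat", "education_cat", "sec_cat"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValueError(f"{name} must be an integer in 1..5, got {v!r}")
        if not 1.0 <= self.rooms_item <= 5.0:
            raise ValueError(f"rooms_item must lie in [1, 5], got {self.rooms_item}")

    def values(self) -> tuple[float, float, float, float]:
        return (
            float(self.occupation_cat),
            float(self.education_cat),
            float(self.sec_cat),
            float(self.rooms_item),
        )


def ses_score(items: SesItems) -> float:
    """Equally-weighted composite score: the mean of the four item values."""
    return float(np.mean(items.values()))


def tertile_cutoffs(scores) -> tuple[float, float]:
    """Empirical 33.3% and 66.7% quantiles of the composite scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("tertile cutoffs need at least 3 scores")
    p33, p67 = np.quantile(scores, [1 / 3, 2 / 3])
    return float(p33), float(p67)


def assign_tertile(score, cutoffs: tuple[float, float]):
    """low if score <= p33, middle if p33 < score <= p67, else high.

    Closed-right intervals: a score exactly at a cutoff belongs to the
    lower group.  Vectorized over arrays.
    """
    p33, p67 = cutoffs
    score = np.asarray(score, dtype=float)
    out = np.where(score <= p33, "low", np.where(score <= p67, "middle", "high"))
    return str(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    alpha_standardized: float


def cronbach_alpha(item_matrix) -> AlphaResult:
    """Cronbach's alpha of a respondents x items matrix (raw and standardized).

    Raw: (k/(k-1)) * (1 - sum of item variances / variance of row sums).
    Standardized: k*rbar / (1 + (k-1)*rbar) with rbar the mean off-diagonal
    inter-item correlation.  Sample variances (ddof=1) throughout.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 respondents and >=2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing cells")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    item_vars = np.var(x, axis=0, ddof=1)
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    corr = np.corrcoef(x, rowvar=False)
    off = corr[~np.eye(k, dtype=bool)]
    rbar = float(np.mean(off))
    alpha_std = k * rbar / (1.0 + (k - 1) * rbar)
    return AlphaResult(float(alpha), float(alpha_std))


@dataclass
class SesMetadata:
    """Sidecar describing one SES-index run: calibration, cutoffs, alpha, exclusions."""

    cutoffs: tuple[float, float]
    rooms_calibration: RoomsCalibration
    alpha: float
    alpha_standardized: float
    n_respondents: int
    n_excluded_missing: int
    binning: BinningMap = field(repr=False, default=DEFAULT_BINNING)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoffs": list(self.cutoffs),
                "rooms_calibration": [self.rooms_calibration.min, self.rooms_calibration.max],
                "alpha": self.alpha,
                "alpha_standardized": self.alpha_standardized,
                "n_respondents": self.n_respondents,
                "n_excluded_missing": self.n_excluded_missing,
                "binning": {
                    item: {str(k): v for k, v in sorted(getattr(self.binning, item).items())}
                    for item in ("occupation", "education", "sec")
                },
            },
            indent=2,
        )


_ITEM_COLUMNS = ("occupation", "education", "sec", "rooms")


def assign_ses(
    records: pd.DataFrame,
    binning: BinningMap = DEFAULT_BINNING,
    cutoffs: tuple[float, float] | None = None,
    columns: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, SesMetadata]:
    """Add ``ses_score`` and ``ses_tertile`` columns to respondent records.

    Rows with any missing SES item are excluded from the returned frame
    (their number is reported in the metadata).  *columns* may rename
    the expected ``occupation`` / ``education`` / ``sec`` / ``rooms``
    inputs; *cutoffs* overrides the empirical tertile cutoffs.
    """
    colmap = {c: c for c in _ITEM_COLUMNS}
    if columns:
        colmap.update(columns)
    missing_cols = [colmap[c] for c in _ITEM_COLUMNS if colmap[c] not in records.columns]
    if missing_cols:
        raise KeyError(f"records lack SES item columns {missing_cols}")
    df = records.copy()
    item_data = df[[colmap[c] for c in _ITEM_COLUMNS]]
    complete = item_data.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    df = df.loc[complete].copy()

    occ = df[colmap["occupation"]].astype(int).map(lambda c: categorize_item(c, binning.occupation, "occupation"))
    edu = df[colmap["education"]].astype(int).map(lambda c: categorize_item(c, binning.education, "education"))
    sec = df[colmap["sec"]].astype(int).map(lambda c: categorize_item(c, binning.sec, "sec"))
    calib = calibrate_rooms(df[colmap["rooms"]].to_numpy(), df[colmap["sec"]].to_numpy())
    rooms = rooms_item(df[colmap["rooms"]].to_numpy(), df[colmap["sec"]].to_numpy(), calib)

    matrix = np.column_stack([occ, edu, sec, rooms]).astype(float)
    score = matrix.mean(axis=1)
    if cutoffs is None:
        cutoffs = tertile_cutoffs(score)
    df["ses_score"] = score
    df["ses_tertile"] = assign_tertile(score, cutoffs)
    a = cronbach_alpha(matrix)
    meta = SesMetadata(
        cutoffs=cutoffs,
        rooms_calibration=calib,
        alpha=a.alpha,
        alpha_standardized=a.alpha_standardized,
        n_respondents=len(df),
        n_excluded_missing=n_excluded,
        binning=binning,
    )
    return df, meta
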