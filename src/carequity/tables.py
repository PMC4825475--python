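"""Dense multiway frequency tables over named categorical axes.

The survey analysis runs entirely on small contingency tables (at most
3 x 2 x 2 x 3 x 2 = 72 cells), so tables are stored densely as numpy
arrays with one axis per categorical variable.  Counts are kept as
floats so that fitted (expected) tables produced by iterative
proportional fitting live in the same container as observed tables.

The canonical five survey axes — residential location, age band, GP
visit, composite SES tertile and specialist (SD) visit — are exposed as
module constants; the published 72-cell frequency table ships as a
packaged CSV fixture loadable with :func:`load_utilization_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalAxis",
    "FrequencyTable",
    "crosstab",
    "read_table_csv",
    "write_table_csv",
    "load_utilization_table",
    "LOCATION",
    "AGE",
    "SES",
    "VIS_GP",
    "VIS_SD",
    "SURVEY_AXES",
]


@dataclass(frozen=True)
class CategoricalAxis:
    """A named categorical variable with an ordered set of category labels.

    The last category is the reference category by convention, matching
    dummy (reference-cell) coding of log-linear parameters.
    """

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(self.categories) < 2:
            raise ValueError(f"axis {self.name!r} needs >=2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"axis {self.name!r} has duplicate category labels")

    @property
    def reference(self) -> str:
        return self.categories[-1]

    @property
    def size(self) -> int:
        return len(self.categories)

    def index(self, label: str) -> int:
        try:
            return self.categories.index(label)
        except ValueError:
            raise KeyError(
                f"unknown category {label!r} on axis {self.name!r}; "
                f"expected one of {list(self.categories)}"
            ) from None


#: Canonical axes of the utilization survey, in fixture column order.
LOCATION = CategoricalAxis("location", ("peripheral", "intermediate", "central"))
AGE = CategoricalAxis("age", ("ge60", "lt60"))
VIS_GP = CategoricalAxis("vis_gp", ("yes", "no"))
SES = CategoricalAxis("ses", ("low", "middle", "high"))
VIS_SD = CategoricalAxis("vis_sd", ("yes", "no"))

SURVEY_AXES: tuple[CategoricalAxis, ...] = (LOCATION, AGE, VIS_GP, SES, VIS_SD)


@dataclass
class FrequencyTable:
    """A dense multiway table of non-negative cell counts.

    Parameters
    ----------
    axes
        Ordered categorical axes; the counts array has one dimension per
        axis, in the same order.
    counts
        Non-negative array of shape ``(axes[0].size, axes[1].size, ...)``.
        Stored as float so fitted tables fit in the same type.
    """

    axes: tuple[CategoricalAxis, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.axes = tuple(self.axes)
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate axis names: {names}")
        self.counts = np.asarray(self.counts, dtype=float)
        expected = tuple(a.size for a in self.axes)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match axes {expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative cell counts")

    # -- basic introspection -------------------------------------------------

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def axis(self, name: str) -> CategoricalAxis:
        for a in self.axes:
            if a.name == name:
                return a
        raise KeyError(f"no axis named {name!r}; table has {self.axis_names}")

    def axis_position(self, name: str) -> int:
        for i, a in enumerate(self.axes):
            if a.name == name:
                return i
        raise KeyError(f"no axis named {name!r}; table has {self.axis_names}")

    def cell(self, **labels: str) -> float:
        """Count of the single cell addressed by one label per axis."""
        if set(labels) != set(self.axis_names):
            raise KeyError(
                f"cell() needs exactly one label per axis {self.axis_names}, "
                f"got {sorted(labels)}"
            )
        idx = tuple(a.index(labels[a.name]) for a in self.axes)
        return float(self.counts[idx])

    # -- marginalization -----------------------------------------------------

    def collapse(self, keep: Iterable[str]) -> "FrequencyTable":
        """Sum the table over every axis not named in *keep*.

        The retained axes keep the table's own order, so collapsing is
        associative and order-insensitive in *keep*.  The grand total is
        preserved exactly.
        """
        keep = set(keep)
        unknown = keep - set(self.axis_names)
        if unknown:
            raise KeyError(f"unknown axes {sorted(unknown)}; table has {self.axis_names}")
        drop = tuple(i for i, a in enumerate(self.axes) if a.name not in keep)
        kept_axes = tuple(a for a in self.axes if a.name in keep)
        summed = self.counts.sum(axis=drop) if drop else self.counts.copy()
        return FrequencyTable(kept_axes, np.asarray(summed, dtype=float))

    def margin(self, keep: Iterable[str]) -> np.ndarray:
        """Marginal count array over the named axes (table axis order)."""
        return self.collapse(keep).counts

    # -- conversion ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long (tidy) representation: one row per cell plus a ``count`` column."""
        index = pd.MultiIndex.from_product(
            [a.categories for a in self.axes], names=self.axis_names
        )
        return (
            pd.Series(self.counts.ravel(), index=index, name="count")
            .reset_index()
        )

    def allclose(self, other: "FrequencyTable", atol: float = 0.0) -> bool:
        return (
            self.axes == other.axes
            and np.allclose(self.counts, other.counts, rtol=0.0, atol=atol)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return self.axes == other.axes and np.array_equal(self.counts, other.counts)


def crosstab(records: pd.DataFrame, axes: Sequence[CategoricalAxis]) -> FrequencyTable:
    """Cross-tabulate respondent records into a dense frequency table.

    *records* must carry one column per axis name holding category
    labels.  A label outside the axis's category list raises a
    ``ValueError`` naming the first offending row.
    """
    axes = tuple(axes)
    shape = tuple(a.size for a in axes)
    counts = np.zeros(shape, dtype=float)
    if len(records) == 0:
        return FrequencyTable(axes, counts)
    flat = np.zeros(len(records), dtype=np.int64)
    for a in axes:
        if a.name not in records.columns:
            raise KeyError(f"records lack a column for axis {a.name!r}")
        codes = pd.Categorical(records[a.name], categories=a.categories).codes
        if (codes < 0).any():
            bad = int(np.flatnonzero(codes < 0)[0])
            raise ValueError(
                f"row {records.index[bad]}: unknown category "
                f"{records[a.name].iloc[bad]!r} on axis {a.name!r}"
            )
        flat = flat * a.size + codes
    np.add.at(counts.ravel(), flat, 1.0)
    return FrequencyTable(axes, counts)


def write_table_csv(table: FrequencyTable, path) -> None:
    """Write a table in long format: one column per axis plus ``count``."""
    frame = table.to_frame()
    counts = frame["count"]
    if np.allclose(counts, np.round(counts)):
        frame["count"] = counts.astype(np.int64)
    frame.to_csv(path, index=False)


def read_table_csv(path, axes: Sequence[CategoricalAxis] | None = None) -> FrequencyTable:
    """Read a long-format CSV into a :class:`FrequencyTable`.

    When *axes* is omitted, category order follows first appearance in
    the file.  Duplicate cell rows are an error; cells absent from the
    file are filled with zero (with a warning).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "count" not in frame.columns:
        raise ValueError(f"{path}: expected a 'count' column")
    axis_cols = [c for c in frame.columns if c != "count"]
    if not axis_cols:
        raise ValueError(f"{path}: no axis columns")
    if axes is None:
        axes = tuple(
            CategoricalAxis(c, tuple(pd.unique(frame[c]))) for c in axis_cols
        )
    else:
        axes = tuple(axes)
        if [a.name for a in axes] != axis_cols:
            # accept any column order; reorder to the declared axes
            missing = [a.name for a in axes if a.name not in axis_cols]
            if missing:
                raise ValueError(f"{path}: missing axis columns {missing}")
            axis_cols = [a.name for a in axes]
    shape = tuple(a.size for a in axes)
    counts = np.full(shape, np.nan)
    for row in frame.itertuples(index=False):
        labels = {c: getattr(row, c) for c in axis_cols}
        idx = tuple(a.index(labels[a.name]) for a in axes)
        if not np.isnan(counts[idx]):
            cell = ", ".join(f"{a.name}={labels[a.name]}" for a in axes)
            raise ValueError(f"{path}: duplicate cell row ({cell})")
        counts[idx] = float(getattr(row, "count"))
    n_missing = int(np.isnan(counts).sum())
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} cell(s) absent from file, filled with 0",
            stacklevel=2,
        )
        counts = np.nan_to_num(counts, nan=0.0)
    return FrequencyTable(axes, counts)


def load_utilization_table() -> FrequencyTable:
    """The published 72-cell utilization frequency table.

    Axes: location (peripheral/intermediate/central), age (>=60 / <60),
    GP visit (yes/no), SES tertile (low/middle/high), specialist visit
    (yes/no).  The cells sum to the 28,968 survey respondents.
    """
    with resources.files("carequity").joinpath("data/table4.csv").open() as fh:
        return read_table_csv(fh, axes=SURVEY_AXES)
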