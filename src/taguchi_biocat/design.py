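"""Three-level orthogonal arrays and factor/level mappings.

An orthogonal array assigns coded levels (1, 2, 3) to each run x factor cell
such that every level appears equally often in each column (balance) and
every ordered pair of levels appears equally often across each pair of
columns (pairwise orthogonality).  The L9 array covers four three-level
factors in nine runs; with it, level means of any response are unconfounded
main-effect estimates under an additive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

__all__ = [
    "FactorSpec",
    "OrthogonalArray",
    "OrthogonalityReport",
    "build_l9",
    "check_orthogonality",
    "decode_design",
    "encode_design",
]

_LEVELS = (1, 2, 3)

# Canonical L9 run order used throughout: run 1 is all-level-1 and the rows
# follow the run sheet of the esterification study this package ships as its
# worked example (see datasets.babassu_study).
_L9_CELLS = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class FactorSpec:
    """A named process factor with exactly three ordered physical levels.

    Parameters
    ----------
    name : str
        Factor label, unique within a design (e.g. ``"Temperature"``).
    unit : str
        Physical unit or label kind (``"degC"``, ``"h"``, ``"%m/m"``,
        ``"FFAs:alcohol"``).
    levels : tuple
        The three physical values (or categorical labels such as molar-ratio
        strings ``"1:1"``) corresponding to coded levels 1, 2, 3.
    """

    name: str
    unit: str
    levels: tuple

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) != 3 or len(set(levels)) != 3:
            raise InvalidDesignError(
                f"factor {self.name!r} needs exactly 3 distinct levels, got {levels!r}"
            )

    def decode(self, code: int):
        """Physical value for a 1-based coded level."""
        if code not in _LEVELS:
            raise InvalidDesignError(f"coded level must be in {{1,2,3}}, got {code!r}")
        return self.levels[code - 1]

    def encode(self, value) -> int:
        """1-based coded level for a physical value (inverse of :meth:`decode`)."""
        try:
            return self.levels.index(value) + 1
        except ValueError:
            raise InvalidDesignError(
                f"value {value!r} is not a level of factor {self.name!r}"
            ) from None


@dataclass(frozen=True)
class OrthogonalArray:
    """Coded design matrix of shape (n_runs, n_factors) over the alphabet {1,2,3}."""

    cells: np.ndarray
    factor_names: tuple = field(default=None)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        if cells.ndim != 2:
            raise InvalidDesignError("design matrix must be two-dimensional")
        object.__setattr__(self, "cells", cells)
        names = self.factor_names
        if names is None:
            names = tuple(f"F{j + 1}" for j in range(cells.shape[1]))
        else:
            names = tuple(names)
            if len(names) != cells.shape[1]:
                raise InvalidDesignError("factor_names length must equal n_factors")
            if len(set(names)) != len(names):
                raise InvalidDesignError("factor names must be unique")
        object.__setattr__(self, "factor_names", names)

    @property
    def n_runs(self) -> int:
        return self.cells.shape[0]

    @property
    def n_factors(self) -> int:
        return self.cells.shape[1]

    def column(self, factor) -> np.ndarray:
        """Coded column for a factor given by name or 0-based index."""
        return self.cells[:, self._factor_index(factor)]

    def _factor_index(self, factor) -> int:
        if isinstance(factor, (int, np.integer)):
            if not 0 <= factor < self.n_factors:
                raise InvalidDesignError(f"factor index {factor} out of range")
            return int(factor)
        try:
            return self.factor_names.index(factor)
        except ValueError:
            raise InvalidDesignError(f"unknown factor {factor!r}") from None

    def with_names(self, names: Sequence[str]) -> "OrthogonalArray":
        return OrthogonalArray(self.cells, tuple(names))

    def to_frame(self) -> pd.DataFrame:
        """Coded run sheet with a 1-based ``run_id`` column."""
        df = pd.DataFrame(self.cells, columns=list(self.factor_names))
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        return df


@dataclass(frozen=True)
class OrthogonalityReport:
    """Outcome of :func:`check_orthogonality`."""

    passed: bool
    unbalanced_columns: tuple
    non_orthogonal_pairs: tuple

    def __bool__(self) -> bool:
        return self.passed


def build_l9(factor_names: Sequence[str] | None = None) -> OrthogonalArray:
    """The standard L9 orthogonal array: 9 runs, 4 three-level columns.

    Run 1 is coded (1,1,1,1); the row order is the canonical run order used
    by all worked examples in this package, so run indices in reports line up
    with the study run sheet.
    """
    return OrthogonalArray(_L9_CELLS.copy(), factor_names and tuple(factor_names))


def check_orthogonality(array: OrthogonalArray) -> OrthogonalityReport:
    """Validate balance and pairwise orthogonality by exhaustive pair counting.

    Balance: each level must appear ``n_runs/3`` times in every column.
    Orthogonality: for every pair of columns each of the 9 ordered level
    pairs must appear ``n_runs/9`` times (exactly once for an L9).

    Raises
    ------
    InvalidDesignError
        If cells contain symbols outside {1,2,3}.
    """
    cells = array.cells
    if not np.isin(cells, _LEVELS).all():
        raise InvalidDesignError("design cells must use the coded alphabet {1,2,3}")

    n = array.n_runs
    unbalanced = []
    if n % 3:
        unbalanced = list(range(array.n_factors))
    else:
        per_level = n // 3
        for j in range(array.n_factors):
            counts = [(cells[:, j] == k).sum() for k in _LEVELS]
            if any(c != per_level for c in counts):
                unbalanced.append(j)

    bad_pairs = []
    if n % 9:
        bad_pairs = [
            (i, j) for i in range(array.n_factors) for j in range(i + 1, array.n_factors)
        ]
    else:
        per_pair = n // 9
        for i in range(array.n_factors):
            for j in range(i + 1, array.n_factors):
                ok = all(
                    ((cells[:, i] == a) & (cells[:, j] == b)).sum() == per_pair
                    for a in _LEVELS
                    for b in _LEVELS
                )
                if not ok:
                    bad_pairs.append((i, j))

    passed = not unbalanced and not bad_pairs
    return OrthogonalityReport(passed, tuple(unbalanced), tuple(bad_pairs))


def decode_design(array: OrthogonalArray, specs: Sequence[FactorSpec]) -> pd.DataFrame:
    """Replace coded levels by physical values, yielding a run sheet.

    Column names come from the specs; a 1-based ``run_id`` column is prepended.
    """
    specs = list(specs)
    if len(specs) != array.n_factors:
        raise InvalidDesignError(
            f"got {len(specs)} factor specs for {array.n_factors} design columns"
        )
    data = {"run_id": np.arange(1, array.n_runs + 1)}
    for j, spec in enumerate(specs):
        data[spec.name] = [spec.decode(int(c)) for c in array.cells[:, j]]
    return pd.DataFrame(data)


def encode_design(run_sheet: pd.DataFrame, specs: Sequence[FactorSpec]) -> OrthogonalArray:
    """Inverse of :func:`decode_design`: physical run sheet back to coded array."""
    specs = list(specs)
    cols = []
    for spec in specs:
        if spec.name not in run_sheet.columns:
            raise InvalidDesignError(f"run sheet lacks a column for factor {spec.name!r}")
        cols.append([spec.encode(v) for v in run_sheet[spec.name]])
    cells = np.array(cols, dtype=int).T
    return OrthogonalArray(cells, tuple(s.name for s in specs))
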