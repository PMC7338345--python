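"""Larger-is-better signal-to-noise analysis for orthogonal-array experiments.

The larger-is-better S/N statistic is

    S/N = -10 * log10( (1/n) * sum_i 1/y_i^2 )   [dB]

over the n replicate responses y_i of a run; for a single observation it
reduces to 20*log10(y).  Maximising S/N simultaneously rewards a large and a
consistent response.  Main effects are summarised in a response table: the
mean S/N at each level of each factor, the delta (range) per factor, and a
rank ordering of factors by delta.  The predicted optimum adds the selected
factors' deviations from the grand mean:

    S/N_pred = mean(S/N) + sum_j ( S/N_j[best level] - mean(S/N) )
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import OrthogonalArray
from .errors import IncompleteDesignError, InvalidResponseError, InvalidSelectionError

__all__ = [
    "ResponseSet",
    "SNRecord",
    "ResponseTable",
    "PredictionResult",
    "snr_larger_is_better",
    "snr_to_response",
    "compute_snr",
    "response_table",
    "predict_optimal_snr",
]


@dataclass(frozen=True)
class ResponseSet:
    """Per-run replicate responses (percent conversion; strictly positive).

    ``responses[i]`` holds the replicate measurements of run ``run_ids[i]``.
    """

    run_ids: tuple
    responses: tuple  # tuple of 1-D float arrays, one per run

    def __post_init__(self) -> None:
        runs = tuple(int(r) for r in self.run_ids)
        resp = tuple(np.atleast_1d(np.asarray(y, dtype=float)) for y in self.responses)
        if len(runs) != len(resp):
            raise InvalidResponseError("run_ids and responses length mismatch")
        for rid, y in zip(runs, resp):
            if y.size < 1:
                raise InvalidResponseError(f"run {rid}: at least one replicate required")
            if not (y > 0).all():
                raise InvalidResponseError(
                    f"run {rid}: responses must be strictly positive, got {y.tolist()}"
                )
        object.__setattr__(self, "run_ids", runs)
        object.__setattr__(self, "responses", resp)

    @classmethod
    def from_single(cls, y: Sequence[float]) -> "ResponseSet":
        """Single-replicate set from one response per run, runs numbered 1..n."""
        y = np.asarray(y, dtype=float)
        return cls(tuple(range(1, y.size + 1)), tuple(np.array([v]) for v in y))

    def __len__(self) -> int:
        return len(self.run_ids)


@dataclass(frozen=True)
class SNRecord:
    run_id: int
    snr: float  # dB


def snr_larger_is_better(y) -> float:
    """Larger-is-better S/N ratio in dB of one run's replicate responses.

    Equals ``20*log10(y)`` for a single replicate.  Raises
    :class:`InvalidResponseError` for any nonpositive response (the statistic
    involves log of 1/y^2).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.size == 0:
        raise InvalidResponseError("empty response set")
    if not (y > 0).all():
        raise InvalidResponseError(f"responses must be strictly positive, got {y.tolist()}")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def snr_to_response(snr: float) -> float:
    """Back-transform a dB value to the response scale: ``10**(snr/20)``.

    Exact inverse of :func:`snr_larger_is_better` for single replicates.
    """
    return float(10.0 ** (np.asarray(snr, dtype=float) / 20.0))


def compute_snr(responses: ResponseSet) -> list[SNRecord]:
    """One larger-is-better S/N record per run."""
    return [
        SNRecord(rid, snr_larger_is_better(y))
        for rid, y in zip(responses.run_ids, responses.responses)
    ]


@dataclass(frozen=True)
class ResponseTable:
    """Main-effects summary: factor x level S/N means, delta and rank.

    Attributes
    ----------
    level_means : pandas.DataFrame
        Index = coded level (1..3), columns = factor names, values in dB.
    delta : pandas.Series
        max - min of each factor's level means (dB).
    rank : pandas.Series
        1 = largest delta; ties broken by column order (leftmost first).
    grand_mean : float
        Mean S/N over all runs (dB).
    """

    level_means: pd.DataFrame
    delta: pd.Series
    rank: pd.Series
    grand_mean: float

    @property
    def factors(self) -> tuple:
        return tuple(self.level_means.columns)

    def best_levels(self) -> dict:
        """Per factor, the coded level with the highest mean S/N (full precision)."""
        return {f: int(self.level_means[f].idxmax()) for f in self.factors}

    def to_frame(self, digits: int | None = None) -> pd.DataFrame:
        """Table-style frame with level rows plus Delta and Rank rows."""
        df = self.level_means.copy()
        if digits is not None:
            df = df.round(digits)
        out = df.astype(object)
        out.index = [str(i) for i in out.index]
        delta = self.delta if digits is None else self.delta.round(digits)
        out.loc["Delta"] = delta.astype(object)
        out.loc["Rank"] = self.rank.astype(int).astype(object)
        out.index.name = "Level"
        return out


def _snr_series(array: OrthogonalArray, snr) -> np.ndarray:
    """Align S/N records (SNRecord list, mapping or array) to design run order."""
    if isinstance(snr, Mapping):
        records = dict(snr)
    elif not isinstance(snr, np.ndarray) and len(snr) and isinstance(next(iter(snr)), SNRecord):
        records = {r.run_id: r.snr for r in snr}
    else:
        vals = np.asarray(list(snr), dtype=float)
        if vals.size != array.n_runs:
            raise IncompleteDesignError(
                f"need {array.n_runs} S/N values, got {vals.size}"
            )
        return vals
    missing = [rid for rid in range(1, array.n_runs + 1) if rid not in records]
    if missing:
        raise IncompleteDesignError(f"missing S/N for runs {missing}")
    return np.array([float(records[rid]) for rid in range(1, array.n_runs + 1)])


def response_table(array: OrthogonalArray, snr) -> ResponseTable:
    """Build the main-effects response table from per-run S/N ratios.

    ``snr`` may be a list of :class:`SNRecord`, a run_id->dB mapping, or a
    sequence of dB values in design run order.
    """
    values = _snr_series(array, snr)
    grand = float(values.mean())
    means = {}
    for name in array.factor_names:
        col = array.column(name)
        means[name] = [float(values[col == k].mean()) for k in (1, 2, 3)]
    level_means = pd.DataFrame(means, index=pd.Index([1, 2, 3], name="level"))
    delta = level_means.max() - level_means.min()
    # rank 1 = largest delta; ties go to the leftmost factor column
    order = sorted(range(len(delta)), key=lambda i: (-delta.iloc[i], i))
    rank = pd.Series(0, index=delta.index, dtype=int)
    for pos, i in enumerate(order, start=1):
        rank.iloc[i] = pos
    return ResponseTable(level_means, delta, rank, grand)


@dataclass(frozen=True)
class PredictionResult:
    """Eq.-style additive prediction of the optimum S/N and response.

    ``predicted_response`` is the single-replicate back-transform
    ``10**(snr/20)``; it can exceed 100% because the prediction is additive
    on the dB scale — such values are flagged (``exceeds_physical_bound``),
    never clipped.
    """

    predicted_snr: float
    predicted_response: float
    selected_factors: tuple
    chosen_levels: dict
    exceeds_physical_bound: bool = field(default=False)


def predict_optimal_snr(
    table: ResponseTable,
    selected_factors: Sequence[str] | None = None,
    chosen_levels: Mapping[str, int] | None = None,
    response_bound: float = 100.0,
) -> PredictionResult:
    """Predicted S/N at a chosen level combination.

    S/N_pred = grand mean + sum over selected factors of
    (level mean - grand mean).  By default all factors are selected at the
    level maximising their mean S/N.  With an empty selection the prediction
    is the grand mean itself.
    """
    if selected_factors is None:
        selected = tuple(table.factors)
    else:
        selected = tuple(selected_factors)
        unknown = [f for f in selected if f not in table.factors]
        if unknown:
            raise InvalidSelectionError(f"unknown factors {unknown}")

    best = table.best_levels()
    levels = {}
    for f in selected:
        k = int(chosen_levels[f]) if chosen_levels and f in chosen_levels else best[f]
        if k not in (1, 2, 3):
            raise InvalidSelectionError(f"factor {f!r}: level {k} not in {{1,2,3}}")
        levels[f] = k

    pred = table.grand_mean + sum(
        float(table.level_means.at[levels[f], f]) - table.grand_mean for f in selected
    )
    resp = snr_to_response(pred)
    over = resp > response_bound
    if over:
        warnings.warn(
            f"predicted response {resp:.1f} exceeds the physical bound "
            f"{response_bound:g}; the dB-additive prediction is reported unclipped",
            stacklevel=2,
        )
    return PredictionResult(float(pred), resp, selected, levels, bool(over))
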