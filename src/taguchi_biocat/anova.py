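"""Taguchi-style ANOVA of S/N ratios with pooling and percent contribution.

For a complete single-replicate three-level design the between-level sum of
squares of factor f is

    SS_f = sum_k n_k * (mean_k - grand_mean)^2,   n_k = runs at level k,

and for a saturated L9 the four factor SS add up exactly to the total SS of
the nine S/N values, leaving zero residual degrees of freedom.  F tests
therefore require pooling: the SS (and df) of factors judged negligible are
folded into a residual term, and each remaining factor is tested with
F = MS_factor / MS_residual against F(df_factor, df_residual).  With
(2, 2) degrees of freedom the survival function has the closed form
P(F > x) = 1/(1+x), a handy analytic cross-check.

Percent contribution of a factor is its share of the total factor SS
(pooled factors included in both numerator set and denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import OrthogonalArray
from .errors import (
    InvalidParameterError,
    InvalidSelectionError,
    NoResidualError,
)
from .snr import _snr_series

__all__ = ["AnovaTable", "factor_ss", "total_ss", "auto_pool", "anova_snr"]

#: SS below this (dB^2) is treated as exactly zero for the degenerate
#: constant-response case, where F, p and contributions are undefined.
_DEGENERATE_SS = 1e-12


def factor_ss(array: OrthogonalArray, snr, factor) -> float:
    """Between-level sum of squares (dB^2) of one factor's S/N means."""
    values = _snr_series(array, snr)
    if isinstance(factor, str) and factor not in array.factor_names:
        raise InvalidSelectionError(f"unknown factor {factor!r}")
    col = array.column(factor)
    grand = values.mean()
    return float(
        sum((col == k).sum() * (values[col == k].mean() - grand) ** 2 for k in (1, 2, 3))
    )


def total_ss(array: OrthogonalArray, snr) -> float:
    """Total corrected sum of squares of the per-run S/N values."""
    values = _snr_series(array, snr)
    return float(((values - values.mean()) ** 2).sum())


def auto_pool(
    array: OrthogonalArray,
    snr,
    strategy: str = "smallest-ss",
    explicit: Sequence[str] | None = None,
    target_residual_df: int = 2,
) -> tuple:
    """Select the factors to pool into the residual.

    ``"smallest-ss"`` pools factors in increasing SS order until the residual
    reaches ``target_residual_df`` degrees of freedom (2 df per pooled
    three-level factor).  ``"explicit"`` returns the user list unchanged.
    A single-factor design pools nothing (the caller will then hit the
    no-residual error downstream).
    """
    if strategy == "explicit":
        return tuple(explicit or ())
    if strategy != "smallest-ss":
        raise InvalidParameterError(f"unknown pooling strategy {strategy!r}")
    if array.n_factors < 2:
        return ()
    ss = {name: factor_ss(array, snr, name) for name in array.factor_names}
    pooled: list[str] = []
    for name in sorted(ss, key=lambda n: (ss[n], array.factor_names.index(n))):
        if 2 * len(pooled) >= target_residual_df:
            break
        if len(pooled) == array.n_factors - 1:
            break  # keep at least one tested factor
        pooled.append(name)
    return tuple(pooled)


@dataclass(frozen=True)
class AnovaTable:
    """Ordered ANOVA rows (factors, Residual, Total) plus the grand mean.

    ``rows`` columns: source, df, ss, ms, f_value, p_value, contribution,
    pooled, significant.  Pooled factors keep their df/SS/contribution but
    carry no MS, F or p of their own (their SS lives on in the residual).
    For a degenerate (constant S/N) input, F, p and contributions are NaN
    and ``degenerate`` is True.
    """

    rows: pd.DataFrame
    grand_mean: float
    alpha: float
    degenerate: bool = False

    def row(self, source: str) -> pd.Series:
        match = self.rows[self.rows["source"] == source]
        if match.empty:
            raise InvalidSelectionError(f"no ANOVA row for source {source!r}")
        return match.iloc[0]


def anova_snr(
    array: OrthogonalArray,
    snr,
    pooled_factors: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> AnovaTable:
    """Pooled ANOVA of per-run S/N ratios.

    Parameters
    ----------
    pooled_factors
        Factors whose SS and df form the residual.  Must be nonempty for a
        saturated design (residual df would otherwise be zero).
    alpha
        Significance level for the ``significant`` flag.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0,1), got {alpha}")
    values = _snr_series(array, snr)
    names = list(array.factor_names)
    pooled = tuple(pooled_factors or ())
    unknown = [f for f in pooled if f not in names]
    if unknown:
        raise InvalidSelectionError(f"unknown pooled factors {unknown}")

    n_runs = array.n_runs
    df_total = n_runs - 1
    ss = {f: factor_ss(array, values, f) for f in names}
    df_f = {f: 2 for f in names}  # three levels -> 2 df each

    # saturated design: all df consumed by factors
    saturated = sum(df_f.values()) == df_total
    resid_df = sum(df_f[f] for f in pooled) + (df_total - sum(df_f.values()))
    resid_ss = sum(ss[f] for f in pooled) + (
        total_ss(array, values) - sum(ss.values())
    )
    if resid_df <= 0:
        raise NoResidualError(
            "no residual degrees of freedom: pool at least one factor "
            "of this saturated design" if saturated else "no residual df"
        )

    ss_all_factors = sum(ss.values())
    degenerate = ss_all_factors < _DEGENERATE_SS
    resid_ms = resid_ss / resid_df

    records = []
    for f in names:
        is_pooled = f in pooled
        ms = ss[f] / df_f[f]
        if degenerate:
            fval = pval = contrib = np.nan
        elif is_pooled or resid_ms <= 0:
            fval = pval = np.nan
            contrib = 100.0 * ss[f] / ss_all_factors
        else:
            fval = ms / resid_ms
            pval = float(stats.f.sf(fval, df_f[f], resid_df))
            contrib = 100.0 * ss[f] / ss_all_factors
        records.append(
            {
                "source": f,
                "df": df_f[f],
                "ss": ss[f],
                "ms": np.nan if is_pooled else ms,
                "f_value": fval,
                "p_value": pval,
                "contribution": contrib,
                "pooled": is_pooled,
                "significant": bool(pval < alpha) if np.isfinite(pval) else False,
            }
        )
    records.append(
        {
            "source": "Residual",
            "df": resid_df,
            "ss": resid_ss,
            "ms": resid_ms,
            "f_value": np.nan,
            "p_value": np.nan,
            "contribution": np.nan,
            "pooled": False,
            "significant": False,
        }
    )
    records.append(
        {
            "source": "Total",
            "df": df_total,
            "ss": total_ss(array, values),
            "ms": np.nan,
            "f_value": np.nan,
            "p_value": np.nan,
            "contribution": np.nan if degenerate else 100.0,
            "pooled": False,
            "significant": False,
        }
    )
    rows = pd.DataFrame.from_records(records)
    return AnovaTable(rows, float(values.mean()), alpha, degenerate)
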