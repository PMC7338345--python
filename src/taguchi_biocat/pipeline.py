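"""End-to-end pipeline: run sheet -> S/N -> response table -> ANOVA -> prediction.

`run_pipeline` consumes a coded or decoded run sheet plus a configuration and
emits the three report tables (per-run S/N, main-effects response table,
pooled ANOVA) together with the additive optimum prediction, in both a
formatted text report and machine-readable JSON carrying the full-precision
numbers.  Rendering is deterministic: identical inputs give identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import snr as snr_mod
from .design import FactorSpec, OrthogonalArray, check_orthogonality, encode_design
from .errors import IncompleteDesignError, InvalidDesignError
from .snr import ResponseSet

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_report", "load_run_sheet"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full analysis.

    ``response_columns`` name the replicate response columns of the run
    sheet; ``pool`` is either the literal ``"auto"`` (smallest-SS pooling to
    2 residual df) or an explicit list of factor names.
    """

    factors: tuple  # FactorSpec, ...
    response_columns: tuple = ("conversion",)
    pool: object = "auto"
    alpha: float = 0.05
    digits: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        factors = tuple(
            FactorSpec(f["name"], f.get("unit", ""), tuple(f["levels"])) for f in d["factors"]
        )
        return cls(
            factors=factors,
            response_columns=tuple(d.get("response_columns", ("conversion",))),
            pool=d.get("pool", "auto"),
            alpha=float(d.get("alpha", 0.05)),
            digits=int(d.get("digits", 1)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class ReportBundle:
    """All pipeline outputs at full precision."""

    snr_table: pd.DataFrame
    response_table: snr_mod.ResponseTable
    anova_table: anova_mod.AnovaTable
    prediction: snr_mod.PredictionResult
    config: PipelineConfig = field(repr=False, default=None)

    def to_json(self) -> str:
        rt = self.response_table
        payload = {
            "snr": {
                str(int(r.run_id)): float(r.snr) for r in self.snr_table.itertuples()
            },
            "response_table": {
                "grand_mean": rt.grand_mean,
                "level_means": {f: list(map(float, rt.level_means[f])) for f in rt.factors},
                "delta": {f: float(rt.delta[f]) for f in rt.factors},
                "rank": {f: int(rt.rank[f]) for f in rt.factors},
            },
            "anova": [
                {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.items()
                }
                for row in self.anova_table.rows.to_dict("records")
            ],
            "prediction": {
                "predicted_snr": self.prediction.predicted_snr,
                "predicted_response": self.prediction.predicted_response,
                "selected_factors": list(self.prediction.selected_factors),
                "chosen_levels": dict(self.prediction.chosen_levels),
                "exceeds_physical_bound": self.prediction.exceeds_physical_bound,
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def load_run_sheet(path) -> pd.DataFrame:
    """Read a run-sheet CSV (comma separator, header row, decimal point)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise InvalidDesignError(f"malformed CSV {path}: {exc}") from exc
    if df.empty:
        raise InvalidDesignError(f"empty run sheet {path}")
    return df


def _array_from_sheet(sheet: pd.DataFrame, config: PipelineConfig) -> OrthogonalArray:
    names = [f.name for f in config.factors]
    missing = [n for n in names if n not in sheet.columns]
    if missing:
        raise IncompleteDesignError(f"run sheet lacks factor columns {missing}")
    # accept either coded {1,2,3} or physical-level columns
    coded = all(set(sheet[n].unique()) <= {1, 2, 3} for n in names)
    if coded:
        return OrthogonalArray(sheet[names].to_numpy(dtype=int), tuple(names))
    return encode_design(sheet, config.factors)


def run_pipeline(config: PipelineConfig, run_sheet: pd.DataFrame) -> ReportBundle:
    """Execute the full S/N -> response table -> ANOVA -> prediction chain.

    Raises distinct diagnostics for an incomplete design, nonpositive
    responses and malformed sheets (see :mod:`taguchi_biocat.errors`).
    """
    array = _array_from_sheet(run_sheet, config)
    report = check_orthogonality(array)
    if not report:
        raise InvalidDesignError(
            f"run sheet is not an orthogonal design: unbalanced columns "
            f"{report.unbalanced_columns}, non-orthogonal pairs {report.non_orthogonal_pairs}"
        )
    missing = [c for c in config.response_columns if c not in run_sheet.columns]
    if missing:
        raise IncompleteDesignError(f"run sheet lacks response columns {missing}")

    reps = run_sheet[list(config.response_columns)].to_numpy(dtype=float)
    responses = ResponseSet(tuple(range(1, array.n_runs + 1)), tuple(reps))
    records = snr_mod.compute_snr(responses)

    snr_table = run_sheet.copy()
    if "run_id" not in snr_table.columns:
        snr_table.insert(0, "run_id", np.arange(1, array.n_runs + 1))
    snr_table["snr"] = [r.snr for r in records]

    table = snr_mod.response_table(array, records)
    pool = config.pool
    if pool == "auto":
        pooled = anova_mod.auto_pool(array, records)
    else:
        pooled = tuple(pool)
    aov = anova_mod.anova_snr(array, records, pooled, config.alpha)
    prediction = snr_mod.predict_optimal_snr(table)
    return ReportBundle(snr_table, table, aov, prediction, config)


def _fmt(x, digits: int) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.{digits}f}"


def render_report(bundle_or_tables, digits: int | None = None) -> str:
    """Plain-text report of the pipeline tables (deterministic bytes).

    Pooled ANOVA sources have their df and SS wrapped in braces.  Accepts a
    :class:`ReportBundle` or an iterable of (title, DataFrame) pairs; an
    empty iterable renders an empty report.
    """
    if not isinstance(bundle_or_tables, ReportBundle):
        parts = []
        for title, frame in bundle_or_tables:
            parts.append(f"== {title} ==\n{frame.to_string()}\n")
        return "\n".join(parts)

    bundle = bundle_or_tables
    digits = bundle.config.digits if digits is None and bundle.config else (digits or 1)
    lines: list[str] = []

    lines.append("== Per-run S/N (dB) ==")
    df = bundle.snr_table.copy()
    df["snr"] = df["snr"].map(lambda v: _fmt(v, digits))
    lines.append(df.to_string(index=False))
    lines.append("")

    lines.append("== Response table (mean S/N per level, dB) ==")
    lines.append(bundle.response_table.to_frame(digits).to_string())
    lines.append("")

    lines.append("== ANOVA of S/N ==")
    header = ["Source", "DF", "SS", "MS", "F-value", "p-value", "Contribution (%)"]
    rows = [header]
    for r in bundle.anova_table.rows.itertuples():
        df_s, ss_s = _fmt(r.df, 0), _fmt(r.ss, digits)
        if r.pooled:
            df_s, ss_s = f"{{{df_s}}}", f"{{{ss_s}}}"
        rows.append(
            [
                str(r.source),
                df_s,
                ss_s,
                _fmt(r.ms, digits),
                _fmt(r.f_value, digits),
                _fmt(r.p_value, 3),
                _fmt(r.contribution, digits),
            ]
        )
    widths = [max(len(row[i]) for row in rows) for i in range(len(header))]
    for row in rows:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
    lines.append("")

    p = bundle.prediction
    lines.append("== Predicted optimum ==")
    levels = ", ".join(f"{f}=L{p.chosen_levels[f]}" for f in p.selected_factors)
    lines.append(f"levels: {levels}")
    lines.append(f"predicted S/N: {_fmt(p.predicted_snr, digits)} dB")
    bound = " (exceeds physical bound)" if p.exceeds_physical_bound else ""
    lines.append(f"predicted response: {_fmt(p.predicted_response, digits)}{bound}")
    lines.append("")
    return "\n".join(lines)
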