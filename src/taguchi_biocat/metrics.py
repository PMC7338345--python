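"""Bioprocess measurement calculators.

Covers the upstream quantities of an enzymatic esterification campaign:

* acidity index from NaOH titration (mg NaOH per g of sample),
* free-fatty-acid conversion from the drop in acidity between a blank and
  the biocatalysed sample,
* spectrophotometric hydrolytic activity (p-NPB assay, Beer-Lambert),
* immobilization parameters (yield, theoretical and recovered activity),
* first-order thermal-deactivation half-life from residual-activity series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidMeasurementError, NoDecayError

__all__ = [
    "TitrationRecord",
    "ActivityAssay",
    "ImmobilizationRecord",
    "DecaySeries",
    "HalfLifeFit",
    "FlaggedValue",
    "acidity_index",
    "ffa_conversion",
    "hydrolytic_activity",
    "immobilization_yield",
    "theoretical_activity",
    "recovered_activity",
    "half_life",
    "stabilization_factor",
]

NAOH_MOLAR_MASS = 40.00  # g/mol


@dataclass(frozen=True)
class TitrationRecord:
    """One acid-base titration of an esterification sample.

    Attributes
    ----------
    sample_mass : g
    titrant_molarity : mol/L of the NaOH solution
    titrant_volume : mL spent to the endpoint
    correction_factor : dimensionless standardization factor of the titrant
    titrant_molar_mass : g/mol (NaOH default 40.00; override for other bases)
    """

    sample_mass: float
    titrant_molarity: float
    titrant_volume: float
    correction_factor: float = 1.0
    titrant_molar_mass: float = NAOH_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise InvalidMeasurementError("sample mass must be positive")
        if self.titrant_molarity <= 0 or self.correction_factor <= 0:
            raise InvalidMeasurementError("titrant molarity and correction factor must be positive")
        if self.titrant_volume < 0:
            raise InvalidMeasurementError("titrant volume cannot be negative")


def acidity_index(rec: TitrationRecord) -> float:
    """Acidity index in mg NaOH per g of sample.

    AI = MM * M * f * V / m with V in mL; linear in the titrant volume.
    """
    return (
        rec.titrant_molar_mass
        * rec.titrant_molarity
        * rec.correction_factor
        * rec.titrant_volume
        / rec.sample_mass
    )


@dataclass(frozen=True)
class FlaggedValue:
    """A numeric result with a data-quality flag instead of silent clamping."""

    value: float
    flag: str | None = None

    def __float__(self) -> float:
        return self.value


def ffa_conversion(ai_blank: float, ai_sample: float) -> FlaggedValue:
    """Percent conversion of free fatty acids to esters from acidity indices.

    conversion = 100 * (AI_blank - AI_sample) / AI_blank.  Values outside
    [0, 100] are returned as-is with a quality flag (``"negative"`` marks
    apparent acid formation, ``"over-100"`` an AI below zero), surfacing
    titration problems rather than masking them.
    """
    if ai_blank <= 0:
        raise InvalidMeasurementError("blank acidity index must be positive")
    conv = 100.0 * (ai_blank - ai_sample) / ai_blank
    flag = None
    if conv < 0:
        flag = "negative"
    elif conv > 100:
        flag = "over-100"
    return FlaggedValue(conv, flag)


@dataclass(frozen=True)
class ActivityAssay:
    """Spectrophotometric p-NPB hydrolysis assay (348 nm).

    Default extinction coefficient 5150 1/(M cm) applies to p-nitrophenol
    released in 25 mM sodium phosphate at pH 7 and 25 degC; default volumes
    follow a 50 uL enzyme + 50 uL substrate + 2.5 mL buffer cuvette.
    """

    absorbance_rate: float  # delta A per minute
    extinction_coefficient: float = 5150.0  # 1/(M cm)
    path_length: float = 1.0  # cm
    reaction_volume: float = 2.6  # mL, total in cuvette
    enzyme_volume: float = 0.05  # mL added
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0 or self.path_length <= 0:
            raise InvalidMeasurementError("extinction coefficient and path length must be positive")
        if self.reaction_volume <= 0 or self.enzyme_volume <= 0 or self.dilution <= 0:
            raise InvalidMeasurementError("volumes and dilution must be positive")


def hydrolytic_activity(assay: ActivityAssay, solids_mass: float | None = None) -> float:
    """Hydrolytic activity in U per mL of enzyme preparation (U = umol/min).

    Beer-Lambert gives the product formation rate dA/dt / (eps * l) in
    mol L^-1 min^-1; scaling by the reaction volume converts to umol/min in
    the cuvette (1 mol/L = 1000 umol/mL), and dividing by the enzyme volume
    (times any dilution) refers the rate back to the preparation.

    With ``solids_mass`` (g of biocatalyst in the assayed volume) the result
    is returned per gram instead of per mL.
    """
    rate_molar = assay.absorbance_rate / (assay.extinction_coefficient * assay.path_length)
    umol_per_min = rate_molar * 1000.0 * assay.reaction_volume
    per_ml = umol_per_min * assay.dilution / assay.enzyme_volume
    if solids_mass is None:
        return per_ml
    if solids_mass <= 0:
        raise InvalidMeasurementError("solids mass must be positive")
    return umol_per_min * assay.dilution / solids_mass


@dataclass(frozen=True)
class ImmobilizationRecord:
    """Supernatant-depletion bookkeeping for one immobilization experiment.

    ``initial_activity`` / ``final_activity`` are supernatant activities
    (U/mL) before and after contact with the support; ``offered_per_g`` is
    the enzyme activity offered per gram of support (U/g) and
    ``biocatalyst_activity`` the activity measured on the washed support
    (U/g, written At_B).
    """

    initial_activity: float
    final_activity: float
    offered_per_g: float | None = None
    biocatalyst_activity: float | None = None

    def __post_init__(self) -> None:
        if self.initial_activity <= 0:
            raise InvalidMeasurementError("initial supernatant activity must be positive")
        if self.final_activity < 0:
            raise InvalidMeasurementError("final supernatant activity cannot be negative")


def immobilization_yield(initial_activity: float, final_activity: float) -> FlaggedValue:
    """Immobilization yield IY = 100 * (A_i - A_f) / A_i, in percent.

    A final activity above the initial one yields a flagged negative value
    (``"negative-retention"``) rather than an exception.
    """
    if initial_activity <= 0:
        raise InvalidMeasurementError("initial activity must be positive")
    iy = 100.0 * (initial_activity - final_activity) / initial_activity
    return FlaggedValue(iy, "negative-retention" if iy < 0 else None)


def theoretical_activity(offered_per_g: float, iy_percent: float) -> float:
    """Expected support activity At_T = offered load (U/g) * IY/100."""
    if offered_per_g < 0 or iy_percent < 0:
        raise InvalidMeasurementError("offered activity and yield must be nonnegative")
    return offered_per_g * iy_percent / 100.0


def recovered_activity(at_b: float, at_t: float) -> float:
    """Recovered (expressed) activity At_R = 100 * At_B / At_T, percent."""
    if at_t <= 0:
        raise InvalidMeasurementError("theoretical activity must be positive")
    return 100.0 * at_b / at_t


@dataclass(frozen=True)
class DecaySeries:
    """Residual-activity time course under thermal incubation.

    Times in minutes, strictly increasing from 0; activities in percent of
    the initial activity (first point 100), strictly positive.
    """

    times: np.ndarray
    residual_activity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.residual_activity, dtype=float)
        if t.size != a.size or t.size < 2:
            raise InvalidMeasurementError("need >= 2 paired (time, activity) points")
        if t[0] != 0:
            raise InvalidMeasurementError("series must start at time 0")
        if not (np.diff(t) > 0).all():
            raise InvalidMeasurementError("times must be strictly increasing")
        if not (a > 0).all():
            raise InvalidMeasurementError("residual activities must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "residual_activity", a)


@dataclass(frozen=True)
class HalfLifeFit:
    """First-order deactivation fit: A(t) = A0 * exp(-k t).

    ``r_squared`` is the coefficient of determination of the (weighted)
    log-linear fit; values well below 1 indicate non-first-order decay.
    """

    t_half: float  # min
    k: float  # 1/min
    a0: float  # fitted intercept on the activity scale
    r_squared: float
    weighted: bool = field(default=True)


def half_life(series: DecaySeries, weighted: bool = True) -> HalfLifeFit:
    """Half-life from a least-squares fit of ln(activity) against time.

    t_1/2 = ln 2 / k.  By default points are weighted by their activity:
    with measurement noise additive on the activity scale, the noise of
    ln(A) scales as 1/A, so weights proportional to A (variance weights
    A^2) are the Gauss-Markov-consistent choice and keep the late, noisy
    tail from dominating the slope.  ``weighted=False`` gives the plain
    ordinary-least-squares fit.

    Raises :class:`NoDecayError` when the fitted rate constant is not
    positive (activity not decreasing over time).
    """
    t = series.times
    log_a = np.log(series.residual_activity)
    w = series.residual_activity if weighted else None
    slope, intercept = np.polyfit(t, log_a, 1, w=w)
    k = -float(slope)
    if k <= 0:
        raise NoDecayError("activity does not decay over time (fitted k <= 0)")
    fitted = intercept + slope * t
    if w is None:
        ss_res = float(((log_a - fitted) ** 2).sum())
        ss_tot = float(((log_a - log_a.mean()) ** 2).sum())
    else:
        w2 = w**2
        mean_w = float((w2 * log_a).sum() / w2.sum())
        ss_res = float((w2 * (log_a - fitted) ** 2).sum())
        ss_tot = float((w2 * (log_a - mean_w) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return HalfLifeFit(math.log(2) / k, k, math.exp(float(intercept)), r2, weighted)


def stabilization_factor(t_half_immobilized: float, t_half_free: float) -> float:
    """Ratio of immobilized to free-enzyme half-life (dimensionless)."""
    if t_half_immobilized <= 0 or t_half_free <= 0:
        raise InvalidMeasurementError("half-lives must be positive")
    return t_half_immobilized / t_half_free
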