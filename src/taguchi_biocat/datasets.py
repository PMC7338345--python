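"""Bundled worked example: the babassu-oil esterification L9 study.

A lipase from *Rhizomucor miehei* immobilized on APTES-coated magnetite
nanoparticles catalyses the esterification of babassu-oil free fatty acids
with ethanol.  Four process factors at three levels each (temperature, time,
FFAs:alcohol molar ratio, biocatalyst content) were screened with an L9
orthogonal array; the response is the titration-derived percent conversion
of one run each.  These published run-sheet numbers are the package's
canonical worked example and regression anchor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import FactorSpec, OrthogonalArray, build_l9, decode_design

__all__ = ["babassu_factors", "babassu_conversions", "babassu_study"]

_FACTORS = (
    FactorSpec("Temperature", "degC", (30, 40, 50)),
    FactorSpec("Time", "h", (2, 4, 6)),
    FactorSpec("Molar ratio", "FFAs:alcohol", ("1:1", "1:3", "1:5")),
    FactorSpec("Biocatalyst", "%m/m", (1, 5, 9)),
)

# Measured percent conversion per run, in canonical L9 run order.
_CONVERSIONS = (14.6, 45.1, 45.3, 50.5, 6.9, 81.7, 10.2, 79.8, 5.4)


def babassu_factors() -> tuple[FactorSpec, ...]:
    """The four esterification factors with their physical levels."""
    return _FACTORS


def babassu_conversions() -> np.ndarray:
    """Measured conversions (%) for the nine L9 runs."""
    return np.array(_CONVERSIONS)


def babassu_study() -> tuple[OrthogonalArray, pd.DataFrame]:
    """The L9 array (named columns) and the decoded run sheet with conversions."""
    factors = babassu_factors()
    array = build_l9([f.name for f in factors])
    sheet = decode_design(array, factors)
    sheet["conversion"] = babassu_conversions()
    return array, sheet
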