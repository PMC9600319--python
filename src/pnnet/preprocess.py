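"""Derived variables and the nonparanormal (rank-Gaussian) transform.

Covers the steps between raw measurements and the panel the network
estimator consumes: the diurnal cortisol slope from a four-sample saliva
profile, BMI from height and weight, listwise complete-case selection
over the 12 analysis variables, and the shrunken-ECDF nonparanormal
transform that Gaussianizes skewed marginals while preserving ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variables import VARIABLES

__all__ = [
    "SalivaProfile",
    "cortisol_slope",
    "bmi",
    "listwise_complete",
    "npn_transform",
    "npn_delta",
]


@dataclass(frozen=True)
class SalivaProfile:
    """Four saliva cortisol samples across one day.

    ``times`` are clock times in decimal hours (awakening, +30 min,
    +60 min, 22:00), strictly increasing; ``concentrations`` in nmol/L.
    ``below_loq`` flags samples under the assay's lower limit of
    quantitation. A missing sample is ``nan``.
    """

    times: tuple[float, float, float, float]
    concentrations: tuple[float, float, float, float]
    below_loq: tuple[bool, bool, bool, bool] = (False, False, False, False)

    def __post_init__(self) -> None:
        if len(self.times) != 4 or len(self.concentrations) != 4:
            raise ValueError("a saliva profile has exactly four samples")
        t = [x for x in self.times if not np.isnan(x)]
        if any(b - a <= 0 for a, b in zip(t, t[1:])):
            raise ValueError("sample clock times must be strictly increasing")
        if any(c < 0 for c in self.concentrations if not np.isnan(c)):
            raise ValueError("concentrations must be non-negative")


def cortisol_slope(profile: SalivaProfile) -> float:
    """Diurnal cortisol slope in nmol/L per hour.

    Awakening concentration minus the 22:00 concentration, divided by the
    elapsed hours between those two samples (the two mid-morning samples
    are not used). A higher value means a steeper decline across the day;
    a negative value means cortisol rose during the day.  Returns ``nan``
    when either endpoint sample is missing.
    """
    c_awake, c_evening = profile.concentrations[0], profile.concentrations[3]
    t_awake, t_evening = profile.times[0], profile.times[3]
    if any(np.isnan(x) for x in (c_awake, c_evening, t_awake, t_evening)):
        return float("nan")
    hours = t_evening - t_awake
    if hours <= 0:
        raise ValueError("evening sample must come after awakening")
    return (c_awake - c_evening) / hours


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) divided by squared height (m), in kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def listwise_complete(panel: pd.DataFrame, columns: tuple[str, ...] = VARIABLES) -> pd.DataFrame:
    """Rows with no missing value in any of the analysis columns.

    Row order is preserved; idempotent.
    """
    missing = [c for c in columns if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns {missing}")
    keep = panel.loc[:, list(columns)].notna().all(axis=1)
    return panel.loc[keep]


def npn_delta(n: int) -> float:
    """Winsorization constant of the shrunken-ECDF nonparanormal transform."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def npn_transform(panel: pd.DataFrame) -> pd.DataFrame:
    """Shrunken-ECDF nonparanormal transform, column by column.

    Each column is replaced by standard-normal quantiles of its shrunken
    empirical CDF: average ranks ``r_i`` give ``u_i = r_i / (n + 1)``,
    winsorized to ``[delta, 1 - delta]`` with
    ``delta = 1 / (4 n^{1/4} sqrt(pi log n))``, then mapped through the
    normal quantile function and rescaled to unit sample standard
    deviation.  The transform is monotone in each column, so ranks (and
    any statistic that depends only on ranks) are preserved; ties map to
    identical outputs.
    """
    if panel.isna().any().any():
        raise ValueError("panel must be complete; apply listwise_complete first")
    n = len(panel)
    if n < 2:
        raise ValueError("need at least two rows")
    delta = npn_delta(n)
    out = {}
    for col in panel.columns:
        x = panel[col].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"column {col!r} is constant and cannot be rank-transformed")
        r = stats.rankdata(x, method="average")
        u = np.clip(r / (n + 1.0), delta, 1.0 - delta)
        z = stats.norm.ppf(u)
        out[col] = z / z.std(ddof=1)
    return pd.DataFrame(out, index=panel.index, columns=panel.columns)
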