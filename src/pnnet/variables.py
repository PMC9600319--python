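"""Canonical variable panel for the symptom–biomarker network.

The analysis operates on a fixed panel of 12 variables per patient:
five patient-reported psychoneurological symptom scores, five biology
measures (the diurnal cortisol slope and four blood inflammation
markers), and two covariates. Everything downstream (transformation,
network estimation, centrality) refers to these canonical column names.
"""

from __future__ import annotations

import pandas as pd

#: Canonical column order of the analysis panel.
VARIABLES: tuple[str, ...] = (
    "sleep",           # PSQI total score, 0-21 (higher = poorer sleep)
    "depression",      # HADS depression subscale, 0-21
    "anxiety",         # HADS anxiety subscale, 0-21
    "oral_pain",       # EORTC QLQ-H&N35 oral pain subscale, 0-100
    "fatigue",         # MFI general fatigue, 4-20
    "cortisol_slope",  # diurnal cortisol slope, nmol/L/hour
    "crp",             # C-reactive protein, mg/L
    "il6",             # interleukin-6, pg/mL
    "il10",            # interleukin-10, pg/mL
    "tnfa",            # tumor necrosis factor alpha, pg/mL
    "age",             # years
    "bmi",             # kg/m^2
)

#: Role of each variable in the network (symptom / biomarker / covariate).
ROLES: dict[str, str] = {
    "sleep": "symptom",
    "depression": "symptom",
    "anxiety": "symptom",
    "oral_pain": "symptom",
    "fatigue": "symptom",
    "cortisol_slope": "biomarker",
    "crp": "biomarker",
    "il6": "biomarker",
    "il10": "biomarker",
    "tnfa": "biomarker",
    "age": "covariate",
    "bmi": "covariate",
}

#: Human-readable display labels (used in summaries and plots).
DISPLAY_LABELS: dict[str, str] = {
    "sleep": "Poor sleep quality",
    "depression": "Depression symptoms",
    "anxiety": "Anxiety symptoms",
    "oral_pain": "Oral pain",
    "fatigue": "Fatigue",
    "cortisol_slope": "Cortisol slope",
    "crp": "CRP",
    "il6": "IL-6",
    "il10": "IL-10",
    "tnfa": "TNF-α",
    "age": "Age",
    "bmi": "BMI",
}


def validate_panel(panel: pd.DataFrame, require_complete: bool = False) -> pd.DataFrame:
    """Check that a DataFrame carries the 12 analysis columns.

    Returns the panel restricted to the canonical columns in canonical
    order.  Raises ``ValueError`` when columns are missing, duplicated,
    or (with ``require_complete``) when any value is missing.
    """
    if panel.columns.duplicated().any():
        dupes = panel.columns[panel.columns.duplicated()].tolist()
        raise ValueError(f"duplicated columns in panel: {dupes}")
    missing = [v for v in VARIABLES if v not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing analysis columns: {missing}")
    out = panel.loc[:, list(VARIABLES)]
    if require_complete and out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"panel contains missing values in {bad}")
    return out
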