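"""Small assay quantifications: glycan-array ranking, MS sialylation
fraction, ELISA normalisation and correlation, internal-standard
quantification."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def rank_glycan_array(table: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalise a glycan microarray replicate table.

    ``table`` has one row per glycan (index or ``glycan`` column) and one
    column per replicate RFU.  Returns a table with the replicate mean,
    sample (n-1) SD and ``rank_pct = 100 * mean / max(mean)``, so the
    strongest glycan ranks exactly 100.
    """
    df = table.copy()
    if "glycan" in df.columns:
        df = df.set_index("glycan")
    values = df.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty table")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(df))
    top = mean.max()
    if top <= 0:
        raise ValueError("no signal: all replicate means are zero")
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "rank_pct": mean / top * 100.0}, index=df.index
    )


def sialylation_fraction(peaks: pd.DataFrame) -> float:
    """Area fraction of sialylated structures among assigned O-glycan
    mass peaks: sum(area | sialylated & assigned) / sum(area | assigned).
    """
    df = peaks
    required = {"area", "sialylated"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    if np.any(df["area"] < 0):
        raise ValueError("peak areas must be non-negative")
    assigned = df["assigned"].astype(bool) if "assigned" in df.columns else np.ones(len(df), bool)
    total = df.loc[assigned, "area"].sum()
    if total <= 0:
        raise ValueError("zero assigned peak area")
    sial = df.loc[assigned & df["sialylated"].astype(bool), "area"].sum()
    return float(sial / total)


def normalize_elisa(
    readings: dict[str, float], blank: float, reference_id: str
) -> dict[str, float]:
    """Blank-subtract and scale A450 readings so the reference is 100%."""
    if reference_id not in readings:
        raise ValueError(f"reference well {reference_id!r} missing")
    ref = readings[reference_id] - blank
    if ref <= 0:
        raise ValueError("invalid reference: reading does not exceed blank")
    # divide before scaling so the reference maps to exactly 100.0
    return {k: (v - blank) / ref * 100.0 for k, v in readings.items()}


def linear_r2(x, y) -> float:
    """Squared Pearson correlation between two measurement series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def internal_standard_quant(
    analyte_peak: float,
    standard_peak: float,
    standard_conc: float,
    response_factor: float = 1.0,
) -> float:
    """Analyte concentration from peak areas against an internal standard
    of known concentration (response factor 1 unless calibrated)."""
    if standard_peak <= 0:
        raise ValueError("standard peak must be positive")
    if analyte_peak < 0:
        raise ValueError("analyte peak must be non-negative")
    return standard_conc * response_factor * analyte_peak / standard_peak
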