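"""Mean and mean-anomaly statistics for monthly environmental series, and
summaries for high-frequency temperature logger records.

The site tables report, for each satellite variable, a long-term mean of
monthly values and a "mean anomaly": each month's value is compared against
its own year's annual mean, and the per-month deviations are averaged over
all months.  The deviation is taken as an absolute value by default — the
signed per-year deviations average to ~0 by construction, whereas observed
anomaly statistics are large and positive (an SST mean anomaly of 2-3 degC
against a ~23 degC mean), which only the absolute form can produce.  The
signed variant remains available via ``absolute=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["MonthlySeries", "EnvSummary", "mean_and_anomaly", "logger_summary",
           "read_monthly_series"]


@dataclass
class MonthlySeries:
    """Monthly records of one environmental variable."""

    name: str
    units: str
    records: list[tuple[int, int, float]]  # (year, month, value)

    def __post_init__(self) -> None:
        seen = set()
        for y, m, _ in self.records:
            if not 1 <= m <= 12:
                raise ValidationError(f"month {m} outside 1..12 (year {y})")
            if (y, m) in seen:
                raise ValidationError(f"duplicate record for {y}-{m:02d}")
            seen.add((y, m))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["year", "month", "value"])


@dataclass(frozen=True)
class EnvSummary:
    mean: float
    mean_anomaly: float
    n_months: int


def mean_and_anomaly(
    series: MonthlySeries,
    absolute: bool = True,
    climatological: bool = False,
) -> EnvSummary:
    """Long-term mean and mean anomaly of a monthly series.

    mean = arithmetic mean of all monthly values.  Each month's anomaly is
    A(y) - v(y, m) with A(y) that year's mean of monthly values (or, with
    ``climatological=True``, the single all-years mean); mean_anomaly
    averages |anomaly| (or the signed anomaly with ``absolute=False``) over
    all months.  Partial years are included with a warning.
    """
    df = series.frame()
    if df.empty:
        raise ValidationError(f"empty series {series.name!r}")
    partial = df.groupby("year")["month"].count()
    if (partial < 12).any():
        warnings.warn(
            f"{series.name}: partial year(s) included: "
            f"{sorted(partial.index[partial < 12].tolist())}",
            stacklevel=2,
        )
    mean = float(df["value"].mean())
    if climatological:
        annual = pd.Series(mean, index=df["year"].unique())
    else:
        annual = df.groupby("year")["value"].mean()
    anom = annual.loc[df["year"]].to_numpy() - df["value"].to_numpy()
    if absolute:
        anom = np.abs(anom)
    return EnvSummary(mean, float(anom.mean()), len(df))


def read_monthly_series(path, name: str = "", units: str = "") -> MonthlySeries:
    """Read a monthly CSV with columns year, month, value."""
    df = pd.read_csv(path)
    missing = [c for c in ("year", "month", "value") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    records = [
        (int(r.year), int(r.month), float(r.value)) for r in df.itertuples()
    ]
    return MonthlySeries(name or str(path), units, records)


def logger_summary(values, threshold: float | None = None) -> dict:
    """Summary statistics of a high-frequency logger record (deg C).

    Returns mean/min/max and, when ``threshold`` is given, the fraction of
    readings strictly below it (e.g. time spent in warm-temperate rather than
    tropical conditions).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("empty logger record")
    out = {
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }
    if threshold is not None:
        out["frac_below_threshold"] = float((v < threshold).mean())
        out["threshold"] = float(threshold)
    return out
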