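"""Record-level quality control and daily aggregation.

Tag records carry a quality index QI from 0 (excellent) to 3 (poor).
QC drops records with QI in {2, 3} and heart rates above 120 bpm or
below 8 bpm — 8 bpm being the theoretical floor measurable in the tag's
short ECG window, so the bounds themselves are kept (strict exceedance).
Surviving records are collapsed to one row per calendar day: median
heart rate (HRm, integer bpm), median temperature (TPm), temperature
interquartile range (TPiq), median activity (ACm), joined with the
daily total feed (TF) from the farm's feeding log.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .signals import round_half_up

__all__ = [
    "RECORD_COLUMNS",
    "QCReport",
    "ValidationError",
    "JoinError",
    "filter_records",
    "daily_summaries",
]

log = logging.getLogger(__name__)

#: Schema of the logger-record table.
RECORD_COLUMNS = ("timestamp", "hr_bpm", "qi", "temp_c", "avg_ea_mg")


class ValidationError(ValueError):
    """A record violates the schema (QI outside 0..3, negative HR, ...)."""


class JoinError(ValueError):
    """Record dates not covered by the feeding log."""


@dataclass(frozen=True)
class QCReport:
    """Per-rule tallies of one QC pass.

    Each record is counted exactly once; the first failing rule wins,
    in the order: quality index, high HR, low HR.
    """

    n_total: int
    n_kept: int
    n_dropped_qi: int
    n_dropped_hr_high: int
    n_dropped_hr_low: int

    @property
    def pass_fraction(self) -> float:
        if self.n_total == 0:
            return 1.0
        return self.n_kept / self.n_total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pass_fraction"] = self.pass_fraction
        return d


def _validate(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"record table lacks column(s) {missing}")
    bad_qi = ~records["qi"].isin([0, 1, 2, 3])
    if bad_qi.any():
        rows = records.index[bad_qi].tolist()[:10]
        raise ValidationError(f"QI outside {{0,1,2,3}} at row(s) {rows}")
    neg_hr = records["hr_bpm"] < 0
    if neg_hr.any():
        rows = records.index[neg_hr].tolist()[:10]
        raise ValidationError(f"negative heart rate at row(s) {rows}")


def filter_records(
    records: pd.DataFrame,
    hr_low: int = 8,
    hr_high: int = 120,
    qi_reject: frozenset = frozenset({2, 3}),
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the QC rules; return (kept records, per-rule report).

    Records with QI in ``qi_reject`` are dropped, as are heart rates
    strictly above ``hr_high`` or strictly below ``hr_low`` (the bounds
    are admissible).  Original order is preserved.
    """
    if not hr_low < hr_high:
        raise ValueError("hr_low must be smaller than hr_high")
    if len(records) == 0:
        return records.copy(), QCReport(0, 0, 0, 0, 0)
    _validate(records)
    bad_qi = records["qi"].isin(list(qi_reject)).to_numpy()
    hr = records["hr_bpm"].to_numpy()
    high = (hr > hr_high) & ~bad_qi
    low = (hr < hr_low) & ~bad_qi & ~high
    keep = ~(bad_qi | high | low)
    report = QCReport(
        n_total=len(records),
        n_kept=int(keep.sum()),
        n_dropped_qi=int(bad_qi.sum()),
        n_dropped_hr_high=int(high.sum()),
        n_dropped_hr_low=int(low.sum()),
    )
    return records.loc[keep].copy(), report


def _day_of(ts: pd.Series) -> pd.Series:
    return pd.to_datetime(ts).dt.date


def daily_summaries(
    kept: pd.DataFrame,
    feeding: pd.DataFrame,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Collapse QC-passed records to the daily covariate table.

    Output columns: date, hrm (median HR rounded half-up to integer),
    tpm (median temperature), tpiq (temperature Q3 - Q1, linear
    interpolation by default), acm (median activity), tf (total feed,
    joined from the feeding log), n_records.  Days with zero surviving
    records are omitted (and logged); a record date missing from the
    feeding log is an error.
    """
    feeding = feeding.copy()
    feeding["date"] = pd.to_datetime(feeding["date"]).dt.date
    if len(kept) == 0:
        return pd.DataFrame(
            columns=["date", "hrm", "tpm", "tpiq", "acm", "tf", "n_records"]
        )
    days = _day_of(kept["timestamp"])
    missing = sorted(set(days) - set(feeding["date"]))
    if missing:
        raise JoinError(
            "record dates missing from feeding log: "
            + ", ".join(d.isoformat() for d in missing)
        )

    def _one(group: pd.DataFrame) -> pd.Series:
        temp = group["temp_c"].to_numpy(float)
        q1, q3 = np.quantile(temp, [0.25, 0.75], method=quantile_method)
        return pd.Series(
            {
                "hrm": round_half_up(float(group["hr_bpm"].median())),
                "tpm": float(group["temp_c"].median()),
                "tpiq": float(q3 - q1),
                "acm": float(group["avg_ea_mg"].median()),
                "n_records": len(group),
            }
        )

    out = (
        kept.groupby(days, sort=True)
        .apply(_one, include_groups=False)
        .reset_index(names="date")
    )
    omitted = sorted(set(feeding["date"]) - set(out["date"]))
    if omitted:
        log.info("days with no surviving records omitted: %s", omitted)
    out = out.merge(
        feeding.rename(columns={"tf_tons": "tf"})[["date", "tf"]],
        on="date",
        how="left",
    )
    out["hrm"] = out["hrm"].astype(int)
    out["n_records"] = out["n_records"].astype(int)
    return out[["date", "hrm", "tpm", "tpiq", "acm", "tf", "n_records"]]
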