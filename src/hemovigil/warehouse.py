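"""Two-granularity warehouse: event-level episodes and daily fact rows.

The event-granularity ``TRANSFUSION`` table holds one row per
reconstructed episode with its dimensions and precomputed compliance
flags; the ``TRANSFUSION_DAILY_FACT`` table aggregates counts per
(date, facility, ward, medical service).  Precomputation exists for query
speed only: every statistic derived from the daily facts must equal the
same statistic recomputed from the event level, and the consistency
helpers here are used by the test suite to enforce that.

Denominator convention: every measure is scored against the number of
transfusions except the post-transfusion measure, whose denominator is
the number of episodes with a documented completion (an episode missing
its completion record is already penalized on the completion measure and
cannot be assessed for post observations).
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compliance import ComplianceResult
from .records import ClinicalEventRecord, POST_NOT_ASSESSABLE, POST_PASS
from .reconstruction import ReconstructionResult, TransfusionEpisode

DEFAULT_TARGET = 0.80

#: measure -> (numerator column, denominator column) in the daily fact table
MEASURES: dict[str, tuple[str, str]] = {
    "consent": ("N_CONSENT_PASS", "N_TRANSFUSIONS"),
    "compatibility": ("N_COMPATIBILITY_PASS", "N_TRANSFUSIONS"),
    "completion": ("N_COMPLETION_DOCUMENTED", "N_TRANSFUSIONS"),
    "baseline": ("N_BASELINE_PASS", "N_TRANSFUSIONS"),
    "min15": ("N_MIN15_PASS", "N_TRANSFUSIONS"),
    "hourly": ("N_HOURLY_PASS", "N_TRANSFUSIONS"),
    "post": ("N_POST_PASS", "N_POST_ASSESSABLE"),
}

DIMENSIONS = {"facility": "FACILITY", "ward": "WARD", "medical_service": "MED_SERVICE"}

#: event-level flag column per measure (post handled separately)
_FLAG_COLS = {
    "consent": "CONSENT_DOCUMENTED",
    "compatibility": "COMPATIBILITY_DOCUMENTED",
    "completion": "COMPLETION_DOCUMENTED",
    "baseline": "BASELINE_PASS",
    "min15": "MIN15_PASS",
    "hourly": "HOURLY_PASS",
}

EVENT_COLUMNS = (
    "ROW_ID",
    "EVENT_KEY",
    "PATIENT_ID",
    "ENCNTR_ID",
    "RESULT_NAME",
    "RESULT_VAL",
    "EVENT_DT_TM",
    "UPDT_CNT",
    "FACILITY",
    "WARD",
    "MED_SERVICE",
    "BATCH_ID",
)


def _iso(dt) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M") if dt is not None else ""


def events_frame(records) -> pd.DataFrame:
    """Canonical records as a DataFrame (timestamps as ISO strings)."""
    rows = [
        (
            r.row_id,
            r.event_key,
            r.patient_id,
            r.encounter_id,
            r.result_name,
            r.result_value,
            _iso(r.event_dt_tm),
            r.updt_cnt,
            r.facility,
            r.ward,
            r.medical_service,
            r.batch_id,
        )
        for r in sorted(records, key=lambda r: (r.event_dt_tm, r.event_key, r.updt_cnt))
    ]
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[ClinicalEventRecord]:
    from datetime import datetime

    return [
        ClinicalEventRecord(
            row_id=row.ROW_ID,
            event_key=row.EVENT_KEY,
            patient_id=row.PATIENT_ID,
            encounter_id=row.ENCNTR_ID,
            result_name=row.RESULT_NAME,
            result_value=row.RESULT_VAL,
            event_dt_tm=datetime.fromisoformat(row.EVENT_DT_TM),
            updt_cnt=int(row.UPDT_CNT),
            facility=row.FACILITY,
            ward=row.WARD,
            medical_service=row.MED_SERVICE,
            batch_id=row.BATCH_ID,
        )
        for row in df.itertuples(index=False)
    ]


def transfusion_table(
    episodes: tuple[TransfusionEpisode, ...],
    results: list[ComplianceResult],
    hourly_max: int = 3,
) -> pd.DataFrame:
    """Event-granularity TRANSFUSION table: one row per episode.

    Flags come precomputed from the compliance stage; foreign keys to the
    attached detail records support drill-down.
    """
    assert len(episodes) == len(results)
    rows = []
    for ep, res in zip(episodes, results):
        row = {
            "EPISODE_ID": ep.episode_id,
            "ENCNTR_ID": ep.encounter_id,
            "PATIENT_ID": ep.patient_id,
            "FACILITY": ep.facility,
            "WARD": ep.ward,
            "MED_SERVICE": ep.medical_service,
            "PRODUCT_TYPE": ep.product_type,
            "START_DT_TM": _iso(ep.start_time),
            "END_DT_TM": _iso(ep.end_time),
            "STATUS": ep.status,
            "INITIATE_KEY": ep.initiate.event_key,
            "COMPLETE_KEY": ep.complete.event_key if ep.complete else "",
            "CONSENT_KEY": ep.consent_event.event_key if ep.consent_event else "",
            "COMPATIBILITY_KEY": ep.compatibility_event.event_key if ep.compatibility_event else "",
            "N_OBSERVATIONS": len(ep.observations),
            "CONSENT_DOCUMENTED": int(res.consent_documented),
            "COMPATIBILITY_DOCUMENTED": int(res.compatibility_documented),
            "COMPLETION_DOCUMENTED": int(res.completion_documented),
            "BASELINE_PASS": int(res.baseline_pass),
            "MIN15_PASS": int(res.min15_pass),
            "HOURLY_PASS": int(res.hourly_pass),
            "POST_PASS": res.post_pass,
            "AMBIGUITY_FLAG": int(res.ambiguity_flag),
        }
        detail = dict(res.hourly_detail)
        for k in range(1, hourly_max + 1):
            row[f"HOURLY_{k}"] = detail.get(k, "NOT_REQUIRED")
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(["START_DT_TM", "EPISODE_ID"], kind="mergesort").reset_index(drop=True)


def aggregate_daily(transfusions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the TRANSFUSION table into daily fact rows."""
    cols = [
        "DATE",
        "FACILITY",
        "WARD",
        "MED_SERVICE",
        "N_TRANSFUSIONS",
        "N_CONSENT_PASS",
        "N_COMPATIBILITY_PASS",
        "N_COMPLETION_DOCUMENTED",
        "N_BASELINE_PASS",
        "N_MIN15_PASS",
        "N_HOURLY_PASS",
        "N_POST_PASS",
        "N_POST_ASSESSABLE",
    ]
    if transfusions.empty:
        return pd.DataFrame(columns=cols)
    df = transfusions.copy()
    df["DATE"] = df["START_DT_TM"].str[:10]
    df["_POST_PASS"] = (df["POST_PASS"] == POST_PASS).astype(int)
    df["_POST_ASSESSABLE"] = (df["POST_PASS"] != POST_NOT_ASSESSABLE).astype(int)
    grouped = (
        df.groupby(["DATE", "FACILITY", "WARD", "MED_SERVICE"], sort=True)
        .agg(
            N_TRANSFUSIONS=("EPISODE_ID", "size"),
            N_CONSENT_PASS=("CONSENT_DOCUMENTED", "sum"),
            N_COMPATIBILITY_PASS=("COMPATIBILITY_DOCUMENTED", "sum"),
            N_COMPLETION_DOCUMENTED=("COMPLETION_DOCUMENTED", "sum"),
            N_BASELINE_PASS=("BASELINE_PASS", "sum"),
            N_MIN15_PASS=("MIN15_PASS", "sum"),
            N_HOURLY_PASS=("HOURLY_PASS", "sum"),
            N_POST_PASS=("_POST_PASS", "sum"),
            N_POST_ASSESSABLE=("_POST_ASSESSABLE", "sum"),
        )
        .reset_index()
    )
    return grouped[cols].astype({c: int for c in cols[4:]})


# ---------------------------------------------------------------------------
# analytical queries

def _period_mask(facts: pd.DataFrame, period: str | None) -> pd.Series:
    if period is None:
        return pd.Series(True, index=facts.index)
    return facts["DATE"].str.startswith(period)


def query_missing_consents(facts: pd.DataFrame, month: str) -> int:
    """Transfusions without a documented consent in a calendar month
    (``month`` formatted ``YYYY-MM``)."""
    mask = facts["DATE"].str.startswith(month + "-") if not facts.empty else pd.Series(dtype=bool)
    if facts.empty or not mask.any():
        warnings.warn(f"no fact rows for month {month}", stacklevel=2)
        return 0
    sub = facts.loc[mask]
    return int((sub["N_TRANSFUSIONS"] - sub["N_CONSENT_PASS"]).sum())


def query_lowest_dimension(
    facts: pd.DataFrame,
    measure: str,
    dimension: str,
    period: str | None = None,
) -> pd.DataFrame:
    """Rank dimension values by measure rate, ascending (worst first).

    Zero-denominator values are excluded from the ranking and listed in
    ``df.attrs["excluded"]``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {sorted(DIMENSIONS)}")
    num_col, den_col = MEASURES[measure]
    dim_col = DIMENSIONS[dimension]
    sub = facts.loc[_period_mask(facts, period)] if not facts.empty else facts
    if sub.empty:
        out = pd.DataFrame(columns=[dim_col, "NUMERATOR", "DENOMINATOR", "RATE"])
        out.attrs["excluded"] = []
        return out
    g = sub.groupby(dim_col)[[num_col, den_col]].sum()
    g.columns = ["NUMERATOR", "DENOMINATOR"]
    excluded = sorted(g.index[g["DENOMINATOR"] == 0])
    g = g[g["DENOMINATOR"] > 0]
    g["RATE"] = g["NUMERATOR"] / g["DENOMINATOR"]
    out = g.reset_index().sort_values(["RATE", dim_col], kind="mergesort").reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


def _apply_filters(df: pd.DataFrame, filters: dict[str, str] | None) -> pd.DataFrame:
    if not filters:
        return df
    for dim, value in filters.items():
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown filter dimension {dim!r}")
        if not df.empty:
            df = df[df[DIMENSIONS[dim]] == value]
    return df


@dataclass
class StatusReport:
    """Current-month compliance status against per-measure targets."""

    period: str
    filters: dict[str, str]
    table: pd.DataFrame  # measure, numerator, denominator, rate, target, met, defined


def status_view(
    facts: pd.DataFrame,
    month: str,
    filters: dict[str, str] | None = None,
    targets: dict[str, float] | None = None,
) -> StatusReport:
    """Per-measure rate vs target for one calendar month.

    Measures with a zero denominator are flagged undefined (``defined``
    False) rather than reported as 0% or 100%.
    """
    targets = {**{m: DEFAULT_TARGET for m in MEASURES}, **(targets or {})}
    sub = _apply_filters(facts, filters)
    if not sub.empty:
        sub = sub.loc[sub["DATE"].str.startswith(month + "-")]
    rows = []
    for measure, (num_col, den_col) in MEASURES.items():
        num = int(sub[num_col].sum()) if not sub.empty else 0
        den = int(sub[den_col].sum()) if not sub.empty else 0
        rate = num / den if den else np.nan
        rows.append(
            {
                "measure": measure,
                "numerator": num,
                "denominator": den,
                "rate": rate,
                "target": targets[measure],
                "met": bool(den and rate >= targets[measure]),
                "defined": bool(den),
            }
        )
    return StatusReport(period=month, filters=dict(filters or {}), table=pd.DataFrame(rows))


_GRANULARITY_SLICE = {"year": 4, "month": 7, "day": 10}
_GRANULARITY_FREQ = {"year": "Y", "month": "M", "day": "D"}


def history_view(
    facts: pd.DataFrame,
    granularity: str,
    filters: dict[str, str] | None = None,
    transfusions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-period, per-measure time series (one row each).

    ``year``/``month``/``day`` aggregate the daily facts over a contiguous
    period range (gaps emitted with zero denominators).  ``hour`` is an
    hour-of-day profile and recomputes from the event-granularity table,
    which must be supplied, since daily facts cannot resolve hours.
    """
    if granularity == "hour":
        if transfusions is None:
            raise ValueError("hour granularity requires the event-granularity table")
        return _hourly_history(transfusions, filters)
    if granularity not in _GRANULARITY_SLICE:
        raise ValueError(f"unknown granularity {granularity!r}")
    sub = _apply_filters(facts, filters)
    width = _GRANULARITY_SLICE[granularity]
    rows = []
    if sub.empty:
        return pd.DataFrame(columns=["period", "measure", "numerator", "denominator", "rate"])
    periods = pd.period_range(
        sub["DATE"].min(), sub["DATE"].max(), freq=_GRANULARITY_FREQ[granularity]
    ).astype(str)
    keyed = sub.assign(period=sub["DATE"].str[:width])
    count_cols = list(dict.fromkeys(c for pair in MEASURES.values() for c in pair))
    sums = keyed.groupby("period")[count_cols].sum()
    for period in periods:
        for measure, (num_col, den_col) in MEASURES.items():
            num = int(sums.at[period, num_col]) if period in sums.index else 0
            den = int(sums.at[period, den_col]) if period in sums.index else 0
            rows.append(
                {
                    "period": period,
                    "measure": measure,
                    "numerator": num,
                    "denominator": den,
                    "rate": num / den if den else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _hourly_history(transfusions: pd.DataFrame, filters: dict[str, str] | None) -> pd.DataFrame:
    sub = _apply_filters(transfusions, filters)
    rows = []
    for hour in range(24):
        if sub.empty:
            block = sub
        else:
            block = sub[sub["START_DT_TM"].str[11:13].astype(int) == hour]
        n = len(block)
        for measure in MEASURES:
            if measure == "post":
                num = int((block["POST_PASS"] == POST_PASS).sum()) if n else 0
                den = int((block["POST_PASS"] != POST_NOT_ASSESSABLE).sum()) if n else 0
            else:
                num = int(block[_FLAG_COLS[measure]].sum()) if n else 0
                den = n
            rows.append(
                {
                    "period": hour,
                    "measure": measure,
                    "numerator": num,
                    "denominator": den,
                    "rate": num / den if den else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event-level recomputation (two-granularity consistency oracles)

def missing_consents_from_events(transfusions: pd.DataFrame, month: str) -> int:
    """Query 1 recomputed from the event-granularity table."""
    if transfusions.empty:
        return 0
    sub = transfusions[transfusions["START_DT_TM"].str.startswith(month + "-")]
    return int((1 - sub["CONSENT_DOCUMENTED"]).sum())


def rates_from_events(
    transfusions: pd.DataFrame, measure: str, dimension: str, period: str | None = None
) -> pd.DataFrame:
    """Query 2 recomputed from the event-granularity table."""
    dim_col = DIMENSIONS[dimension]
    sub = transfusions
    if period is not None and not sub.empty:
        sub = sub[sub["START_DT_TM"].str.startswith(period)]
    rows = []
    for value, block in sub.groupby(dim_col):
        if measure == "post":
            num = int((block["POST_PASS"] == POST_PASS).sum())
            den = int((block["POST_PASS"] != POST_NOT_ASSESSABLE).sum())
        else:
            num = int(block[_FLAG_COLS[measure]].sum())
            den = len(block)
        if den:
            rows.append({dim_col: value, "NUMERATOR": num, "DENOMINATOR": den, "RATE": num / den})
    out = pd.DataFrame(rows, columns=[dim_col, "NUMERATOR", "DENOMINATOR", "RATE"])
    return out.sort_values(["RATE", dim_col], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# persistence and deterministic export

def save_tables(path: str | Path, tables: dict[str, pd.DataFrame]) -> None:
    with sqlite3.connect(path) as conn:
        for name, df in tables.items():
            df.to_sql(name, conn, if_exists="replace", index=False)


def load_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    with sqlite3.connect(path) as conn:
        names = [
            r[0]
            for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'").fetchall()
        ]
        return {n: pd.read_sql(f'SELECT * FROM "{n}"', conn) for n in names}


def export_csv(df: pd.DataFrame, path: str | Path | None = None) -> bytes:
    """Deterministic CSV bytes of a table (optionally also written out)."""
    data = df.to_csv(index=False, lineterminator="\n", float_format="%.6f").encode()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_bytes(data)
    return data
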