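"""Episode CSV dialect and results serialization.

The episode CSV has one row per hospitalization with columns

    patient_id, provider_id, admission_index, admission_date, discharge_date,
    in_hospital_death (0/1), death_date, followup_end_date,
    age, sex, comorb3, n_procedures

Date columns hold either ISO-8601 calendar dates (converted on read to day
offsets from the earliest admission in the file) or plain numeric day offsets,
possibly fractional; an empty string means absent.  Internally all times are
day offsets (columns ``*_day``).
"""

from __future__ import annotations

import pandas as pd

from .episodes import EPISODE_COLUMNS, validate_episodes

_DATE_TO_DAY = {
    "admission_date": "admission_day",
    "discharge_date": "discharge_day",
    "death_date": "death_day",
    "followup_end_date": "followup_end_day",
}
CSV_COLUMNS = [
    "patient_id", "provider_id", "admission_index",
    "admission_date", "discharge_date", "in_hospital_death",
    "death_date", "followup_end_date",
    "age", "sex", "comorb3", "n_procedures",
]


def _resolve_dates(df: pd.DataFrame) -> pd.DataFrame:
    """Turn date columns into float day offsets from the earliest admission."""
    date_cols = list(_DATE_TO_DAY)
    numeric = {}
    all_numeric = True
    for c in date_cols:
        as_num = pd.to_numeric(df[c], errors="coerce")
        # numeric if every non-empty entry parses as a number
        filled = df[c].notna() & (df[c].astype(str).str.strip() != "")
        if (filled & as_num.isna()).any():
            all_numeric = False
            break
        numeric[c] = as_num
    if all_numeric:
        for c, day_c in _DATE_TO_DAY.items():
            df[day_c] = numeric[c]
    else:
        parsed = {}
        for c in date_cols:
            parsed[c] = pd.to_datetime(df[c], format="ISO8601", errors="raise")
        origin = parsed["admission_date"].min()
        for c, day_c in _DATE_TO_DAY.items():
            df[day_c] = (parsed[c] - origin).dt.total_seconds() / 86400.0
    return df.drop(columns=date_cols)


def read_episodes(path, validate: bool = True) -> pd.DataFrame:
    """Read an episode CSV; optionally validate the structural rules."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"episode CSV is missing required columns: {missing}")
    dup = df.duplicated(subset=["patient_id", "admission_index"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # 1-based incl. header
        raise ValueError(f"duplicate (patient_id, admission_index) at CSV rows {rows}")
    df = _resolve_dates(df)
    df = df[EPISODE_COLUMNS]
    if validate:
        df, _ = validate_episodes(df)
    return df


def write_episodes(df: pd.DataFrame, path) -> None:
    """Write an episode table in the CSV dialect (numeric day offsets)."""
    out = df.copy()
    for c, day_c in _DATE_TO_DAY.items():
        out[c] = out[day_c]
    out = out[CSV_COLUMNS]
    out.to_csv(path, index=False)
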