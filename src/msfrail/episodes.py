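"""Episode tables and clock-reset transition datasets.

An *episode* is one hospitalization of one patient at one provider.  The episode
table is long-format, one row per episode, with day offsets from the cohort
origin.  From it we derive the four clock-reset transition datasets of the
multi-state model:

    l=1  admission -> discharge           (origin: in hospital)
    l=2  admission -> in-hospital death   (origin: in hospital)
    l=3  discharge -> readmission         (origin: out of hospital)
    l=4  discharge -> out-of-hospital death

Within each origin state the two outgoing transitions are competing risks: the
occurrence of one censors the other, and both are capped by administrative
censoring at end of follow-up.  The clock resets at every state entry, so all
times are durations in days since entering the origin state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSITION_LABELS = {
    1: "admission->discharge",
    2: "admission->in-hospital death",
    3: "discharge->readmission",
    4: "discharge->out-of-hospital death",
}

COVARIATE_COLUMNS = ["age", "sex", "comorb3", "n_procedures"]

EPISODE_COLUMNS = [
    "patient_id",
    "provider_id",
    "admission_index",
    "admission_day",
    "discharge_day",
    "in_hospital_death",
    "death_day",
    "followup_end_day",
    "age",
    "sex",
    "comorb3",
    "n_procedures",
]

#: zero-length in-state spells are recoded to this duration (days) so that all
#: transition times are strictly positive
HALF_DAY = 0.5

MAX_PROCEDURES = 5


class EpisodeValidationError(ValueError):
    """Raised when the episode table violates a structural rule.

    Carries ``rule`` (the violated rule name) and ``patient_ids`` (offenders).
    """

    def __init__(self, rule: str, patient_ids, message: str):
        self.rule = rule
        self.patient_ids = list(patient_ids)
        super().__init__(f"[{rule}] {message} (patients: {self.patient_ids[:10]})")


@dataclass
class TransitionDataset:
    """Rows of one clock-reset transition: (time since state entry, event flag).

    ``frame`` has columns patient_id, provider_id, episode_index, time, event
    plus the covariates.  Every spell in the origin state contributes exactly
    one row; the competing transition's event appears here as a censoring.
    """

    transition: int
    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = TRANSITION_LABELS[self.transition]
        t = self.frame["time"].to_numpy()
        if len(t) and (t <= 0).any():
            raise ValueError(f"non-positive times in transition {self.transition}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def X(self) -> np.ndarray:
        return self.frame[COVARIATE_COLUMNS].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["provider_id"].to_numpy()


def _check_columns(episodes: pd.DataFrame) -> None:
    missing = [c for c in EPISODE_COLUMNS if c not in episodes.columns]
    if missing:
        raise EpisodeValidationError("missing-columns", [], f"missing columns {missing}")


def validate_episodes(
    episodes: pd.DataFrame, merge_same_day: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Validate an episode table; return (validated table, diagnostics).

    Structural rules enforced (violations raise :class:`EpisodeValidationError`):

    - admission indices consecutive from 1 within patient, episodes ordered and
      non-overlapping;
    - one provider per patient (patients treated at several institutions are
      outside the cohort definition);
    - discharge on/after admission; an in-hospital death has no discharge day
      and a death day at the episode end; death is terminal;
    - covariates in range: age > 0, sex/comorb3 binary, 0 <= n_procedures <= 5.

    A readmission on the same calendar day as the previous discharge is merged
    into the previous episode (one continuous stay); the count is reported in
    the diagnostics under ``"merged_same_day"``.
    """
    _check_columns(episodes)
    df = episodes.copy()
    df = df.sort_values(["patient_id", "admission_index"], kind="stable").reset_index(drop=True)
    diagnostics: dict[str, int] = {}

    def _fail(rule: str, mask_patients, msg: str):
        raise EpisodeValidationError(rule, mask_patients, msg)

    # covariate ranges
    if (df["age"] <= 0).any():
        _fail("age-positive", df.loc[df["age"] <= 0, "patient_id"].unique(), "age must be > 0")
    for col in ("sex", "comorb3"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            _fail(f"{col}-binary", df.loc[bad, "patient_id"].unique(), f"{col} must be 0/1")
    bad = (df["n_procedures"] < 0) | (df["n_procedures"] > MAX_PROCEDURES)
    if bad.any():
        _fail(
            "n-procedures-range",
            df.loc[bad, "patient_id"].unique(),
            f"n_procedures must be in 0..{MAX_PROCEDURES}",
        )

    # one provider per patient
    nprov = df.groupby("patient_id")["provider_id"].nunique()
    multi = nprov[nprov > 1]
    if len(multi):
        _fail(
            "same-institution",
            multi.index,
            "patients must be hospitalised at the same institution throughout",
        )

    # episode-level dates
    has_disch = df["discharge_day"].notna()
    bad = has_disch & (df["discharge_day"] < df["admission_day"])
    if bad.any():
        _fail("discharge-after-admission", df.loc[bad, "patient_id"].unique(),
              "discharge_day earlier than admission_day")
    ihd = df["in_hospital_death"].astype(bool)
    bad = ihd & has_disch
    if bad.any():
        _fail("in-hospital-death-no-discharge", df.loc[bad, "patient_id"].unique(),
              "in-hospital death rows must not carry a discharge day")
    bad = ihd & df["death_day"].isna()
    if bad.any():
        _fail("in-hospital-death-day", df.loc[bad, "patient_id"].unique(),
              "in-hospital death rows must carry the death day")
    bad = ihd & (df["death_day"] < df["admission_day"])
    if bad.any():
        _fail("death-after-admission", df.loc[bad, "patient_id"].unique(),
              "death_day earlier than admission_day")

    # within-patient sequencing
    merged_rows = 0
    grouped = df.groupby("patient_id", sort=False)
    idx_ok = grouped["admission_index"].apply(
        lambda s: bool((s.to_numpy() == np.arange(1, len(s) + 1)).all())
    )
    if not idx_ok.all():
        _fail("admission-index-consecutive", idx_ok[~idx_ok].index,
              "admission_index must run 1,2,... within patient")

    # terminal death / overlap / same-day merges, per patient
    drop_rows: list[int] = []
    for pid, g in grouped:
        n = len(g)
        dead = g["in_hospital_death"].astype(bool).to_numpy()
        if dead[:-1].any():
            _fail("death-terminal", [pid], "episodes recorded after an in-hospital death")
        adm = g["admission_day"].to_numpy(dtype=float)
        dis = g["discharge_day"].to_numpy(dtype=float)
        death = g["death_day"].to_numpy(dtype=float)
        if n > 1:
            if np.isnan(dis[:-1]).any():
                _fail("discharge-before-readmission", [pid],
                      "readmission without a discharge from the previous episode")
            # out-of-hospital death can only follow the final episode
            if np.isfinite(death[:-1][~dead[:-1]]).any():
                _fail("death-terminal", [pid], "death recorded before a later admission")
            gap = adm[1:] - dis[:-1]
            if (gap < 0).any():
                _fail("non-overlapping", [pid], "episode intervals overlap")
            same_day = np.where(gap == 0)[0]
            if len(same_day) and merge_same_day:
                # merge episode i+1 into episode i; only safe pairwise, so do
                # it iteratively on the row labels
                rows = g.index.to_numpy()
                for i in same_day[::-1]:  # reverse so chained merges propagate
                    df.loc[rows[i], "discharge_day"] = df.loc[rows[i + 1], "discharge_day"]
                    df.loc[rows[i], "in_hospital_death"] = df.loc[rows[i + 1], "in_hospital_death"]
                    df.loc[rows[i], "death_day"] = df.loc[rows[i + 1], "death_day"]
                    drop_rows.append(rows[i + 1])
                merged_rows += len(same_day)
            elif len(same_day):
                _fail("same-day-readmission", [pid],
                      "readmission on the discharge day (merging disabled)")

    if drop_rows:
        df = df.drop(index=drop_rows)
        # renumber admission indices after merges
        df["admission_index"] = df.groupby("patient_id").cumcount() + 1
        df = df.reset_index(drop=True)
        diagnostics["merged_same_day"] = merged_rows

    # follow-up end covers everything observed
    last_day = df[["admission_day", "discharge_day", "death_day"]].max(axis=1)
    bad = last_day > df["followup_end_day"]
    if bad.any():
        _fail("followup-covers-events", df.loc[bad, "patient_id"].unique(),
              "events recorded after followup_end_day")

    return df, diagnostics


def filter_providers(
    episodes: pd.DataFrame, min_patients: int = 20
) -> tuple[pd.DataFrame, list]:
    """Keep providers contributing at least ``min_patients`` distinct patients.

    Small providers give unstable frailty estimates; the default threshold of
    20 patients follows the simulation evidence behind the modelling approach.
    Returns the filtered table and the list of excluded provider ids.
    """
    counts = episodes.groupby("provider_id")["patient_id"].nunique()
    excluded = sorted(counts[counts < min_patients].index.tolist())
    kept = episodes[~episodes["provider_id"].isin(excluded)].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            f"no provider has >= {min_patients} patients; lower min_patients"
        )
    return kept, excluded


def truncate_admissions(episodes: pd.DataFrame, max_admissions: int = 5) -> pd.DataFrame:
    """Administratively censor each patient after their ``max_admissions``-th discharge.

    Episodes beyond the cap are dropped, the patient's follow-up ends at the
    capped discharge day, and any out-of-hospital death after that day is
    recoded as censored.
    """
    if max_admissions < 1:
        raise ValueError("max_admissions must be >= 1")
    df = episodes.copy()
    over = df["admission_index"] > max_admissions
    affected = df.loc[over, "patient_id"].unique()
    df = df[~over]
    if len(affected):
        last = df[df["patient_id"].isin(affected) & (df["admission_index"] == max_admissions)]
        cap = last.set_index("patient_id")["discharge_day"]
        pid = df["patient_id"]
        df.loc[pid.isin(affected), "followup_end_day"] = pid.map(cap).loc[pid.isin(affected)]
        # death observed only within the new window
        late_death = pid.isin(affected) & (df["death_day"] > pid.map(cap))
        df.loc[late_death & ~df["in_hospital_death"].astype(bool), "death_day"] = np.nan
    return df.reset_index(drop=True)


def build_transition_datasets(
    episodes: pd.DataFrame, followup_days: int = 1826
) -> dict[int, TransitionDataset]:
    """Convert a validated episode table into the four clock-reset datasets.

    For every in-hospital episode, one row goes to l=1 (event = discharged) and
    one to l=2 (event = died in hospital), with identical times — the competing
    event censors the other.  For every post-discharge spell, rows go to l=3
    (event = readmitted) and l=4 (event = died out of hospital), capped at the
    patient's administrative follow-up end.  The dead state is absorbing.
    ``followup_days`` is used only for patients whose followup_end_day is
    missing (origin + 5 years by default).
    """
    df = episodes.sort_values(["patient_id", "admission_index"], kind="stable")
    fu = df["followup_end_day"].to_numpy(dtype=float)
    fu = np.where(np.isnan(fu), df["admission_day"].to_numpy(dtype=float) + followup_days, fu)

    pid = df["patient_id"].to_numpy()
    prov = df["provider_id"].to_numpy()
    aidx = df["admission_index"].to_numpy()
    adm = df["admission_day"].to_numpy(dtype=float)
    dis = df["discharge_day"].to_numpy(dtype=float)
    ihd = df["in_hospital_death"].astype(bool).to_numpy()
    death = df["death_day"].to_numpy(dtype=float)
    covs = df[COVARIATE_COLUMNS].to_numpy(dtype=float)

    # next admission day within patient (NaN for the last episode)
    next_adm = np.full(len(df), np.nan)
    same_pat = pid[1:] == pid[:-1]
    next_adm[:-1][same_pat] = adm[1:][same_pat]

    rows: dict[int, list] = {1: [], 2: [], 3: [], 4: []}

    # in-hospital spells
    end = np.where(ihd, death, dis)
    end = np.where(np.isnan(end), fu, end)  # censored in hospital at follow-up end
    los = end - adm
    los = np.where(los == 0, HALF_DAY, los)
    discharged = ~np.isnan(dis)
    for l, ev in ((1, discharged.astype(int)), (2, ihd.astype(int))):
        rows[l] = [pid, prov, aidx, los, ev, covs]

    # out-of-hospital spells (only after an actual discharge, none after death)
    has_next = ~np.isnan(next_adm)
    died_out = ~has_next & ~np.isnan(death) & ~ihd
    spell_end = np.where(has_next, next_adm, np.where(died_out, death, fu))
    t_out = spell_end - dis
    t_out = np.where(t_out == 0, HALF_DAY, t_out)
    keep = discharged.copy()
    rows[3] = [pid[keep], prov[keep], aidx[keep], t_out[keep],
               has_next[keep].astype(int), covs[keep]]
    rows[4] = [pid[keep], prov[keep], aidx[keep], t_out[keep],
               died_out[keep].astype(int), covs[keep]]

    out_ds = {}
    for l, (p, pr, ai, t, ev, xc) in ((l, rows[l]) for l in (1, 2, 3, 4)):
        frame = pd.DataFrame(
            {
                "patient_id": p,
                "provider_id": pr,
                "episode_index": ai,
                "time": t,
                "event": ev,
            }
        )
        frame[COVARIATE_COLUMNS] = xc
        out_ds[l] = TransitionDataset(transition=l, frame=frame.reset_index(drop=True))
    return out_ds


def percentage(count: float, denominator: float, decimals: int = 2) -> float:
    """Percentage of ``count`` over ``denominator`` rounded to ``decimals``."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * count / denominator, decimals)


def next_admissions(
    n_admitted: int,
    n_in_hospital_death: int,
    n_death_after_discharge: int,
    n_censored_after_discharge: int,
) -> int:
    """Patients admitted a (k+1)-th time, by the cohort flow identity.

    Of those admitted a k-th time, the in-hospital deaths never leave alive,
    and of the discharged, those who die out of hospital or reach end of
    follow-up before a readmission never return.
    """
    return (
        n_admitted
        - n_in_hospital_death
        - n_death_after_discharge
        - n_censored_after_discharge
    )


def cohort_accounting(episodes: pd.DataFrame, max_admissions: int = 5) -> pd.DataFrame:
    """Descriptive cohort summary by admission index (statistics x index).

    Column k describes the patients hospitalised at least k times.  Counts and
    percentages of the column's admitted patients: discharges, in-hospital
    deaths, deaths after discharge (before any readmission), administrative
    censorings after discharge; length of stay, age, sex, comorbidity and
    procedure-count distributions.  The flow identity

        n_admitted(k+1) = n_discharged(k) - deaths after discharge(k)
                          - censored after discharge(k)

    holds exactly by construction.
    """
    df = episodes.sort_values(["patient_id", "admission_index"], kind="stable")
    cols = {}
    for k in range(1, max_admissions + 1):
        g = df[df["admission_index"] == k]
        n_adm = g["patient_id"].nunique()
        if n_adm == 0:
            break
        discharged = g["discharge_day"].notna()
        n_dis = int(discharged.sum())
        n_ihd = int(g["in_hospital_death"].astype(bool).sum())
        # of the discharged at k: readmitted vs died out vs censored
        nxt = df[df["admission_index"] == k + 1]["patient_id"]
        readmitted = g["patient_id"].isin(set(nxt))
        died_out = discharged & ~readmitted & g["death_day"].notna() & ~g["in_hospital_death"].astype(bool)
        censored = discharged & ~readmitted & ~died_out
        end = np.where(
            g["in_hospital_death"].astype(bool),
            g["death_day"],
            g["discharge_day"],
        ).astype(float)
        los = end - g["admission_day"].to_numpy(dtype=float)
        los = los[np.isfinite(los)]
        stats = {
            "n_admitted": n_adm,
            "n_discharged": n_dis,
            "pct_discharged": percentage(n_dis, n_adm),
            "n_in_hospital_death": n_ihd,
            "pct_in_hospital_death": percentage(n_ihd, n_adm),
            "n_death_after_discharge": int(died_out.sum()),
            "pct_death_after_discharge": percentage(int(died_out.sum()), n_adm),
            "n_censored_after_discharge": int(censored.sum()),
            "pct_censored_after_discharge": percentage(int(censored.sum()), n_adm),
            "mean_los": round(float(np.mean(los)), 2) if len(los) else float("nan"),
            "sd_los": round(float(np.std(los, ddof=1)), 2) if len(los) > 1 else float("nan"),
            "mean_age": round(float(g["age"].mean()), 2),
            "sd_age": round(float(g["age"].std(ddof=1)), 2) if n_adm > 1 else float("nan"),
            "n_female": int((g["sex"] == 0).sum()),
            "pct_female": percentage(int((g["sex"] == 0).sum()), n_adm),
            "n_comorb3": int((g["comorb3"] == 1).sum()),
            "pct_comorb3": percentage(int((g["comorb3"] == 1).sum()), n_adm),
        }
        for npro in range(MAX_PROCEDURES + 1):
            cnt = int((g["n_procedures"] == npro).sum())
            stats[f"n_procedures_{npro}"] = cnt
            stats[f"pct_procedures_{npro}"] = percentage(cnt, n_adm)
        cols[k] = stats
    summary = pd.DataFrame(cols)
    summary.columns.name = "admission_index"
    return summary
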