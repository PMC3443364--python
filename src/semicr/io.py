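"""Dataset CSV dialect, loading with exclusion accounting, and serialization.

One row per subject; empty cells denote absent values; times are years from
study entry stored with 6-decimal precision.  Columns:

    id, age, sex, baseline_state, last_healthy_time, ci_first_time,
    ci_last_time, ltf_lower, ltf_upper, death_time, end_time, died, uncertain

``baseline_state`` is ``H`` or ``CI`` (empty means the prevalence screen is
missing and the row is excluded).  ``died`` flags an audited death: a row
flagged dead without a recorded ``death_time`` is excluded.  ``uncertain``
flags records the study could not resolve; they are excluded too.  Rows that
fail the record invariants are reported individually and tallied as
``malformed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import IndividualRecord, RecordError
from .model import DEFAULT_AGE_CENTER, Covariates, State

COLUMNS = [
    "id",
    "age",
    "sex",
    "baseline_state",
    "last_healthy_time",
    "ci_first_time",
    "ci_last_time",
    "ltf_lower",
    "ltf_upper",
    "death_time",
    "end_time",
    "died",
    "uncertain",
]

_TIME_COLS = [
    "last_healthy_time",
    "ci_first_time",
    "ci_last_time",
    "ltf_lower",
    "ltf_upper",
    "death_time",
    "end_time",
]


@dataclass
class ExclusionAudit:
    """Accounting of rows removed before analysis."""

    initial_count: int
    exclusions: dict[str, int] = field(default_factory=dict)
    analysis_count: int = 0

    def validate(self) -> None:
        total = sum(self.exclusions.values())
        if self.analysis_count != self.initial_count - total:
            raise ValueError("exclusion audit arithmetic does not balance")
        if self.analysis_count < 0 or any(v < 0 for v in self.exclusions.values()):
            raise ValueError("negative counts in exclusion audit")


@dataclass
class LoadResult:
    records: list[IndividualRecord]
    audit: ExclusionAudit
    row_errors: list[tuple[object, str]] = field(default_factory=list)


def records_to_frame(
    records: Sequence[IndividualRecord], age_center: float = DEFAULT_AGE_CENTER
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "age": round(r.x.age_c + age_center, 6),
                "sex": r.x.sex,
                "baseline_state": r.baseline_state.value,
                "last_healthy_time": r.last_healthy_time,
                "ci_first_time": r.ci_first_time,
                "ci_last_time": r.ci_last_time,
                "ltf_lower": r.ltf_lower,
                "ltf_upper": r.ltf_upper,
                "death_time": r.death_time,
                "end_time": r.end_time,
                "died": int(r.death_time is not None),
                "uncertain": 0,
            }
        )
    df = pd.DataFrame(rows, columns=COLUMNS)
    for c in _TIME_COLS:
        df[c] = df[c].astype(float).round(6)
    return df


def write_dataset(
    records: Sequence[IndividualRecord],
    path,
    age_center: float = DEFAULT_AGE_CENTER,
) -> None:
    records_to_frame(records, age_center).to_csv(path, index=False)


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def load_dataset(path, age_center: float = DEFAULT_AGE_CENTER) -> LoadResult:
    """Read the CSV dialect, excluding and tallying unusable rows."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns and c not in ("died", "uncertain")]
    if missing:
        raise ValueError(f"dataset is missing columns {missing}")
    if "died" not in df.columns:
        df["died"] = df["death_time"].notna().astype(int)
    if "uncertain" not in df.columns:
        df["uncertain"] = 0
    n0 = len(df)
    excl = {
        "missing_baseline": 0,
        "death_without_date": 0,
        "uncertain_record": 0,
        "malformed": 0,
    }
    records: list[IndividualRecord] = []
    row_errors: list[tuple[object, str]] = []
    for _, row in df.iterrows():
        base = row["baseline_state"]
        if pd.isna(base) or str(base).strip() == "":
            excl["missing_baseline"] += 1
            continue
        if int(row["died"]) == 1 and pd.isna(row["death_time"]):
            excl["death_without_date"] += 1
            continue
        if int(row["uncertain"]) == 1:
            excl["uncertain_record"] += 1
            continue
        try:
            rec = IndividualRecord(
                id=row["id"],
                x=Covariates(float(row["age"]) - age_center, int(row["sex"])),
                baseline_state=State(str(base).strip()),
                end_time=float(row["end_time"]),
                last_healthy_time=_opt(row["last_healthy_time"]),
                ci_first_time=_opt(row["ci_first_time"]),
                ci_last_time=_opt(row["ci_last_time"]),
                ltf_lower=_opt(row["ltf_lower"]),
                ltf_upper=_opt(row["ltf_upper"]),
                death_time=_opt(row["death_time"]),
            )
            rec.validate()
        except (RecordError, ValueError) as exc:
            excl["malformed"] += 1
            row_errors.append((row["id"], str(exc)))
            continue
        records.append(rec)
    audit = ExclusionAudit(n0, excl, len(records))
    audit.validate()
    if not records:
        raise ValueError("all rows were excluded; nothing to analyse")
    return LoadResult(records, audit, row_errors)


def make_screening_fixture(
    path,
    n_total: int = 2524,
    n_missing_baseline: int = 56,
    n_death_without_date: int = 4,
    n_uncertain: int = 12,
    seed: int = 20870,
    params=None,
) -> pd.DataFrame:
    """Write a synthetic screening file with the classic exclusion structure:
    a simulated cohort in which the first rows are corrupted to carry a
    missing prevalence screen, an audited death without a date, or an
    uncertain-record flag.  Synthetic stand-in for a real study export."""
    from .simulate import default_params, simulate_cohort

    p = params or default_params()
    sim = simulate_cohort(p, n_total, seed=seed)
    df = records_to_frame(sim.records, p.age_center)
    i0 = 0
    df.loc[i0 : i0 + n_missing_baseline - 1, "baseline_state"] = ""
    i0 += n_missing_baseline
    idx = slice(i0, i0 + n_death_without_date - 1)
    df.loc[idx, "died"] = 1
    df.loc[idx, "death_time"] = np.nan
    i0 += n_death_without_date
    df.loc[i0 : i0 + n_uncertain - 1, "uncertain"] = 1
    df.to_csv(path, index=False)
    return df
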