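"""Cohort preparation: portal-status classification, inclusion criteria,
baseline definition, and baseline covariate discretization.

The study window is 12 calendar quarters, indexed t = 0..11 and labelled
Y13Q3..Y16Q2 (Q1 = Jan-Mar).  Each patient carries two event quarters: the
quarter of the first ("New") primary-care visit, ``new_index``, and -- for
portal adopters -- the quarter of portal activation, ``adopt_index``.  The
matching baseline is the quarter immediately before the earlier of the two
events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Number of quarters in the study window (t = 0 .. N_QUARTERS-1).
N_QUARTERS = 12

#: Calendar anchor of t = 0: third quarter (Jul-Sep) of 2013.
_BASE_YEAR = 2013
_BASE_QUARTER = 3  # 1-based within year

STATUS_USER = "user"
STATUS_CONSISTENT = "consistent-user"
STATUS_TEMPORARY = "temporary-user"
STATUS_NONUSER = "non-user"
STATUSES = (STATUS_USER, STATUS_CONSISTENT, STATUS_TEMPORARY, STATUS_NONUSER)

#: Level sets used both at baseline and for the time-varying APN covariate.
APN_LEVELS = ("0", "1-4", "5+")
ARRIVED_LEVELS = ("0", "1", "2+")
BINARY_LEVELS = ("0", "1+")

#: Time-invariant demographic covariates (matching + regression adjustment).
DEMOGRAPHIC_COLUMNS = ("age_category", "sex", "race", "marital_status", "insurance")

#: Baseline utilization categories added for matching.
BASELINE_CATEGORY_COLUMNS = ("apn_cat", "arrived_cat", "noshow_cat", "cancel_cat")


class CohortError(ValueError):
    """Raised for inconsistent patient histories or malformed cohort tables."""


def quarter_label(t: int) -> str:
    """Map quarter index t (0..11) to its calendar label, e.g. 0 -> 'Y13Q3'."""
    t = int(t)
    if not 0 <= t < N_QUARTERS:
        raise ValueError(f"quarter index {t} outside study window 0..{N_QUARTERS - 1}")
    q0 = (_BASE_QUARTER - 1) + t  # 0-based absolute quarter offset
    year = _BASE_YEAR + q0 // 4
    return f"Y{year % 100}Q{q0 % 4 + 1}"


def quarter_index(label: str) -> int:
    """Inverse of :func:`quarter_label`: 'Y13Q3' -> 0, 'Y16Q2' -> 11."""
    try:
        year = int(label[1:3])
        quarter = int(label[4])
        if label[0] != "Y" or label[3] != "Q":
            raise ValueError
    except (ValueError, IndexError):
        raise ValueError(f"malformed quarter label {label!r}") from None
    t = (2000 + year - _BASE_YEAR) * 4 + (quarter - 1) - (_BASE_QUARTER - 1)
    if not 0 <= t < N_QUARTERS:
        raise ValueError(f"label {label!r} outside study window Y13Q3..Y16Q2")
    return t


def classify_patient_status(
    adopt_quarter: float | None,
    active_at_end: bool,
    window: tuple[int, int] = (0, N_QUARTERS - 1),
) -> str:
    """Classify a patient into the four-way portal-status partition.

    Parameters
    ----------
    adopt_quarter
        Quarter of portal activation.  ``None``/NaN means the patient never
        registered.  Values below ``window[0]`` mean pre-study adoption.
    active_at_end
        Whether the portal account was still active at the end of the window.
    """
    missing = adopt_quarter is None or (
        isinstance(adopt_quarter, float) and math.isnan(adopt_quarter)
    )
    if missing:
        if active_at_end:
            raise CohortError("patient active at end of study but never adopted portal")
        return STATUS_NONUSER
    if not active_at_end:
        return STATUS_TEMPORARY
    if adopt_quarter < window[0]:
        return STATUS_CONSISTENT
    if adopt_quarter > window[1]:
        raise CohortError(f"adoption quarter {adopt_quarter} beyond study window")
    return STATUS_USER


def apply_inclusion_criteria(
    patients: pd.DataFrame, allow_window_start_adoption: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the primary-cohort inclusion criteria.

    Retains non-users with a new visit strictly after the first study quarter
    and users whose new visit *and* portal adoption are strictly after it;
    consistent-users and temporary-users are dropped.  Returns the retained
    table and an exclusion report (reason, count).

    ``allow_window_start_adoption`` relaxes the adoption criterion to
    ``adopt_index >= 0`` (used by the consistent-user sensitivity scenario,
    which assigns those patients adoption at t = 0).
    """
    reasons = pd.Series("retained", index=patients.index, dtype=object)
    status = patients["status"]
    reasons[status == STATUS_CONSISTENT] = "consistent-user"
    reasons[status == STATUS_TEMPORARY] = "temporary-user"
    early_new = (reasons == "retained") & ~(patients["new_index"] > 0)
    reasons[early_new] = "new visit not after window start"
    adopt_floor = 0 if allow_window_start_adoption else 1
    early_adopt = (
        (reasons == "retained")
        & (status == STATUS_USER)
        & ~(patients["adopt_index"] >= adopt_floor)
    )
    reasons[early_adopt] = "adoption not after window start"

    kept = patients.loc[reasons == "retained"].copy()
    counts = reasons.value_counts()
    report = pd.DataFrame(
        {"reason": counts.index, "count": counts.to_numpy()}
    ).sort_values("reason", ignore_index=True)
    return kept, report


def compute_baseline_quarter(new_index: float, adopt_index: float | None = None) -> int:
    """Baseline quarter: the quarter before the earlier of new visit and adoption."""
    events = []
    for v in (new_index, adopt_index):
        if v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            continue
        events.append(int(v))
    if not events:
        raise CohortError("cannot define baseline: no event quarter provided")
    return min(events) - 1


def apn_category(apn: int) -> str:
    if apn < 0:
        raise ValueError(f"negative active problem number {apn}")
    if apn == 0:
        return "0"
    return "1-4" if apn <= 4 else "5+"


def arrived_category(arrived: int) -> str:
    if arrived < 0:
        raise ValueError(f"negative arrived count {arrived}")
    if arrived >= 2:
        return "2+"
    return str(int(arrived))


def binary_category(count: int) -> str:
    if count < 0:
        raise ValueError(f"negative count {count}")
    return "0" if count == 0 else "1+"


@dataclass(frozen=True)
class BaselineProfile:
    """Discretized utilization and disease-burden state at the baseline quarter."""

    patient_id: int
    baseline_t: int
    apn_cat: str
    arrived_cat: str
    noshow_cat: str
    cancel_cat: str


def discretize_baseline(
    patient_id: int, baseline_t: int, apn: int, arrived: int, no_show: int, cancelled: int
) -> BaselineProfile:
    """Discretize baseline-quarter counts into the matching level sets."""
    return BaselineProfile(
        patient_id=patient_id,
        baseline_t=int(baseline_t),
        apn_cat=apn_category(apn),
        arrived_cat=arrived_category(arrived),
        noshow_cat=binary_category(no_show),
        cancel_cat=binary_category(cancelled),
    )


def baseline_table(patients: pd.DataFrame, quarters: pd.DataFrame) -> pd.DataFrame:
    """Build the per-patient baseline profile table for an included cohort.

    Requires each patient's baseline-quarter observation row to be present.
    """
    baseline_t = patients.apply(
        lambda row: max(
            compute_baseline_quarter(row["new_index"], row.get("adopt_index")), 0
        ),
        axis=1,
    )
    base = patients[["patient_id"]].copy()
    base["baseline_t"] = baseline_t.to_numpy()

    merged = base.merge(
        quarters,
        left_on=["patient_id", "baseline_t"],
        right_on=["patient_id", "t"],
        how="left",
    )
    missing = merged["apn"].isna()
    if missing.any():
        first = merged.loc[missing].iloc[0]
        raise CohortError(
            f"missing baseline observation for patient {int(first['patient_id'])} "
            f"at t={int(first['baseline_t'])}"
        )
    out = pd.DataFrame(
        {
            "patient_id": merged["patient_id"],
            "baseline_t": merged["baseline_t"].astype(int),
            "apn_cat": merged["apn"].astype(int).map(apn_category),
            "arrived_cat": merged["arrived"].astype(int).map(arrived_category),
            "noshow_cat": merged["no_show"].astype(int).map(binary_category),
            "cancel_cat": merged["cancelled"].astype(int).map(binary_category),
        }
    )
    return out


def validate_observations(quarters: pd.DataFrame) -> None:
    """Check the per-quarter observation invariants; raise CohortError on violation.

    Invariants: all counts and APN nonnegative; one row per (patient, t);
    APN nondecreasing within each patient's emitted window.
    """
    for col in ("apn", "arrived", "no_show", "cancelled"):
        if (quarters[col] < 0).any():
            raise CohortError(f"negative values in column {col!r}")
    if quarters.duplicated(["patient_id", "t"]).any():
        raise CohortError("duplicate (patient_id, t) observation rows")
    ordered = quarters.sort_values(["patient_id", "t"])
    diffs = ordered.groupby("patient_id")["apn"].diff()
    if (diffs.dropna() < 0).any():
        bad = ordered.loc[diffs < 0, "patient_id"].iloc[0]
        raise CohortError(f"active problem number decreases for patient {bad}")
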