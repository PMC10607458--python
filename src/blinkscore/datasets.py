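"""The packaged 20-participant pilot cohort.

One minute of blink data and a questionnaire were collected for each of
10 confirmed dry-eye patients (group DED) and 10 participants with no known
eye condition (group CONTROL); the table ships with the package so cohort
analyses run fully offline.

Columns: participant id, group, age (years), sex, daily electronics use
(+ roughly 0-3 h up to ++++ over 8 h), regular contact-lens wearing,
dry/gritty feeling, eye healthiness score (0-10), full and partial blink
rates (per minute), recording duration (s), and the open/close EAR ratio
(%).

The ``dry_gritty`` column needs a caveat: the source cohort table records
rates, demographics and totals but not the gritty answer itself.  Where the
printed total uniquely determines the answer it is filled in ("no" for the
participants whose scores need no symptom points, "yes" where the total is
reachable only with them); for DED8 and DED9 no answer reproduces the
printed total under the scoring formula, so the cell is left blank and
their questionnaires are omitted from :func:`pilot_questionnaires`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import ParticipantRecord
from .scoring import QuestionnaireRecord

__all__ = ["load_pilot_cohort", "pilot_participants", "pilot_questionnaires"]


def load_pilot_cohort() -> pd.DataFrame:
    """The pilot cohort as a DataFrame, one row per participant."""
    ref = resources.files("blinkscore").joinpath("data/pilot_cohort.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"id": str})


def pilot_participants() -> list[ParticipantRecord]:
    """The cohort as ParticipantRecord objects for the cohort-stats API."""
    df = load_pilot_cohort()
    return [
        ParticipantRecord(
            id=row["id"],
            group=row["group"],
            age=float(row["age"]),
            sex=row["sex"],
            full_rate_per_min=float(row["full_rate"]),
            partial_rate_per_min=float(row["partial_rate"]),
            eye_score=int(row["eye_score"]),
            video_duration_s=float(row["duration"]),
        )
        for _, row in df.iterrows()
    ]


def pilot_questionnaires() -> dict[str, QuestionnaireRecord]:
    """Questionnaire records keyed by participant id.

    Participants whose dry/gritty answer is indeterminate (see module
    docstring) are omitted.
    """
    df = load_pilot_cohort()
    out: dict[str, QuestionnaireRecord] = {}
    for _, row in df.iterrows():
        if pd.isna(row["dry_gritty"]):
            continue
        out[row["id"]] = QuestionnaireRecord(
            age=float(row["age"]),
            sex=row["sex"],
            dry_gritty=str(row["dry_gritty"]).lower() == "yes",
            regular_contact_lens=str(row["regular_contact_lens"]).lower() == "yes",
        )
    return out
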