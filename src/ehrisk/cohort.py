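"""Case/control cohort construction from patient timelines.

A case is a PTSD patient with a substance-use-disorder (ASUD) code within the
outcome window (default 90 days) after the index date; a control has none.
The index date is the latest encounter strictly after the first PTSD code and
strictly before the first ASUD code, with no ASUD record in the washout year
before it. Patients with ASUD on or before the day of the first PTSD code are
excluded, as are patients whose data span cannot cover the outcome window.

Interval conventions (the source rules name windows but not endpoints):
outcome window is half-open on the left and closed on the right,
``(index, index + 90]``; washout is closed, ``[index - 365, index]``; the
lookback keeps visits in ``[index - 365, index]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Sequence

import pandas as pd

from .synthetic_ehr import PatientTimeline

__all__ = ["CohortConfig", "CohortSample", "eligible_index_dates",
           "select_index_date", "label_sample", "build_cohort",
           "DEFAULT_PTSD_CODES", "DEFAULT_ASUD_CODES"]

DEFAULT_PTSD_CODES = frozenset({"309.81", "F43.10", "F43.11", "F43.12"})

# Editable default ASUD code list (common alcohol/substance-use ICD-9/10
# codes). The authoritative list used with real data is site-specific; this
# default exists so the pipeline runs end-to-end on synthetic data.
DEFAULT_ASUD_CODES = frozenset({
    "F10.10", "F10.20", "F11.10", "F11.20", "F12.10", "F12.20",
    "F13.20", "F14.10", "F14.20", "F15.20", "F16.10", "F19.20",
    "303.90", "304.00", "304.20", "304.30", "305.00", "305.20",
})


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    ptsd_codes: frozenset[str] = DEFAULT_PTSD_CODES
    asud_codes: frozenset[str] = DEFAULT_ASUD_CODES
    outcome_window_days: int = 90
    washout_days: int = 365
    lookback_days: int = 365

    def validate(self) -> None:
        if not self.ptsd_codes or not self.asud_codes:
            raise ValueError("code sets must be non-empty")
        if min(self.outcome_window_days, self.washout_days, self.lookback_days) <= 0:
            raise ValueError("window lengths must be positive")


@dataclasses.dataclass
class CohortSample:
    patient_id: str
    label: str                      # "case" | "control"
    index_date: dt.date
    # oldest -> newest; offset = whole days before the index date
    visits: list[tuple[int, list[str]]]
    static_tokens: list[str] = dataclasses.field(default_factory=list)

    @property
    def y(self) -> int:
        return 1 if self.label == "case" else 0


def _dx_code(token: str) -> str | None:
    if token.startswith("DX|"):
        return token.split("|", 1)[1]
    return None


def _code_dates(timeline: PatientTimeline, codes: frozenset[str]) -> list[dt.date]:
    return sorted(d for d, toks in timeline.encounters
                  for t in toks if (_dx_code(t) or "") in codes)


def eligible_index_dates(timeline: PatientTimeline, config: CohortConfig) -> list[dt.date]:
    """Encounter dates usable as the index date, oldest first.

    Empty when the patient is ineligible (no PTSD code, ASUD on/before the
    first PTSD day, or no qualifying encounter).
    """
    config.validate()
    ptsd_dates = _code_dates(timeline, config.ptsd_codes)
    if not ptsd_dates:
        return []
    first_ptsd = ptsd_dates[0]
    asud_dates = _code_dates(timeline, config.asud_codes)
    first_asud = asud_dates[0] if asud_dates else None
    if first_asud is not None and first_asud <= first_ptsd:
        return []

    out = []
    for d in sorted({dd for dd, _ in timeline.encounters}):
        if d <= first_ptsd:
            continue
        if first_asud is not None and d >= first_asud:
            continue
        washout_lo = d - dt.timedelta(days=config.washout_days)
        if any(washout_lo <= a <= d for a in asud_dates):
            continue
        out.append(d)
    return out


def select_index_date(dates: Sequence[dt.date], *,
                      span_end: dt.date | None = None,
                      first_asud: dt.date | None = None,
                      outcome_window_days: int = 90) -> dt.date | None:
    """Latest eligible date whose outcome window is observable.

    The window counts as observable when an ASUD code falls inside it or the
    data span extends past its right edge. Returns None when no date
    qualifies (no-sample signal).
    """
    best = None
    for d in dates:
        observable = True
        if span_end is not None:
            right = d + dt.timedelta(days=outcome_window_days)
            in_window = first_asud is not None and d < first_asud <= right
            observable = in_window or span_end >= right
        if observable and (best is None or d > best):
            best = d
    return best


def label_sample(timeline: PatientTimeline, index_date: dt.date,
                 config: CohortConfig) -> CohortSample:
    """Label one patient at `index_date` and clip visits to the lookback."""
    encounter_dates = {d for d, _ in timeline.encounters}
    if index_date not in encounter_dates:
        raise ValueError(f"index_date {index_date} is not an encounter date "
                         f"for patient {timeline.patient_id}")
    asud_dates = _code_dates(timeline, config.asud_codes)
    right = index_date + dt.timedelta(days=config.outcome_window_days)
    is_case = any(index_date < a <= right for a in asud_dates)

    visits: list[tuple[int, list[str]]] = []
    lo = index_date - dt.timedelta(days=config.lookback_days)
    for d, toks in sorted(timeline.encounters, key=lambda e: e[0]):
        if lo <= d <= index_date:
            visits.append(((index_date - d).days, list(toks)))
    return CohortSample(
        patient_id=timeline.patient_id,
        label="case" if is_case else "control",
        index_date=index_date,
        visits=visits,
    )


def build_cohort(timelines: Iterable[PatientTimeline], config: CohortConfig,
                 ) -> tuple[list[CohortSample], pd.DataFrame]:
    """Apply the eligibility rules to every timeline.

    Returns (samples, exclusion log); every input patient lands in exactly
    one of case / control / excluded-with-reason.
    """
    config.validate()
    samples: list[CohortSample] = []
    excluded: list[tuple[str, str]] = []
    seen: set[str] = set()
    for tl in timelines:
        if tl.patient_id in seen:
            raise ValueError(f"duplicate patient_id {tl.patient_id!r}")
        seen.add(tl.patient_id)

        ptsd_dates = _code_dates(tl, config.ptsd_codes)
        if not ptsd_dates:
            excluded.append((tl.patient_id, "no PTSD diagnosis"))
            continue
        asud_dates = _code_dates(tl, config.asud_codes)
        first_asud = asud_dates[0] if asud_dates else None
        if first_asud is not None and first_asud < ptsd_dates[0]:
            excluded.append((tl.patient_id, "ASUD before PTSD diagnosis"))
            continue
        if first_asud is not None and first_asud == ptsd_dates[0]:
            excluded.append((tl.patient_id, "PTSD and ASUD on the same day"))
            continue

        dates = eligible_index_dates(tl, config)
        if not dates:
            excluded.append((tl.patient_id, "no eligible index encounter"))
            continue
        span_end = max(d for d, _ in tl.encounters)
        index = select_index_date(dates, span_end=span_end, first_asud=first_asud,
                                  outcome_window_days=config.outcome_window_days)
        if index is None:
            excluded.append((tl.patient_id, "insufficient follow-up"))
            continue
        samples.append(label_sample(tl, index, config))

    log = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return samples, log
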