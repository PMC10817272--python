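"""Synthetic EMR cohort generator.

Emulates the statistical structure of a longitudinal claims/EMR extract for
patients carrying a PTSD diagnosis: irregularly timed encounters (homogeneous
Poisson process per patient), sparse diagnosis / medication / abnormal-lab
events, zip-code-linked neighbourhood SDoH covariates, psychotherapy status
expressed through free-text note snippets, and a substance-use-disorder
outcome drawn from a logistic hazard over planted risk and protective
features. Ground truth (outcome, exposures, the linear predictor actually
used) is returned separately from the timelines so downstream stages cannot
leak labels.

Event strings carry a modality tag: ``DX|<icd code>``, ``RX|<drug name>``,
``LAB|<analyte>|<flag>``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PatientTimeline",
    "default_config",
    "generate_cohort",
    "generate_sdoh_table",
    "default_drug_map",
    "generate_note",
    "write_fixtures",
    "read_timelines",
    "read_sdoh_table",
    "read_drug_map",
    "THERAPY_KEYWORDS",
    "RISK_DRUG",
    "PROTECTIVE_DRUG",
    "NULL_DRUG",
]

STUDY_START = dt.date(2015, 1, 1)

PTSD_CODE = "F43.10"
ASUD_CODE = "F10.20"

# planted benchmark drugs (mapped to synthetic DrugBank ids by the default map)
RISK_DRUG = "riskonium"
PROTECTIVE_DRUG = "protectol"
NULL_DRUG = "nullin"

THERAPY_KEYWORDS = {
    "CPT": "cognitive processing therapy",
    "PE": "prolonged exposure",
    "EMDR": "eye movement desensitization and reprocessing",
    "CBT": "cognitive behavioral therapy",
}

_ACTIVE_TEMPLATES = [
    "Patient is currently undergoing {k} weekly.",
    "Pt continues {k} sessions and reports good progress.",
    "{k} ongoing, completed another session this week.",
]
_INACTIVE_TEMPLATES = [
    "Patient declined {k} at this time.",
    "History of {k} completed years ago, not currently in treatment.",
    "Patient was referred for {k} but has not started.",
]
_FILLER_SENTENCES = [
    "Patient seen for routine follow up.",
    "Vitals stable and reviewed.",
    "Medication list reconciled.",
    "Sleep remains poor with frequent awakenings.",
    "Denies suicidal ideation.",
    "Will follow up in three months.",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    `vocab_spec` maps a raw event string to its per-visit occurrence
    probability. `planted_effects` maps an event prefix (``RX|name``,
    ``DX|code``, ``LAB|analyte``) or a therapy flag (``THX:TF``/``THX:CBT``)
    to its log-odds contribution to the outcome; positive = risk,
    negative = protective. `sdoh_spec` maps a neighbourhood feature name to
    ``{"coef": <log-odds per unit>}``; values are drawn per zip code from
    Uniform(-1, 1).
    """

    n_patients: int
    seed: int
    visit_rate: float = 12.0          # mean visits per patient-year
    study_span_days: int = 730
    vocab_spec: Mapping[str, float] = dataclasses.field(default_factory=dict)
    planted_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    base_logit: float = 0.0
    sdoh_spec: Mapping[str, Mapping[str, float]] = dataclasses.field(default_factory=dict)
    psychotherapy_rate: float = 0.3
    outcome_window_days: int = 90
    lookback_days: int = 365
    n_zips: int = 40
    # chronic PTSD re-coding: per-visit coding probability is
    # ptsd_code_rate_lo + u * ptsd_code_rate_range for latent severity
    # u ~ Uniform(0,1); ptsd_severity_coef * (2u - 1) adds to the outcome
    # log-odds. Defaults make PTSD coding a common, outcome-neutral feature,
    # which is what the reference-scaling step of the contribution analysis
    # assumes of its reference.
    ptsd_code_rate_lo: float = 0.07
    ptsd_code_rate_range: float = 0.0
    ptsd_severity_coef: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be positive")
        if self.study_span_days <= 0:
            raise ValueError("study_span_days must be positive")
        if not 0.0 <= self.psychotherapy_rate <= 1.0:
            raise ValueError("psychotherapy_rate must be in [0, 1]")
        for tok, p in self.vocab_spec.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"vocab_spec probability out of [0, 1] for {tok!r}")
        if self.outcome_window_days <= 0 or self.lookback_days <= 0:
            raise ValueError("outcome_window_days and lookback_days must be positive")


@dataclasses.dataclass
class PatientTimeline:
    patient_id: str
    birth_year: int
    sex: str
    race: str
    zip5: str
    encounters: list[tuple[dt.date, list[str]]]
    notes: list[tuple[dt.date, str]]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "birth_year": self.birth_year,
            "sex": self.sex,
            "race": self.race,
            "zip5": self.zip5,
            "encounters": [[d.isoformat(), toks] for d, toks in self.encounters],
            "notes": [[d.isoformat(), text] for d, text in self.notes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientTimeline":
        return cls(
            patient_id=d["patient_id"],
            birth_year=int(d["birth_year"]),
            sex=d["sex"],
            race=d["race"],
            zip5=d["zip5"],
            encounters=[(dt.date.fromisoformat(x), list(t)) for x, t in d["encounters"]],
            notes=[(dt.date.fromisoformat(x), t) for x, t in d["notes"]],
        )


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def _default_vocab_spec() -> dict[str, float]:
    return {
        # diagnoses (ICD-10 style codes)
        "DX|F32.9": 0.06, "DX|F41.1": 0.06, "DX|R52": 0.06, "DX|Z00.00": 0.06,
        "DX|J45.909": 0.05, "DX|I10": 0.08, "DX|E11.9": 0.05, "DX|M54.5": 0.06,
        "DX|K21.9": 0.05, "DX|G47.00": 0.05, "DX|R51": 0.04, "DX|Z79.01": 0.03,
        # medications (names, mapped to DrugBank ids downstream)
        f"RX|{RISK_DRUG}": 0.06, f"RX|{PROTECTIVE_DRUG}": 0.06, f"RX|{NULL_DRUG}": 0.06,
        "RX|acetaminophen": 0.07, "RX|oxycodone": 0.04, "RX|gabapentin": 0.05,
        "RX|lisinopril": 0.04, "RX|sertraline": 0.06, "RX|prazosin": 0.04,
        "RX|trazodone": 0.04, "RX|ibuprofen": 0.05, "RX|unknownium": 0.02,
        # labs: analyte + result flag; NORMAL results are never tokenized
        "LAB|HGB|LOW": 0.05, "LAB|HGB|HIGH": 0.03, "LAB|GLUCOSE|HIGH": 0.06,
        "LAB|WBC|HIGH": 0.04, "LAB|NA|LOW": 0.03, "LAB|K|NORMAL": 0.05,
        "LAB|RAREST|ABNORMAL": 0.0005,
    }


def _default_effects() -> dict[str, float]:
    return {
        "DX|F43.10": 1.0,          # PTSD itself: the moderate reference risk
        f"RX|{RISK_DRUG}": 2.0,
        f"RX|{PROTECTIVE_DRUG}": -2.0,
        f"RX|{NULL_DRUG}": 0.0,
        "DX|R52": 2.0, "DX|Z00.00": -2.0,
        "DX|F32.9": 1.5, "DX|F41.1": 1.5, "DX|J45.909": 1.2,
        "DX|I10": 0.8, "DX|M54.5": 1.0, "DX|K21.9": 1.0, "DX|G47.00": 1.0,
        "RX|acetaminophen": 1.5, "RX|oxycodone": 2.0,
        "RX|gabapentin": 1.2, "RX|lisinopril": -1.2,
        "LAB|HGB": 1.5, "LAB|GLUCOSE": 1.2,
        "THX:TF": -1.2, "THX:CBT": -0.8,
    }


def _default_sdoh_spec() -> dict[str, dict[str, float]]:
    return {
        "nses": {"coef": -1.5},
        "ice_race": {"coef": -1.0},
        "ndvi": {"coef": -0.6},
        "gini": {"coef": 0.0},
        "aridity": {"coef": -0.5},
    }


def default_config(n_patients: int, seed: int, **overrides) -> SimulationConfig:
    """The standard synthetic study conditions used throughout the package."""
    kw = dict(
        n_patients=n_patients,
        seed=seed,
        vocab_spec=_default_vocab_spec(),
        planted_effects=_default_effects(),
        base_logit=-7.6,
        sdoh_spec=_default_sdoh_spec(),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def default_drug_map() -> pd.DataFrame:
    """Medication-name -> DrugBank-ID mapping table (synthetic ids DB9xxxx)."""
    rows = [
        (RISK_DRUG, "DB90001"), (PROTECTIVE_DRUG, "DB90002"), (NULL_DRUG, "DB90003"),
        ("acetaminophen", "DB00316"), ("oxycodone", "DB00497"),
        ("gabapentin", "DB00996"), ("lisinopril", "DB00722"),
        ("sertraline", "DB01104"), ("prazosin", "DB00457"),
        ("trazodone", "DB00656"), ("ibuprofen", "DB01050"),
        ("enalapril", "DB00584"),
    ]
    return pd.DataFrame(rows, columns=["name", "drugbank_id"])


def generate_sdoh_table(config: SimulationConfig) -> pd.DataFrame:
    """Zip-level SDoH table: one row per zip, features ~ Uniform(-1, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5D0]))
    zips = [f"{15201 + i:05d}" for i in range(config.n_zips)]
    data = {"zip5": zips}
    for name in config.sdoh_spec:
        data[name] = np.round(rng.uniform(-1.0, 1.0, size=config.n_zips), 4)
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# note text
# --------------------------------------------------------------------------

def generate_note(active_therapy: bool, therapy_kind: str, seed: int) -> str:
    """One synthetic note snippet.

    Active notes phrase the therapy keyword as ongoing treatment; inactive
    notes either avoid keywords entirely (kind 'none') or phrase the keyword
    as declined / historical / not yet started.
    """
    if therapy_kind not in set(THERAPY_KEYWORDS) | {"none"}:
        raise ValueError(f"unknown therapy_kind {therapy_kind!r}")
    if active_therapy and therapy_kind == "none":
        raise ValueError("active_therapy requires a named therapy_kind")
    rng = np.random.default_rng(seed)
    sentences = list(rng.choice(_FILLER_SENTENCES, size=2, replace=False))
    if therapy_kind != "none":
        phrase = THERAPY_KEYWORDS[therapy_kind]
        pool = _ACTIVE_TEMPLATES if active_therapy else _INACTIVE_TEMPLATES
        template = pool[int(rng.integers(len(pool)))]
        sentences.insert(int(rng.integers(len(sentences) + 1)), template.format(k=phrase))
    return " ".join(sentences)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _effect_matches(effect_key: str, event: str) -> bool:
    return event == effect_key or event.startswith(effect_key + "|")


def generate_cohort(config: SimulationConfig,
                    sdoh_table: pd.DataFrame | None = None,
                    ) -> tuple[list[PatientTimeline], pd.DataFrame]:
    """Simulate patient timelines and the ground-truth table.

    Returns (timelines, ground_truth) where ground_truth has one row per
    patient: outcome flag and date, the anchor (index) encounter date, the
    linear predictor actually used for the outcome draw, therapy status and
    per-planted-feature exposure flags.
    """
    config.validate()
    if sdoh_table is None:
        sdoh_table = generate_sdoh_table(config)
    sdoh_by_zip = sdoh_table.set_index("zip5")

    master = np.random.SeedSequence([config.seed, 0xC0])
    child_seeds = master.spawn(config.n_patients)
    span = config.study_span_days
    window = config.outcome_window_days
    kinds = list(THERAPY_KEYWORDS)
    zips = list(sdoh_by_zip.index)

    timelines: list[PatientTimeline] = []
    truth_rows: list[dict] = []
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        pid = f"P{i:06d}"
        birth_year = int(rng.integers(1950, 2001))
        sex = str(rng.choice(["F", "M"]))
        race = str(rng.choice(["WHITE", "BLACK", "ASIAN", "OTHER"], p=[0.6, 0.25, 0.05, 0.1]))
        zip5 = str(rng.choice(zips))

        n_visits = max(1, int(rng.poisson(config.visit_rate * span / 365.0)))
        offsets = np.sort(rng.integers(0, span, size=n_visits))
        dates = [STUDY_START + dt.timedelta(days=int(o)) for o in offsets]

        # latent PTSD severity: severer disease is re-coded at more visits
        # and independently raises the outcome log-odds
        severity = float(rng.random())
        ptsd_rate = config.ptsd_code_rate_lo + severity * config.ptsd_code_rate_range

        encounters: list[tuple[dt.date, list[str]]] = []
        events = list(config.vocab_spec.items())
        for d in dates:
            toks = [tok for tok, p in events if rng.random() < p]
            if rng.random() < ptsd_rate:
                toks.insert(0, f"DX|{PTSD_CODE}")
            encounters.append((d, toks))
        # first PTSD code anchors the diagnosis at the first encounter
        if not encounters[0][1] or encounters[0][1][0] != f"DX|{PTSD_CODE}":
            encounters[0][1].insert(0, f"DX|{PTSD_CODE}")

        # index anchor: latest encounter leaving a full outcome window inside
        # the patient's own observed span
        anchor_idx = 0
        for j, d in enumerate(dates):
            if (dates[-1] - d).days >= window:
                anchor_idx = j
        anchor = dates[anchor_idx]

        # therapy status
        active = bool(rng.random() < config.psychotherapy_rate)
        kind = str(rng.choice(kinds)) if active else str(rng.choice(kinds + ["none"]))
        therapy_flags = {"THX:TF": active and kind in {"CPT", "PE", "EMDR"},
                         "THX:CBT": active and kind == "CBT"}

        # planted exposures inside [anchor - lookback, anchor]
        lookback_events: set[str] = set()
        for d, toks in encounters:
            if 0 <= (anchor - d).days <= config.lookback_days:
                lookback_events.update(toks)
        lp = config.base_logit
        exposures: dict[str, bool] = {}
        for key, beta in config.planted_effects.items():
            if key.startswith("THX:"):
                exposed = therapy_flags.get(key, False)
            else:
                exposed = any(_effect_matches(key, ev) for ev in lookback_events)
            exposures[key] = exposed
            lp += beta * exposed
        for name, spec in config.sdoh_spec.items():
            lp += spec["coef"] * float(sdoh_by_zip.loc[zip5, name])
        lp += config.ptsd_severity_coef * (2.0 * severity - 1.0)

        is_case = bool(rng.random() < 1.0 / (1.0 + math.exp(-lp)))
        outcome_date = None
        if is_case:
            outcome_date = anchor + dt.timedelta(days=int(rng.integers(1, window + 1)))
            # visits between onset anchor and the ASUD diagnosis are dropped,
            # so the anchor is the last encounter before the first ASUD code
            encounters = [(d, t) for d, t in encounters
                          if not (anchor < d < outcome_date)]
            encounters.append((outcome_date, [f"DX|{ASUD_CODE}"]))
        encounters.sort(key=lambda e: e[0])

        # notes: one therapy-status note plus fillers, dated on/before anchor
        notes: list[tuple[dt.date, str]] = []
        note_date = dates[min(anchor_idx, len(dates) - 1)]
        notes.append((note_date, generate_note(active, kind, int(rng.integers(2**31)))))
        for _ in range(int(rng.poisson(0.8))):
            d = dates[int(rng.integers(len(dates)))]
            notes.append((d, generate_note(False, "none", int(rng.integers(2**31)))))
        notes.sort(key=lambda n: n[0])

        timelines.append(PatientTimeline(pid, birth_year, sex, race, zip5, encounters, notes))
        row = {
            "patient_id": pid,
            "case": is_case,
            "outcome_date": outcome_date.isoformat() if outcome_date else "",
            "anchor_date": anchor.isoformat(),
            "linear_predictor": lp,
            "ptsd_severity": severity,
            "therapy_active": active,
            "therapy_kind": kind,
        }
        for key, exposed in exposures.items():
            row[f"exp:{key}"] = exposed
        truth_rows.append(row)

    return timelines, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# fixtures I/O
# --------------------------------------------------------------------------

def write_fixtures(timelines: Sequence[PatientTimeline], out_dir: str | Path,
                   sdoh_table: pd.DataFrame | None = None,
                   drug_map: pd.DataFrame | None = None,
                   ground_truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write timelines (JSONL), SDoH table (CSV) and drug map (CSV)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {"timelines": out / "timelines.jsonl"}
        with open(paths["timelines"], "w", encoding="utf-8") as fh:
            for t in timelines:
                fh.write(json.dumps(t.to_dict(), ensure_ascii=False) + "\n")
        if sdoh_table is not None:
            paths["sdoh"] = out / "sdoh.csv"
            sdoh_table.to_csv(paths["sdoh"], index=False)
        if drug_map is not None:
            paths["drug_map"] = out / "drug_map.csv"
            drug_map.to_csv(paths["drug_map"], index=False)
        if ground_truth is not None:
            paths["ground_truth"] = out / "ground_truth.csv"
            ground_truth.to_csv(paths["ground_truth"], index=False)
    except OSError as exc:
        raise OSError(f"cannot write fixtures under {out}: {exc}") from exc
    return paths


def read_timelines(path: str | Path) -> list[PatientTimeline]:
    with open(path, encoding="utf-8") as fh:
        return [PatientTimeline.from_dict(json.loads(line)) for line in fh if line.strip()]


def read_sdoh_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"zip5": str})


def read_drug_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
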