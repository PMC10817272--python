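"""Tokenisation and integer encoding of cohort samples.

Raw timeline events (``DX|code``, ``RX|name``, ``LAB|analyte|flag``) become
namespaced vocabulary tokens: diagnoses are grouped by the first three
characters of the code (``DX:F43``), medication names map to DrugBank ids
(``RX:DB00584``), and abnormal lab results (ABNORMAL/HIGH/LOW) with cohort-
wide frequency >= 100 become ``LAB:<analyte>``. Demographics, neighbourhood
SDoH quintiles and psychotherapy flags are static tokens attached at the
index date. Index 0 of the vocabulary is reserved for padding.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortSample

__all__ = ["VocabMap", "SdohEncoder", "EncodedSample", "group_diagnosis",
           "map_drug", "filter_labs", "build_vocab", "encode_sample",
           "tokenize_visits", "encode_cohort", "REFERENCE_TOKEN"]

logger = logging.getLogger(__name__)

REFERENCE_TOKEN = "DX:F43"          # grouped PTSD diagnosis token
ABNORMAL_FLAGS = {"ABNORMAL", "HIGH", "LOW"}


# --------------------------------------------------------------------------
# token-level operations
# --------------------------------------------------------------------------

def group_diagnosis(code: str) -> str:
    """Group a diagnosis code by its first three characters: ``DX:F43``.

    Idempotent: an already grouped token keeps its 3-character core. The
    same prefix rule is applied to ICD-9 codes (``309.81`` -> ``DX:309``).
    """
    core = code.strip().upper()
    if core.startswith("DX:"):
        core = core[3:]
    if len(core) < 3:
        raise ValueError(f"diagnosis code too short to group: {code!r}")
    return f"DX:{core[:3]}"


def map_drug(name: str, mapping: Mapping[str, str]) -> str | None:
    """Case-insensitive medication-name lookup; None when unmapped."""
    dbid = mapping.get(name.strip().lower())
    return None if dbid is None else f"RX:{dbid}"


def drug_mapping_from_table(table: pd.DataFrame) -> dict[str, str]:
    return {str(n).strip().lower(): str(d).strip()
            for n, d in zip(table["name"], table["drugbank_id"])}


def filter_labs(lab_events: Iterable[tuple[str, str]], min_freq: int = 100) -> set[str]:
    """Retained abnormal-lab tokens from cohort-wide (analyte, flag) events.

    Only ABNORMAL/HIGH/LOW results count; analytes with fewer than
    `min_freq` abnormal events across the cohort are dropped.
    """
    counts: Counter[str] = Counter()
    for analyte, flag in lab_events:
        if flag.upper() in ABNORMAL_FLAGS:
            counts[analyte.upper()] += 1
    return {f"LAB:{a}" for a, c in counts.items() if c >= min_freq}


def tokenize_event(event: str, drug_mapping: Mapping[str, str],
                   retained_labs: set[str]) -> str | None:
    """Raw timeline event -> vocabulary token, or None when dropped."""
    parts = event.split("|")
    if parts[0] == "DX" and len(parts) == 2:
        return group_diagnosis(parts[1])
    if parts[0] == "RX" and len(parts) == 2:
        return map_drug(parts[1], drug_mapping)
    if parts[0] == "LAB" and len(parts) == 3:
        analyte, flag = parts[1].upper(), parts[2].upper()
        if flag not in ABNORMAL_FLAGS:
            return None
        tok = f"LAB:{analyte}"
        return tok if tok in retained_labs else None
    raise ValueError(f"unrecognised event string {event!r}")


def tokenize_visits(sample: CohortSample, drug_mapping: Mapping[str, str],
                    retained_labs: set[str]) -> list[tuple[int, list[str]]]:
    """Map a sample's raw visit events to vocabulary tokens (drops logged)."""
    out = []
    dropped = 0
    for offset, events in sample.visits:
        toks = []
        for ev in events:
            tok = tokenize_event(ev, drug_mapping, retained_labs)
            if tok is None:
                dropped += 1
            else:
                toks.append(tok)
        out.append((offset, toks))
    if dropped:
        logger.debug("patient %s: dropped %d unmapped/filtered events",
                     sample.patient_id, dropped)
    return out


# --------------------------------------------------------------------------
# SDoH + demographics
# --------------------------------------------------------------------------

class SdohEncoder:
    """Cohort-level encoder for zip-linked SDoH features.

    Continuous features are z-scored over the cohort and binned into
    quintile tokens ``SDOH:<name>:Q1..Q5`` (ties resolved rank-then-first-
    bin); the standardized vector is kept for the regression-coefficient
    analysis. Demographics become tokens (SEX:/RACE:/AGE: by decade).
    """

    MISSING_TOKEN = "SDOH:MISSING"

    def __init__(self, table: pd.DataFrame):
        self.table = table.set_index("zip5")
        self.features = [c for c in table.columns if c != "zip5"]
        self._mean: dict[str, float] = {}
        self._sd: dict[str, float] = {}
        self._edges: dict[str, np.ndarray] = {}
        self._fitted = False

    def fit(self, zips: Sequence[str]) -> "SdohEncoder":
        """Learn z-score parameters and quintile edges from cohort zips."""
        known = [z for z in zips if z in self.table.index]
        if not known:
            raise ValueError("no cohort zip code appears in the SDoH table")
        for f in self.features:
            vals = self.table.loc[known, f].to_numpy(dtype=float)
            mu, sd = float(vals.mean()), float(vals.std(ddof=0))
            self._mean[f], self._sd[f] = mu, (sd if sd > 0 else 1.0)
            z = (vals - mu) / self._sd[f]
            self._edges[f] = np.quantile(z, [0.2, 0.4, 0.6, 0.8])
        self._fitted = True
        return self

    def encode(self, zip5: str, demographics: Mapping[str, object] | None = None,
               ) -> tuple[list[str], np.ndarray | None]:
        """Static tokens plus the standardized covariate vector for one patient."""
        if not self._fitted:
            raise RuntimeError("SdohEncoder.fit must run before encode")
        tokens: list[str] = []
        if demographics:
            if "sex" in demographics:
                tokens.append(f"SEX:{str(demographics['sex']).upper()}")
            if "race" in demographics:
                tokens.append(f"RACE:{str(demographics['race']).upper()}")
            if "age" in demographics:
                decade = max(0, min(9, int(demographics["age"]) // 10))
                tokens.append(f"AGE:{decade * 10}S")
        if zip5 not in self.table.index:
            tokens.append(self.MISSING_TOKEN)
            return tokens, None
        vec = np.empty(len(self.features))
        for k, f in enumerate(self.features):
            z = (float(self.table.loc[zip5, f]) - self._mean[f]) / self._sd[f]
            vec[k] = z
            q = int(np.searchsorted(self._edges[f], z, side="left"))
            tokens.append(f"SDOH:{f.upper()}:Q{q + 1}")
        return tokens, vec


def encode_sdoh(zip5: str, encoder: SdohEncoder,
                demographics: Mapping[str, object] | None = None,
                ) -> tuple[list[str], np.ndarray | None]:
    """Functional wrapper over a fitted :class:`SdohEncoder`."""
    return encoder.encode(zip5, demographics)


# --------------------------------------------------------------------------
# vocabulary
# --------------------------------------------------------------------------

@dataclasses.dataclass
class VocabMap:
    token_to_idx: dict[str, int]
    idx_to_token: dict[int, str]
    freq: dict[str, int]
    reference_token: str = REFERENCE_TOKEN

    def __len__(self) -> int:          # includes the padding slot
        return len(self.token_to_idx) + 1

    def encode(self, token: str) -> int | None:
        return self.token_to_idx.get(token)

    def decode(self, idx: int) -> str:
        return self.idx_to_token[idx]


def build_vocab(tokenized_samples: Sequence[tuple[list[tuple[int, list[str]]], list[str]]],
                max_vocab: int = 30000,
                reference_token: str = REFERENCE_TOKEN) -> VocabMap:
    """Frequency-ranked vocabulary over visit + static tokens.

    Index 0 is reserved for padding; at most max_vocab - 1 tokens are kept
    and the reference (PTSD-group) token is force-retained when observed.
    """
    counts: Counter[str] = Counter()
    for visits, static in tokenized_samples:
        for _, toks in visits:
            counts.update(toks)
        counts.update(static)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = [t for t, _ in ranked[: max_vocab - 1]]
    if reference_token in counts and reference_token not in keep:
        keep[-1] = reference_token
    token_to_idx = {t: i + 1 for i, t in enumerate(keep)}
    return VocabMap(
        token_to_idx=token_to_idx,
        idx_to_token={i: t for t, i in token_to_idx.items()},
        freq={t: counts[t] for t in keep},
        reference_token=reference_token,
    )


# --------------------------------------------------------------------------
# indexed samples
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EncodedSample:
    patient_id: str
    y: int
    visit_indices: list[list[int]]     # oldest -> newest, no empty visits
    offsets: list[int]                 # days before index, parallel to visits
    elapsed: list[int]                 # days since previous kept visit; [0, ...]
    static_indices: list[int]
    covariates: np.ndarray | None = None   # standardized SDoH vector


def _elapsed_from_offsets(offsets: Sequence[int]) -> list[int]:
    return [0] + [offsets[i - 1] - offsets[i] for i in range(1, len(offsets))]


def encode_sample(visits: Sequence[tuple[int, list[str]]], static_tokens: Sequence[str],
                  vocab: VocabMap, *, patient_id: str = "", y: int = 0,
                  covariates: np.ndarray | None = None) -> EncodedSample:
    """Integer-encode tokenized visits; out-of-vocabulary tokens are dropped
    and visits left empty by the drop are omitted with elapsed times
    recomputed over the remaining visits."""
    kept_indices: list[list[int]] = []
    kept_offsets: list[int] = []
    for offset, toks in sorted(visits, key=lambda v: -v[0]):
        idxs = [i for t in toks if (i := vocab.encode(t)) is not None]
        if idxs:
            kept_indices.append(idxs)
            kept_offsets.append(offset)
    return EncodedSample(
        patient_id=patient_id,
        y=y,
        visit_indices=kept_indices,
        offsets=kept_offsets,
        elapsed=_elapsed_from_offsets(kept_offsets),
        static_indices=[i for t in static_tokens if (i := vocab.encode(t)) is not None],
        covariates=covariates,
    )


def decode_sample(enc: EncodedSample, vocab: VocabMap) -> list[list[str]]:
    return [[vocab.decode(i) for i in visit] for visit in enc.visit_indices]


# --------------------------------------------------------------------------
# cohort-level pipeline
# --------------------------------------------------------------------------

def encode_cohort(samples: Sequence[CohortSample], sdoh_table: pd.DataFrame,
                  drug_map_table: pd.DataFrame,
                  demographics: Mapping[str, Mapping[str, object]] | None = None,
                  therapy_flags: Mapping[str, tuple[bool, bool]] | None = None,
                  min_lab_freq: int = 100, max_vocab: int = 30000,
                  ) -> tuple[list[EncodedSample], VocabMap, SdohEncoder]:
    """Tokenize, attach static features and integer-encode a whole cohort.

    `demographics` maps patient_id -> {sex, race, age, zip5}; `therapy_flags`
    maps patient_id -> (cbt_active, trauma_focused_active). The abnormal-lab
    frequency threshold is applied cohort-wide, once, before any split.
    """
    mapping = drug_mapping_from_table(drug_map_table)

    lab_events: list[tuple[str, str]] = []
    for s in samples:
        for _, events in s.visits:
            for ev in events:
                parts = ev.split("|")
                if parts[0] == "LAB" and len(parts) == 3:
                    lab_events.append((parts[1], parts[2]))
    retained = filter_labs(lab_events, min_freq=min_lab_freq)

    encoder = None
    if demographics:
        encoder = SdohEncoder(sdoh_table).fit(
            [str(demographics[s.patient_id].get("zip5", "")) for s in samples
             if s.patient_id in demographics])

    tokenized: list[tuple[list[tuple[int, list[str]]], list[str]]] = []
    covs: list[np.ndarray | None] = []
    for s in samples:
        visits = tokenize_visits(s, mapping, retained)
        static = list(s.static_tokens)
        cov = None
        if demographics and s.patient_id in demographics:
            demo = demographics[s.patient_id]
            toks, cov = encoder.encode(str(demo.get("zip5", "")), demo)
            static.extend(toks)
        if therapy_flags and s.patient_id in therapy_flags:
            cbt, tf = therapy_flags[s.patient_id]
            if cbt:
                static.append("THX:CBT")
            if tf:
                static.append("THX:TF")
        tokenized.append((visits, static))
        covs.append(cov)

    vocab = build_vocab(tokenized, max_vocab=max_vocab)
    encoded = [
        encode_sample(visits, static, vocab, patient_id=s.patient_id, y=s.y,
                      covariates=cov)
        for s, (visits, static), cov in zip(samples, tokenized, covs)
    ]
    return encoded, vocab, encoder
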