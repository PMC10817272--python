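"""Perturbation-based relative-contribution analysis.

For a trained sequence classifier, the contribution of a feature (token) to
one patient's predicted risk is measured by occlusion: remove the token's
occurrences from the visit sequence, re-run the forward pass, and take the
drop in predicted probability (FC, feature contribution). Per patient, FCs
are normalized by the sum of absolute FCs over all of that patient's
features, so patients with heavy utilisation do not dominate. Per feature,
the relative contribution is

    RC = median(normalized FC among cases) / median(normalized FC among controls)

then rescaled so the reference feature (the grouped PTSD diagnosis token)
has RC exactly 1; RC > 1 marks a risk-associated feature, RC < 1 a
protective one. Significance is a two-sided Wilcoxon rank-sum test of the
case vs control FC distributions with Benjamini-Hochberg FDR adjustment at
alpha = 0.05.

A companion analysis refits the logistic baseline on re-randomized splits
(default 10) and t-tests the mean SDoH coefficients against zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import EncodedSample, VocabMap
from .models import LogisticBaseline
from .training_eval import SplitSpec, split

__all__ = ["raw_feature_contribution", "remove_token", "normalize_fc",
           "rc_value", "scale_rc", "rc_significance", "wilcoxon_ranksum",
           "fdr_adjust", "feature_report", "sdoh_coefficient_analysis",
           "ContributionRecord"]

REPORT_COLUMNS = ["Feature", "RelativeContribution", "Wilcoxon_p", "FDR_Q",
                  "CaseSupport", "ControlSupport"]


@dataclasses.dataclass
class ContributionRecord:
    patient_id: str
    label: str
    normalized_fc: dict[str, float]


# --------------------------------------------------------------------------
# feature contribution by occlusion
# --------------------------------------------------------------------------

def remove_token(sample: EncodedSample, token_idx: int,
                 visit: int | None = None) -> EncodedSample:
    """Copy of `sample` with occurrences of `token_idx` removed.

    `visit=None` removes every occurrence; an integer removes only the
    occurrence(s) in that visit position. Visits emptied by the removal are
    dropped and elapsed times recomputed from the remaining visit offsets.
    """
    new_visits, new_offsets = [], []
    for t, (idxs, off) in enumerate(zip(sample.visit_indices, sample.offsets)):
        if visit is None or visit == t:
            kept = [i for i in idxs if i != token_idx]
        else:
            kept = list(idxs)
        if kept:
            new_visits.append(kept)
            new_offsets.append(off)
    static = [i for i in sample.static_indices if i != token_idx] \
        if visit is None else list(sample.static_indices)
    elapsed = [0] + [new_offsets[i - 1] - new_offsets[i]
                     for i in range(1, len(new_offsets))]
    return EncodedSample(patient_id=sample.patient_id, y=sample.y,
                         visit_indices=new_visits, offsets=new_offsets,
                         elapsed=elapsed, static_indices=static,
                         covariates=sample.covariates)


def _occurrence_visits(sample: EncodedSample, token_idx: int) -> list[int]:
    return [t for t, idxs in enumerate(sample.visit_indices) if token_idx in idxs]


def raw_feature_contribution(model, sample: EncodedSample, token_idx: int,
                             mode: str = "all",
                             baseline: float | None = None) -> float:
    """FC of one token for one patient: p(full) - p(perturbed).

    mode="all" (default): one forward pass with every occurrence removed.
    mode="per_occurrence": occurrences perturbed one visit at a time and the
    deltas summed.
    """
    occ = _occurrence_visits(sample, token_idx)
    in_static = token_idx in sample.static_indices
    if not occ and not in_static:
        raise ValueError(f"token {token_idx} absent from patient "
                         f"{sample.patient_id!r}")
    if baseline is None:
        baseline = float(model.predict_proba([sample])[0])
    if mode == "all":
        pert = remove_token(sample, token_idx)
        return baseline - _proba_or_degenerate(model, pert, baseline)
    if mode == "per_occurrence":
        total = 0.0
        for t in occ:
            pert = remove_token(sample, token_idx, visit=t)
            total += baseline - _proba_or_degenerate(model, pert, baseline)
        if in_static:
            pert = remove_token(sample, token_idx)
            # static occurrence handled through the all-occurrence path
            total += baseline - _proba_or_degenerate(model, pert, baseline)
        return total
    raise ValueError(f"unknown mode {mode!r}")


def _proba_or_degenerate(model, sample: EncodedSample, fallback: float) -> float:
    if not sample.visit_indices and not sample.static_indices:
        return fallback       # removing the only token empties the sequence
    return float(model.predict_proba([sample])[0])


def normalize_fc(raw: Mapping[str, float]) -> dict[str, float]:
    """Per-patient normalization: signed FC over the sum of absolute FCs.

    The absolute-value denominator keeps signed contributions from
    cancelling to a tiny divisor; an all-zero patient maps to all zeros.
    """
    denom = sum(abs(v) for v in raw.values())
    if denom == 0.0:
        return {k: 0.0 for k in raw}
    return {k: v / denom for k, v in raw.items()}


# --------------------------------------------------------------------------
# relative contribution
# --------------------------------------------------------------------------

def rc_value(fc_cases: Sequence[float], fc_controls: Sequence[float],
             ) -> float | None:
    """median(case FCs) / median(control FCs); None when the denominator
    median is zero (undefined-RC signal)."""
    if not len(fc_cases) or not len(fc_controls):
        raise ValueError("both FC lists must be non-empty")
    denom = float(np.median(fc_controls))
    if denom == 0.0:
        return None
    return float(np.median(fc_cases)) / denom


def scale_rc(rc_table: Mapping[str, float | None], reference_token: str,
             ) -> dict[str, float | None]:
    """Multiply every RC so the reference token's RC is exactly 1."""
    ref = rc_table.get(reference_token)
    if ref is None or ref == 0.0 or not math.isfinite(ref):
        raise ValueError(f"reference token {reference_token!r} has no usable RC")
    factor = 1.0 / ref
    out = {tok: (None if rc is None else rc * factor)
           for tok, rc in rc_table.items()}
    out[reference_token] = 1.0
    return out


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                     exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Combined n <= `exact_max_n`: exact enumeration of all label assignments
    of the pooled midranks, p = P(|W - E[W]| >= |w_obs - E[W]|). Larger
    samples: normal approximation with tie correction and continuity
    correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0

    if n <= exact_max_n:
        dev = abs(w - mean_w)
        count = total = 0
        for comb in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_w) >= dev - 1e-12:
                count += 1
        return count / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n * (n - 1)))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)   # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def rc_significance(fc_cases: Sequence[float], fc_controls: Sequence[float],
                    ) -> float:
    """Wilcoxon rank-sum p for the case vs control FC distributions."""
    return wilcoxon_ranksum(fc_cases, fc_controls)


def fdr_adjust(pvalues: Sequence[float], alpha: float = 0.05,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q values, q <= alpha flags)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return np.empty(0), np.empty(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


# --------------------------------------------------------------------------
# cohort-level reports
# --------------------------------------------------------------------------

def compute_contributions(model, samples: Sequence[EncodedSample],
                          vocab: VocabMap, mode: str = "all",
                          ) -> list[ContributionRecord]:
    """Normalized FCs for every (patient, token) pair, batched per token."""
    baselines = model.predict_proba(samples)
    raw: list[dict[int, float]] = [dict() for _ in samples]

    present: dict[int, list[int]] = {}
    for si, s in enumerate(samples):
        toks = set(i for visit in s.visit_indices for i in visit)
        toks.update(s.static_indices)
        for i in toks:
            present.setdefault(i, []).append(si)

    for token_idx, sample_ids in present.items():
        if mode == "all":
            perturbed = [remove_token(samples[si], token_idx) for si in sample_ids]
            keep = [(si, p) for si, p in zip(sample_ids, perturbed)
                    if p.visit_indices or p.static_indices]
            if keep:
                probs = model.predict_proba([p for _, p in keep])
                for (si, _), pp in zip(keep, probs):
                    raw[si][token_idx] = float(baselines[si]) - float(pp)
            for si in set(sample_ids) - {si for si, _ in keep}:
                raw[si][token_idx] = 0.0
        else:
            for si in sample_ids:
                raw[si][token_idx] = raw_feature_contribution(
                    model, samples[si], token_idx, mode=mode,
                    baseline=float(baselines[si]))

    records = []
    for s, fc in zip(samples, raw):
        named = {vocab.decode(i): v for i, v in fc.items()}
        records.append(ContributionRecord(
            patient_id=s.patient_id, label="case" if s.y else "control",
            normalized_fc=normalize_fc(named)))
    return records


def feature_report(model, samples: Sequence[EncodedSample], vocab: VocabMap,
                   min_support: int = 10, mode: str = "all",
                   alpha: float = 0.05,
                   records: Sequence[ContributionRecord] | None = None,
                   ) -> pd.DataFrame:
    """Per-feature scaled RC, Wilcoxon p, BH q and support counts.

    Features are kept when at least `min_support` cases and controls carry
    them; rows are ranked by q ascending, then total support descending,
    then feature name. RC left NaN (never dropped) when the control median
    is zero or the reference scaling is unavailable.
    """
    if records is None:
        records = compute_contributions(model, samples, vocab, mode=mode)
    by_token: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        for tok, v in rec.normalized_fc.items():
            by_token.setdefault(tok, {"case": [], "control": []})[rec.label].append(v)

    rows = []
    raw_rc: dict[str, float | None] = {}
    for tok, d in by_token.items():
        nc, nk = len(d["case"]), len(d["control"])
        if tok != vocab.reference_token and (nc < min_support or nk < min_support):
            continue
        if nc == 0 or nk == 0:
            continue
        raw_rc[tok] = rc_value(d["case"], d["control"])
        rows.append({"Feature": tok,
                     "Wilcoxon_p": wilcoxon_ranksum(d["case"], d["control"]),
                     "CaseSupport": nc, "ControlSupport": nk})
    if not rows:
        return pd.DataFrame(columns=REPORT_COLUMNS)

    scaled: dict[str, float | None]
    try:
        scaled = scale_rc(raw_rc, vocab.reference_token)
    except (ValueError, KeyError):
        scaled = dict(raw_rc)          # reference unusable: report raw RCs
    for row in rows:
        rc = scaled.get(row["Feature"])
        row["RelativeContribution"] = np.nan if rc is None else rc

    q, _ = fdr_adjust([r["Wilcoxon_p"] for r in rows], alpha=alpha)
    for row, qv in zip(rows, q):
        row["FDR_Q"] = qv
    df = pd.DataFrame(rows)[REPORT_COLUMNS]
    df["_support"] = df["CaseSupport"] + df["ControlSupport"]
    df = df.sort_values(["FDR_Q", "_support", "Feature"],
                        ascending=[True, False, True]).drop(columns="_support")
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# SDoH coefficient analysis
# --------------------------------------------------------------------------

def sdoh_coefficient_analysis(samples: Sequence[EncodedSample],
                              vocab_size: int,
                              covariate_names: Sequence[str],
                              repeats: int = 10, seed: int = 0,
                              C: float = 1.0) -> pd.DataFrame:
    """Refit the logistic baseline on `repeats` re-randomized splits and
    t-test the mean SDoH coefficient of each covariate against zero.

    Columns: Name, Mean, sd, p, Direction. A zero-variance coefficient
    sequence is reported with p = NaN (degenerate t-test) rather than 0.
    """
    coefs: dict[str, list[float]] = {c: [] for c in covariate_names}
    for r in range(repeats):
        tr, va, te = split(samples, SplitSpec(seed=seed * 1000 + r))
        lr = LogisticBaseline(vocab_size, n_covariates=len(covariate_names),
                              covariate_names=covariate_names, C=C,
                              seed=seed).fit(list(tr))
        for name, val in lr.covariate_coefficients().items():
            coefs[name].append(val)
    return summarize_coefficients(coefs)


def summarize_coefficients(coefs: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean / sd / one-sample t-test (vs 0) summary of repeated coefficients."""
    rows = []
    for name, vals in coefs.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1))
        if sd == 0.0:
            p = np.nan       # zero-variance sentinel, not an exact zero
        else:
            p = float(stats.ttest_1samp(arr, 0.0).pvalue)
        mean = float(arr.mean())
        rows.append({"Name": name, "Mean": mean, "sd": sd, "p": p,
                     "Direction": "risk" if mean > 0 else "protective"})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
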