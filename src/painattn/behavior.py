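"""Behavioral phenotyping: IAP scoring and A/P reaction-time typing.

Two phenotypes are computed per participant:

* **IAP score** — from a 20-trial experience-sampling task in which the
  participant reports, after each painful stimulus, whether their thoughts
  were about the pain or about something else (four ordered categories).
  The score is the per-trial mean of category weights +2 (only pain),
  +1 (mostly pain), −1 (mostly something else), −2 (only something else),
  so it lives in [−2, +2]. Negative scores define the low-IAP group
  (mind-wanders away from pain), positive scores the high-IAP group.

* **A/P type** — from a numeric interference (NI) task of six 24-trial
  blocks alternating no-pain / pain, starting with no-pain. After dropping
  the first two blocks (learning effects) and trials with reaction times
  outside [200, 2500] ms, ΔRT_mean = RT_mean(pain) − RT_mean(no-pain).
  Negative ΔRT_mean → A type (attention to task dominates; pain speeds the
  task), positive → P type (pain dominates; pain slows the task).

Scores of exactly 0 (either phenotype) are labelled ``boundary`` and are
excluded from two-group contrasts downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The four ordered thought-probe responses, from "attention toward pain"
#: to "attention away from pain", with their score weights.
RESPONSE_WEIGHTS: dict[str, int] = {
    "only_pain": 2,
    "mostly_pain": 1,
    "mostly_else": -1,
    "only_else": -2,
}

RESPONSES: tuple[str, ...] = tuple(RESPONSE_WEIGHTS)

RT_MIN_MS = 200.0
RT_MAX_MS = 2500.0
N_BLOCKS = 6
#: First analysed block; blocks 1-2 are discarded as practice.
FIRST_ANALYSIS_BLOCK = 3


class EmptyInputError(ValueError):
    """Raised when an operation receives no records."""


class EmptyAfterFilterError(ValueError):
    """Raised when trial filtering leaves a required condition empty."""


@dataclass(frozen=True)
class ExperienceSamplingRecord:
    subject_id: str
    trial_index: int
    response: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_WEIGHTS:
            raise ValueError(
                f"unknown response {self.response!r}; "
                f"expected one of {RESPONSES}"
            )


@dataclass(frozen=True)
class IAPResult:
    subject_id: str
    iap_score: float
    group: str  # low | high | boundary
    n_trials: int


def block_condition(block_index: int) -> str:
    """Condition of an NI block: blocks alternate starting with no-pain."""
    return "no_pain" if block_index % 2 == 1 else "pain"


@dataclass(frozen=True)
class NITrialRecord:
    subject_id: str
    block_index: int
    condition: str  # pain | no_pain
    rt_ms: float
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("pain", "no_pain"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 1 <= self.block_index <= N_BLOCKS:
            raise ValueError(
                f"block_index {self.block_index} outside 1..{N_BLOCKS}"
            )
        if self.rt_ms <= 0:
            raise ValueError(f"non-positive rt_ms {self.rt_ms}")


@dataclass(frozen=True)
class APResult:
    subject_id: str
    rt_mean_pain: float
    rt_mean_nopain: float
    delta_rt_mean: float
    ap_type: str  # A | P | boundary
    n_trials_used_pain: int
    n_trials_used_nopain: int


def compute_iap_score(records: Sequence[ExperienceSamplingRecord]) -> IAPResult:
    """IAP score: (2·n_onlypain + n_mostlypain − 2·n_onlyelse − n_mostlyelse) / n_total.

    Equivalently the mean of per-trial weights (+2/+1/−1/−2), hence bounded
    in [−2, +2]. Group is ``low`` for negative scores, ``high`` for positive,
    ``boundary`` for exactly 0.
    """
    if not records:
        raise EmptyInputError("no experience-sampling records")
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) != 1:
        raise ValueError(f"records span multiple subjects: {sorted(subject_ids)}")
    trials = [r.trial_index for r in records]
    if len(set(trials)) != len(trials):
        raise ValueError("duplicate trial indices")
    total = sum(RESPONSE_WEIGHTS[r.response] for r in records)
    score = total / len(records)
    if score < 0:
        group = "low"
    elif score > 0:
        group = "high"
    else:
        group = "boundary"
        logger.warning(
            "subject %s has IAP score exactly 0; labelled boundary",
            records[0].subject_id,
        )
    return IAPResult(records[0].subject_id, score, group, len(records))


def filter_ni_trials(
    records: Iterable[NITrialRecord],
) -> list[NITrialRecord]:
    """Drop practice blocks (1-2) and implausible reaction times.

    RT bounds are inclusive: trials are removed only when strictly below
    200 ms or strictly above 2500 ms (the trial-duration ceiling).
    """
    return [
        r
        for r in records
        if r.block_index >= FIRST_ANALYSIS_BLOCK
        and RT_MIN_MS <= r.rt_ms <= RT_MAX_MS
    ]


def compute_ap_type(records: Sequence[NITrialRecord]) -> APResult:
    """ΔRT_mean = RT_mean(pain) − RT_mean(no-pain); sign gives the A/P type.

    Expects already-filtered trials. A condition left without trials raises
    :class:`EmptyAfterFilterError` naming the condition.
    """
    if not records:
        raise EmptyAfterFilterError("no surviving NI trials in either condition")
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) != 1:
        raise ValueError(f"records span multiple subjects: {sorted(subject_ids)}")
    pain = [r.rt_ms for r in records if r.condition == "pain"]
    nopain = [r.rt_ms for r in records if r.condition == "no_pain"]
    for name, trials in (("pain", pain), ("no_pain", nopain)):
        if not trials:
            raise EmptyAfterFilterError(
                f"no surviving trials in condition {name!r} "
                f"for subject {records[0].subject_id}"
            )
    rt_pain = sum(pain) / len(pain)
    rt_nopain = sum(nopain) / len(nopain)
    delta = rt_pain - rt_nopain
    if delta < 0:
        ap_type = "A"
    elif delta > 0:
        ap_type = "P"
    else:
        ap_type = "boundary"
        logger.warning(
            "subject %s has ΔRT_mean exactly 0; labelled boundary",
            records[0].subject_id,
        )
    return APResult(
        subject_id=records[0].subject_id,
        rt_mean_pain=rt_pain,
        rt_mean_nopain=rt_nopain,
        delta_rt_mean=delta,
        ap_type=ap_type,
        n_trials_used_pain=len(pain),
        n_trials_used_nopain=len(nopain),
    )


def _es_records_from_frame(df: pd.DataFrame) -> dict[str, list[ExperienceSamplingRecord]]:
    out: dict[str, list[ExperienceSamplingRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            ExperienceSamplingRecord(str(row.subject_id), int(row.trial), str(row.response))
        )
    return out


def _ni_records_from_frame(df: pd.DataFrame) -> dict[str, list[NITrialRecord]]:
    out: dict[str, list[NITrialRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            NITrialRecord(
                str(row.subject_id), int(row.block), str(row.condition), float(row.rt_ms)
            )
        )
    return out


def phenotype_table(
    es_table: pd.DataFrame, ni_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject phenotypes from the two behavioral tables.

    ``es_table`` needs columns subject_id/trial/response; ``ni_table`` needs
    subject_id/block/condition/rt_ms. Returns one row per subject with
    iap_score, iap_group, delta_rt_mean, ap_type (NaN/None where a subject is
    missing one task).
    """
    iap = {
        sid: compute_iap_score(recs)
        for sid, recs in _es_records_from_frame(es_table).items()
    }
    ap = {
        sid: compute_ap_type(filter_ni_trials(recs))
        for sid, recs in _ni_records_from_frame(ni_table).items()
    }
    subjects = sorted(set(iap) | set(ap))
    rows = []
    for sid in subjects:
        i = iap.get(sid)
        a = ap.get(sid)
        rows.append(
            {
                "subject_id": sid,
                "iap_score": i.iap_score if i else float("nan"),
                "iap_group": i.group if i else None,
                "delta_rt_mean": a.delta_rt_mean if a else float("nan"),
                "ap_type": a.ap_type if a else None,
                "rt_mean_pain": a.rt_mean_pain if a else float("nan"),
                "rt_mean_nopain": a.rt_mean_nopain if a else float("nan"),
            }
        )
    return pd.DataFrame(rows)
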