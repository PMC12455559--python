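"""Candidate prioritization rules for screening rounds 2 and 3."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, greedy_identity_filter


@dataclass
class CandidateScores:
    """Predicted scores for one candidate sequence."""

    record: SequenceRecord
    activity: float
    tm: float
    acid_tolerance: float

    def __post_init__(self) -> None:
        for v in (self.activity, self.tm, self.acid_tolerance):
            if not np.isfinite(v):
                raise ValueError(f"non-finite score for {self.record.id}")


@dataclass
class SelectionAudit:
    """Which rule admitted each candidate, and why others were dropped."""

    admitted: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)


def multiobjective_select(
    candidates: list[CandidateScores],
    percentile: float = 50.0,
    identity_threshold: float = 0.90,
    known: list[SequenceRecord] = (),
    top_n: int = 1,
) -> tuple[list[CandidateScores], SelectionAudit]:
    """Round-2 rule: keep candidates that maximize any individual score (top_n
    per score) OR sit at/above the given percentile on all three, then apply
    the greedy identity filter against known sequences and each other.

    Percentiles are linear-interpolation percentiles over the candidate pool.
    """
    if not candidates:
        raise ValueError("no candidates")
    audit = SelectionAudit()
    arr = {
        "activity": np.array([c.activity for c in candidates]),
        "tm": np.array([c.tm for c in candidates]),
        "acid_tolerance": np.array([c.acid_tolerance for c in candidates]),
    }
    cuts = {k: np.percentile(v, percentile) for k, v in arr.items()}
    argmax_ids: dict[str, str] = {}
    for key, v in arr.items():
        order = np.argsort(-v, kind="stable")[:top_n]
        for i in order:
            argmax_ids.setdefault(candidates[int(i)].record.id, f"argmax:{key}")
    prelim = []
    for c in candidates:
        if c.record.id in argmax_ids:
            prelim.append((c, argmax_ids[c.record.id]))
        elif all(getattr(c, k) >= cuts[k] for k in arr):
            prelim.append((c, f"above {percentile:g}th percentile on all scores"))
        else:
            audit.dropped[c.record.id] = "below percentile and not an argmax"
    kept_records = greedy_identity_filter(
        [c.record for c, _ in prelim], list(known), identity_threshold
    )
    kept_ids = {r.id for r in kept_records}
    selected = []
    for c, reason in prelim:
        if c.record.id in kept_ids:
            audit.admitted[c.record.id] = reason
            selected.append(c)
        else:
            audit.dropped[c.record.id] = (
                f"identity >= {identity_threshold:g} to a known or retained sequence"
            )
    return selected, audit


def threshold_select(
    candidates: list[CandidateScores],
    activity_min: float = 10.0,
    tm_min: float = 55.0,
    identity_threshold: float = 0.95,
    known: list[SequenceRecord] = (),
) -> tuple[list[CandidateScores], SelectionAudit]:
    """Round-3 rule: predicted activity >= activity_min AND predicted Tm
    strictly above tm_min, then the identity filter below identity_threshold.

    activity_min is in the assay's activity unit (umol product / mg enzyme).
    """
    audit = SelectionAudit()
    prelim = []
    for c in candidates:
        if c.activity < activity_min:
            audit.dropped[c.record.id] = f"activity {c.activity:g} < {activity_min:g}"
        elif not c.tm > tm_min:
            audit.dropped[c.record.id] = f"Tm {c.tm:g} not > {tm_min:g}"
        else:
            prelim.append(c)
    kept_records = greedy_identity_filter(
        [c.record for c in prelim], list(known), identity_threshold
    )
    kept_ids = {r.id for r in kept_records}
    selected = []
    for c in prelim:
        if c.record.id in kept_ids:
            audit.admitted[c.record.id] = "passed activity and Tm thresholds"
            selected.append(c)
        else:
            audit.dropped[c.record.id] = (
                f"identity >= {identity_threshold:g} to a known or retained sequence"
            )
    return selected, audit
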