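"""Parse raw payloads into validated records and apply the exclusion rule.

Every planned execution yields exactly one :class:`AuditRecord`, either
valid (carrying a parsed :class:`ModelOutput`) or excluded with the first
failing reason from a fixed check order:

1. ``missing`` — no payload, or an empty/whitespace payload;
2. ``parse_failure`` — not exactly one JSON object (truncated text, non-JSON
   prose, and multiple concatenated objects all land here);
3. ``schema_violation`` — a required field absent or of the wrong shape;
4. ``oov_action`` — an action field outside the ``A0``..``A9`` vocabulary;
5. ``out_of_range_confidence`` — confidence outside ``[0, 1]``.

Nothing is repaired or coerced; unexpected extra fields are tolerated (and
counted) because schema-constrained APIs commonly attach metadata.  Failures
never raise: they become exclusion records, which downstream metrics drop
from every denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from numbers import Real
from typing import Iterable, Sequence

import pandas as pd

from .codebook import ActionCode, Codebook, OOVActionError, load_codebook
from .prompts import REQUIRED_FIELDS
from .responder import ExecutionCondition, RawResponse

__all__ = [
    "ModelOutput",
    "AuditRecord",
    "EXCLUSION_REASONS",
    "ingest",
    "ingest_all",
    "tally_validity",
    "IntegrityError",
]

EXCLUSION_REASONS = (
    "missing",
    "parse_failure",
    "schema_violation",
    "oov_action",
    "out_of_range_confidence",
)


class IntegrityError(RuntimeError):
    """Duplicate (pair, condition, run) among ingested records."""


@dataclass(frozen=True)
class ModelOutput:
    action_primary: ActionCode
    action_time: str
    reason_tags: tuple[str, ...]
    confidence: float
    escalation_if_worse: ActionCode


@dataclass(frozen=True)
class AuditRecord:
    persona_id: str
    scenario_id: str
    pair_index: int
    condition: ExecutionCondition
    output: ModelOutput | None
    exclusion_reason: str | None = None
    exclusion_detail: str | None = None
    extra_fields: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return self.output is not None


def _parse_single_object(payload: str) -> dict:
    obj = json.loads(payload)  # raises on trailing garbage / concatenated objects
    if not isinstance(obj, dict):
        raise ValueError("payload is JSON but not an object")
    return obj


def ingest(raw: RawResponse, codebook: Codebook | None = None) -> AuditRecord:
    """Validate one raw response into exactly one audit record."""
    codebook = codebook or load_codebook()

    def excluded(reason: str, detail: str) -> AuditRecord:
        return AuditRecord(raw.persona_id, raw.scenario_id, raw.pair_index,
                           raw.condition, None, reason, detail)

    if raw.payload is None or not raw.payload.strip():
        return excluded("missing", "no payload")
    try:
        obj = _parse_single_object(raw.payload)
    except (json.JSONDecodeError, ValueError) as exc:
        return excluded("parse_failure", str(exc))

    missing = [f for f in REQUIRED_FIELDS if f not in obj]
    if missing:
        return excluded("schema_violation", f"missing fields: {missing}")
    if not isinstance(obj["reason_tags"], list) or not all(
        isinstance(t, str) for t in obj["reason_tags"]
    ):
        return excluded("schema_violation", "reason_tags must be a list of strings")
    if not isinstance(obj["action_time"], str):
        return excluded("schema_violation", "action_time must be a string token")
    if isinstance(obj["confidence"], bool) or not isinstance(obj["confidence"], Real):
        return excluded("schema_violation", "confidence must be a number")

    try:
        primary = codebook.parse(obj["action_primary"])
        escalation = codebook.parse(obj["escalation_if_worse"])
    except OOVActionError as exc:
        return excluded("oov_action", str(exc))

    confidence = float(obj["confidence"])
    if not 0.0 <= confidence <= 1.0:
        return excluded("out_of_range_confidence", f"confidence={confidence}")

    output = ModelOutput(
        action_primary=primary,
        action_time=obj["action_time"],
        reason_tags=tuple(obj["reason_tags"]),
        confidence=confidence,
        escalation_if_worse=escalation,
    )
    extras = tuple(sorted(set(obj) - set(REQUIRED_FIELDS)))
    return AuditRecord(raw.persona_id, raw.scenario_id, raw.pair_index,
                       raw.condition, output, extra_fields=extras)


def ingest_all(raws: Iterable[RawResponse], codebook: Codebook | None = None) -> list[AuditRecord]:
    codebook = codebook or load_codebook()
    return [ingest(r, codebook) for r in raws]


def tally_validity(records: Sequence[AuditRecord]) -> pd.DataFrame:
    """Per-slice planned/valid/excluded counts (plus an ``overall`` row).

    Raises :class:`IntegrityError` if any (pair, condition, run) occurs more
    than once — the matrix plans each cell exactly once.
    """
    seen: set = set()
    for r in records:
        key = (r.persona_id, r.scenario_id, r.condition)
        if key in seen:
            raise IntegrityError(f"duplicate execution record: {key}")
        seen.add(key)

    rows = []
    by_slice: dict[str, list[AuditRecord]] = {}
    for r in records:
        by_slice.setdefault(r.condition.slice_name, []).append(r)
    for slice_name in sorted(by_slice):
        recs = by_slice[slice_name]
        valid = sum(r.valid for r in recs)
        rows.append({"slice": slice_name, "planned": len(recs), "valid": valid,
                     "excluded": len(recs) - valid})
    rows.append({
        "slice": "overall",
        "planned": len(records),
        "valid": sum(r.valid for r in records),
        "excluded": sum(not r.valid for r in records),
    })
    return pd.DataFrame(rows, columns=["slice", "planned", "valid", "excluded"])
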