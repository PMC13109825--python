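"""Run-to-run modal agreement.

For one persona-scenario pair under one condition group (slice,
formulation, regime, schema_mode), the modal agreement is the fraction of
that pair's valid runs returning the most frequent ``action_primary``.
Pair fractions are then averaged, unweighted, within the group.  Pairs with
fewer than two valid runs carry no run-to-run information and are excluded
from the mean (their count is reported).  Ties over the maximal count do
not change the fraction; the companion modal-action column reports the
lowest-rank action among tied modes and flags the tie.

Agreement uses ``action_primary`` only.  ``slice_agreement`` accepts any
value field name, so timing/escalation agreement is available as a clearly
secondary extension, but reproducibility claims concern the action outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .ingest import AuditRecord
from .safety import GROUP_KEYS, round_half_away

__all__ = ["pair_modal_agreement", "slice_agreement", "AgreementResult"]


def pair_modal_agreement(actions: list) -> float:
    """Max category count / list length for one pair's valid runs."""
    if not actions:
        raise ValueError("modal agreement is undefined for an empty run list")
    counts = Counter(a.code if hasattr(a, "code") else a for a in actions)
    return max(counts.values()) / len(actions)


@dataclass(frozen=True)
class AgreementResult:
    grouping: tuple[str, str, str, str]
    mean: float          # unrounded
    mean_rounded: float  # two decimals, half away from zero
    pairs_used: int
    pairs_excluded: int


def _modal_action(actions: list[str]) -> tuple[str, bool]:
    counts = Counter(actions)
    top = max(counts.values())
    tied = sorted(a for a, c in counts.items() if c == top)
    return tied[0], len(tied) > 1


def slice_agreement(
    records: list[AuditRecord], value_field: str = "action_primary"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair fractions and per-group means over all condition groups.

    Returns ``(pair_table, summary_table)``.  Only valid records enter;
    groups with no qualifying pair (≥2 valid runs) appear in the summary
    with a null mean — an empty-result marker, never a fabricated 0.
    """
    by_group_pair: dict[tuple, dict[tuple, list]] = {}
    for r in records:
        if not r.valid:
            continue
        g = r.condition.condition_class
        pair = (r.pair_index, r.persona_id, r.scenario_id)
        value = getattr(r.output, value_field)
        value = value.code if hasattr(value, "code") else value
        by_group_pair.setdefault(g, {}).setdefault(pair, []).append(value)

    pair_rows, summary_rows = [], []
    for g in sorted(by_group_pair):
        fractions = []
        excluded = 0
        for pair in sorted(by_group_pair[g]):
            values = by_group_pair[g][pair]
            frac = pair_modal_agreement(values)
            modal, tie = _modal_action(values)
            pair_rows.append({
                **dict(zip(GROUP_KEYS, g)),
                "pair_index": pair[0], "persona_id": pair[1], "scenario_id": pair[2],
                "valid_runs": len(values), "modal_fraction": frac,
                "modal_value": modal, "modal_tie": tie,
                "included": len(values) >= 2,
            })
            if len(values) >= 2:
                fractions.append(frac)
            else:
                excluded += 1
        mean = sum(fractions) / len(fractions) if fractions else None
        summary_rows.append({
            **dict(zip(GROUP_KEYS, g)),
            "mean_agreement": mean,
            "mean_agreement_rounded": None if mean is None else round_half_away(mean, 2),
            "pairs_used": len(fractions),
            "pairs_excluded": excluded,
        })
    pair_cols = GROUP_KEYS + ["pair_index", "persona_id", "scenario_id", "valid_runs",
                              "modal_fraction", "modal_value", "modal_tie", "included"]
    summary_cols = GROUP_KEYS + ["mean_agreement", "mean_agreement_rounded",
                                 "pairs_used", "pairs_excluded"]
    return (pd.DataFrame(pair_rows, columns=pair_cols),
            pd.DataFrame(summary_rows, columns=summary_cols))
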