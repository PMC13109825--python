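"""Run-to-run modal agreement: per-pair fractions and slice means."""

import json
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triageaudit.agreement import pair_modal_agreement, slice_agreement
from triageaudit.ingest import ingest_all
from triageaudit.responder import (
    BehaviorProfile,
    ExecutionCondition,
    RawResponse,
    STOCHASTIC,
    SimulatedResponder,
    build_condition_matrix,
)


def test_pair_modal_agreement_direct_counts():
    assert pair_modal_agreement(["A1"] * 9 + ["A2"]) == 0.9
    assert pair_modal_agreement(["A1"] * 5 + ["A2"] * 5) == 0.5  # tie: value unaffected
    assert pair_modal_agreement(["A3"]) == 1.0


def test_empty_run_list_is_undefined():
    with pytest.raises(ValueError):
        pair_modal_agreement([])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from([f"A{k}" for k in range(10)]), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_permutation_invariance(actions, rnd):
    before = pair_modal_agreement(actions)
    shuffled = list(actions)
    rnd.shuffle(shuffled)
    assert pair_modal_agreement(shuffled) == before
    # independent brute-force tally
    counts = Counter(actions)
    assert before == max(counts.values()) / len(actions)


def _records_from_actions(actions_by_pair, runs):
    """Build valid records for one condition group from explicit run patterns."""
    raws = []
    for pair_index, actions in enumerate(actions_by_pair):
        for run, action in enumerate(actions, start=1):
            cond = ExecutionCondition("redflag24", "P1", STOCHASTIC, "prompt_only", run)
            payload = json.dumps({
                "action_primary": action, "action_time": "T_now", "reason_tags": [],
                "confidence": 0.5, "escalation_if_worse": action,
            })
            raws.append(RawResponse(cond, f"P{pair_index:03d}", "S008", pair_index, payload))
    return ingest_all(raws)


def test_slice_mean_from_configured_run_patterns():
    """18 unanimous pairs + 2 pairs at 9/10 + 4 pairs at 5/10 average to 0.91."""
    patterns = (
        [["A1"] * 10] * 18
        + [["A1"] * 9 + ["A2"]] * 2
        + [["A1"] * 5 + ["A2"] * 5] * 4
    )
    records = _records_from_actions(patterns, 10)
    _, summary = slice_agreement(records)
    assert len(summary) == 1
    assert summary.iloc[0]["mean_agreement_rounded"] == 0.91
    assert summary.iloc[0]["pairs_used"] == 24


def test_pairs_with_fewer_than_two_valid_runs_are_excluded():
    patterns = [["A1"] * 10] * 3 + [["A2"]]  # one single-run pair
    records = _records_from_actions(patterns, 10)
    pairs, summary = slice_agreement(records)
    assert summary.iloc[0]["pairs_used"] == 3
    assert summary.iloc[0]["pairs_excluded"] == 1
    assert summary.iloc[0]["mean_agreement"] == 1.0
    assert not pairs[pairs["valid_runs"] < 2]["included"].any()


def test_modal_tie_reports_lowest_rank_action():
    records = _records_from_actions([["A4"] * 5 + ["A2"] * 5], 10)
    pairs, _ = slice_agreement(records)
    assert pairs.iloc[0]["modal_value"] == "A2"
    assert bool(pairs.iloc[0]["modal_tie"])


def test_point_mass_profile_gives_agreement_exactly_one(slices):
    planned = build_condition_matrix(slices)
    responder = SimulatedResponder(BehaviorProfile.point_mass("A9"), seed=11)
    records = ingest_all(responder.run_matrix(planned))
    _, summary = slice_agreement(records)
    assert (summary["mean_agreement"] == 1.0).all()


def test_oracle_equivalence_on_random_groups():
    """Group means match an independent brute-force tally."""
    rng = np.random.default_rng(42)
    patterns = [
        [f"A{rng.integers(0, 10)}" for _ in range(10)] for _ in range(24)
    ]
    records = _records_from_actions(patterns, 10)
    _, summary = slice_agreement(records)
    expected = np.mean([
        max(Counter(p).values()) / len(p) for p in patterns
    ])
    assert summary.iloc[0]["mean_agreement"] == pytest.approx(expected)


def test_sharpening_the_distribution_does_not_reduce_agreement(slices):
    """Moving probability mass toward the mode never decreases expected
    agreement (simulated over a fixed seed grid)."""
    def mean_agreement(dist, seed):
        doc = {
            "name": "t", "slices": {
                s: {"primary": {"P1": dist, "P2": dist},
                    "escalation_offsets": {"prompt_only": {0: 1.0},
                                           "response_schema": {0: 1.0}},
                    "timing": {"T_now": 1.0}}
                for s in ("sev1_24", "nonredflag24", "redflag24")
            },
        }
        planned = build_condition_matrix(slices)
        planned = [p for p in planned
                   if p.condition.condition_class
                   == ("redflag24", "P1", "stochastic", "prompt_only")]
        responder = SimulatedResponder(BehaviorProfile(doc), seed=seed)
        records = ingest_all([responder.respond(p, i) for i, p in enumerate(planned)])
        _, summary = slice_agreement(records)
        return summary.iloc[0]["mean_agreement"]

    flat = {"A1": 0.34, "A2": 0.33, "A3": 0.33}
    peaked = {"A1": 0.8, "A2": 0.1, "A3": 0.1}
    flat_means = [mean_agreement(flat, s) for s in range(3)]
    peaked_means = [mean_agreement(peaked, s) for s in range(3)]
    assert np.mean(peaked_means) >= np.mean(flat_means)
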