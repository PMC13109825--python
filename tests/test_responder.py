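"""Condition matrix arithmetic and the synthetic responder."""

import json
from collections import Counter

import pytest

from triageaudit.ingest import ingest
from triageaudit.responder import (
    BehaviorProfile,
    ConfigurationError,
    ExecutionCondition,
    NEAR_DETERMINISTIC,
    STOCHASTIC,
    ResponderAdapter,
    SimulatedResponder,
    build_condition_matrix,
    external_responses,
    load_profile,
)


@pytest.fixture(scope="module")
def matrix(slices):
    return build_condition_matrix(slices)


def test_matrix_counts(matrix):
    counts = Counter(p.condition.slice_name for p in matrix)
    assert counts["sev1_24"] == 480
    assert counts["nonredflag24"] == 1440
    assert counts["redflag24"] == 1440
    assert len(matrix) == 3360


def test_mild_slice_has_no_schema_conditions(matrix):
    assert not any(
        p.condition.schema_mode == "response_schema"
        for p in matrix
        if p.condition.slice_name == "sev1_24"
    )


def test_schema_mode_requires_stochastic_regime():
    with pytest.raises(ValueError):
        ExecutionCondition("redflag24", "P1", NEAR_DETERMINISTIC, "response_schema", 1)
    ExecutionCondition("redflag24", "P1", STOCHASTIC, "response_schema", 1)  # fine


def test_decoding_regimes_carry_the_audited_settings():
    assert (NEAR_DETERMINISTIC.temperature, NEAR_DETERMINISTIC.top_p) == (0.0, 1.0)
    assert (STOCHASTIC.temperature, STOCHASTIC.top_p) == (1.0, 0.95)


def test_neardet_redflag_modal_action_is_self_care(matrix):
    """Under T=0 prompt-only the default profile maps S008 to A1."""
    responder = SimulatedResponder(load_profile(), seed=1)
    cells = [
        (i, p) for i, p in enumerate(matrix)
        if p.scenario_id == "S008"
        and p.condition.regime.name == "near_deterministic"
        and p.condition.run_index == 1
    ]
    assert cells
    for i, p in cells:
        payload = json.loads(responder.respond(p, i).payload)
        assert payload["action_primary"] == "A1"


def test_point_mass_profile_repeats_itself(matrix):
    responder = SimulatedResponder(BehaviorProfile.point_mass("A9"), seed=7)
    cells = [(i, p) for i, p in enumerate(matrix)
             if p.condition.condition_class == ("redflag24", "P1", "stochastic", "prompt_only")
             and p.pair_index == 0]
    payloads = {responder.respond(i_p[1], i_p[0]).payload for i_p in cells}
    assert len(payloads) == 1
    assert json.loads(payloads.pop())["action_primary"] == "A9"


def test_same_seed_same_payload(matrix):
    a = SimulatedResponder(load_profile(), seed=3).respond(matrix[100], 100)
    b = SimulatedResponder(load_profile(), seed=3).respond(matrix[100], 100)
    c = SimulatedResponder(load_profile(), seed=4).respond(matrix[100], 100)
    assert a == b
    assert a != c or a.payload == c.payload  # different seed may still collide per-cell


def test_default_profile_designates_18_invalid_outputs():
    assert load_profile().injection_count == 18


class _EchoAdapter(ResponderAdapter):
    def __init__(self, payload):
        self.payload = payload

    def respond(self, prompt_text, temperature, top_p, schema_mode):
        return self.payload


def test_missing_adapter_is_a_configuration_error(matrix):
    with pytest.raises(ConfigurationError):
        external_responses(matrix[:1], {}, None)


def test_adapter_substitutability(matrix, personas, vignettes):
    from triageaudit.prompts import render_prompt

    planned = matrix[:2]
    prompts = {}
    pmap = {p.persona_id: p for p in personas}
    vmap = {v.scenario_id: v for v in vignettes}
    for p in planned:
        key = (p.persona_id, p.scenario_id, p.condition.formulation)
        prompts[key] = render_prompt(pmap[p.persona_id], vmap[p.scenario_id],
                                     p.condition.formulation)
    good = json.dumps({"action_primary": "A7", "action_time": "T_today",
                       "reason_tags": [], "confidence": 0.5,
                       "escalation_if_worse": "A8"})
    raws = external_responses(planned, prompts, _EchoAdapter(good))
    assert all(ingest(r).valid for r in raws)
    raws = external_responses(planned, prompts, _EchoAdapter(""))
    records = [ingest(r) for r in raws]
    assert all(r.exclusion_reason == "missing" for r in records)
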