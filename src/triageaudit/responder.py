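"""Synthetic responder and the condition matrix.

The audit needs a responder that maps a rendered prompt plus a decoding
configuration to a raw text payload.  Two routes exist:

* :class:`SimulatedResponder` — the seeded synthetic stand-in used for all
  shipped analyses.  Its behavior is a :class:`BehaviorProfile` (packaged
  YAML data): per-slice categorical distributions over primary actions,
  escalation-offset and timing distributions, explicitly designated
  single-output overrides, designated malformed outputs, and the
  near-deterministic minority-run patterns.  Identical seed and profile
  give byte-identical payloads.
* :class:`ResponderAdapter` — the provider-agnostic contract for plugging a
  real LLM behind the same pipeline.  The pipeline only ever sees the raw
  text an adapter returns; transport failures surface as missing payloads
  and are excluded downstream.

Decoding semantics of the simulator: near-deterministic decoding
(temperature 0.0, top_p 1.0) emits the arg-max of each distribution, so a
point-mass profile repeats itself exactly; stochastic decoding (temperature
1.0, top_p 0.95) samples from the distributions.  Response-schema mode
sharpens the action distribution (probability mass moves toward the mode)
and can never produce a malformed payload, mirroring schema-constrained
decoding's formatting guarantees.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import Slice, SLICE_NAMES
from .prompts import FORMULATIONS, PromptSpec

__all__ = [
    "DecodingRegime",
    "NEAR_DETERMINISTIC",
    "STOCHASTIC",
    "ExecutionCondition",
    "PlannedExecution",
    "RawResponse",
    "BehaviorProfile",
    "load_profile",
    "build_condition_matrix",
    "SimulatedResponder",
    "ResponderAdapter",
    "external_responses",
    "ConfigurationError",
]

TIMING_TOKENS = ("T_now", "T_today", "T_within_days", "T_routine")


class ConfigurationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DecodingRegime:
    name: str
    temperature: float
    top_p: float


NEAR_DETERMINISTIC = DecodingRegime("near_deterministic", 0.0, 1.0)
STOCHASTIC = DecodingRegime("stochastic", 1.0, 0.95)
_REGIMES = {r.name: r for r in (NEAR_DETERMINISTIC, STOCHASTIC)}


def regime_by_name(name: str) -> DecodingRegime:
    return _REGIMES[name]


@dataclass(frozen=True)
class ExecutionCondition:
    slice_name: str
    formulation: str
    regime: DecodingRegime
    schema_mode: str  # prompt_only | response_schema
    run_index: int

    def __post_init__(self) -> None:
        if self.schema_mode not in ("prompt_only", "response_schema"):
            raise ValueError(f"unknown schema_mode {self.schema_mode!r}")
        if self.schema_mode == "response_schema" and self.regime.name != "stochastic":
            raise ValueError("response_schema runs only occur under stochastic decoding")
        if self.run_index < 1:
            raise ValueError("run_index starts at 1")

    @property
    def condition_class(self) -> tuple[str, str, str, str]:
        """Grouping key without the run index."""
        return (self.slice_name, self.formulation, self.regime.name, self.schema_mode)


@dataclass(frozen=True)
class PlannedExecution:
    """One cell of the full matrix: a pair under a condition and run."""

    condition: ExecutionCondition
    pair_index: int
    persona_id: str
    scenario_id: str


@dataclass(frozen=True)
class RawResponse:
    condition: ExecutionCondition
    persona_id: str
    scenario_id: str
    pair_index: int
    payload: str | None  # None = transport failure / missing


# Condition classes executed per slice: (regime, schema_mode, run count).
# The mild slice gets a lighter design; the two higher-acuity slices add the
# longer stochastic arm and the schema-constrained arm.
MATRIX_DESIGN: dict[str, tuple[tuple[DecodingRegime, str, int], ...]] = {
    "sev1_24": (
        (NEAR_DETERMINISTIC, "prompt_only", 5),
        (STOCHASTIC, "prompt_only", 5),
    ),
    "nonredflag24": (
        (NEAR_DETERMINISTIC, "prompt_only", 10),
        (STOCHASTIC, "prompt_only", 15),
        (STOCHASTIC, "response_schema", 5),
    ),
    "redflag24": (
        (NEAR_DETERMINISTIC, "prompt_only", 10),
        (STOCHASTIC, "prompt_only", 15),
        (STOCHASTIC, "response_schema", 5),
    ),
}


def build_condition_matrix(
    slices: Mapping[str, Slice], runs_override: int | None = None
) -> list[PlannedExecution]:
    """Enumerate every planned execution, in canonical order.

    Canonical order is slice → formulation → condition class → run → pair;
    the position in this list seeds the simulator, so the matrix is
    invariant under seed and the full design always totals 3,360 cells
    (480 + 1,440 + 1,440).  ``runs_override`` caps the run count of every
    condition class (smoke tests).
    """
    planned: list[PlannedExecution] = []
    for slice_name in SLICE_NAMES:
        sl = slices[slice_name]
        for formulation in FORMULATIONS:
            for regime, schema_mode, runs in MATRIX_DESIGN[slice_name]:
                if runs_override is not None:
                    runs = min(runs, runs_override)
                for run_index in range(1, runs + 1):
                    cond = ExecutionCondition(slice_name, formulation, regime, schema_mode, run_index)
                    for pair_index, (persona_id, scenario_id) in enumerate(sl.pairs):
                        planned.append(
                            PlannedExecution(cond, pair_index, persona_id, scenario_id)
                        )
    return planned


def _runs_in_class(condition: ExecutionCondition) -> int:
    for regime, schema_mode, runs in MATRIX_DESIGN[condition.slice_name]:
        if regime == condition.regime and schema_mode == condition.schema_mode:
            return runs
    raise KeyError(condition.condition_class)


def _validate_dist(dist: Mapping, what: str) -> dict:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{what} distribution sums to {total}, not 1")
    return {k: float(v) / total for k, v in dist.items()}


_INVALID_PAYLOADS = {
    "not_json": "まずは安静にして様子を見るのがよいと思います。",
    "truncated": '{"action_primary": "A1", "action_time": ',
    "multiple_objects": '{"action_primary": "A1"}\n{"action_primary": "A2"}',
    "missing_field": json.dumps(
        {"action_primary": "A1", "action_time": "T_today", "reason_tags": ["worry"], "confidence": 0.7},
        sort_keys=True,
    ),
    "oov_action": json.dumps(
        {"action_primary": "A10", "action_time": "T_today", "reason_tags": ["worry"],
         "confidence": 0.7, "escalation_if_worse": "A6"},
        sort_keys=True,
    ),
    "bad_confidence": json.dumps(
        {"action_primary": "A1", "action_time": "T_today", "reason_tags": ["worry"],
         "confidence": 1.5, "escalation_if_worse": "A6"},
        sort_keys=True,
    ),
    "empty": "",
}


class BehaviorProfile:
    """Validated, immutable view of a responder behavior profile."""

    def __init__(self, doc: dict):
        self.name = doc.get("name", "unnamed")
        self.confidence_range = tuple(doc.get("confidence_range", (0.55, 0.95)))
        self.confidence_neardet = float(doc.get("confidence_neardet", 0.9))
        self.schema_sharpen = float(doc.get("schema_sharpen", 2.0))
        self.reason_tag_vocab = {
            s: tuple(v) for s, v in doc.get("reason_tag_vocab", {}).items()
        }
        self.slices: dict[str, dict] = {}
        for slice_name, spec in doc["slices"].items():
            primary = {
                f: _validate_dist(d, f"{slice_name}/{f} primary")
                for f, d in spec["primary"].items()
            }
            offsets = {
                mode: _validate_dist(d, f"{slice_name}/{mode} escalation")
                for mode, d in spec["escalation_offsets"].items()
            }
            timing = _validate_dist(spec["timing"], f"{slice_name} timing")
            self.slices[slice_name] = {
                "primary": primary,
                "escalation_offsets": offsets,
                "timing": timing,
            }
        self._overrides = {
            (o["slice"], o["formulation"], o["regime"], o["schema_mode"],
             int(o["pair_index"]), int(o["run_index"])): o["action_primary"]
            for o in doc.get("overrides", [])
        }
        self._injections = {
            (o["slice"], o["formulation"], o["regime"], o["schema_mode"],
             int(o["pair_index"]), int(o["run_index"])): o["kind"]
            for o in doc.get("invalid_injections", [])
        }
        for key, kind in self._injections.items():
            if key[3] == "response_schema":
                raise ValueError("schema-constrained decoding cannot emit malformed output")
            if kind not in _INVALID_PAYLOADS:
                raise ValueError(f"unknown invalid-injection kind {kind!r}")
        self._patterns: dict[tuple[str, str, int], tuple[int, str]] = {}
        for pat in doc.get("neardet_patterns", []):
            for p in pat["pairs"]:
                self._patterns[(pat["slice"], pat["formulation"], int(p))] = (
                    int(pat["minority_runs"]),
                    pat["minority_action"],
                )

    # --- constructors -------------------------------------------------
    @classmethod
    def point_mass(cls, action: str = "A9", offset: int = 0, timing: str = "T_now") -> "BehaviorProfile":
        """Degenerate profile: every output identical (used in limit checks)."""
        spec = {
            "primary": {f: {action: 1.0} for f in FORMULATIONS},
            "escalation_offsets": {"prompt_only": {offset: 1.0}, "response_schema": {offset: 1.0}},
            "timing": {timing: 1.0},
        }
        return cls({
            "name": f"point_mass_{action}",
            "confidence_range": [0.9, 0.9],
            "slices": {s: spec for s in SLICE_NAMES},
        })

    # --- accessors ----------------------------------------------------
    def primary_dist(self, condition: ExecutionCondition) -> dict[str, float]:
        dist = self.slices[condition.slice_name]["primary"][condition.formulation]
        if condition.schema_mode == "response_schema":
            powered = {a: p ** self.schema_sharpen for a, p in dist.items()}
            total = sum(powered.values())
            dist = {a: p / total for a, p in powered.items()}
        return dist

    def offset_dist(self, condition: ExecutionCondition) -> dict[int, float]:
        return self.slices[condition.slice_name]["escalation_offsets"][condition.schema_mode]

    def timing_dist(self, condition: ExecutionCondition) -> dict[str, float]:
        return self.slices[condition.slice_name]["timing"]

    def override_for(self, planned: PlannedExecution) -> str | None:
        c = planned.condition
        return self._overrides.get(
            (c.slice_name, c.formulation, c.regime.name, c.schema_mode,
             planned.pair_index, c.run_index)
        )

    def injection_for(self, planned: PlannedExecution) -> str | None:
        c = planned.condition
        return self._injections.get(
            (c.slice_name, c.formulation, c.regime.name, c.schema_mode,
             planned.pair_index, c.run_index)
        )

    def minority_pattern(self, condition: ExecutionCondition, pair_index: int) -> tuple[int, str] | None:
        if condition.regime.name != "near_deterministic":
            return None
        return self._patterns.get((condition.slice_name, condition.formulation, pair_index))

    @property
    def injection_count(self) -> int:
        return len(self._injections)


def load_profile(name_or_path: str | Path = "calibrated") -> BehaviorProfile:
    """Load a behavior profile by packaged name or by file path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text("utf-8")
    else:
        res = resources.files("triageaudit.data").joinpath(f"profile_{name_or_path}.yaml")
        try:
            text = res.read_text("utf-8")
        except FileNotFoundError:
            raise ConfigurationError(f"unknown profile {name_or_path!r}") from None
    return BehaviorProfile(yaml.safe_load(text))


def _argmax(dist: Mapping, key_order=None) -> object:
    """Arg-max with deterministic tie-break (first key in sorted order)."""
    best_p = max(dist.values())
    candidates = [k for k, v in dist.items() if v == best_p]
    return sorted(candidates, key=lambda k: (str(k) if key_order is None else key_order(k)))[0]


class SimulatedResponder:
    """Seeded synthetic responder over a behavior profile."""

    def __init__(self, profile: BehaviorProfile, seed: int):
        self.profile = profile
        self.seed = int(seed)

    def respond(self, planned: PlannedExecution, record_index: int,
                prompt: PromptSpec | None = None) -> RawResponse:
        """Produce the raw payload for one planned execution.

        ``record_index`` is the cell's position in the canonical matrix; it
        seeds an independent stream, so payloads are reproducible and
        independent of execution order.  The ``prompt`` argument is accepted
        for adapter-signature parity; the simulator never inspects it.
        """
        profile, cond = self.profile, planned.condition
        kind = profile.injection_for(planned)
        if kind is not None:
            return RawResponse(cond, planned.persona_id, planned.scenario_id,
                               planned.pair_index, _INVALID_PAYLOADS[kind])

        rng = np.random.default_rng([self.seed, 101, int(record_index)])
        near_det = cond.regime.name == "near_deterministic"
        primary_dist = profile.primary_dist(cond)
        if near_det:
            action = _argmax(primary_dist)
        else:
            actions = sorted(primary_dist)
            probs = np.array([primary_dist[a] for a in actions])
            action = actions[int(rng.choice(len(actions), p=probs / probs.sum()))]

        forced = profile.override_for(planned)
        if forced is not None:
            action = forced
        pattern = profile.minority_pattern(cond, planned.pair_index)
        if pattern is not None:
            minority_runs, minority_action = pattern
            if cond.run_index > _runs_in_class(cond) - minority_runs:
                action = minority_action

        offset_dist = profile.offset_dist(cond)
        if near_det:
            offset = int(_argmax(offset_dist, key_order=lambda k: (-offset_dist[k], k)))
        else:
            offsets = sorted(offset_dist)
            probs = np.array([offset_dist[o] for o in offsets])
            offset = int(offsets[int(rng.choice(len(offsets), p=probs / probs.sum()))])
        esc_rank = min(9, max(0, int(action[1:]) + offset))
        escalation = f"A{esc_rank}"

        timing_dist = profile.timing_dist(cond)
        if near_det:
            timing = _argmax(timing_dist, key_order=lambda k: (-timing_dist[k], k))
        else:
            timings = sorted(timing_dist)
            probs = np.array([timing_dist[t] for t in timings])
            timing = timings[int(rng.choice(len(timings), p=probs / probs.sum()))]

        vocab = profile.reason_tag_vocab.get(cond.slice_name, ("worry",))
        if near_det:
            tags = [vocab[0]]
            confidence = profile.confidence_neardet
        else:
            k = 1 + int(rng.integers(0, min(2, len(vocab))))
            tags = list(rng.choice(vocab, size=k, replace=False))
            lo, hi = profile.confidence_range
            confidence = round(float(rng.uniform(lo, hi)), 2)

        payload = json.dumps(
            {
                "action_primary": action,
                "action_time": timing,
                "reason_tags": tags,
                "confidence": confidence,
                "escalation_if_worse": escalation,
            },
            ensure_ascii=False,
            sort_keys=True,
        )
        return RawResponse(cond, planned.persona_id, planned.scenario_id,
                           planned.pair_index, payload)

    def run_matrix(self, planned: Sequence[PlannedExecution]) -> list[RawResponse]:
        return [self.respond(p, i) for i, p in enumerate(planned)]


class ResponderAdapter(ABC):
    """Provider-agnostic contract for executing prompts against a real LLM.

    An adapter receives the rendered prompt text and the decoding
    configuration and returns the raw response text.  Returning ``None``,
    an empty string, or raising marks the output missing; the pipeline
    never inspects adapter internals.
    """

    @abstractmethod
    def respond(self, prompt_text: str, temperature: float, top_p: float,
                schema_mode: str) -> str | None:
        ...


def external_responses(
    planned: Sequence[PlannedExecution],
    prompts: Mapping[tuple[str, str, str], PromptSpec],
    adapter: ResponderAdapter | None,
) -> list[RawResponse]:
    """Execute the matrix through a registered adapter.

    ``prompts`` maps (persona_id, scenario_id, formulation) to the rendered
    prompt.  Transport failures become missing payloads, excluded downstream.
    """
    if adapter is None:
        raise ConfigurationError("no responder adapter registered")
    out: list[RawResponse] = []
    for p in planned:
        spec = prompts[(p.persona_id, p.scenario_id, p.condition.formulation)]
        try:
            payload = adapter.respond(
                spec.full_text, p.condition.regime.temperature,
                p.condition.regime.top_p, p.condition.schema_mode,
            )
        except Exception:
            payload = None
        out.append(RawResponse(p.condition, p.persona_id, p.scenario_id, p.pair_index, payload))
    return out
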