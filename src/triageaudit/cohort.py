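"""Synthetic cohort: persona bank, vignette bank, and the three audit slices.

The audit operates on a fixed bank of 60 lay personas and 30 symptom
vignettes (3 per symptom category, 6 of them red-flag), combined into three
prespecified slices of 24 persona-scenario pairs each:

* ``sev1_24`` — 12 distinct mild (severity-1) non-red-flag scenarios, 2 pairs each;
* ``nonredflag24`` — 12 distinct intermediate (severity-2) non-red-flag
  scenarios, 2 pairs each;
* ``redflag24`` — the 6 urgent red-flag scenarios, 4 pairs each.

Slice membership implies severity, so the bank's severity metadata is the
single source of slice eligibility.  All generation is seeded and
reproducible: the same seed yields byte-identical banks and slices.

Persona selection per slice is stratified round-robin over health-literacy
strata (with an anxiety-coverage repair step) from a seeded shuffle, so each
slice's 24 personas span all three health-literacy and all three
anxiety-tendency levels — required downstream by the subgroup analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Persona",
    "Vignette",
    "Slice",
    "SLICE_NAMES",
    "build_persona_bank",
    "build_vignette_bank",
    "build_slices",
    "load_attribute_vocab",
]

SLICE_NAMES = ("sev1_24", "nonredflag24", "redflag24")

# Persona attributes, in rendering order.  Ordinal attributes use the level
# order of the packaged vocabulary file.
PERSONA_ATTRIBUTES = (
    "age_group",
    "region_access",
    "household",
    "financial_constraint",
    "chronic_condition",
    "health_literacy",
    "trust_in_medicine",
    "regular_doctor",
    "anxiety_tendency",
)

_DURATION_JA = {
    "a_few_hours": "数時間前から",
    "since_yesterday": "昨日から",
    "several_days": "数日前から",
    "over_a_week": "1週間以上前から",
}
_DURATION_EN = {
    "a_few_hours": "for a few hours",
    "since_yesterday": "since yesterday",
    "several_days": "for several days",
    "over_a_week": "for over a week",
}
# Red-flag presentations are acute: restrict their duration slot.
_ACUTE_DURATIONS = ("a_few_hours", "since_yesterday")


@dataclass(frozen=True)
class Persona:
    persona_id: str
    age_group: str
    region_access: str
    household: str
    financial_constraint: str
    chronic_condition: bool
    health_literacy: str
    trust_in_medicine: str
    regular_doctor: bool
    anxiety_tendency: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Vignette:
    scenario_id: str
    category: str
    severity: int
    duration: str
    time_context: str
    red_flag: bool
    vignette_text: str
    vignette_text_en: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Slice:
    """A prespecified, ordered list of 24 (persona_id, scenario_id) pairs."""

    name: str
    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def scenario_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sid in self.pairs:
            seen.setdefault(sid)
        return list(seen)

    def persona_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.pairs:
            seen.setdefault(pid)
        return list(seen)

    def to_dict(self) -> dict:
        return {"name": self.name, "pairs": [list(p) for p in self.pairs]}


def load_attribute_vocab() -> dict:
    text = resources.files("triageaudit.data").joinpath("persona_vocab.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def build_persona_bank(seed: int, n: int = 60) -> list[Persona]:
    """Generate the persona bank.

    Each attribute column is a seeded shuffle of its vocabulary cycled to
    length ``n``, which guarantees every level of every attribute appears
    (and appears near-uniformly) while assignments across attributes are
    independent shuffles of the same stream.
    """
    vocab = load_attribute_vocab()
    rng = np.random.default_rng([int(seed), 11])
    columns: dict[str, list] = {}
    for attr in PERSONA_ATTRIBUTES:
        levels = vocab[attr]
        col = [levels[i % len(levels)] for i in range(n)]
        rng.shuffle(col)
        columns[attr] = col
    return [
        Persona(persona_id=f"P{i + 1:03d}", **{a: columns[a][i] for a in PERSONA_ATTRIBUTES})
        for i in range(n)
    ]


def _archetypes() -> list[dict]:
    text = resources.files("triageaudit.data").joinpath("vignettes.json").read_text("utf-8")
    return json.loads(text)


def build_vignette_bank(seed: int) -> list[Vignette]:
    """Generate the 30-vignette bank from the packaged archetype table.

    Category, severity, red-flag status, ids and body text are fixed design
    data (including the three urgent archetypes S008, S018, S027); the seed
    only fills the duration and time-context metadata slots and the duration
    phrase in the rendered text.
    """
    vocab = load_attribute_vocab()
    rng = np.random.default_rng([int(seed), 13])
    out = []
    for row in _archetypes():
        durations = _ACUTE_DURATIONS if row["red_flag"] else vocab["duration"]
        duration = durations[int(rng.integers(len(durations)))]
        time_context = vocab["time_context"][int(rng.integers(len(vocab["time_context"])))]
        out.append(
            Vignette(
                scenario_id=row["scenario_id"],
                category=row["category"],
                severity=int(row["severity"]),
                duration=duration,
                time_context=time_context,
                red_flag=bool(row["red_flag"]),
                vignette_text=row["text_ja"].format(duration=_DURATION_JA[duration]),
                vignette_text_en=row["text_en"].format(duration=_DURATION_EN[duration]),
            )
        )
    _check_vignette_bank(out)
    return out


def _check_vignette_bank(bank: Sequence[Vignette]) -> None:
    if len(bank) != 30 or len({v.scenario_id for v in bank}) != 30:
        raise ValueError("vignette bank must hold 30 uniquely identified vignettes")
    reds = [v for v in bank if v.red_flag]
    if len(reds) != 6 or any(v.severity != 3 for v in reds):
        raise ValueError("exactly 6 red-flag vignettes, all severity 3, are required")


class SliceConfigurationError(ValueError):
    """The banks cannot supply the scenarios a slice requires."""


def _stratified_personas(personas: Sequence[Persona], k: int, rng: np.random.Generator) -> list[Persona]:
    """Pick ``k`` personas spanning all literacy and anxiety strata.

    Round-robin over health-literacy groups from a seeded shuffle gives
    literacy balance; a deterministic repair pass then guarantees every
    anxiety level is represented.
    """
    order = list(personas)
    rng.shuffle(order)
    groups: dict[str, list[Persona]] = {}
    for p in order:
        groups.setdefault(p.health_literacy, []).append(p)
    levels = sorted(groups)
    picked: list[Persona] = []
    i = 0
    while len(picked) < k:
        g = groups[levels[i % len(levels)]]
        if g:
            picked.append(g.pop(0))
        i += 1
        if i > 10 * k:  # all groups exhausted
            raise SliceConfigurationError("not enough personas to fill a slice")
    rest = [p for p in order if p not in picked]
    for level in ("low", "mid", "high"):
        if any(p.anxiety_tendency == level for p in picked):
            continue
        donor = next((p for p in rest if p.anxiety_tendency == level), None)
        if donor is None:
            raise SliceConfigurationError(f"anxiety level {level!r} absent from bank")
        # evict someone whose strata stay covered without them
        for j, q in enumerate(picked):
            lit_ok = sum(p.health_literacy == q.health_literacy for p in picked) > 1
            anx_ok = sum(p.anxiety_tendency == q.anxiety_tendency for p in picked) > 1
            if lit_ok and anx_ok:
                picked[j] = donor
                break
        else:
            raise SliceConfigurationError("cannot repair anxiety coverage")
    return picked


def build_slices(
    personas: Sequence[Persona], vignettes: Sequence[Vignette], seed: int
) -> dict[str, Slice]:
    """Build the three fixed 24-pair slices, seeded and stratified."""
    sev1 = sorted(v.scenario_id for v in vignettes if v.severity == 1 and not v.red_flag)
    sev2 = sorted(v.scenario_id for v in vignettes if v.severity == 2 and not v.red_flag)
    red = sorted(v.scenario_id for v in vignettes if v.red_flag)
    specs = [("sev1_24", sev1, 12, 2), ("nonredflag24", sev2, 12, 2), ("redflag24", red, 6, 4)]
    slices: dict[str, Slice] = {}
    for idx, (name, scen, need, per) in enumerate(specs):
        if len(scen) < need:
            raise SliceConfigurationError(
                f"slice {name} needs {need} scenarios of its class, found {len(scen)}"
            )
        scen = scen[:need]
        rng = np.random.default_rng([int(seed), 17, idx])
        chosen = _stratified_personas(personas, need * per, rng)
        pairs = tuple(
            (chosen[k * per + j].persona_id, sid)
            for k, sid in enumerate(scen)
            for j in range(per)
        )
        slices[name] = Slice(name=name, pairs=pairs)
    return slices


def dump_bank(objs: Sequence, path) -> None:
    """Serialize a bank (personas/vignettes/slices) as deterministic JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([o.to_dict() for o in objs], fh, ensure_ascii=False, sort_keys=True, indent=1)
        fh.write("\n")
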