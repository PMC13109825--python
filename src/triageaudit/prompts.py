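"""Prompt rendering for the two formulations.

P1 presents the persona as one narrative paragraph and the vignette as
natural language; P2 presents the same information as structured key-value
fields.  Both carry the identical instruction block: the layperson role
constraint, the no-diagnosis constraint, the full codebook legend, and the
five required JSON field names.  Rendering is deterministic, and the two
formulations have information parity — every persona attribute phrase
appears verbatim in both persona blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .codebook import Codebook, load_codebook
from .cohort import PERSONA_ATTRIBUTES, Persona, Vignette

__all__ = ["REQUIRED_FIELDS", "PromptSpec", "render_prompt", "attribute_phrases"]

# Field names the responder must return, verbatim, in one JSON object.
REQUIRED_FIELDS = (
    "action_primary",
    "action_time",
    "reason_tags",
    "confidence",
    "escalation_if_worse",
)

FORMULATIONS = ("P1", "P2")


@dataclass(frozen=True)
class PromptSpec:
    formulation: str
    persona_block: str
    scenario_block: str
    instruction_block: str
    required_fields: tuple[str, ...] = REQUIRED_FIELDS

    @property
    def full_text(self) -> str:
        return "\n\n".join((self.persona_block, self.scenario_block, self.instruction_block))


@lru_cache(maxsize=None)
def _templates() -> dict:
    text = resources.files("triageaudit.data").joinpath("templates.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def attribute_phrases(persona: Persona, language: str = "ja") -> dict[str, str]:
    """Phrase for each persona attribute value, in attribute order."""
    maps = _templates()[language]["phrases"]
    out = {}
    for attr in PERSONA_ATTRIBUTES:
        value = getattr(persona, attr)
        out[attr] = maps[attr][value]
    return out


def render_prompt(
    persona: Persona,
    vignette: Vignette,
    formulation: str,
    language: str = "ja",
    codebook: Codebook | None = None,
) -> PromptSpec:
    """Render the P1 (narrative) or P2 (structured) prompt for one pair."""
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    tpl = _templates()[language]
    codebook = codebook or load_codebook()
    phrases = attribute_phrases(persona, language)

    if formulation == "P1":
        persona_block = tpl["persona_narrative"].format(
            phrases=tpl["phrase_join"].join(phrases.values())
        )
        text = vignette.vignette_text if language == "ja" else vignette.vignette_text_en
        scenario_block = tpl["scenario_narrative"].format(text=text)
    else:
        persona_block = "\n".join(f"{attr}: {phrase}" for attr, phrase in phrases.items())
        text = vignette.vignette_text if language == "ja" else vignette.vignette_text_en
        scenario_block = "\n".join(
            (
                f"scenario_id: {vignette.scenario_id}",
                f"category: {vignette.category}",
                f"duration: {vignette.duration}",
                f"time_context: {vignette.time_context}",
                f"vignette: {text}",
            )
        )

    instruction_block = tpl["instruction"].format(
        legend=codebook.legend(), fields=", ".join(REQUIRED_FIELDS)
    )
    return PromptSpec(
        formulation=formulation,
        persona_block=persona_block,
        scenario_block=scenario_block,
        instruction_block=instruction_block,
    )
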