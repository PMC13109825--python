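"""Ordinal action codebook for lay self-triage.

The codebook maps ten lay next-step actions, from watchful waiting (A0) to
calling an ambulance (A9), onto integer ranks 0..9.  The ranks give a total
order used by the interval arithmetic below, but the codebook is a behavioral
taxonomy of common lay options, not a normative clinical escalation ladder:
clinical acceptability judgments live entirely in the reference policy's
per-scenario intervals, never in the rank order itself.

The codebook ships as packaged data (``data/codebook.json``) so alternative
codebooks can be audited with the same machinery.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

__all__ = [
    "ActionCode",
    "ActionInterval",
    "Codebook",
    "OOVActionError",
    "load_codebook",
]


class OOVActionError(ValueError):
    """Raised when a token is not in the action vocabulary.

    Carries the offending text so ingest can log it with the exclusion.
    """

    def __init__(self, text: object):
        self.text = text
        super().__init__(f"out-of-vocabulary action token: {text!r}")


@functools.total_ordering
@dataclass(frozen=True)
class ActionCode:
    """One action category: token (``A0``..``A9``), rank, human label."""

    code: str
    rank: int
    label: str

    def __lt__(self, other: "ActionCode") -> bool:
        if not isinstance(other, ActionCode):
            return NotImplemented
        return self.rank < other.rank

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class ActionInterval:
    """Closed interval of acceptable actions, ``[min_action, max_action]``."""

    min_action: ActionCode
    max_action: ActionCode

    def __post_init__(self) -> None:
        if self.min_action.rank > self.max_action.rank:
            raise ValueError(
                f"interval minimum {self.min_action.code} ranks above "
                f"maximum {self.max_action.code}"
            )

    def contains(self, action: ActionCode) -> bool:
        """True iff ``rank(min) <= rank(action) <= rank(max)``."""
        return self.min_action.rank <= action.rank <= self.max_action.rank

    def issubset(self, other: "ActionInterval") -> bool:
        return (
            other.min_action.rank <= self.min_action.rank
            and self.max_action.rank <= other.max_action.rank
        )

    def __str__(self) -> str:
        return f"[{self.min_action.code},{self.max_action.code}]"


class Codebook:
    """The ordered action vocabulary, loaded from a data table."""

    def __init__(self, entries: list[ActionCode]):
        entries = sorted(entries, key=lambda a: a.rank)
        if [a.rank for a in entries] != list(range(len(entries))):
            raise ValueError("codebook ranks must be 0..n-1 with no gaps")
        if len({a.code for a in entries}) != len(entries):
            raise ValueError("codebook tokens must be unique")
        self._by_rank = entries
        self._by_code = {a.code: a for a in entries}

    def __len__(self) -> int:
        return len(self._by_rank)

    def __iter__(self) -> Iterator[ActionCode]:
        return iter(self._by_rank)

    def __getitem__(self, key: int | str) -> ActionCode:
        if isinstance(key, int):
            return self._by_rank[key]
        return self._by_code[key]

    def parse(self, text: object) -> ActionCode:
        """Parse an exact action token (surrounding whitespace tolerated).

        Matching is case-sensitive and token-exact: a payload saying
        "self-care" without the ``A1`` token is a vocabulary violation, per
        the prompt contract that demands the coded field.

        Raises
        ------
        OOVActionError
            If ``text`` is not a string or not an exact in-vocabulary token.
        """
        if not isinstance(text, str):
            raise OOVActionError(text)
        token = text.strip()
        try:
            return self._by_code[token]
        except KeyError:
            raise OOVActionError(text) from None

    def render(self, action: ActionCode) -> str:
        return action.code

    def interval(self, min_code: str, max_code: str) -> ActionInterval:
        return ActionInterval(self.parse(min_code), self.parse(max_code))

    def legend(self) -> str:
        """Code + label lines, in rank order (embedded in prompts)."""
        return "\n".join(f"{a.code}: {a.label}" for a in self._by_rank)


def load_codebook() -> Codebook:
    """Load the packaged ten-category action codebook."""
    text = resources.files("triageaudit.data").joinpath("codebook.json").read_text("utf-8")
    rows = json.loads(text)
    book = Codebook([ActionCode(r["code"], r["rank"], r["label"]) for r in rows])
    if len(book) != 10:
        raise ValueError("packaged codebook must contain exactly 10 actions")
    return book
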