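"""Operational reference policy: per-scenario acceptable action intervals.

A policy maps each scenario to a *hard* acceptable interval (the safety
tolerance band for the primary classification) and a *soft* interval (a
stricter subset used for sensitivity analysis).  Policies are pure data,
shipped and loaded as YAML, so auditors can inspect and swap the benchmark;
invalid files are rejected, never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .codebook import ActionInterval, Codebook, load_codebook

__all__ = [
    "PolicyEntry",
    "ReferencePolicy",
    "PolicyValidationError",
    "PolicyCoverageError",
    "PolicyLookupError",
    "load_policy",
]


class PolicyValidationError(ValueError):
    pass


class PolicyCoverageError(KeyError):
    """A scenario required by the audit has no policy entry."""


class PolicyLookupError(KeyError):
    pass


@dataclass(frozen=True)
class PolicyEntry:
    scenario_id: str
    hard: ActionInterval
    soft: ActionInterval

    def __post_init__(self) -> None:
        if not self.soft.issubset(self.hard):
            raise PolicyValidationError(
                f"{self.scenario_id}: soft interval {self.soft} is not a "
                f"subset of hard interval {self.hard}"
            )


class ReferencePolicy:
    """Immutable scenario_id → PolicyEntry map."""

    def __init__(self, entries: Iterable[PolicyEntry]):
        self._entries: dict[str, PolicyEntry] = {}
        for e in entries:
            if e.scenario_id in self._entries:
                raise PolicyValidationError(f"duplicate policy entry {e.scenario_id}")
            self._entries[e.scenario_id] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferencePolicy) and self._entries == other._entries

    @property
    def entries(self) -> Mapping[str, PolicyEntry]:
        return dict(self._entries)

    def entry_for(self, scenario_id: str) -> PolicyEntry:
        try:
            return self._entries[scenario_id]
        except KeyError:
            raise PolicyLookupError(scenario_id) from None

    def check_coverage(self, scenario_ids: Iterable[str]) -> None:
        missing = sorted(set(scenario_ids) - self._entries.keys())
        if missing:
            raise PolicyCoverageError(f"scenarios without a policy entry: {missing}")


def load_policy(path: str | Path | None = None, codebook: Codebook | None = None) -> ReferencePolicy:
    """Load a policy file (``path=None`` loads the packaged default).

    The file is a list of ``{scenario_id, hard: [min, max], soft: [min, max]}``
    mappings with actions as ``"A0".."A9"`` tokens.  Any violation of the
    interval invariants raises :class:`PolicyValidationError`.
    """
    codebook = codebook or load_codebook()
    if path is None:
        text = resources.files("triageaudit.data").joinpath("policy.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    doc = yaml.safe_load(text)
    rows = doc["entries"] if isinstance(doc, dict) else doc
    entries = []
    for row in rows:
        try:
            hard = codebook.interval(*row["hard"])
            soft = codebook.interval(*row["soft"])
        except (ValueError, KeyError, TypeError) as exc:
            raise PolicyValidationError(f"{row.get('scenario_id')}: {exc}") from exc
        entries.append(PolicyEntry(scenario_id=row["scenario_id"], hard=hard, soft=soft))
    return ReferencePolicy(entries)
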