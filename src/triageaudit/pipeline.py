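"""End-to-end audit orchestration.

``run_audit`` ties the stages together — cohort synthesis → policy load →
prompt rendering → response generation (simulated, or an external adapter)
→ ingest/validation → safety metrics → agreement — and writes a
reproducible report bundle: raw and validated JSONL, exclusion log, tidy
CSV tables, and a summary JSON echoing the configuration.  A configuration
(and its seed) fully determines a simulated audit: the same config yields a
byte-identical bundle.  No file carries timestamps.

Each stage also exists as a standalone function reading/writing files, so
externally produced responses (a real-API trace) can be dropped in between
the simulate and ingest stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import agreement as agreement_mod
from . import cohort, safety
from .ingest import ingest_all, tally_validity
from .codebook import load_codebook
from .policy import ReferencePolicy, load_policy
from .prompts import FORMULATIONS, render_prompt
from .responder import (
    BehaviorProfile,
    PlannedExecution,
    RawResponse,
    ResponderAdapter,
    SimulatedResponder,
    build_condition_matrix,
    ExecutionCondition,
    external_responses,
    load_profile,
    regime_by_name,
)

__all__ = ["AuditConfig", "AuditBundle", "run_audit", "render_report",
           "write_raw_jsonl", "read_raw_jsonl"]

log = logging.getLogger("triageaudit")

SUBGROUP_ATTRIBUTES = ("age_group", "health_literacy", "anxiety_tendency")


class AuditConfig(BaseModel):
    """Declarative audit configuration; fully determines a simulated run."""

    seed: int = 1
    profile: str = "calibrated"
    policy_path: str | None = None
    language: str = "ja"
    out_dir: str = "audit_out"
    runs_override: int | None = Field(default=None, ge=1)
    slice_filter: str | None = None
    make_plots: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AuditConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text("utf-8")) or {}))


@dataclass
class AuditBundle:
    config: AuditConfig
    personas: list
    vignettes: list
    slices: dict
    planned: list[PlannedExecution]
    raws: list[RawResponse]
    records: list
    validity: pd.DataFrame
    rates: pd.DataFrame
    distribution: pd.DataFrame
    agreement_pairs: pd.DataFrame
    agreement_summary: pd.DataFrame
    subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _condition_dict(c: ExecutionCondition) -> dict:
    return {
        "slice": c.slice_name,
        "formulation": c.formulation,
        "regime": c.regime.name,
        "temperature": c.regime.temperature,
        "top_p": c.regime.top_p,
        "schema_mode": c.schema_mode,
        "run_index": c.run_index,
    }


def _condition_from_dict(d: Mapping) -> ExecutionCondition:
    return ExecutionCondition(
        d["slice"], d["formulation"], regime_by_name(d["regime"]),
        d["schema_mode"], int(d["run_index"]),
    )


def write_raw_jsonl(raws: Sequence[RawResponse], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in raws:
            fh.write(json.dumps({
                **_condition_dict(r.condition),
                "persona_id": r.persona_id,
                "scenario_id": r.scenario_id,
                "pair_index": r.pair_index,
                "payload": r.payload,
            }, ensure_ascii=False, sort_keys=True) + "\n")


def read_raw_jsonl(path: str | Path) -> list[RawResponse]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            out.append(RawResponse(
                _condition_from_dict(d), d["persona_id"], d["scenario_id"],
                int(d["pair_index"]), d["payload"],
            ))
    return out


def _write_records_jsonl(records, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            row = {
                **_condition_dict(r.condition),
                "persona_id": r.persona_id,
                "scenario_id": r.scenario_id,
                "pair_index": r.pair_index,
                "status": "valid" if r.valid else "excluded",
                "exclusion_reason": r.exclusion_reason,
            }
            if r.valid:
                row.update(
                    action_primary=r.output.action_primary.code,
                    action_time=r.output.action_time,
                    reason_tags=list(r.output.reason_tags),
                    confidence=r.output.confidence,
                    escalation_if_worse=r.output.escalation_if_worse.code,
                )
            fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")


def run_audit(
    config: AuditConfig,
    adapter: ResponderAdapter | None = None,
    profile: BehaviorProfile | None = None,
    write: bool = True,
) -> AuditBundle:
    """Execute the full audit per ``config`` and return the report bundle.

    With ``adapter=None`` the synthetic responder generates all outputs;
    passing an adapter routes every planned execution through it instead.
    ``write=False`` keeps everything in memory (used by tests).
    """
    codebook = load_codebook()
    log.info("stage synthesize: seed=%s", config.seed)
    personas = cohort.build_persona_bank(config.seed)
    vignettes = cohort.build_vignette_bank(config.seed)
    slices = cohort.build_slices(personas, vignettes, config.seed)

    policy = load_policy(config.policy_path, codebook)
    for sl in slices.values():
        policy.check_coverage(sl.scenario_ids())

    planned = build_condition_matrix(slices, config.runs_override)
    if config.slice_filter:
        planned = [p for p in planned if p.condition.slice_name == config.slice_filter]
    log.info("stage matrix: %d planned executions", len(planned))

    if adapter is None:
        prof = profile or load_profile(config.profile)
        responder = SimulatedResponder(prof, config.seed)
        raws = responder.run_matrix(planned)
    else:
        vmap = {v.scenario_id: v for v in vignettes}
        pmap = {p.persona_id: p for p in personas}
        prompts = {}
        for p in planned:
            key = (p.persona_id, p.scenario_id, p.condition.formulation)
            if key not in prompts:
                prompts[key] = render_prompt(
                    pmap[p.persona_id], vmap[p.scenario_id],
                    p.condition.formulation, config.language, codebook,
                )
        raws = external_responses(planned, prompts, adapter)
    log.info("stage respond: %d raw responses", len(raws))

    records = ingest_all(raws, codebook)
    validity = tally_validity(records)
    log.info("stage ingest: %s", validity.to_dict("records")[-1])

    rates = safety.aggregate_rates(records, policy)
    distribution = safety.action_distribution(records)
    pair_table, summary_table = agreement_mod.slice_agreement(records)
    subgroups = {
        attr: safety.pooled_stratified_rates(records, policy, personas, attr, "redflag24")
        for attr in SUBGROUP_ATTRIBUTES
    }

    overall = validity[validity["slice"] == "overall"].iloc[0]
    summary = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "planned": int(overall["planned"]),
        "valid": int(overall["valid"]),
        "excluded": int(overall["excluded"]),
        "per_slice": validity[validity["slice"] != "overall"].to_dict("records"),
    }

    bundle = AuditBundle(
        config=config, personas=personas, vignettes=vignettes, slices=slices,
        planned=planned, raws=raws, records=records, validity=validity,
        rates=rates, distribution=distribution,
        agreement_pairs=pair_table, agreement_summary=summary_table,
        subgroups=subgroups, summary=summary,
    )
    if write:
        _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: AuditBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.dump_bank(bundle.personas, out / "personas.json")
    cohort.dump_bank(bundle.vignettes, out / "vignettes.json")
    cohort.dump_bank(list(bundle.slices.values()), out / "slices.json")
    write_raw_jsonl(bundle.raws, out / "raw_responses.jsonl")
    _write_records_jsonl(bundle.records, out / "records.jsonl")
    exclusions = pd.DataFrame(
        [{
            "slice": r.condition.slice_name, "formulation": r.condition.formulation,
            "regime": r.condition.regime.name, "schema_mode": r.condition.schema_mode,
            "run_index": r.condition.run_index, "persona_id": r.persona_id,
            "scenario_id": r.scenario_id, "reason": r.exclusion_reason,
            "detail": r.exclusion_detail,
        } for r in bundle.records if not r.valid],
        columns=["slice", "formulation", "regime", "schema_mode", "run_index",
                 "persona_id", "scenario_id", "reason", "detail"],
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)
    bundle.validity.to_csv(out / "validity.csv", index=False)
    bundle.rates.to_csv(out / "safety_rates.csv", index=False)
    bundle.distribution.to_csv(out / "action_distribution.csv", index=False)
    bundle.agreement_pairs.to_csv(out / "agreement_pairs.csv", index=False)
    bundle.agreement_summary.to_csv(out / "agreement_summary.csv", index=False)
    for attr, frame in bundle.subgroups.items():
        frame.to_csv(out / f"subgroup_redflag_by_{attr}.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.summary, fh, ensure_ascii=False, sort_keys=True, indent=1)
        fh.write("\n")
    if bundle.config.make_plots:
        _write_plots(bundle, out)
    bundle.out_dir = out


REPORT_ARTIFACTS = ("validity", "rates", "distribution", "agreement_summary")


def render_report(bundle: AuditBundle) -> str:
    """Human-readable per-slice safety, distribution and agreement tables."""
    missing = [a for a in REPORT_ARTIFACTS if getattr(bundle, a, None) is None]
    if missing:
        raise ValueError(f"incomplete bundle, missing artifacts: {missing}")
    sections = [
        ("Validity (planned / valid / excluded)", bundle.validity),
        ("Safety rates by slice and condition", bundle.rates),
        ("Primary-action distribution", bundle.distribution),
        ("Run-to-run modal agreement", bundle.agreement_summary),
    ]
    esc = bundle.rates[bundle.rates["label"].isin(
        ["escalation_monotone", "escalation_below_hard_min"])]
    sections.append(("Escalation quality", esc))
    parts = []
    for title, frame in sections:
        parts.append(f"== {title} ==")
        parts.append(frame.to_string(index=False) if len(frame) else "(empty)")
        parts.append("")
    return "\n".join(parts)


def _write_plots(bundle: AuditBundle, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hard = bundle.rates[bundle.rates["label"] == "hard_under"]
    if len(hard):
        fig, ax = plt.subplots(figsize=(9, 4))
        labels = hard.apply(
            lambda r: f"{r['slice']}\n{r['formulation']}/{r['regime'][:6]}/{r['schema_mode'][:6]}",
            axis=1,
        )
        ax.bar(range(len(hard)), hard["percentage"])
        ax.set_xticks(range(len(hard)), labels, fontsize=6, rotation=90)
        ax.set_ylabel("hard under-triage (%)")
        fig.tight_layout()
        fig.savefig(out / "hard_under_triage.png", dpi=120)
        plt.close(fig)
    agr = bundle.agreement_summary.dropna(subset=["mean_agreement"])
    if len(agr):
        fig, ax = plt.subplots(figsize=(9, 4))
        labels = agr.apply(
            lambda r: f"{r['slice']}\n{r['formulation']}/{r['regime'][:6]}/{r['schema_mode'][:6]}",
            axis=1,
        )
        ax.bar(range(len(agr)), agr["mean_agreement"])
        ax.set_xticks(range(len(agr)), labels, fontsize=6, rotation=90)
        ax.set_ylabel("modal agreement")
        fig.tight_layout()
        fig.savefig(out / "modal_agreement.png", dpi=120)
        plt.close(fig)
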