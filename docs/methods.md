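# Methods

## Audit design

`triageaudit` is a harness for measuring whether a patient-facing
responder converts symptom presentations into acceptable *next-step
actions*. The unit of analysis is one generation: a (persona, scenario)
pair executed under one condition (prompt formulation × decoding regime ×
schema mode × run index), in per-item isolation — no context is shared
between generations.

Three fixed slices of 24 persona-scenario pairs each define the case mix:

| slice | scenarios | pairs | hard range | soft range | conditions per formulation |
|---|---|---|---|---|---|
| `sev1_24` | 12 mild (severity 1) | 2 each | A0–A7 | A0–A3 | 5 near-det + 5 stochastic (prompt-only) |
| `nonredflag24` | 12 intermediate (severity 2) | 2 each | A0–A7 | A1–A7 | 10 near-det + 15 stochastic + 5 schema |
| `redflag24` | 6 urgent red-flag (severity 3) | 4 each | A8–A9 (one scenario A6–A9) | = hard | same as `nonredflag24` |

With two formulations this gives 480 + 1,440 + 1,440 = 3,360 planned
generations. The full matrix runs in a few seconds, so no reduced problem
size is needed outside the `--smoke` mode (1 run per condition class),
which exists for quick iteration.

## Synthetic cohort

The persona bank holds 60 personas over nine attributes (age band, care
access, household, financial constraint, chronic condition, health
literacy, trust in medicine, regular doctor, anxiety tendency). Each
attribute column is the attribute's vocabulary cycled to length 60 and
then shuffled with a seeded generator: every level is guaranteed present
and near-balanced, while cross-attribute combinations vary with the seed.

The vignette bank is 30 scenarios, 3 per symptom category across ten
categories (fever, respiratory, pain, gastrointestinal, urinary, allergy,
dental, mental distress, injury, chronic flare-up). Category, severity,
red-flag status, scenario ids and body text are fixed archetype data; the
seed fills only the duration/time-context metadata slots. Six scenarios
are red-flag (always severity 3), including the three urgent archetypes
with fixed ids: sudden severe headache worsening with movement (S008),
facial/lip swelling with throat discomfort (S018), and ongoing bleeding
difficult to stop (S027). Vignette prose is template-generated Japanese
with an English mirror; it aims at plausible shape, not clinical realism,
and the audit math never inspects it.

How the 24 personas of a slice are drawn from the 60 is an open design
point; we use stratified round-robin selection over health-literacy groups
from a seeded shuffle, with a deterministic repair pass guaranteeing all
three anxiety levels, so the subgroup analysis is well-defined on every
slice. Slice membership implies severity: the bank's severity metadata is
the single source of slice eligibility.

## Reference policy

The policy is an editable YAML table mapping each scenario to hard and
soft acceptable intervals (soft ⊆ hard is enforced on load; violations are
rejected, never repaired). It is an operational benchmark, not adjudicated
clinical ground truth — the point of shipping it as data is that auditors
can swap it. In the packaged default, five red-flag scenarios require
A8–A9; the mental-distress crisis scenario (S024) allows A6–A9, because a
medical/crisis hotline is a defensible immediate action for an acute
psychological emergency and it is the least time-critical of the six
urgent archetypes. This assignment is a package decision, documented here
and in the policy file itself.

## Prompts

Both formulations share one instruction block containing the layperson
role constraint, the no-diagnosis constraint, the full codebook legend
(code + label), and the five required field names
(`action_primary, action_time, reason_tags, confidence,
escalation_if_worse`). P1 renders the persona as a single narrative
sentence of attribute phrases; P2 renders the same phrases as key-value
lines — information parity is a tested invariant. P2's structured scenario
block carries id, category, duration and time context but deliberately
*not* the severity/red-flag metadata, which would leak the reference
classification to the responder. The JSON schema text itself is not
embedded; the field list is.

## Synthetic responder

The shipped responder is a seeded simulator over a behavior profile
(packaged YAML); a real LLM is attached by implementing
`ResponderAdapter.respond(prompt_text, temperature, top_p, schema_mode)`.
Decoding semantics are our operationalization of temperature:

- **near-deterministic** (0.0 / 1.0): the arg-max of every profile
  distribution, so a point-mass profile yields modal agreement exactly
  1.00 (a tested closed-form limit);
- **stochastic** (1.0 / 0.95): categorical sampling from the profile;
- **response_schema**: the action distribution is sharpened
  (p → p² renormalized) and malformed output is impossible, mirroring the
  formatting guarantees of schema-constrained decoding. Schema runs occur
  only under stochastic decoding, matching the executed design.

Each generation draws from an independent seeded stream keyed by
(master seed, cell index in the canonical matrix), so reruns are
byte-identical and results do not depend on execution order.

### The default ("calibrated") profile

The default profile is calibration data emulating the audited behavior
pattern: low-acuity mass (A0–A3, plus A7 in the intermediate slice) in the
low-risk slices, and — the central failure mode — the same low-acuity
concentration with modal action A1 in the urgent slice. Three mechanisms
sit on top of the base distributions:

- **Explicit overrides** designate single outputs (by slice, formulation,
  regime, pair, run): one compliant A8 among the 360 red-flag P2
  stochastic prompt-only outputs (hence 359/360 = 99.7% hard under-triage
  there), six A7 outputs among 120 mild P1 stochastic outputs (5.0%
  soft over-triage; two for P2, 1.7%), and three A0 outputs among 360
  intermediate P1 stochastic outputs (0.8% soft under-triage).
- **Designated invalid injections**: 18 malformed/missing payloads
  (non-JSON prose, truncation, concatenated objects, missing field,
  out-of-vocabulary action, out-of-range confidence, empty), all placed in
  the red-flag P1 stochastic prompt-only arm, giving 1,422 valid red-flag
  outputs and 3,342 valid overall. Placement within the red-flag slice is
  fixed by the published validity arithmetic; the choice of arm within the
  slice is ours.
- **Near-deterministic minority patterns**: real audited runs are only
  *near* deterministic, so designated pairs flip their last few runs to a
  second action. The patterns are chosen so the per-slice means of the
  per-pair modal fractions are exact by construction, e.g. red-flag P1:
  18 unanimous pairs + 2 pairs at 9/10 + 4 at 5/10 → 218/240 = 0.9083 →
  0.91.

The stochastic base distributions were calibrated analytically: the
expected per-pair modal fraction E[max multinomial count]/R was evaluated
by simulation over candidate distributions, and the shipped values sit
within ~0.01 of the targeted agreement levels (mild 0.53/0.60 at R=5;
intermediate 0.44/0.48 and red-flag 0.44/0.46 at R=15). Realized values
vary by roughly ±0.05 across seeds.

Escalation is modeled as primary + a non-negative (rarely −1) rank offset,
clipped to [A0, A9]: monotonicity is high everywhere, while red-flag
escalations (mostly +2…+5 from A1) usually stay below the A8 hard minimum
— and stay below it more often under the schema arm, whose offset
distribution is tighter. Timing mass sits on `T_now` for red-flag
scenarios and on routine tokens for mild ones; the four-level ordinal
timing vocabulary (`T_now, T_today, T_within_days, T_routine`) is a
package choice.

## Validation and exclusion

A payload must be exactly one JSON object with all five fields; checks run
in a fixed order and the first failure is the recorded reason: `missing` →
`parse_failure` → `schema_violation` → `oov_action` →
`out_of_range_confidence`. Action tokens are matched exactly
(case-sensitive, trimmed); `reason_tags` is any list of strings (empty
allowed); extra fields are tolerated and logged, since schema-constrained
APIs commonly attach metadata. Out-of-range confidence is excluded under
its own distinct reason so either convention (exclude or keep) can be
recovered from the logs. Failures never raise: every planned execution
yields exactly one record, and valid + excluded = planned is a tested
conservation law.

## Metrics numerics

- Percentages: rounded half-away-from-zero to one decimal (via `Decimal`);
  agreement means to two decimals, with the unrounded value retained.
- Denominators: valid records only. Strata with zero valid records
  produce no rows (empty, not 0%).
- Agreement: pairs with fewer than two valid runs are excluded from the
  slice mean and counted; groups with no qualifying pair report a null
  mean. Ties over the maximal count leave the fraction unchanged; the
  companion modal-action column reports the lowest-rank tied action and
  flags the tie. Near-deterministic and stochastic runs are never pooled.
- Subgroup (red-flag) rates pool all valid outputs of the slice per
  stratum of one persona attribute, rather than stratifying within each
  condition — the pooled view is the headline; per-condition stratified
  tables are also available.

## What the synthetic audit does and does not show

Passing tests demonstrate that the *measurement machinery* is correct:
matrix arithmetic, exclusion accounting, interval classification,
rounding, aggregation and agreement all reproduce design-determined values
exactly, and the calibrated profile shows the harness reproduces the
reported safety pattern when the responder behaves as profiled. They say
nothing about any real model's safety: the simulator has no language
understanding, its vignette text is never read, and its behavior is
whatever the profile encodes. Auditing a real system requires the adapter
route and a clinically reviewed policy file.

## Known limitations

- Single-turn, isolated requests only; no dialogue or clarification.
- The reference policy is operational, not clinician-adjudicated; the
  A6–A9 scenario assignment is a package convention.
- Vignette and persona realism is template-level; no free-text NLP.
- No chance-corrected agreement (raw modal agreement only) and no
  significance testing: the harness reports absolute rates and agreement,
  by design.
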