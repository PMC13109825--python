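# Operational reference policy: per-scenario hard and soft acceptable action
# intervals over the A0..A9 codebook.
#
# The hard interval is the safety tolerance band used for the primary
# under-/over-triage classification; the soft interval is a stricter subset
# used for sensitivity analysis.  This file is a transparent operational
# benchmark, not clinical ground truth: auditors are expected to edit or
# swap it.
#
# Conventions in this default:
#   severity-1 scenarios:  hard A0-A7, soft A0-A3
#   severity-2 scenarios:  hard A0-A7, soft A1-A7
#   red-flag scenarios:    hard A8-A9 (soft = hard), except S024 below
#
# S024 (acute mental-distress crisis) is the one red-flag scenario whose
# hard minimum is A6 rather than A8: a medical/crisis hotline is a
# defensible immediate action for an acute psychological emergency, making
# it the least time-critical of the six urgent archetypes.
entries:
  # --- severity 1 (mild, non-red-flag) ---
  - {scenario_id: S001, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S002, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S004, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S007, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S010, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S013, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S016, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S019, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S020, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S022, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S025, hard: [A0, A7], soft: [A0, A3]}
  - {scenario_id: S028, hard: [A0, A7], soft: [A0, A3]}
  # --- severity 2 (intermediate, non-red-flag) ---
  - {scenario_id: S003, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S005, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S009, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S011, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S014, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S015, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S017, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S021, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S023, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S026, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S029, hard: [A0, A7], soft: [A1, A7]}
  - {scenario_id: S030, hard: [A0, A7], soft: [A1, A7]}
  # --- red-flag (urgent; soft = hard) ---
  - {scenario_id: S006, hard: [A8, A9], soft: [A8, A9]}
  - {scenario_id: S008, hard: [A8, A9], soft: [A8, A9]}
  - {scenario_id: S012, hard: [A8, A9], soft: [A8, A9]}
  - {scenario_id: S018, hard: [A8, A9], soft: [A8, A9]}
  - {scenario_id: S024, hard: [A6, A9], soft: [A6, A9]}
  - {scenario_id: S027, hard: [A8, A9], soft: [A8, A9]}
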