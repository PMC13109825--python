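# Finite vocabularies for the synthetic persona attributes.  The attribute
# dimensions are fixed by the audit design; the levels below are the
# packaged defaults and can be swapped for an alternative vocabulary file.
age_group: ["18-29", "30-49", "50-64", "65-79", "80+"]
region_access: ["urban_good_access", "suburban_moderate_access", "rural_limited_access"]
household: ["living_alone", "couple", "family_with_children", "multigenerational"]
financial_constraint: ["low", "mid", "high"]
chronic_condition: [false, true]
health_literacy: ["low", "mid", "high"]
trust_in_medicine: ["low", "mid", "high"]
regular_doctor: [false, true]
anxiety_tendency: ["low", "mid", "high"]

# Vignette free-slot vocabularies (metadata only; the audit math never
# inspects these).
duration: ["a_few_hours", "since_yesterday", "several_days", "over_a_week"]
time_context: ["weekday_daytime", "weekday_night", "weekend", "public_holiday"]
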