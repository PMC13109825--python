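# Prompt templates and persona attribute phrase maps.
#
# The audit's default language is Japanese (the intended use case is
# Japanese-language lay self-triage); the English templates are a mirror for
# documentation and debugging.  The downstream audit math never inspects the
# rendered text, only the structured responses.
#
# Both formulations (P1 narrative, P2 structured) share the same instruction
# block; they differ only in how the persona and scenario are presented.
ja:
  instruction: |-
    あなたは医療従事者ではなく、一般の生活者として答えてください。診断名を挙げたり治療の助言をしたりしないでください。
    以下の行動コード一覧から、自分が次にとる行動として最も近いものを1つ選んでください。
    {legend}
    回答は、次の5つのフィールドを持つ単一のJSONオブジェクトのみで返してください: {fields}
    action_primary と escalation_if_worse には行動コード(A0〜A9)を入れてください。
    action_time には T_now / T_today / T_within_days / T_routine のいずれかを入れてください。
    confidence には 0 から 1 の数値を入れてください。
    reason_tags には理由を表す短い語のリストを入れてください。
  persona_narrative: "あなたは{phrases}という人物です。"
  scenario_narrative: "今のあなたの状況: {text}"
  phrase_join: "、"
  phrases:
    age_group:
      "18-29": "18〜29歳"
      "30-49": "30〜49歳"
      "50-64": "50〜64歳"
      "65-79": "65〜79歳"
      "80+": "80歳以上"
    region_access:
      urban_good_access: "都市部に住み医療機関を受診しやすい"
      suburban_moderate_access: "郊外に住み受診はある程度可能"
      rural_limited_access: "地方在住で医療機関へのアクセスが限られている"
    household:
      living_alone: "一人暮らし"
      couple: "夫婦二人暮らし"
      family_with_children: "子どもと同居している"
      multigenerational: "三世代で同居している"
    financial_constraint:
      low: "家計に余裕がある"
      mid: "家計はやや厳しい"
      high: "家計が苦しい"
    chronic_condition:
      false: "持病はない"
      true: "持病がある"
    health_literacy:
      low: "健康情報にあまり詳しくない"
      mid: "健康情報をある程度理解できる"
      high: "健康情報に詳しい"
    trust_in_medicine:
      low: "医療への信頼は低め"
      mid: "医療への信頼はふつう"
      high: "医療を信頼している"
    regular_doctor:
      false: "かかりつけ医はいない"
      true: "かかりつけ医がいる"
    anxiety_tendency:
      low: "あまり心配性ではない"
      mid: "ときどき不安になりやすい"
      high: "とても心配性"
en:
  instruction: |-
    Answer as an ordinary layperson, not as a healthcare professional. Do not name diagnoses or give treatment advice.
    From the action codebook below, choose the single action closest to what you would do next.
    {legend}
    Reply with exactly one JSON object containing these five fields: {fields}
    Put an action code (A0-A9) in action_primary and escalation_if_worse.
    Put one of T_now / T_today / T_within_days / T_routine in action_time.
    Put a number between 0 and 1 in confidence.
    Put a list of short reason words in reason_tags.
  persona_narrative: "You are a person who is {phrases}."
  scenario_narrative: "Your current situation: {text}"
  phrase_join: ", "
  phrases:
    age_group:
      "18-29": "aged 18-29"
      "30-49": "aged 30-49"
      "50-64": "aged 50-64"
      "65-79": "aged 65-79"
      "80+": "aged 80 or over"
    region_access:
      urban_good_access: "living in a city with easy access to care"
      suburban_moderate_access: "living in the suburbs with moderate access to care"
      rural_limited_access: "living rurally with limited access to care"
    household:
      living_alone: "living alone"
      couple: "living as a couple"
      family_with_children: "living with children"
      multigenerational: "living in a multigenerational household"
    financial_constraint:
      low: "financially comfortable"
      mid: "somewhat financially constrained"
      high: "under heavy financial constraint"
    chronic_condition:
      false: "without a chronic condition"
      true: "living with a chronic condition"
    health_literacy:
      low: "not very familiar with health information"
      mid: "moderately familiar with health information"
      high: "very familiar with health information"
    trust_in_medicine:
      low: "with low trust in medicine"
      mid: "with average trust in medicine"
      high: "with high trust in medicine"
    regular_doctor:
      false: "without a regular doctor"
      true: "with a regular doctor"
    anxiety_tendency:
      low: "not prone to worry"
      mid: "sometimes prone to worry"
      high: "very prone to worry"
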