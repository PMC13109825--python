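[
  {"scenario_id": "S001", "category": "fever", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、37度台前半の微熱が続いているが、食欲はあり普段どおり過ごせている。",
   "text_en": "A low-grade fever in the low 37s has persisted {duration}, but appetite is intact and daily life continues as usual."},
  {"scenario_id": "S002", "category": "fever", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、軽い発熱と倦怠感があるが、水分は十分にとれている。",
   "text_en": "Mild fever and fatigue {duration}; fluid intake remains adequate."},
  {"scenario_id": "S003", "category": "fever", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、38度台の発熱が下がらず、解熱剤を飲んでも数時間で戻ってしまう。",
   "text_en": "A fever in the 38s has not broken {duration}; antipyretics bring it down only for a few hours."},
  {"scenario_id": "S004", "category": "respiratory", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、軽い咳と鼻水があるが、呼吸は楽で夜も眠れている。",
   "text_en": "A light cough and runny nose {duration}; breathing is easy and sleep is undisturbed."},
  {"scenario_id": "S005", "category": "respiratory", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、咳き込みが強くなり、階段を上ると息切れを感じるようになった。",
   "text_en": "Coughing fits have worsened {duration}, with breathlessness now noticeable when climbing stairs."},
  {"scenario_id": "S006", "category": "respiratory", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、安静にしていても息が苦しく、短い文章を話すのもつらい。唇の色が悪いと家族に言われた。",
   "text_en": "Breathing has been difficult even at rest {duration}; speaking a short sentence is a struggle and family noticed bluish lips."},
  {"scenario_id": "S007", "category": "pain", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、肩から首にかけて軽い張りと痛みがあるが、動かせないほどではない。",
   "text_en": "Mild tightness and pain from the shoulder to the neck {duration}, without loss of movement."},
  {"scenario_id": "S008", "category": "pain", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、突然これまでに経験したことのない激しい頭痛が起こり、頭を動かすと痛みがさらに悪化する。",
   "text_en": "A sudden, unprecedented severe headache began {duration}, and the pain worsens with any head movement."},
  {"scenario_id": "S009", "category": "pain", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、腰の痛みが強まり、市販の湿布ではほとんど楽にならない。",
   "text_en": "Lower-back pain has intensified {duration}; over-the-counter patches give little relief."},
  {"scenario_id": "S010", "category": "gastrointestinal", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、軽い胃のむかつきと食欲低下があるが、嘔吐や下痢はない。",
   "text_en": "Mild stomach upset and reduced appetite {duration}, without vomiting or diarrhea."},
  {"scenario_id": "S011", "category": "gastrointestinal", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、水様の下痢が繰り返し続き、食事をとるとすぐに腹痛が起こる。",
   "text_en": "Repeated watery diarrhea {duration}; eating promptly triggers abdominal pain."},
  {"scenario_id": "S012", "category": "gastrointestinal", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、繰り返し嘔吐し、吐いたものに血が混じっているのに気づいた。立ち上がるとふらつく。",
   "text_en": "Repeated vomiting {duration} with blood noticed in the vomit; standing up brings dizziness."},
  {"scenario_id": "S013", "category": "urinary", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、排尿時に軽い違和感があるが、発熱や腰の痛みはない。",
   "text_en": "Slight discomfort on urination {duration}, with no fever or flank pain."},
  {"scenario_id": "S014", "category": "urinary", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、排尿時の痛みが強まり、トイレが近くなって残尿感も続いている。",
   "text_en": "Painful urination has worsened {duration}, with frequency and a persistent feeling of incomplete emptying."},
  {"scenario_id": "S015", "category": "urinary", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、尿の色が濃く濁っており、下腹部の鈍い痛みが続いている。",
   "text_en": "Urine has been dark and cloudy {duration}, with a dull lower abdominal ache."},
  {"scenario_id": "S016", "category": "allergy", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、腕に軽いかゆみのある発疹が出ているが、広がってはいない。",
   "text_en": "A mildly itchy rash on the arm {duration}, without spreading."},
  {"scenario_id": "S017", "category": "allergy", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、じんましんが体のあちこちに広がり、かゆみで夜眠りにくい。",
   "text_en": "Hives have spread over the body {duration}; itching disturbs sleep."},
  {"scenario_id": "S018", "category": "allergy", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、顔と唇が腫れてきて、のどの違和感と圧迫感が強まっている。",
   "text_en": "The face and lips have been swelling {duration}, with growing throat discomfort and tightness."},
  {"scenario_id": "S019", "category": "dental", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、冷たいものを口にすると奥歯が少ししみる。",
   "text_en": "A back tooth is slightly sensitive to cold {duration}."},
  {"scenario_id": "S020", "category": "dental", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、歯ぐきから歯みがきのときに少量の出血があるが、痛みはほとんどない。",
   "text_en": "Minor gum bleeding when brushing {duration}, with little pain."},
  {"scenario_id": "S021", "category": "dental", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、奥歯のズキズキする痛みが続き、頬が少し腫れてきた。",
   "text_en": "Throbbing pain in a back tooth {duration}, and the cheek has begun to swell."},
  {"scenario_id": "S022", "category": "mental_distress", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、仕事のことが頭から離れず寝つきが悪いが、日常生活は送れている。",
   "text_en": "Work worries have disturbed falling asleep {duration}, though daily life continues."},
  {"scenario_id": "S023", "category": "mental_distress", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、気分の落ち込みと食欲低下が続き、好きだったことにも興味がわかない。",
   "text_en": "Low mood and poor appetite {duration}, with loss of interest in previously enjoyed activities."},
  {"scenario_id": "S024", "category": "mental_distress", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、強い絶望感に襲われ、自分を傷つけたい考えが繰り返し浮かんで振り払えない。",
   "text_en": "Overwhelming hopelessness {duration}, with recurrent thoughts of self-harm that cannot be pushed away."},
  {"scenario_id": "S025", "category": "injury", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、足首を軽くひねり、少し腫れているが体重はかけられる。",
   "text_en": "A lightly twisted ankle {duration}; slight swelling but weight-bearing is possible."},
  {"scenario_id": "S026", "category": "injury", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、転んで手首を打ち、腫れと痛みで物を持つのがつらい。",
   "text_en": "A fall onto the wrist {duration}; swelling and pain make gripping difficult."},
  {"scenario_id": "S027", "category": "injury", "severity": 3, "red_flag": true,
   "text_ja": "{duration}、切り傷からの出血が続いており、強く押さえてもなかなか止まらない。",
   "text_en": "Bleeding from a cut has continued {duration} and is difficult to stop even with firm pressure."},
  {"scenario_id": "S028", "category": "chronic_flare", "severity": 1, "red_flag": false,
   "text_ja": "{duration}、持病の症状がいつもよりわずかに強いが、普段の薬でおおむね落ち着いている。",
   "text_en": "A chronic condition has been slightly more symptomatic {duration}, but largely settles with the usual medication."},
  {"scenario_id": "S029", "category": "chronic_flare", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、持病の症状が明らかに悪化し、いつもの薬では抑えきれなくなってきた。",
   "text_en": "A chronic condition has clearly worsened {duration}; the usual medication no longer controls it."},
  {"scenario_id": "S030", "category": "chronic_flare", "severity": 2, "red_flag": false,
   "text_ja": "{duration}、持病の数値が自己測定で普段より悪く、体のだるさも続いている。",
   "text_en": "Self-measured readings for a chronic condition have been worse than usual {duration}, with persistent fatigue."}
]
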