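{
  "feel_fat": ["Exposure", "Imaginal exposure", "Mindfulness"],
  "fear_weight": ["Imaginal exposure"],
  "worth_weight": ["CBT-E cognitive techniques", "Mindfulness-based acceptance techniques"],
  "skip_meals_urge": ["CBT-E self-monitoring"],
  "food_rules_restrict": ["CBT-E behavioral experiments"],
  "restrict_food_urge": ["CBT-E self-monitoring"],
  "mirror_checking": ["CBT-E cognitive strategies", "Mindfulness-based acceptance techniques"],
  "desire_live": ["DBT skills, such as Accumulating Positive Emotions", "Behavioral Activation"],
  "fear_death": ["Means safety", "Safety planning"],
  "reasons_die": ["Reasons for living"],
  "passive_ideation_1": ["DBT skills", "Behavioral Activation"]
}
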