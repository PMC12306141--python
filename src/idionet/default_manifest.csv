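item_id,label,prompt,community
feel_fat,Feel fat,I feel fat,ED
fear_weight,Fear weight,I am terrified of gaining weight,ED
worth_weight,Worth weight,My worth as a person (how I think about myself) is influenced by my weight and/or shape,ED
skip_meals_urge,Skip meals urge,I had the urge to skip meals (whether or not I actually skipped meals),ED
food_rules_restrict,Food rules restrict,I have tried to follow definite rules regarding eating in order to influence my shape or weight,ED
restrict_food_urge,Restrict food urge,I had the urge to restrict my food intake (whether or not I actually restricted my food intake),ED
mirror_checking,Mirror checking,"I checked my appearance (e.g., in the mirror, on my phone, in a picture)",ED
desire_live,Desire live,How strong is your desire to live?,SUI
fear_death,Fear of death,I am afraid to die,SUI
reasons_die,Reasons to die,There are more reasons to die than to live,SUI
passive_ideation_1,Passive ideation 1,Life is not worth living to me,SUI
problem_solving,Problem solving,I thought that suicide could be a way to solve the problem I was facing,SUI
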