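{
  "declared_fields": ["first_name"],
  "fallbacks": {"first_name": "participant"},
  "blocks": [
    {"slot": "welcome", "tailored": false,
     "objective": "Greet the participant and orient them to the newsletter",
     "body": "Dear {{first_name}}, welcome to your personalised activity newsletter."},
    {"slot": "expert_advice", "tailored": false,
     "constructs": ["observational learning"],
     "objective": "Credible role-model advice from an exercise physiologist",
     "body": "Our exercise physiologist recommends building activity up gradually and mixing aerobic sessions with simple resistance exercises."},

    {"slot": "behaviour_feedback", "code": 1, "tailored": true,
     "constructs": ["behavioural capability"],
     "objective": "Not meeting guideline, little limitation, activity unchanged since diagnosis",
     "body": "You are not yet reaching the recommended 150 weighted minutes over 5 sessions a week. Your health allows more activity, and your level has stayed the same since diagnosis - a few extra sessions would get you there."},
    {"slot": "behaviour_feedback", "code": 2, "tailored": true,
     "constructs": ["behavioural capability", "self-efficacy"],
     "objective": "Not meeting guideline, little limitation, doing more since diagnosis",
     "body": "You are doing more than before your diagnosis - keep that momentum. You are still short of the guideline, so try adding one more session this week."},
    {"slot": "behaviour_feedback", "code": 3, "tailored": true,
     "constructs": ["behavioural capability", "self-efficacy"],
     "objective": "Not meeting guideline, little limitation, doing less since diagnosis",
     "body": "Many survivors do less activity after treatment. Your health permits a gradual return - start with short moderate sessions and build back up."},
    {"slot": "behaviour_feedback", "code": 4, "tailored": true,
     "constructs": ["behavioural capability"],
     "objective": "Not meeting guideline, marked limitation, activity unchanged",
     "body": "Your physical health limits how much activity you can do. Gentle, regular movement within your limits still counts towards your health."},
    {"slot": "behaviour_feedback", "code": 5, "tailored": true,
     "constructs": ["behavioural capability", "self-efficacy"],
     "objective": "Not meeting guideline, marked limitation, doing more",
     "body": "Despite real physical limitations you are doing more than before - that is a genuine achievement. Keep sessions gentle and regular."},
    {"slot": "behaviour_feedback", "code": 6, "tailored": true,
     "constructs": ["behavioural capability", "expectations"],
     "objective": "Not meeting guideline, marked limitation, doing less",
     "body": "When health limits activity it is easy to stop altogether. Even small amounts of gentle movement can reduce fatigue and help you feel better."},
    {"slot": "behaviour_feedback", "code": 7, "tailored": true,
     "constructs": ["behavioural capability", "self-control"],
     "objective": "Meeting guideline, little limitation, activity unchanged",
     "body": "Well done - you are meeting the aerobic activity guideline. Keeping your routine steady is the best way to hold on to these benefits."},
    {"slot": "behaviour_feedback", "code": 8, "tailored": true,
     "constructs": ["self-efficacy", "self-control"],
     "objective": "Meeting guideline, little limitation, doing more",
     "body": "Excellent - you are meeting the guideline and doing more than before your diagnosis. Consider setting yourself a new challenge to stay motivated."},
    {"slot": "behaviour_feedback", "code": 9, "tailored": true,
     "constructs": ["self-control"],
     "objective": "Meeting guideline, little limitation, doing less",
     "body": "You are meeting the guideline even though you do less than before diagnosis. Protect your current routine so it does not slip further."},
    {"slot": "behaviour_feedback", "code": 10, "tailored": true,
     "constructs": ["self-efficacy"],
     "objective": "Meeting guideline despite marked limitation, unchanged",
     "body": "You are meeting the guideline despite health limitations - an impressive, steady effort. Keep listening to your body."},
    {"slot": "behaviour_feedback", "code": 11, "tailored": true,
     "constructs": ["self-efficacy"],
     "objective": "Meeting guideline despite marked limitation, doing more",
     "body": "Meeting the guideline and doing more than before, despite limitations - outstanding. Make sure to include rest days."},
    {"slot": "behaviour_feedback", "code": 12, "tailored": true,
     "constructs": ["self-control"],
     "objective": "Meeting guideline despite marked limitation, doing less",
     "body": "You still meet the guideline although you do less than before. Plan your week so your remaining sessions stay regular."},
    {"slot": "behaviour_feedback", "code": 13, "tailored": true,
     "constructs": ["behavioural capability"],
     "objective": "Default message when activity items were not answered",
     "body": "We could not work out your current activity level from your answers. As a guide, aim for at least 150 minutes of moderate activity across 5 or more sessions each week."},

    {"slot": "persuasive_sct", "code": 1, "tailored": true,
     "constructs": ["self-efficacy", "expectations"],
     "objective": "Build confidence and positive outcome expectations in participants below the guideline",
     "body": "Small steps count: survivors who build up activity gradually report less fatigue and better mood within weeks. Choose one day this week to add a 10-minute walk."},
    {"slot": "persuasive_sct", "code": 2, "tailored": true,
     "constructs": ["self-control", "environment"],
     "objective": "Support maintenance and social embedding in participants meeting the guideline",
     "body": "To keep your routine going, share your weekly activity plan with one or two people close to you - a little accountability goes a long way."},
    {"slot": "persuasive_sct", "code": 3, "tailored": true,
     "constructs": ["self-efficacy"],
     "objective": "Default persuasive message for non-response",
     "body": "Whatever your starting point, regular activity is one of the most useful things you can do for your recovery - and confidence grows with every session."},

    {"slot": "action_plan", "tailored": false,
     "constructs": ["self-control", "self-efficacy"],
     "objective": "Prompt a concrete weekly activity plan",
     "body": "Your action plan: write down what activity you will do this week, on which days, at what time, and who with. Be specific - specific plans are far more likely to happen."}
  ],
  "templates": [
    {"wave": 1, "bindings": {
      "welcome": null, "expert_advice": null,
      "behaviour_feedback": "aerobic_feedback",
      "persuasive_sct": "persuasive_feedback", "action_plan": null}},
    {"wave": 2, "bindings": {
      "welcome": null, "expert_advice": null,
      "behaviour_feedback": "aerobic_feedback",
      "persuasive_sct": "persuasive_feedback", "action_plan": null}},
    {"wave": 3, "bindings": {
      "welcome": null, "expert_advice": null,
      "behaviour_feedback": "aerobic_feedback",
      "persuasive_sct": "persuasive_feedback", "action_plan": null}}
  ]
}
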