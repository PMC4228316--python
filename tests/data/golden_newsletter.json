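{"blocks":[{"code":null,"constructs":[],"slot":"welcome","text":"Dear Jane, welcome to your personalised activity newsletter."},{"code":null,"constructs":["observational learning"],"slot":"expert_advice","text":"Our exercise physiologist recommends building activity up gradually and mixing aerobic sessions with simple resistance exercises."},{"code":7,"constructs":["behavioural capability","self-control"],"slot":"behaviour_feedback","text":"Well done - you are meeting the aerobic activity guideline. Keeping your routine steady is the best way to hold on to these benefits."},{"code":2,"constructs":["self-control","environment"],"slot":"persuasive_sct","text":"To keep your routine going, share your weekly activity plan with one or two people close to you - a little accountability goes a long way."},{"code":null,"constructs":["self-control","self-efficacy"],"slot":"action_plan","text":"Your action plan: write down what activity you will do this week, on which days, at what time, and who with. Be specific - specific plans are far more likely to happen."}],"chart":{"available":true,"labels":["baseline"],"reference":150.0,"series":[150.0]},"iterative":false,"participant_id":"FIX01","wave":1}
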