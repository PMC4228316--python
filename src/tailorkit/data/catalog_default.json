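{
  "raw": [
    {"name": "first_name",
     "description": "Participant's first name (salutation merge field)",
     "domain": {"kind": "free-text", "max_length": 20}},
    {"name": "strenuous_sessions",
     "description": "Average sessions per week of strenuous aerobic activity",
     "domain": {"kind": "numeric", "lower": 0, "upper": 50}},
    {"name": "strenuous_minutes",
     "description": "Average minutes per strenuous session",
     "domain": {"kind": "numeric", "lower": 0, "upper": 1000}},
    {"name": "moderate_sessions",
     "description": "Average sessions per week of moderate aerobic activity",
     "domain": {"kind": "numeric", "lower": 0, "upper": 50}},
    {"name": "moderate_minutes",
     "description": "Average minutes per moderate session",
     "domain": {"kind": "numeric", "lower": 0, "upper": 1000}},
    {"name": "resistance_exercises",
     "description": "Resistance exercises performed per week",
     "domain": {"kind": "numeric", "lower": 0, "upper": 100}},
    {"name": "disability",
     "description": "How much physical health limits regular activity",
     "domain": {"kind": "coded-category", "levels": {
       "1": "not at all limited", "2": "a little limited",
       "3": "somewhat limited", "4": "mostly limited",
       "5": "completely limited"}}},
    {"name": "aerobic_change",
     "description": "Change in aerobic exercise since cancer diagnosis",
     "domain": {"kind": "coded-category", "levels": {
       "1": "same amount now", "2": "more now", "3": "less now"}}},
    {"name": "age",
     "description": "Age in years",
     "domain": {"kind": "numeric", "lower": 18, "upper": 110}},
    {"name": "bmi",
     "description": "Body-mass index, kg/m^2",
     "domain": {"kind": "numeric", "lower": 10, "upper": 70}},
    {"name": "married",
     "description": "Married or de facto",
     "domain": {"kind": "coded-category", "levels": {"1": "yes", "2": "no"}}}
  ],
  "intermediate": [
    {"name": "aerobic_guideline",
     "description": "Meeting the aerobic guideline (>=150 weighted min/wk across >=5 sessions; vigorous minutes doubled). 1 = not meeting, 2 = meeting.",
     "builtin": "aerobic_guideline",
     "inputs": {
       "strenuous_sessions": "strenuous_sessions",
       "strenuous_minutes": "strenuous_minutes",
       "moderate_sessions": "moderate_sessions",
       "moderate_minutes": "moderate_minutes"},
     "codes": {"1": "not meeting", "2": "meeting"}},
    {"name": "resistance_criterion",
     "description": "More than 6 resistance exercises per week. 1 = below, 2 = meeting.",
     "chain": {
       "clauses": [
         {"when": [{"variable": "resistance_exercises", "op": ">", "value": 6}],
          "result": 2}
       ],
       "default": 1}}
  ],
  "feedback": [
    {"name": "aerobic_feedback",
     "description": "Selects the activity-behaviour feedback message from guideline status, disability rating and post-diagnosis change; code 13 is the default (non-response) message.",
     "chain": {
       "clauses": [
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 1}],
          "result": 1},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 2}],
          "result": 2},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 3}],
          "result": 3},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 1}],
          "result": 4},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 2}],
          "result": 5},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 3}],
          "result": 6},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 1}],
          "result": 7},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 2}],
          "result": 8},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": "<", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 3}],
          "result": 9},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 1}],
          "result": 10},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 2}],
          "result": 11},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2},
                   {"variable": "disability", "op": ">=", "value": 3},
                   {"variable": "post_diagnosis_change", "op": "==", "value": 3}],
          "result": 12}
       ],
       "default": 13}},
    {"name": "persuasive_feedback",
     "description": "Selects the persuasive SCT-matched message from guideline status; code 3 is the default (non-response) message.",
     "chain": {
       "clauses": [
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 1}],
          "result": 1},
         {"when": [{"variable": "aerobic_guideline", "op": "==", "value": 2}],
          "result": 2}
       ],
       "default": 3}}
  ],
  "aliases": {"post_diagnosis_change": "aerobic_change"}
}
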