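# Evaluation-survey generator: printed marginal triples per rating item,
# the relevance -> usefulness proportional-odds ratio, and the response
# rate of the evaluation survey.
attention:  {mean: 3.6, sd: 0.88, p_ge3: 0.74}
relevance:  {mean: 3.7, sd: 0.96, p_ge3: 0.73}
usefulness: {mean: 3.2, sd: 1.11, p_ge3: 0.632}
odds_ratio: 4.8
response_rate: 0.84
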