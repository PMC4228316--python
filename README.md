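# tailorkit

A rule-based computer-tailoring engine for multi-wave physical-activity
print interventions, built for behaviour-change researchers who want to
specify, audit and simulate tailored-communication programs — such as
newsletter interventions for post-treatment breast cancer survivors —
without re-implementing the plumbing each time.

Computer-tailored interventions map each participant's survey responses to
individualised messages through three tiers of variables: **raw** survey
responses, **intermediate** derived values, and **feedback** variables —
first-match rule chains (if / else-if / else cascades with a default code
for non-response) whose output codes index a message library.  For the
aerobic guideline the shipped intermediate classifies a weekly activity
profile as *meeting* iff

    st_sess + mo_sess >= 5   and   2·st_sess·st_min + mo_sess·mo_min >= 150

(sessions per week and average minutes per session for strenuous and
moderate activity; vigorous minutes count double toward the 150 min/wk
guideline).  Messages fill a fixed five-slot newsletter (welcome, expert
advice, behaviour feedback, persuasive message matched on Social Cognitive
Theory constructs, action plan).  A three-wave pipeline iterates the
tailoring on interim "update cards", falling back to baseline data when a
card is not returned within two weeks, and logs delivered message ids for
heterogeneity auditing (per-slot Shannon entropy).  A calibrated synthetic
cohort generator and process-evaluation statistics (Likert summaries,
proportional-odds regression with Wald intervals) close the loop so the
whole system is testable end to end.  Details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import tailorkit as tk

catalog, library = tk.default_catalog(), tk.default_library()
assert tk.validate_coverage(library, catalog).passed

cohort = tk.simulate_baseline(tk.default_cohort_config(), n=200, seed=1)
cards = tk.simulate_update_returns(cohort, tk.default_return_model(), seed=2)
docs, log = tk.run_program(cohort, catalog, library, cards,
                           tk.default_schedule(), seed=3)
print(len(docs), "newsletters")
het = tk.message_heterogeneity(log)
print(het[["wave", "slot", "n_variants", "entropy_bits"]].head(2))
```

prints

```
600 newsletters
   wave                slot  n_variants  entropy_bits
0     1  behaviour_feedback          12      3.225425
1     1      persuasive_sct           2      0.826746
```

600 documents = 200 participants × 3 waves.  The behaviour-feedback slot
delivered 12 distinct message variants with an entropy of 3.23 bits
(maximum possible for 13 codes ≈ 3.70): the cascade genuinely
differentiates the cohort rather than funnelling everyone to one message.
The persuasive slot distinguishes participants meeting vs not meeting the
guideline, hence ~0.8 bits over two variants at the 23.5% meeting rate.

The same run is available from the shell:

```bash
tailor simulate --out work/ --seed 1
tailor validate
tailor run --cohort work/cohort.csv --cards work/cards.csv --out work/run --seed 3
tailor evaluate --ratings work/ratings.csv --out work/report
```

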