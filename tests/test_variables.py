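"""Variable engine: domains, first-match rule chains, guideline
classification and whole-record resolution."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import tailorkit as tk
from tailorkit.errors import CatalogError, RuleTypeError
from tailorkit.variables import UNRESOLVED, evaluate_rule_chain


def brute_force_chain(chain: tk.RuleChain, bindings) -> int:
    """Independent oracle: evaluate every clause's truth value separately
    and take the first true one, without reusing the chain evaluator."""
    for clause in chain.clauses:
        truths = []
        for cmp_ in clause.when:
            value = bindings.get(cmp_.variable)
            if value is None:
                truths.append(False)
                continue
            op, const = cmp_.op, cmp_.value
            truths.append(
                value in const if op == "in"
                else value < const if op == "<"
                else value <= const if op == "<="
                else value == const if op == "=="
                else value >= const if op == ">="
                else value > const
            )
        if all(truths):
            return clause.result
    return chain.default


class TestRuleChain:
    def test_first_matching_clause_wins(self, feedback_chain):
        bindings = {"aerobic_guideline": 1, "disability": 2,
                    "post_diagnosis_change": 1}
        assert evaluate_rule_chain(feedback_chain, bindings) == 1

    def test_disability_branch_switches_message(self, feedback_chain):
        bindings = {"aerobic_guideline": 1, "disability": 4,
                    "post_diagnosis_change": 1}
        assert evaluate_rule_chain(feedback_chain, bindings) == 4

    def test_missing_binding_falls_to_default(self, feedback_chain):
        assert evaluate_rule_chain(feedback_chain, {}) == 13
        partial = {"aerobic_guideline": 1, "disability": 2}
        assert evaluate_rule_chain(feedback_chain, partial) == 13

    def test_exhaustive_truth_table_oracle(self, feedback_chain):
        """All 30 complete input combinations agree with the brute-force
        oracle (2 guideline codes x 5 disability levels x 3 change codes)."""
        for guid, dis, change in itertools.product((1, 2), range(1, 6), (1, 2, 3)):
            bindings = {"aerobic_guideline": guid, "disability": dis,
                        "post_diagnosis_change": change}
            assert evaluate_rule_chain(feedback_chain, bindings) == \
                brute_force_chain(feedback_chain, bindings)

    def test_text_against_numeric_threshold_raises(self):
        chain = tk.RuleChain(clauses=[tk.LogicClause(
            when=[tk.Comparison(variable="x", op="<", value=3)], result=1)],
            default=9)
        with pytest.raises(RuleTypeError):
            evaluate_rule_chain(chain, {"x": "three"})

    @given(st.dictionaries(
        st.sampled_from(["aerobic_guideline", "disability", "post_diagnosis_change"]),
        st.integers(min_value=1, max_value=5), max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_appending_clauses_never_changes_a_match(self, bindings):
        """First-match semantics: extra clauses after the cascade are dead
        code for inputs the original cascade already decided."""
        chain = tk.default_catalog().feedback_def("aerobic_feedback").chain
        extended = tk.RuleChain(
            clauses=chain.clauses + (tk.LogicClause(
                when=[tk.Comparison(variable="disability", op=">=", value=1)],
                result=99),),
            default=chain.default)
        original = evaluate_rule_chain(chain, bindings)
        if original != chain.default:
            assert evaluate_rule_chain(extended, bindings) == original

    @given(st.permutations(["aerobic_guideline", "disability", "post_diagnosis_change"]),
           st.integers(1, 2), st.integers(1, 5), st.integers(1, 3))
    @settings(max_examples=40, deadline=None)
    def test_binding_insertion_order_is_irrelevant(self, order, guid, dis, change):
        chain = tk.default_catalog().feedback_def("aerobic_feedback").chain
        values = {"aerobic_guideline": guid, "disability": dis,
                  "post_diagnosis_change": change}
        permuted = {name: values[name] for name in order}
        assert evaluate_rule_chain(chain, permuted) == \
            evaluate_rule_chain(chain, values)

    @given(st.integers(1, 2), st.integers(1, 5), st.integers(1, 3),
           st.sets(st.sampled_from(
               ["aerobic_guideline", "disability", "post_diagnosis_change"])))
    @settings(max_examples=60, deadline=None)
    def test_removing_bindings_only_moves_toward_default(self, guid, dis, change, drop):
        """Missing-data monotonicity: deleting answers can only push the
        result to the default code, never to a different message."""
        chain = tk.default_catalog().feedback_def("aerobic_feedback").chain
        full = {"aerobic_guideline": guid, "disability": dis,
                "post_diagnosis_change": change}
        reduced = {k: v for k, v in full.items() if k not in drop}
        before = evaluate_rule_chain(chain, full)
        after = evaluate_rule_chain(chain, reduced)
        assert after in (before, chain.default)


class TestGuidelineClassifier:
    def test_moderate_five_by_thirty_meets(self):
        profile = tk.ActivityProfile(
            strenuous_sessions=0, strenuous_minutes=0,
            moderate_sessions=5, moderate_minutes=30)
        assert tk.classify_aerobic_guideline(profile) == 2

    @pytest.mark.parametrize("mode", ["weekly-total", "literal"])
    def test_too_few_sessions_never_meets(self, mode):
        profile = tk.ActivityProfile(
            strenuous_sessions=2, strenuous_minutes=40,
            moderate_sessions=0, moderate_minutes=0)
        assert tk.classify_aerobic_guideline(profile, mode) == 1

    def test_zero_activity_does_not_meet(self):
        profile = tk.ActivityProfile(
            strenuous_sessions=0, strenuous_minutes=0,
            moderate_sessions=0, moderate_minutes=0)
        assert tk.classify_aerobic_guideline(profile) == 1

    def test_missing_minutes_with_sessions_is_unresolved(self):
        profile = tk.ActivityProfile(
            strenuous_sessions=0, strenuous_minutes=0, moderate_sessions=6)
        assert tk.classify_aerobic_guideline(profile) is None

    def test_literal_mode_uncovered_case_warns_and_is_conservative(self, caplog):
        # 5 sessions but short per-session minutes: neither literal branch.
        profile = tk.ActivityProfile(
            strenuous_sessions=0, strenuous_minutes=0,
            moderate_sessions=5, moderate_minutes=20)
        with caplog.at_level("WARNING"):
            assert tk.classify_aerobic_guideline(profile, "literal") == 1
        assert any("neither" in rec.message for rec in caplog.records)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tk.ActivityProfile(moderate_sessions=-1)


class TestCatalog:
    def test_default_catalog_order_puts_feedback_last(self, catalog):
        order = catalog.topological_order
        assert order.index("aerobic_guideline") < order.index("aerobic_feedback")
        assert set(catalog.raw_names) < set(order)

    def test_empty_document_rejected(self):
        with pytest.raises(CatalogError, match="no variables"):
            tk.load_catalog({"raw": [], "intermediate": [], "feedback": []})

    def test_undeclared_reference_named_in_error(self):
        doc = {
            "raw": [{"name": "a", "domain": {"kind": "numeric"}}],
            "feedback": [{"name": "f", "chain": {
                "clauses": [{"when": [{"variable": "R_foo", "op": "==",
                                       "value": 1}], "result": 1}],
                "default": 2}}],
        }
        with pytest.raises(CatalogError, match="R_foo"):
            tk.load_catalog(doc)

    def test_duplicate_names_rejected(self):
        doc = {"raw": [{"name": "a", "domain": {"kind": "numeric"}},
                       {"name": "a", "domain": {"kind": "numeric"}}]}
        with pytest.raises(CatalogError, match="duplicate"):
            tk.load_catalog(doc)

    def test_coded_domain_requires_levels(self):
        with pytest.raises(ValueError):
            tk.ValueDomain(kind="coded-category")

    def test_alias_lookup_is_transparent(self, catalog):
        assert catalog.canonical("post_diagnosis_change") == "aerobic_change"
        assert catalog.raw_def("post_diagnosis_change").name == "aerobic_change"


class TestResolveRecord:
    def test_fully_answered_record_gets_one_code_per_feedback(self, catalog, full_record):
        assignments = tk.resolve_record(catalog, full_record)
        for defn in catalog.feedback:
            assert assignments[defn.name] in defn.output_codes
        # 5x30 moderate meets the guideline; low disability; unchanged -> 7
        assert assignments["aerobic_guideline"] == 2
        assert assignments["aerobic_feedback"] == 7

    def test_all_missing_record_lands_on_defaults(self, catalog, empty_record):
        assignments = tk.resolve_record(catalog, empty_record)
        assert assignments["aerobic_guideline"] == UNRESOLVED
        assert assignments["aerobic_feedback"] == 13
        assert assignments["persuasive_feedback"] == 3

    def test_resolution_matches_per_chain_oracle_on_random_records(self, catalog):
        """On 200 generated records, whole-record resolution agrees with
        independent per-chain brute-force evaluation."""
        cohort = tk.simulate_baseline(
            tk.default_cohort_config(), n=200, seed=77)
        for record in cohort:
            assignments = tk.resolve_record(catalog, record)
            env = dict(record.bindings["baseline"])
            for defn in catalog.intermediate:
                if defn.builtin:
                    env[defn.name] = assignments[defn.name] or None
                else:
                    env[defn.name] = brute_force_chain(defn.chain, env)
                    assert assignments[defn.name] == env[defn.name]
            env["post_diagnosis_change"] = env.get("aerobic_change")
            for defn in catalog.feedback:
                assert assignments[defn.name] == brute_force_chain(defn.chain, env)

    def test_type_error_names_offending_variable(self, catalog, full_record):
        record = full_record.model_copy(deep=True)
        record.bindings["baseline"]["disability"] = "bad"
        with pytest.raises(RuleTypeError, match="aerobic_feedback"):
            tk.resolve_record(catalog, record)


class TestCohortCsv:
    def test_round_trip_preserves_bindings(self, catalog, tmp_path, small_cohort):
        frame = tk.records_to_frame(small_cohort, catalog)
        path = tmp_path / "cohort.csv"
        frame.to_csv(path, index=False)
        back = tk.load_cohort_csv(path, catalog)
        assert len(back) == len(small_cohort)
        by_id = {r.participant_id: r for r in back}
        for record in small_cohort:
            twin = by_id[record.participant_id]
            for name, value in record.bindings["baseline"].items():
                expected = pytest.approx(value) if isinstance(value, float) else value
                assert twin.bindings["baseline"][name] == expected

    def test_empty_cells_become_missing(self, catalog, tmp_path):
        path = tmp_path / "cohort.csv"
        header = ",".join(["participant_id", "wave", *catalog.raw_names])
        blanks = "," * len(catalog.raw_names)
        path.write_text(f"{header}\nX1,baseline{blanks}\n")
        (record,) = tk.load_cohort_csv(path, catalog)
        assert record.bindings["baseline"] == {}

    def test_undeclared_column_rejected(self, catalog, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("participant_id,wave,mystery\nX1,baseline,1\n")
        with pytest.raises(CatalogError, match="mystery"):
            tk.load_cohort_csv(path, catalog)
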