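"""Message library: validation, merge-field rendering, charts, coverage
and deterministic newsletter assembly."""

import itertools

import pytest

import tailorkit as tk
from tailorkit.errors import AssemblyError, LibraryError, MergeFieldError
from tailorkit.messages import reachable_codes


def minimal_library_doc():
    return {
        "declared_fields": ["first_name"],
        "blocks": [
            {"slot": "welcome", "tailored": False, "body": "Dear {{first_name}},"},
            {"slot": "expert_advice", "tailored": False, "body": "Advice."},
            {"slot": "behaviour_feedback", "code": 1, "tailored": True, "body": "A"},
            {"slot": "persuasive_sct", "code": 1, "tailored": True,
             "constructs": ["self-efficacy"], "body": "B"},
            {"slot": "action_plan", "tailored": False, "body": "Plan."},
        ],
        "templates": [{"wave": 1, "bindings": {
            "welcome": None, "expert_advice": None,
            "behaviour_feedback": None, "persuasive_sct": None,
            "action_plan": None}}],
    }


class TestLoadLibrary:
    def test_default_library_covers_every_feedback_code(self, library, catalog):
        for defn in catalog.feedback:
            slot = "aerobic" in defn.name and "behaviour_feedback" or "persuasive_sct"
            assert set(defn.output_codes) <= set(library.codes_for(slot))

    def test_duplicate_slot_code_rejected(self):
        doc = minimal_library_doc()
        doc["blocks"].append(dict(doc["blocks"][2]))
        with pytest.raises(LibraryError, match="duplicate"):
            tk.load_library(doc)

    def test_unknown_construct_rejected(self):
        doc = minimal_library_doc()
        doc["blocks"][3]["constructs"] = ["willpower"]
        with pytest.raises(LibraryError, match="willpower"):
            tk.load_library(doc)

    def test_undeclared_merge_field_rejected_at_load(self):
        doc = minimal_library_doc()
        doc["blocks"][0]["body"] = "Dear {{surname}},"
        with pytest.raises(LibraryError, match="surname"):
            tk.load_library(doc)


class TestRenderBlock:
    def test_substitutes_bound_name(self):
        block = tk.MessageBlockDef(slot="welcome", body="Dear {{first_name}}")
        assert tk.render_block(block, {"first_name": "Jane"}) == "Dear Jane"

    def test_missing_name_uses_fallback_salutation(self):
        block = tk.MessageBlockDef(slot="welcome", body="Dear {{first_name}}")
        assert tk.render_block(block, {}) == "Dear participant"

    def test_unknown_field_raises_with_name(self):
        block = tk.MessageBlockDef(slot="welcome", body="{{unknown}}")
        with pytest.raises(MergeFieldError, match="unknown"):
            tk.render_block(block, {"first_name": "Jane"})

    def test_rendered_output_never_contains_delimiters(self, library, full_record):
        bindings = full_record.bindings["baseline"]
        for block in library.blocks:
            assert "{{" not in tk.render_block(
                block, bindings, library.fallbacks, library.declared_fields)


class TestFeedbackChart:
    def test_baseline_only_weighted_minutes(self, catalog, full_record):
        chart = tk.build_feedback_chart(full_record, 1, catalog)
        assert chart.series == (150.0,)
        assert chart.reference == 150.0
        assert chart.available

    def test_update_wave_appends_a_point(self, catalog, full_record):
        record = full_record.model_copy(deep=True)
        record.bindings["update1"] = {
            "strenuous_sessions": 0, "strenuous_minutes": 0,
            "moderate_sessions": 3, "moderate_minutes": 30}
        chart = tk.build_feedback_chart(record, 2, catalog)
        assert chart.series == (150.0, 90.0)
        assert chart.labels == ("baseline", "update1")

    def test_all_missing_chart_flagged_unavailable(self, catalog, empty_record):
        chart = tk.build_feedback_chart(empty_record, 1, catalog)
        assert chart.series == ()
        assert not chart.available


class TestCoverage:
    def test_default_pair_passes_cleanly(self, library, catalog):
        report = tk.validate_coverage(library, catalog)
        assert report.passed
        assert report.warnings == ()

    def test_missing_code_fails_and_is_listed(self, library, catalog):
        pruned = library.model_copy(update={"blocks": tuple(
            b for b in library.blocks
            if not (b.slot == "behaviour_feedback" and b.code == 4))})
        report = tk.validate_coverage(pruned, catalog)
        assert not report.passed
        entry = next(e for e in report.entries if e.slot == "behaviour_feedback")
        assert 4 in entry.unmapped_codes

    def test_orphan_message_warned(self, library, catalog):
        extra = tk.MessageBlockDef(slot="behaviour_feedback", code=99,
                                   tailored=True, body="orphan")
        bloated = library.model_copy(
            update={"blocks": library.blocks + (extra,)})
        report = tk.validate_coverage(bloated, catalog)
        assert report.passed  # orphans do not fail coverage
        assert any("99" in w for w in report.warnings)

    def test_reachable_codes_match_syntactic_set_for_complete_chain(
            self, catalog, feedback_chain):
        # every printed code 1..12 plus default 13 is reachable
        assert reachable_codes(catalog, feedback_chain) == tuple(range(1, 14))


class TestAssembly:
    def assemble(self, catalog, library, record):
        assignments = tk.resolve_record(catalog, record)
        chart = tk.build_feedback_chart(record, 1, catalog)
        return tk.assemble_newsletter(
            library.template_for(1), library, assignments, record, chart)

    def test_five_blocks_in_printed_order(self, catalog, library, full_record):
        document = self.assemble(catalog, library, full_record)
        assert tuple(b.slot for b in document.blocks) == tk.SLOTS
        assert not document.iterative

    def test_assembly_is_byte_deterministic(self, catalog, library, full_record):
        one = tk.document_to_json(self.assemble(catalog, library, full_record))
        two = tk.document_to_json(self.assemble(catalog, library, full_record))
        assert one == two

    def test_missing_assignment_raises_assembly_error(self, catalog, library, full_record):
        chart = tk.build_feedback_chart(full_record, 1, catalog)
        with pytest.raises(AssemblyError, match="aerobic_feedback"):
            tk.assemble_newsletter(library.template_for(1), library,
                                   {}, full_record, chart)

    def test_coverage_closure_over_all_coded_inputs(self, catalog, library):
        """If coverage passes, assembly cannot fail for any record valid
        against the catalog: exhaustively enumerate disability x change x
        guideline-relevant activity patterns, including full non-response."""
        assert tk.validate_coverage(library, catalog).passed
        activity_patterns = [
            {},  # non-response
            {"strenuous_sessions": 0, "strenuous_minutes": 0,
             "moderate_sessions": 5, "moderate_minutes": 30},   # meeting
            {"strenuous_sessions": 1, "strenuous_minutes": 20,
             "moderate_sessions": 1, "moderate_minutes": 20},   # not meeting
        ]
        for activity, disability, change in itertools.product(
                activity_patterns, [None, *range(1, 6)], [None, 1, 2, 3]):
            bindings = dict(activity)
            if disability is not None:
                bindings["disability"] = disability
            if change is not None:
                bindings["aerobic_change"] = change
            record = tk.ParticipantRecord(
                participant_id="ENUM", bindings={"baseline": bindings})
            document = self.assemble(catalog, library, record)
            assert len(document.blocks) == 5

    def test_golden_fixture_participant(self, catalog, library, full_record, request):
        """Frozen end-to-end output for one fixture participant."""
        golden = request.path.parent / "data" / "golden_newsletter.json"
        produced = tk.document_to_json(self.assemble(catalog, library, full_record))
        assert produced == golden.read_text().strip()
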