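"""Prompt rendering, output parsing and batch extraction behavior."""

import json

import pytest
from hypothesis import given, strategies as st

from geinfo import (
    Backend,
    ExtractionRecord,
    TemplateError,
    extract_article,
    get_template,
    parse_output,
    render_prompt,
    run_extraction,
    write_records,
    load_records,
)
from geinfo.corpus_io import ArticleText
from geinfo.extraction import PromptTemplate, ReplayBackend, prompt_digest

ARTICLE = ArticleText(
    pmcid="PMC1",
    pmid="101",
    title="Editing FOS in human cells",
    abstract="FOS was knocked out using CRISPR-Cas9 in Homo sapiens.",
    methods="All experiments were conducted in Homo sapiens.",
    results="The edited cells exhibited reduced proliferation.",
)


class TestTemplates:
    def test_round2_output_schema(self, round2):
        assert round2.output_fields == [
            "targeted_genes",
            "differentially_expressed_genes",
            "species",
            "genome_editing_tools",
            "genome_editing_event",
            "phenotypes",
        ]

    def test_round1_swaps_phenotypes_for_summary_fields(self, round1):
        assert "phenotypes" not in round1.output_fields
        assert round1.output_fields[-3:] == [
            "study_context",
            "key_findings",
            "implications",
        ]

    def test_duplicate_slot_is_a_template_error(self):
        with pytest.raises(TemplateError, match="exactly once"):
            PromptTemplate(
                name="bad",
                body="{{GENES}} and again {{GENES}}",
                required_slots=["GENES"],
                output_fields=[],
            )


class TestRendering:
    def test_rendered_prompt_contains_instruction_and_inputs(self, round2):
        prompt = render_prompt(
            round2, ["FOS"], ["Homo sapiens"], ["CRISPR-Cas9"], ARTICLE
        )
        assert (
            "If genome editing is not mentioned in the text, state 'Not mentioned'"
            in prompt
        )
        assert "GENES: FOS by Homo sapiens" in prompt
        assert "genome editing tools:CRISPR-Cas9" in prompt
        assert "{{" not in prompt  # no placeholder residue

    def test_empty_sections_leave_no_residue(self, round2):
        bare = ArticleText(pmcid="PMC2", pmid="102", title="T")
        prompt = render_prompt(round2, [], [], [], bare)
        assert "METHODS:\nRESULTS:" in prompt
        assert "{{" not in prompt

    def test_rendering_is_deterministic(self, round2):
        args = (round2, ["FOS"], ["Homo sapiens"], ["CRISPR-Cas9"], ARTICLE)
        assert render_prompt(*args) == render_prompt(*args)

    def test_unknown_slot_is_fatal(self):
        template = PromptTemplate(
            name="bad", body="{{WHAT}}", required_slots=["WHAT"], output_fields=[]
        )
        with pytest.raises(TemplateError, match="WHAT"):
            render_prompt(template, [], [], [], ARTICLE)


PAYLOAD = {
    "targeted_genes": ["FOS"],
    "differentially_expressed_genes": ["Not mentioned"],
    "species": ["Homo sapiens"],
    "genome_editing_tools": ["CRISPR-Cas9"],
    "genome_editing_event": ["knockout"],
    "phenotypes": [],
}


class TestParsing:
    def test_sentinel_lists_become_empty(self, round2):
        record = parse_output(json.dumps(PAYLOAD), round2)
        assert record.status == "ok"
        assert record.targeted_genes == ["FOS"]
        assert record.differentially_expressed_genes == []
        assert record.phenotypes == []

    @pytest.mark.parametrize(
        "wrap",
        [
            "```json\n{}\n```",
            "Here is the summary you asked for:\n{}\nLet me know!",
            "```\n{}\n```",
        ],
        ids=["fenced-json", "prose", "bare-fence"],
    )
    def test_fences_and_prose_are_stripped(self, round2, wrap):
        raw = wrap.format(json.dumps(PAYLOAD))
        assert parse_output(raw, round2) == parse_output(json.dumps(PAYLOAD), round2)

    def test_single_quoted_output_parses(self, round2):
        raw = str(PAYLOAD)  # Python repr: single quotes
        record = parse_output(raw, round2)
        assert record.targeted_genes == ["FOS"]

    @pytest.mark.parametrize(
        "sentinel", ["Not mentioned", "not mentioned", "NONE", "", "Not mentioned."]
    )
    def test_sentinel_spellings(self, round2, sentinel):
        payload = dict(PAYLOAD, targeted_genes=[sentinel], species=sentinel)
        record = parse_output(json.dumps(payload), round2)
        assert record.targeted_genes == []
        assert record.species == []

    def test_unparseable_output_gives_parse_failed(self, round2):
        record = parse_output("I cannot determine this.", round2)
        assert record.status == "parse_failed"
        assert record.targeted_genes == []

    def test_missing_field_becomes_empty_list_with_warning(self, round2, caplog):
        payload = {k: v for k, v in PAYLOAD.items() if k != "phenotypes"}
        with caplog.at_level("WARNING"):
            record = parse_output(json.dumps(payload), round2)
        assert record.status == "ok" and record.phenotypes == []
        assert "phenotypes" in caplog.text

    @given(
        genes=st.lists(
            st.text(
                alphabet=st.characters(whitelist_categories=["Lu", "Nd"]),
                min_size=1,
                max_size=8,
            ).filter(lambda g: g.casefold() not in {"none", "n/a"}),
            max_size=4,
        )
    )
    def test_parse_is_idempotent_on_serialized_records(self, genes):
        template = get_template("round2")
        record = ExtractionRecord(
            pmid="7", targeted_genes=genes, species=["Homo sapiens"], backend="x"
        )
        reparsed = parse_output(record.to_json(), template)
        for name in template.list_fields:
            assert getattr(reparsed, name) == getattr(record, name)
        assert reparsed.pmid == record.pmid


class TestBatch:
    def make_backend(self, raw=None, fail_times=0):
        calls = {"n": 0}

        def fn(prompt):
            calls["n"] += 1
            if calls["n"] <= fail_times:
                raise ConnectionError("transport down")
            return raw if raw is not None else json.dumps(PAYLOAD)

        return Backend(name="stub", fn=fn), calls

    def test_extract_article_tags_pmid_and_backend(self, round2, corpus):
        backend, _ = self.make_backend()
        context = corpus.contexts()[corpus.articles[0].pmid]
        record = extract_article(corpus.articles[0], context, round2, backend)
        assert record.pmid == corpus.articles[0].pmid
        assert record.backend == "stub"

    def test_one_retry_then_parse_failed(self, round2):
        backend, calls = self.make_backend(fail_times=1)
        record = extract_article(ARTICLE, _ctx(), round2, backend)
        assert record.status == "ok" and calls["n"] == 2

        backend, calls = self.make_backend(fail_times=2)
        record = extract_article(ARTICLE, _ctx(), round2, backend)
        assert record.status == "parse_failed" and calls["n"] == 2

    def test_backend_failure_never_aborts_the_batch(self, round2, corpus):
        flaky_pmid = corpus.articles[2].pmid

        def fn(prompt):
            if corpus.articles[2].title in prompt:
                raise ConnectionError("down")
            return json.dumps(PAYLOAD)

        backend = Backend(name="flaky", fn=fn)
        records = run_extraction(
            corpus.articles[:5], corpus.contexts(), round2, backend
        )
        assert len(records) == 5
        by_status = {r.pmid: r.status for r in records}
        assert by_status[flaky_pmid] == "parse_failed"
        assert sum(s == "ok" for s in by_status.values()) == 4

    def test_record_count_equals_article_count_and_order(self, corpus, round2,
                                                         zero_error_records):
        assert len(zero_error_records) == len(corpus.articles)
        assert [r.pmid for r in zero_error_records] == [
            a.pmid for a in corpus.articles
        ]

    def test_empty_article_list(self, round2, tmp_path):
        out = tmp_path / "records.jsonl"
        backend, _ = self.make_backend()
        records = run_extraction([], {}, round2, backend, out_path=out)
        assert records == [] and out.read_text() == ""

    def test_records_round_trip(self, zero_error_records, tmp_path):
        path = tmp_path / "records.jsonl"
        write_records(zero_error_records, path)
        assert load_records(path) == zero_error_records


class TestReplay:
    def test_replay_reproduces_records_across_runs(self, corpus, round2, tmp_path):
        from geinfo import ErrorProfile, MockBackend
        from geinfo.extraction import render_prompt

        mock = MockBackend(corpus, ErrorProfile(seed=5))
        contexts = corpus.contexts()
        rows = []
        for article in corpus.articles[:10]:
            ctx = contexts[article.pmid]
            prompt = render_prompt(round2, ctx.genes, ctx.species, ctx.tools, article)
            rows.append({"prompt_sha256": prompt_digest(prompt), "raw": mock(prompt)})
        path = tmp_path / "replay.jsonl"
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")

        replay = ReplayBackend.from_jsonl(path)
        first = run_extraction(corpus.articles[:10], contexts, round2, replay)
        second = run_extraction(corpus.articles[:10], contexts, round2, replay)
        assert first == second
        mock_records = run_extraction(corpus.articles[:10], contexts, round2,
                                      MockBackend(corpus, ErrorProfile(seed=5)))
        for a, b in zip(first, mock_records):
            assert a.targeted_genes == b.targeted_genes

    def test_unknown_prompt_yields_parse_failed_record(self, round2):
        replay = ReplayBackend({})
        record = extract_article(ARTICLE, _ctx(), round2, replay)
        assert record.status == "parse_failed"


def _ctx():
    from geinfo.corpus_io import ArticleContext

    return ArticleContext(pmid="101", genes=["FOS"], species=["Homo sapiens"],
                          tools=["CRISPR-Cas9"])
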