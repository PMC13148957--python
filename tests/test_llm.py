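"""Prompt assembly, confidence math, output parsing, prediction files."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srameta.context import ContextBundle
from srameta.llm import (
    MockBackend,
    Prediction,
    build_prompt,
    confidence_from_logprobs,
    infer_class,
    infer_run,
    load_prediction_file,
    route_adapter,
    write_prediction_file,
)
from srameta.synthetic import generate_pool


@pytest.fixture
def bundle():
    return ContextBundle(
        paragraphs=[("Study title: melanoma cohort.", "sra_xml")],
        ambiguity_notes=["organ: sra_xml says 'lung'; biosample says 'liver'"],
        run_accession="SRR1",
    ).recount()


class TestBuildPrompt:
    def test_blocks_in_order_with_single_definition(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("is_cancer"))
        text = prompt.render()
        a = text.index("(a) Run accession: SRR1")
        b = text.index("(b) Context summary:")
        c = text.index("(c) Class definition line: - is_cancer:")
        d = text.index("(d) Extract information")
        assert a < b < c < d
        for other in registry.llm_routed:
            if other.name != "is_cancer":
                assert f"- {other.name}:" not in text

    def test_instruction_block_contains_unknown_rule(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("organ"))
        assert 'return "unknown."' in prompt.instruction_block

    def test_api_direct_class_is_rejected(self, registry, bundle):
        with pytest.raises(ValueError):
            build_prompt("SRR1", bundle, registry.get("study_accession"))

    def test_prompts_differ_only_in_definition_block(self, registry, bundle):
        p1 = build_prompt("SRR1", bundle, registry.get("organ"))
        p2 = build_prompt("SRR1", bundle, registry.get("disease"))
        assert p1.summary_text == p2.summary_text
        assert p1.ambiguity_text == p2.ambiguity_text
        assert p1.instruction_block == p2.instruction_block
        assert p1.class_definition_line != p2.class_definition_line


class TestRouteAdapter:
    def test_configured_adapter_map(self, registry):
        config = {"adapter_map": {"organ": "adapter_organ"}, "base_model": "base-7b"}
        assert route_adapter(registry.get("organ"), config) == "adapter_organ"
        assert route_adapter(registry.get("disease"), config) == "base-7b"

    def test_mock_backend_routes_to_mock(self, registry):
        assert route_adapter(registry.get("organ"), {"backend": "mock"}) == "mock"

    def test_api_direct_never_routed(self, registry):
        with pytest.raises(ValueError):
            route_adapter(registry.get("library_strategy"), {})


class TestConfidence:
    @pytest.mark.parametrize(
        "logprobs, mean_nll, ppl",
        [
            ([0.0, 0.0, 0.0], 0.0, 1.0),
            ([-math.log(2)], math.log(2), 2.0),
            ([-1.0, -3.0], 2.0, math.exp(2.0)),
        ],
    )
    def test_closed_forms(self, logprobs, mean_nll, ppl):
        conf = confidence_from_logprobs(logprobs)
        assert conf.mean_nll == pytest.approx(mean_nll, abs=1e-12)
        assert conf.ppl == pytest.approx(ppl, rel=1e-12)

    def test_empty_list_is_contract_violation(self):
        with pytest.raises(ValueError):
            confidence_from_logprobs([])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=-20, max_value=0), min_size=1, max_size=50))
    def test_ppl_equals_exp_mean_nll(self, logprobs):
        conf = confidence_from_logprobs(logprobs)
        assert abs(conf.ppl - math.exp(conf.mean_nll)) <= 1e-9 * max(1.0, conf.ppl)


class _FixedBackend:
    model_name = "fixed"

    def __init__(self, text):
        self.text = text

    def generate(self, prompt):
        return self.text, [-0.1, -0.2]


class _BrokenBackend:
    model_name = "broken"

    def generate(self, prompt):
        raise RuntimeError("backend down")


class TestInferClass:
    def test_discrete_output_snaps_to_canonical(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("library_selection"))
        pred = infer_class(_FixedBackend("polya"), prompt, registry.get("library_selection"))
        assert pred.values == ("polyA",)

    def test_multi_value_open_output_split(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("organ"))
        pred = infer_class(_FixedBackend("lung, Liver"), prompt, registry.get("organ"))
        assert pred.values == ("lung", "Liver")

    def test_unparseable_closed_output_becomes_unknown(self, registry, bundle, caplog):
        prompt = build_prompt("SRR1", bundle, registry.get("is_cancer"))
        with caplog.at_level("WARNING"):
            pred = infer_class(_FixedBackend("maybe-cancer"), prompt,
                               registry.get("is_cancer"))
        assert pred.values == ("unknown",)
        assert "unparseable" in caplog.text

    def test_backend_failure_degrades_to_flagged_unknown(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("organ"))
        pred = infer_class(_BrokenBackend(), prompt, registry.get("organ"))
        assert pred.values == ("unknown",)
        assert pred.failed

    def test_unknown_never_cooccurs_with_values(self, registry, bundle):
        prompt = build_prompt("SRR1", bundle, registry.get("organ"))
        pred = infer_class(_FixedBackend("lung, unknown"), prompt, registry.get("organ"))
        assert pred.values == ("lung",)
        with pytest.raises(ValueError):
            Prediction("organ", ("lung", "unknown"), None)


class TestMockBackend:
    def test_answers_from_planted_truth(self, registry, lexicons):
        sample = generate_pool(1, seed=9, config={"lexicons": lexicons})[0]
        bundle = ContextBundle(paragraphs=[(sample.context_text, "sra_xml")],
                               run_accession="SRR1").recount()
        backend = MockBackend(seed=4)
        for cls in registry.llm_routed:
            pred = infer_class(backend, build_prompt("SRR1", bundle, cls), cls)
            want = tuple(sample.truth[cls.name])
            assert {v.casefold() for v in pred.values} == {v.casefold() for v in want}

    def test_bit_reproducible_for_fixed_seed(self, registry, lexicons):
        sample = generate_pool(1, seed=9, config={"lexicons": lexicons})[0]
        bundle = ContextBundle(paragraphs=[(sample.context_text, "sra_xml")],
                               run_accession="SRR1").recount()
        runs = [infer_run(MockBackend(substitution_rate=0.3, abstention_rate=0.2, seed=7),
                          bundle) for _ in range(2)]
        assert runs[0] == runs[1]

    def test_noise_rates_validated(self):
        with pytest.raises(ValueError):
            MockBackend(substitution_rate=0.7, abstention_rate=0.6)


class TestPredictionFile:
    def test_round_trip(self, tmp_path, registry, lexicons):
        sample = generate_pool(1, seed=9, config={"lexicons": lexicons})[0]
        bundle = ContextBundle(paragraphs=[(sample.context_text, "sra_xml")],
                               run_accession="SRR1").recount()
        predictions = infer_run(MockBackend(seed=2), bundle)
        assert len(predictions) == 15
        path = write_prediction_file("SRR1", predictions, tmp_path / "p.json")
        run, loaded = load_prediction_file(path)
        assert run == "SRR1"
        assert sorted(loaded, key=lambda p: p.class_name) == \
            sorted(predictions, key=lambda p: p.class_name)

    def test_missing_class_is_contract_violation(self, tmp_path, registry, lexicons):
        sample = generate_pool(1, seed=9, config={"lexicons": lexicons})[0]
        bundle = ContextBundle(paragraphs=[(sample.context_text, "sra_xml")],
                               run_accession="SRR1").recount()
        predictions = infer_run(MockBackend(seed=2), bundle)[:-1]
        with pytest.raises(ValueError, match="missing"):
            write_prediction_file("SRR1", predictions, tmp_path / "p.json")
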