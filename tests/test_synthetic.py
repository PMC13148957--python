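"""Generator balance/determinism, proximity splits, leakage diagnostics."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srameta import schema
from srameta.sra_io import ConfigError
from srameta.synthetic import (
    SyntheticSample,
    generate_benchmark,
    generate_pool,
    jaccard_similarity,
    leakage_check,
    mean_reference_similarity,
    split_by_proximity,
)


class TestGeneratePool:
    def test_balanced_within_one_including_unknown(self, lexicons):
        pool = generate_pool(100, classes=["sequencing_source"], seed=1,
                             config={"lexicons": lexicons})
        counts = Counter(s.truth["sequencing_source"][0] for s in pool)
        assert set(counts) == {"bulk", "single cell", "spatial", "unknown"}
        assert all(v == 25 for v in counts.values())

    def test_balance_holds_for_every_class(self, small_pool, registry):
        for cls in registry.llm_routed:
            counts = Counter(s.truth[cls.name][0] for s in small_pool)
            assert max(counts.values()) - min(counts.values()) <= 1, cls.name

    def test_seed_determinism(self, lexicons):
        cfg = {"lexicons": lexicons}
        a = generate_pool(20, seed=5, config=cfg)
        b = generate_pool(20, seed=5, config=cfg)
        assert [s.context_text for s in a] == [s.context_text for s in b]
        assert [s.truth for s in a] == [s.truth for s in b]
        c = generate_pool(20, seed=6, config=cfg)
        assert [s.context_text for s in a] != [s.context_text for s in c]

    def test_absent_mode_means_unknown_and_no_cue(self, small_pool):
        for sample in small_pool:
            for name, mode in sample.mode.items():
                if mode == "absent":
                    assert sample.truth[name] == ("unknown",)
                else:
                    assert sample.truth[name] != ("unknown",)
                    assert sample.truth[name][0] in sample.hidden_marker

    def test_paraphrase_mode_uses_synonym_for_anatomy(self, lexicons):
        pool = generate_pool(
            60, classes=["organ"], seed=2,
            config={"lexicons": lexicons,
                    "value_pools": {"organ": ["oral cavity"]},
                    "mode_props": {"explicit": 0.0, "paraphrase": 1.0}})
        hits = [s for s in pool if s.truth["organ"] == ("oral cavity",)]
        assert hits
        assert any("mouth" in s.context_text for s in hits)
        for s in hits:
            visible = s.context_text.replace(s.hidden_marker, "")
            assert "oral cavity" not in visible

    def test_hidden_marker_consistent_with_truth(self, small_pool):
        from srameta._markers import parse_markers
        for sample in small_pool:
            assert parse_markers(sample.context_text) == sample.truth

    def test_empty_open_vocab_pool_is_config_error(self, lexicons):
        with pytest.raises(ConfigError):
            generate_pool(10, classes=["organ"], seed=1,
                          config={"lexicons": lexicons, "value_pools": {"organ": []}})


def _sample(sid, text):
    return SyntheticSample(sample_id=sid, context_text=text, truth={}, mode={})


class TestSplitByProximity:
    def test_partition_sizes_and_exhaustiveness(self, lexicons):
        ref, pool = generate_benchmark(seed=3, sizes=(10, 30, 10),
                                       n_reference=8, lexicons=lexicons)
        id_p, mid_p, ood_p = split_by_proximity(pool, ref, sizes=(10, 30, 10))
        assert (len(id_p), len(mid_p), len(ood_p)) == (10, 30, 10)
        all_ids = {s.sample_id for s in id_p + mid_p + ood_p}
        assert all_ids == {s.sample_id for s in pool}

    def test_monotone_mean_similarity(self, lexicons):
        ref, pool = generate_benchmark(seed=3, sizes=(10, 30, 10),
                                       n_reference=8, lexicons=lexicons)
        id_p, mid_p, ood_p = split_by_proximity(pool, ref, sizes=(10, 30, 10))
        assert mean_reference_similarity(id_p) >= mean_reference_similarity(mid_p)
        assert mean_reference_similarity(mid_p) >= mean_reference_similarity(ood_p)

    def test_ranks_respected_on_tiny_input(self):
        ref = [_sample("R0", "alpha beta gamma")]
        pool = [
            _sample("P0", "alpha beta gamma"),        # sim 1.0
            _sample("P1", "alpha beta delta"),        # sim 0.5
            _sample("P2", "epsilon zeta eta"),        # sim 0.0
        ]
        id_p, mid_p, ood_p = split_by_proximity(pool, ref, sizes=(1, 1, 1))
        assert id_p[0].sample_id == "P0"
        assert mid_p[0].sample_id == "P1"
        assert ood_p[0].sample_id == "P2"

    def test_all_equal_scores_tie_break_by_id(self):
        ref = [_sample("R0", "alpha beta")]
        pool = [_sample(f"P{i}", "alpha beta") for i in (2, 0, 1)]
        id_p, mid_p, ood_p = split_by_proximity(pool, ref, sizes=(1, 1, 1))
        assert [p[0].sample_id for p in (id_p, mid_p, ood_p)] == ["P0", "P1", "P2"]

    def test_size_mismatch_is_error(self):
        ref = [_sample("R0", "a")]
        with pytest.raises(ValueError):
            split_by_proximity([_sample("P0", "a")], ref, sizes=(1, 1, 1))


class TestJaccard:
    def test_markers_ignored(self):
        assert jaccard_similarity("alpha beta @@organ=lung@@", "alpha beta") == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ab c", max_size=30), st.text(alphabet="ab c", max_size=30))
    def test_bounded_and_symmetric(self, a, b):
        s = jaccard_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == jaccard_similarity(b, a)


class TestLeakageCheck:
    def test_identical_text_across_splits_counts(self):
        splits = {"ID": [_sample("a", "exact same words here")],
                  "OOD": [_sample("b", "exact same words here")]}
        report = leakage_check(splits, threshold=0.9)
        assert report["near_duplicates"] >= 1

    def test_distinct_texts_at_threshold_one(self):
        splits = {"ID": [_sample("a", "first text")],
                  "OOD": [_sample("b", "second content")]}
        assert leakage_check(splits, threshold=1.0)["near_duplicates"] == 0

    def test_disjoint_benchmark_pools_have_zero_violations(self, lexicons):
        ref, pool = generate_benchmark(seed=3, sizes=(10, 30, 10),
                                       n_reference=8, lexicons=lexicons)
        id_p, mid_p, ood_p = split_by_proximity(pool, ref, sizes=(10, 30, 10))
        report = leakage_check(
            {"reference": ref, "ID": id_p, "MID": mid_p, "OOD": ood_p},
            threshold=0.95,
        )
        assert report["label_pool_violations"] == 0
        assert report["near_duplicates"] == 0

    def test_shared_open_vocab_value_is_reported(self):
        a = SyntheticSample("a", "t1", {"organ": ("lung",)}, {})
        b = SyntheticSample("b", "t2", {"organ": ("lung",)}, {})
        report = leakage_check({"ID": [a], "OOD": [b]}, threshold=1.0)
        assert report["label_pool_violations"] == 1
        assert "lung" in report["violating_values"]["organ"]


class TestBenchmarkStructure:
    def test_vocab_partition_respected_in_strata(self, lexicons):
        ref, pool = generate_benchmark(seed=5, sizes=(10, 30, 10),
                                       n_reference=8, lexicons=lexicons)
        strata = {"ref": ref, "id": pool[:10], "mid": pool[10:40], "ood": pool[40:]}
        for cls_name in ("organ", "disease", "cell_line"):
            seen = {}
            for name, samples in strata.items():
                seen[name] = {s.truth[cls_name][0] for s in samples} - {"unknown"}
            names = list(seen)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    assert not (seen[a] & seen[b]), (cls_name, a, b)
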