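import dataclasses

import numpy as np
import pytest

from adrnet import (
    GeneratorConfig,
    Thread,
    expected_lift,
    generate_corpus,
    generate_corpus_with_truth,
    read_corpus,
    write_corpus,
)
from adrnet.corpus import CorpusError


class TestCorpusIO:
    def test_roundtrip_preserves_order_and_content(self, tmp_path):
        threads = [
            Thread("a", "first post", ("c1", "c2"), timestamp="2016-10-10T00:00:00"),
            Thread("b", "second post", ()),
        ]
        path = tmp_path / "corpus.jsonl"
        write_corpus(threads, path)
        assert read_corpus(path) == threads

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_corpus(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"thread_id": "a", "post": "x", "comments": []}\nnot json\n')
        with pytest.raises(CorpusError, match=":2"):
            read_corpus(path)

    def test_missing_comments_key_reports_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"thread_id": "a", "post": "x"}\n')
        with pytest.raises(CorpusError, match="comments"):
            read_corpus(path)

    def test_duplicate_thread_id_rejected(self, tmp_path):
        path = tmp_path / "dup.jsonl"
        line = '{"thread_id": "a", "post": "x", "comments": []}\n'
        path.write_text(line * 2)
        with pytest.raises(CorpusError, match="duplicate"):
            read_corpus(path)


class TestGenerator:
    def test_pure_pattern_threads_mention_both_or_neither(self, small_lexicon):
        config = GeneratorConfig(
            n_threads=10,
            patterns=((frozenset({"parkinson", "levodopa"}), 0.5),),
            background_rate=0.0,
            lexicon=small_lexicon,
            seed=3,
        )
        _, truth = generate_corpus_with_truth(config)
        assert all(t in (set(), {"parkinson", "levodopa"}) for t in truth)

    def test_zero_threads(self, mixed_config):
        config = dataclasses.replace(mixed_config, n_threads=0)
        assert generate_corpus(config) == []

    def test_determinism_byte_identical(self, tmp_path, mixed_config):
        config = dataclasses.replace(mixed_config, n_threads=50)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(generate_corpus(config), p1)
        write_corpus(generate_corpus(config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_probabilities_rejected(self, small_lexicon):
        with pytest.raises(CorpusError, match="sum"):
            GeneratorConfig(
                n_threads=1,
                patterns=(
                    (frozenset({"parkinson"}), 0.7),
                    (frozenset({"levodopa"}), 0.6),
                ),
                background_rate=0.0,
                lexicon=small_lexicon,
            )
        with pytest.raises(CorpusError, match="background_rate"):
            GeneratorConfig(
                n_threads=1,
                patterns=((frozenset({"parkinson"}), 0.5),),
                background_rate=1.0,
                lexicon=small_lexicon,
            )

    def test_pattern_entity_must_be_in_lexicon(self, small_lexicon):
        with pytest.raises(CorpusError, match="not in lexicon"):
            GeneratorConfig(
                n_threads=1,
                patterns=((frozenset({"quetiapine"}), 0.5),),
                background_rate=0.0,
                lexicon=small_lexicon,
            )


class TestExpectedLift:
    def test_single_shared_pattern_no_noise(self, small_lexicon):
        config = GeneratorConfig(
            n_threads=1,
            patterns=((frozenset({"parkinson", "levodopa"}), 0.5),),
            background_rate=0.0,
            lexicon=small_lexicon,
        )
        assert expected_lift(config, "parkinson", "levodopa") == pytest.approx(2.0)

    def test_disjoint_patterns_with_noise_are_independent(self, small_lexicon):
        config = GeneratorConfig(
            n_threads=1,
            patterns=(),
            background_rate=0.2,
            lexicon=small_lexicon,
        )
        # no pattern mass at all: presence is pure background, hence lift 1
        config = dataclasses.replace(
            config,
            patterns=(
                (frozenset({"parkinson"}), 0.0),
                (frozenset({"levodopa"}), 0.0),
            ),
        )
        assert expected_lift(config, "parkinson", "levodopa") == pytest.approx(1.0)

    def test_closed_form_matches_monte_carlo(self, small_lexicon):
        config = GeneratorConfig(
            n_threads=1,
            patterns=((frozenset({"parkinson", "levodopa"}), 0.2),),
            background_rate=0.1,
            lexicon=small_lexicon,
        )
        value = expected_lift(config, "parkinson", "levodopa")
        # closed form by hand: P(e) = 0.2 + 0.8*0.1 = 0.28,
        # P(a,b) = 0.2 + 0.8*0.01 = 0.208, lift = 0.208/0.28^2
        assert value == pytest.approx(0.208 / 0.28**2)
        # Monte-Carlo cross-check at 10^6 presence draws
        rng = np.random.default_rng(0)
        n = 1_000_000
        pattern_on = rng.random(n) < 0.2
        bg_a = rng.random(n) < 0.1
        bg_b = rng.random(n) < 0.1
        a = pattern_on | bg_a
        b = pattern_on | bg_b
        mc_lift = (a & b).mean() / (a.mean() * b.mean())
        assert value == pytest.approx(mc_lift, rel=5e-3)

    def test_undefined_marginal_raises(self, small_lexicon):
        config = GeneratorConfig(
            n_threads=1,
            patterns=(
                (frozenset({"parkinson"}), 0.5),
                (frozenset({"levodopa"}), 0.0),
            ),
            background_rate=0.0,
            lexicon=small_lexicon,
        )
        with pytest.raises(CorpusError, match="undefined"):
            expected_lift(config, "parkinson", "levodopa")
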