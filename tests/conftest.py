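import pytest

from adrnet import GeneratorConfig, build_lexicon


@pytest.fixture
def small_lexicon():
    """A compact Parkinson-flavored lexicon exercising multiword and
    many-to-one consumer expressions."""
    return build_lexicon(
        [
            ("parkinson", "disease", "pd"),
            ("parkinson", "disease", "parkinsons"),
            ("levodopa", "drug", "l dopa"),
            ("levodopa", "drug", "sinemet"),
            ("ropinirole", "drug", "requip"),
            ("pramipexole", "drug", "mirapex"),
            ("anorexia", "adr", "no appetite"),
            ("anorexia", "adr", "appetite loss"),
            ("anorexia", "adr", "appetite lost"),
            ("nausea", "adr", "feeling sick"),
            ("somnolence", "adr", "sleepy all day"),
            ("tremor", "adr", "shaking"),
            ("dizziness", "adr", "dizzy"),
        ]
    )


@pytest.fixture
def mixed_config(small_lexicon):
    """Generator config with overlapping patterns and background noise."""
    return GeneratorConfig(
        n_threads=2000,
        patterns=(
            (frozenset({"parkinson", "levodopa", "nausea"}), 0.25),
            (frozenset({"parkinson", "ropinirole", "tremor"}), 0.15),
            (frozenset({"levodopa", "somnolence"}), 0.10),
            (frozenset({"dizziness"}), 0.08),
        ),
        background_rate=0.02,
        lexicon=small_lexicon,
        seed=42,
    )
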