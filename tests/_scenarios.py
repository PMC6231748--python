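"""Shared synthetic planted-recovery scenario used by several tests.

One disease, five known drugs that heavily co-mention ADR X with the
disease, three decoy ADRs occurring on their own, and a held-out drug Q
that lists X as a frequent side effect but never appears in the corpus.
A correct pipeline makes X the sole significant ADR, nominates Q, and
excludes the five indicated drugs.
"""

from adrnet import GeneratorConfig, IndicationRecord, SideEffectRecord, build_lexicon

KNOWN_DRUGS = [f"drug{i}" for i in range(1, 6)]
HELD_OUT_DRUG = "drug q"


def planted_scenario(seed, n_threads=2000):
    rows = [("pd", "disease", "pd")]
    for r in KNOWN_DRUGS:
        rows.append((r, "drug", r))
    for adr in ["adr x", "adr y", "adr z", "adr w"]:
        rows.append((adr, "adr", adr))
    lexicon = build_lexicon(rows)
    patterns = [(frozenset({"pd", r, "adr x"}), 0.1) for r in KNOWN_DRUGS]
    patterns += [
        (frozenset({"adr y"}), 0.05),
        (frozenset({"adr z"}), 0.05),
        (frozenset({"adr w"}), 0.05),
    ]
    config = GeneratorConfig(
        n_threads=n_threads,
        patterns=tuple(patterns),
        background_rate=0.01,
        lexicon=lexicon,
        seed=seed,
    )
    side_effects = [
        SideEffectRecord(HELD_OUT_DRUG, "adr x", "frequent", None),
        SideEffectRecord(KNOWN_DRUGS[0], "adr x", "frequent", None),
        SideEffectRecord("drug noise", "adr y", "frequent", None),
    ]
    indications = [IndicationRecord(r, "pd") for r in KNOWN_DRUGS]
    return config, lexicon, side_effects, indications
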