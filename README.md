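# adrnet

Drug repositioning from online-health-community threads via a
lift-weighted disease–drug–ADR heterogeneous network.

## The problem

New indications for approved drugs can be suggested by the adverse drug
reactions (ADRs) they share with the drugs already used for a disease:
when the drugs treating disease *D* all produce ADR *X*, *X* and *D* are
likely connected by a common mechanism, and *other* drugs that also
produce *X* become repositioning candidates for *D*. Patients describe
drugs and reactions in lay language on health forums, so forum threads
are a rich, timely co-occurrence signal for exactly these associations.
`adrnet` is for pharmacovigilance and drug-discovery researchers who
want to run this pipeline end to end on a thread corpus, or to study its
statistical behavior on synthetic corpora with known ground truth.

## The method

1. **Extraction.** A consumer-health-vocabulary lexicon maps lay
   expressions ("no appetite") to preferred terms (*anorexia*), typed as
   drug / disease / ADR. Matching is greedy longest-match over
   normalized text; presence is binary per thread (post + all comments).
2. **Association.** Each thread is a transaction; the strength of a
   cross-type pair is the association-rule lift

   ```
   lift(a, b) = P(a, b) / (P(a) · P(b))
   ```

   with probabilities estimated as thread proportions. Lift 1 means
   independence; pairs with a zero marginal are *undefined*, not 0 or ∞.
3. **Network.** Nodes are drugs, the disease, and ADRs; undirected links
   (drug–ADR, disease–ADR, disease–drug) carry their lift as weight.
   The disease–ADR association score is the sum over all length-2
   metapaths D–R–ADR of `W(D,R) · W(R,ADR)` — the drug is the bridge.
4. **Significance.** Each ADR's path score is tested against the
   remaining scores with a one-sided leave-one-out t test
   (df = m − 2, default α = 0.05).
5. **Repositioning.** Drugs listing a significant ADR as
   frequent/common/postmarketing (or above 10% occurrence) in a
   SIDER-style table become candidates, minus drugs already indicated
   for the disease in a PharmGKB-style table.

The package also bundles the reference tables of the published
Parkinson-disease application of this method (44 nominated drugs, their
literature-evidence flags and original labeled indications) and a
synthetic-corpus generator whose planted co-mention structure has a
closed-form expected lift, used throughout the tests as an analytic
oracle.

## Worked example

```python
import adrnet as a

lex = a.build_lexicon([
    ("parkinson", "disease", "pd"),
    ("levodopa", "drug", "l dopa"),
    ("ropinirole", "drug", "requip"),
    ("nausea", "adr", "feeling sick"),
    ("tremor", "adr", "shaking"),
    ("insomnia", "adr", "cant sleep"),
    ("dizziness", "adr", "dizzy"),
    ("headache", "adr", "head ache"),
])
cfg = a.GeneratorConfig(
    n_threads=3000,
    patterns=(
        (frozenset({"parkinson", "levodopa", "nausea"}), 0.25),
        (frozenset({"parkinson", "ropinirole", "nausea"}), 0.20),
        (frozenset({"levodopa", "tremor"}), 0.10),
        (frozenset({"insomnia"}), 0.10),
        (frozenset({"dizziness"}), 0.05),
        (frozenset({"headache"}), 0.05),
    ),
    background_rate=0.02, lexicon=lex, seed=7,
)
corpus = a.generate_corpus(cfg)
side_effects = [a.SideEffectRecord("quetiapine", "nausea", "frequent", None)]
indications = [a.IndicationRecord("levodopa", "parkinson"),
               a.IndicationRecord("ropinirole", "parkinson")]
result = a.run_pipeline(corpus, lex, side_effects, indications, "parkinson")
print(result.network.node_type_counts())
print([(r.adr, round(r.score, 2), r.significant) for r in result.significance])
print([c.drug for c in result.candidates])
```

prints

```
{'adr': 5, 'drug': 2, 'disease': 1}
[('nausea', 7.0, True), ('tremor', 4.6, False), ('dizziness', 1.39, False),
 ('headache', 1.26, False), ('insomnia', 0.72, False)]
['quetiapine']
```

Nausea is planted as the ADR shared by both Parkinson drugs, so its
disease–ADR path score (7.0, two bridging drugs) dominates the others
and it is the only significant ADR; quetiapine, which lists nausea as a
frequent side effect and is not indicated for Parkinson, is nominated.

The same pipeline is available from the shell:

```sh
adrnet generate --config config.json --seed 7 --out corpus.jsonl
adrnet run --corpus corpus.jsonl --lexicon lexicon.tsv \
    --side-effects sider.tsv --indications pharmgkb.tsv \
    --disease parkinson --alpha 0.05 --out results/
```

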