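# Methods

## Model and assumptions

The pipeline treats a forum thread — one original post plus all of its
comments — as the transaction unit of a market-basket model. A thread is
too long to pin a drug and a reaction to the same sentence, and a single
post or comment is too short to carry context, so presence is binary at
thread level: the transaction is the *set* of preferred terms mentioned
anywhere in the thread. Association strength between two items is the
association-rule lift, the ratio of the observed joint thread proportion
to the product of the marginals. Only cross-type pairs (drug–ADR,
disease–ADR, disease–drug) are counted, because those are the three link
types of the network the method builds.

The heterogeneous network has the three node types and three undirected
link types, each link weighted by the lift of its endpoints. The
disease–ADR association is the unnormalized sum, over every length-2
disease–drug–ADR metapath, of the product of the two link weights. Drugs
are the only admissible bridge: an ADR profile is caused by the drugs
taken for the disease, so a direct disease–ADR link (which reflects
symptom overlap as much as pharmacology) is kept in the network and
reported, but never contributes to the path score. A `normalize` flag
divides the score by its path count; it is off by default because the
unnormalized sum is the model — well-bridged ADRs *should* score higher.

Key assumptions, and what violates them: thread-level co-occurrence is a
proxy for a real drug–reaction link (violated by discussions that merely
compare drugs); lift treats all threads as exchangeable (violated by
duplicate or near-duplicate threads); dictionary extraction assumes the
lexicon covers the ways patients write (misspellings and novel slang are
missed — there is deliberately no fuzzy matching by default).

## Significance of disease–ADR scores

The path scores have no external null distribution, so each ADR is
tested against the others: a one-sided leave-one-out outlier t test,

    t_i = (s_i − mean(s_−i)) / (sd(s_−i) · √(1 + 1/(m−1))),  df = m − 2,

significant when the upper-tail p falls below α (default 0.05,
conventional). The test needs m ≥ 3 scored ADRs. When the hold-out
scores have zero spread the statistic degenerates and the limiting
p value is used (0 above the hold-out mean, 1 below, 0.5 at equality);
this makes an all-equal score vector mark nothing, while a single
dominant score over a flat remainder is maximally significant. Two
variants are exposed and off by default: a user-supplied reference mean
(`null_mean`) replacing the hold-out mean, and Benjamini–Hochberg FDR
adjustment of the per-ADR p values (the baseline procedure applies no
multiplicity correction).

## Candidate nomination

A drug is nominated when a side-effect record passing the frequency
gate — class `frequent`, `common` or `postmarketing`, or occurrence
percentage strictly above 10 — names a significant ADR, and the drug has
no recorded indication for the target disease. Frequency classes are
normalized case-insensitively; unparseable class strings become
`unknown` and fail the gate, so dirty rows can only lose candidates,
never invent them. Side-effect ADR names are matched to lexicon
preferred terms by exact normalized-string equality. Candidates are
ranked by number of supporting ADRs, then aggregate disease–ADR score,
then name; the unranked candidate *set* of the original procedure is the
full list.

## Synthetic corpus generator

The generator emulates the co-mention statistics of a crawled thread
corpus with a model simple enough to integrate in closed form: each
thread draws at most one entity pattern from a categorical `{q_k}`
(residual mass → no pattern), then every universe entity independently
switches on with background rate ε, and each present entity is realized
as one uniformly chosen surface expression inserted at a random word
boundary of the post or a comment. One pattern per thread plus
independent noise gives the exact expected lift by inclusion–exclusion
(see `expected_lift`), which is what makes analytic recovery tests
possible. Defaults — 1–4 comments per thread, 6–14 neutral filler words
per text unit, a filler vocabulary disjoint from any fixture lexicon —
are chosen to resemble short forum exchanges while keeping extraction
exactly invertible on generated text.

What the generator does *not* emulate: misspellings, negation ("no
tremor"), cross-thread duplicates, user identity, temporal structure,
and correlated background mentions. Passing the planted-recovery tests
therefore demonstrates correctness of the counting, scoring and
selection machinery under clean co-mention signal — not robustness of
extraction on real, noisy forum text.

## Numerical choices and degenerate inputs

- Lift with a zero marginal is undefined (flagged, excluded from
  ranking), never 0 or ∞: a 0/0 has no evidence behind it.
- `build_network` keeps every defined lift above `min_weight` (default
  0); `min_weight=1` restricts to positively associated pairs.
- Ties in candidate ranking break lexicographically so output order is
  reproducible; path lists are sorted by descending product.
- Text normalization is lowercase + punctuation→space + whitespace
  collapse, applied identically to lexicon expressions and thread text;
  all spans are in normalized coordinates (a single coordinate system).
- The generator is fully driven by one `numpy` generator seeded from the
  config, so identical configs produce byte-identical JSONL corpora.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 100 random corpora of up to 50 threads and
10 entities, and 100 random networks of up to 12 nodes — small enough to
compare against exhaustive rescans and path enumeration at full floating
precision. Lift-recovery checks generate 20,000-thread corpora per
config and compare the empirical lift of every planted cross-type pair
to the closed form within 3 bootstrap standard errors (200 thread
resamples). The end-to-end planted-recovery study uses 2,000-thread
corpora across 10 seeds; at that size the dominant ADR's path score
separates from the decoys by an order of magnitude, so recovery is
stable seed to seed.

## Known limitations

- Exact dictionary matching only; recall on real forum text depends
  entirely on lexicon coverage.
- The leave-one-out test is an interpretation of "test each score
  against the score distribution"; with very few scored ADRs (m close
  to 3) its power is poor and df = m − 2 makes p values coarse.
- Lift is noisy for rare items (small marginals inflate it); no minimum
  support threshold is applied by default, matching the baseline
  procedure, so rare-item links should be read with care.
- Candidate quality is bounded by the side-effect and indication tables
  supplied; name mismatches between those tables and the lexicon
  silently reduce support (exact-match policy).
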