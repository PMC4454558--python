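# Methods

This note documents the modelling decisions behind `sentsim`: what each
stage assumes, the parameters that matter, how degenerate inputs are
handled, and what the bundled synthetic data can and cannot demonstrate.

## Preprocessing

Every linguistic layer is produced by deterministic rule systems shipped
with the package (manifest string `sentsim-rules/1.0`, echoed in CLI logs):

* **Tokenisation.** Lower-cased word tokens; punctuation-only tokens are
  dropped; intra-word hyphens and apostrophes are kept, so compounds like
  `M-ADL` or `intra-operative` stay single tokens. This dialect is pinned
  because it reproduces the worked example's token counts (20/19) and
  14-word intersection; sentence-pair measures are sensitive to the
  dialect, so it is not configurable.
* **POS tagging.** Closed-class lexicons (determiners, prepositions,
  coordinators, subordinators, pronouns, modals, be/have/do) plus suffix
  heuristics (-ly → RB, -ing/-ed → verb forms with an auxiliary-context
  VBN rule, adjectival suffixes, plural -s) and a small open-class verb
  lemma list. Unknown hyphenated words tag as adjectives; the default is
  noun. This is a coarse tagger: its purpose is stable, deterministic
  effective-word marking and clause chunking, not treebank accuracy.
* **Lemmatisation.** Irregular-form table (be/have/do paradigms, common
  strong verbs, irregular plurals) plus POS-guided suffix stripping with
  e-restoration heuristics (`observed → observe`, `reported → report`,
  `disturbances → disturbance`). Unknown words map to themselves.
  Stemming is a full implementation of the classic Porter algorithm.
* **Effective words.** Two policies. `content` (default) removes the
  closed classes and the negative particle, keeping nouns, verbs,
  adjectives and adverbs. `nouns_verbs` keeps only nouns and verbs
  (including the copula), which is the reading under which the worked
  example's printed effective-lemma sets are reproduced exactly. The two
  policies exist because the source formulation is ambiguous about
  adjectives/adverbs; the choice is a constructor/CLI switch.
* **Polarity.** NegEx-style trigger matching (no, not, neither, nor,
  without, never, …) with sentence-wide scope. Polarity is a pure function
  of the token sequence.
* **Clauses.** Clause boundaries are coordinating conjunctions joining two
  finite-verb segments where the right segment has a noun/pronoun before
  its first verb group; this approximates the sentential S nodes of a
  constituency parse without requiring a parser. Within a clause, the
  first verb group is the predicate; tokens to its left/right form the
  pre-/post-verb components. A verbless input falls back to a single
  clause with an empty predicate and a logged warning, never silently.
* **Reduced parse tree.** Each clause is collapsed to its NP/VP leaf
  sequence (noun chunks and verb groups in order) under an S node, all
  under ROOT. Trees serialise to Penn-style bracket strings.

## Feature measures

All 34 features are symmetric in the pair and clipped/bounded to [0, 1].
Notable conventions:

* **Naive overlap** uses multiset matching without replacement (each token
  matches at most once), which reproduces the 14/20 worked-example count.
  A pair that is empty on both sides raises a degenerate-pair error
  rather than returning 0, so corpus-level bugs surface early.
* **Window overlap** counts equal k-gram position pairs for every window
  size k ≥ 2 and normalises by C(n, 2) with n the shorter length. That
  normaliser is not a strict upper bound, so the value is capped at 1.
* **Skipped bigrams** are ordered pairs (i < j) over content words;
  the ratio normalises by the larger bigram set.
* **Reduced-tree overlap** counts identical subtrees (recursive
  label-and-child-order equality, enumerated at every node) per clause
  pair and normalises by the product of clause *word* counts, then by the
  product of clause counts. With this normaliser the measure is neither 1
  on identical sentences nor maximal there; it is implemented as
  formulated, the raw value is logged, and the feature value is clipped
  to [0, 1]. Tests treat it as symmetric-and-bounded only.
* **Role similarity** averages word-pair similarities over all cross
  pairs of role bags: Lin and Wu–Palmer (averaged, best-matching synset
  pair) for pre-/post-verb bags, shared-frame indicator for predicates.
  A word missing from a backend contributes 0 *without* shrinking the
  denominator, keeping the normalisers as formulated; consequently the
  double-sum role and sentence-wide semantic means are exactly 1 only for
  single-word bags.
* **Lin similarity** uses the standard form 2·IC(lcs)/(IC(s₁)+IC(s₂));
  it is 0 when the only common ancestor is the zero-IC root.
* **Lesk** scores each candidate sense by gloss–context token overlap
  (context = the whole sentence, minus the target word); ties break to
  the lowest sense rank.
* **Category vectors** for the cosine variant are positional one-hot
  matrices over the union category vocabulary, zero-padded to equal row
  count; Frobenius cosine. Positional alignment (rather than sorted) was
  chosen to retain compositional order information.
* **Term-matrix cosine** stacks effective-word vectors in sentence order,
  zero-pads the smaller matrix at the bottom, and takes the Frobenius
  cosine; the raw value lies in [-1, 1] and is clipped at 0 in the
  feature vector.

## Lexical backends

Three contracts: a taxonomy with IC values, depths, lexicographer
categories, glosses and related synsets (hypernym + hyponyms + siblings);
a lemma → frame-set lexicon; and a fixed-dimension term-vector store with
top-k cosine neighbours (`associated_terms_k`, default 20). IC values are
consumed from a precomputed table, not recomputed. Real WordNet/FrameNet/
vector-store resources can be supplied through the documented text formats
(JSON taxonomy, TSV IC table, TSV frame lexicon, word2vec-style text
vectors); the core test suite runs entirely on the bundled mini-lexicon.

The mini-lexicon is a pure function of its seed: a fixed 25-synset,
4-level clinical-trial flavoured noun taxonomy with 7 lexicographer
categories and engineered polysemy for Lesk tests; a 40-lemma frame
lexicon over 14 frames; and 8-dimensional term vectors clustered by
taxonomy branch so taxonomic neighbours are also distributional
neighbours. The seed controls IC jitter and vector noise only; topology
and vocabulary are fixed.

## Regression ensemble

* Bagging (default 10 estimators) over variance-reduction regression
  trees with `min_samples_leaf = 2` — the leaf-size analogue of
  reduced-error-pruned trees.
* Random subspace (10 members, 50% of features, no bootstrap) over a
  distance-weighted k-nearest-neighbour regressor (k = 10). This is a
  documented stand-in for entropic-distance instance-based learning,
  whose blend parameter has no portable analogue; the ensemble scheme,
  not the instance learner's internals, is the point.
* Regression by discretisation: 10 equal-width bins over [1, 5], a
  150-tree random-forest classifier, prediction = probability-weighted
  per-bin mean of the training targets (empty bins fall back to the bin
  midpoint).

The ensemble prediction is the arithmetic mean of the three sub-model
outputs, clipped to [1, 5]. All sub-model seeds derive from a single
`random_state`, so fixed seeds give bit-identical models. Training
requires at least 10 pairs, scores inside [1, 5], and a non-constant
target. Ablation runs 10-fold cross-validation stratified by score bin
and reports pooled out-of-fold Pearson for leave-one-group-out and
group-only variants over the 8 registry feature groups (7/6/3/2/7/2/5/2
features).

## Evaluation conventions

Deviation bins follow the interval labelling [-2.5, -2], (-2, -1.5], …,
(2, 2.5]: the first bin is closed, the rest half-open, so a deviation of
exactly 0 falls in (-0.5, 0]. Deviations outside ±2.5 go to a flagged
overflow bin with a warning. The score-range split partitions gold scores
into [1,2), [2,3), [3,4), [4,5]; ties (prediction = gold) count as
overestimates so the under/over counts always sum to the range count.
Inter-annotator statistics use pairwise Pearson with an empty diagonal;
the inverse agreement is the mean per-item standard deviation of ratings,
population formula by default (switchable to the sample formula).

## Synthetic pairs

The generator emulates the one property the feature set is built around:
graded lexical overlap driving graded relatedness. Each sentence carries 8
content words from the mini-lexicon vocabulary and 4 interspersed function
words; a pair shares a content fraction ρ drawn from {0, 0.25, 0.5, 0.75,
1}, and the gold score is clip(1 + 4ρ + ε, 1, 5) with ε ~ N(0, 0.5) by
default. The function words are there because real sentences contain
stopwords that dilute the naive overlap — without them the word-overlap
baseline would be an oracle for the gold score and no model could beat it.

What the generator does **not** emulate: grammatical English (sentences
are shuffled word lists, often verbless), paraphrase without lexical
overlap, negation flips, clause-structure variation, or domain
terminology outside the mini-lexicon. Passing the synthetic recovery test
therefore shows that the pipeline extracts overlap-correlated signal and
that the ensemble regresses it out of sample — it does not certify
human-judgement-level accuracy on natural corpora. The recovery protocol
trains on 375 of 500 generated pairs and evaluates on the held-out 125, a
size chosen to keep the full suite fast on one CPU while leaving the
correlation estimate stable.

## Known limitations

* The rule tagger and clause chunker are approximations; parser-dependent
  measures (reduced-tree overlap, role decomposition) inherit their
  errors. The worked example's window-overlap and tree-overlap magnitudes
  are tokeniser/parser-dependent and are treated as documentation
  examples, not contracts.
* Negation detection is trigger-based with sentence scope; it has no
  notion of scope boundaries or pseudo-negation.
* The mini-lexicon covers a small vocabulary by design; on out-of-lexicon
  text all backend-dependent features degrade to 0 and the model leans on
  the syntactic family.
* Verbs are covered by frames only; the taxonomy is nominal. Mixed-POS
  word pairs contribute 0 to the semantic means.
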