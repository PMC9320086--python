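# Methods

## The Semantic Depth Index

The package quantifies how *specific* the words of a narrative are by
their taxonomic depth in a WordNet-style hypernym hierarchy.  Synsets
(sets of synonymous lemmas) are the nodes; directed "is-a" links run from
hyponym to hypernym; each word class (noun, verb, adjective, adverb) is
rooted in its own tree or forest.  The Semantic Depth Index of a word is

    SDI(w) = number of hypernym edges on the shortest path from the
             synset of w up to any root of its word class,

equivalently the number of nodes separating the word from the root, root
excluded.  On the canonical chain *entity -> ... -> animal -> ... -> cat*,
SDI(animal) = 3 and SDI(cat) = 10; a bare top-level term like *thing*
scores 1.  Low mean SDI in connected speech marks a preference for
generic, superordinate vocabulary — the characteristic narrative profile
of the semantic variant of primary progressive aphasia (svPPA), in
contrast to the logopenic variant (lvPPA).

Conventions where the definition leaves room:

* **Multiple hypernym paths** (DAGs): the minimum edge count to any root
  is used — deterministic, and the natural reading of "separation".
* **Polysemy**: the default sense policy is `first_sense` (sense rank 1 in
  the lemma index, i.e. registration order in the taxonomy file);
  `min_depth`, `max_depth` and `mean_depth` are exposed for sensitivity
  analysis.  `mean_depth` reports an exact rational value.
* **Multiword lemmas** ("come out") are matched as exact strings; the
  transcript layer is responsible for chunking.
* **Missing words** are skipped from the mean and surfaced in the
  coverage report; they are never imputed.

## Feature profiles

Transcripts arrive fully annotated (word class, paraphasia tags,
well-formedness, word-finding events); the package does no tagging of its
own, which keeps the pipeline language-agnostic.  Per speaker (tasks
merged in a fixed elicitation order) the profile row holds:
distinct-lemma (type) counts of nouns, verbs and adjectives; token counts
of open- and closed-class words; the well-formed sentence count;
phonemic/semantic paraphasia, anomic-pause and conduite-d'approche
counts; mean occurrences = open tokens / open types (kept as an exact
fraction, so the identity `mean_occurrences x types = tokens` holds
exactly); mean lexical frequency of use over types found in the norms;
and mean SDI.  Mean SDI is **type-weighted by default** (each distinct
word counted once, however often it recurs); token weighting is a flag.
Fillers and false starts are excluded tokens; adverbs count toward
open-class totals but have no dedicated type column.

## Statistics

Group comparisons use the two-sided Mann-Whitney U test with midranks:
the null distribution is enumerated exactly when the pooled sample has at
most 25 observations and no ties, otherwise a normal approximation with
tie and continuity corrections is used (both modes are labelled in the
output).  The reported U is min(U1, U2).  SDI-thickness associations are
Pearson correlations with two-sided p from the t transform (n-2 df).
Multiplicity is handled by Benjamini-Hochberg step-up adjustment within
two pre-declared families: the 68 (region x hemisphere) thickness
contrasts of a clinical group against controls, and the 28
semantic-network ROI correlations.  Significance is declared at adjusted
p < 0.05 (configurable q).

The semantic-network family comprises 14 bilateral Desikan regions
associated with conceptual processing: temporal pole (standing in for the
anterior temporal lobe, which has no dedicated Desikan label), superior /
middle / inferior temporal, fusiform, parahippocampal, entorhinal, pars
opercularis (the inferior-frontal-gyrus subdivision), caudal middle
frontal, superior frontal, precuneus, supramarginal, posterior cingulate
and rostral anterior cingulate.

## The synthetic cohort

Clinical narrative and imaging data are not redistributable, so a
generator produces all four pipeline inputs with the structure the
analysis assumes.  Defaults are the study conditions: 6 svPPA, 16 lvPPA,
30 controls.

**Taxonomy.** Complete binary hypernym trees with unique pseudo-word
lemmas: depth 8 for nouns (511 synsets), 6 for verbs, 5 for adjectives,
4 for adverbs.

**Lexical choice.** Open-class lemmas are drawn within each word class
with probability proportional to `exp(theta_g * depth)` — the minimal
one-parameter family in which a lower group weight produces
stochastically shallower (more generic) word choices.  The class mix is
noun 0.40 / verb 0.38 / adjective 0.14 / adverb 0.08.  Each group's theta
is calibrated once by root-finding so that the *expected type-weighted
mean depth at the group's token budget* matches the published group mean
SDI (svPPA 3.99, lvPPA 4.42; controls are set to 4.60).  The type-level
expectation matters: shallow words recur heavily under negative theta and
collapse into single types, so a token-level calibration would overshoot.
Observation probabilities enter as `1 - (1-p)^N` with N the expected
open-token count.

**Counts and events.** Open/closed token totals are normal draws at the
published group means/SDs (svPPA 285.83/78.04 open, 349.33/120.52 closed;
lvPPA 161.81/55.09 and 271.07/100.95; nominal values for controls).
Paraphasias, anomic pauses and conduites d'approche are independent
Poissons at the published group means, with no within-speaker
correlation.  Utterances are 3-7 tokens long; well-formedness is
Bernoulli at a rate chosen so the expected well-formed count matches the
published group means given the token budget (0.91 svPPA, 0.62 lvPPA).
Filler and false-start rates (12/4 svPPA, 15/6 lvPPA per speaker) are
nominal: the study reports their presence, not counts.

**Frequency norms.** Synthetic frequency-of-use values decay
log-linearly in depth (`fpm = exp(ln 2000 - 0.25 d + eps)`,
`eps ~ N(0, 0.8)`): generic words are frequent, which reproduces the
scale (hundreds per million) of published mean FU without targeting its
exact group values.

**Thickness.** Regional values are normal draws at the published
per-group (region, hemisphere) means/SDs.  The SDI association is planted
in designated ROIs (default: the eight ROIs reported as associated) in
one of two modes:

* `group_anchored` (default): each clinical group keeps its published
  mean/SD exactly; the within-group residual is coupled to the speaker's
  mean SDI with correlation `link_r` (default 0.4).  Pooled clinical
  correlations then also pick up the between-group component, as in real
  data.
* `pooled`: a single linear model across the pooled clinical sample with
  pooled target correlation `link_r`; at `link_r = 0` the designated ROIs
  are drawn from the pooled baseline, exactly independent of SDI.  This
  mode drives the parameter-recovery and null-calibration experiments.

**Determinism.** One master seed; every stage derives its stream from
fixed integer labels (`[seed, stage, index]`), so a seed reproduces
byte-identical output files within this implementation.

**What the generator does not emulate.** No natural language (pseudo-word
lemmas, no syntax or discourse structure), no within-speaker correlation
between error types, no covariance between neighbouring cortical regions,
no age/sex/education structure.  Passing simulation tests therefore
demonstrates that the *pipeline* recovers planted structure at realistic
sample sizes and noise levels — not that the clinical findings themselves
generalize.

## Verification experiment sizes

The statistical kernel is checked against brute-force oracles (pair
counting, full permutation enumeration, the classical step-up rule) on
500 random cases each.  Correlation recovery uses 500 replicate cohorts
of the imaging subsample (6 + 15 clinical subjects; one lvPPA patient had
no MRI) with planted pooled r = 0.66, asserting mean estimated r within
±0.05; null calibration uses 200 replicates with r = 0, asserting an
average FDR-significant fraction at or below 0.05.  Detection power for
the left-entorhinal atrophy contrast (svPPA 1.77 ± 0.27 vs controls
3.20 ± 0.42 mm, n = 6 vs 30) is at least 95% over 200 replicates.

## Known limitations

* The per-patient SDI scores bundled under `data/` are synthetic
  reconstructions matching published group summaries; individual values
  are not real measurements.
* Per-word SDI values depend on the taxonomy edition and sense policy;
  absolute depths are not comparable across taxonomies, only within one.
* Adjective/adverb scoring requires the taxonomy file to supply is-a
  links for those classes (standard WordNet distributions have no
  adjective hypernymy); unscored classes are excluded from mean SDI and
  logged via the coverage report.
* Group contrasts are unadjusted rank tests; no covariate adjustment,
  partial correlation or vertex-wise analysis is attempted.
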