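# Methods

This note documents the models, parameter choices and numerical conventions
behind litatlas, and what the packaged synthetic study does and does not
establish.

## Cleaning and labeling rules

Records are kept when they are English, have a non-empty abstract whose
cleaned single-paragraph text is 250–4,000 characters long (inclusive at both
ends — "shorter than / longer than" excludes only strict violations) and ends
with `.`, `?` or `!`. Cleaning happens first: section labels are dropped,
texts joined with single spaces, `(ABSTRACT TRUNCATED AT <n> WORDS)` phrases
removed, whitespace collapsed; the length and sentence-ending checks apply to
the cleaned text. Unfinished abstracts are excluded because they otherwise
form artifact clusters in learned representations. Duplicate PMIDs are
dropped (first kept occurrence wins; `dedupe=False` disables this).
Rejections are data, not errors: `filter_records` returns per-reason counts
that always sum to input minus kept.

Journal labels use 38 discipline keywords matched as substrings of the
journal title. "Capitalized or not" is implemented as full case-insensitive
matching by default; `case_mode="first_letter"` restricts to the literal
`term`/`Term` pair. Word boundaries are not required (substring semantics);
both choices are defensible and the mode is exposed. Multi-keyword titles are
resolved by one seeded uniform draw per record, so labeling is deterministic
given the seed and seed-independent in the absence of ties.

Author forenames are the first whitespace-delimited word of the forename
field after hyphen→space replacement; single-letter results (initials) are
discarded. Gender inference is a lookup of (name, year) in a pluggable
table of proportion-female values with years clamped to the covered range
(1930–2012 in the packaged table); `female` iff the proportion is ≥ 0.5, so
an exact tie resolves to female. The packaged table is synthetic
illustration data with a "Leslie"-style majority flip, not SSA records;
substantive analyses must supply a real table.

## Vectorization

Tokenization is scikit-learn's default: lowercase, tokens are runs of ≥ 2
word characters, vocabulary sorted alphabetically; no stop-word removal. The
TF-IDF weighting is the log-scaled variant

    X_ij = (1 + ln C_ij) · (1 + ln((1 + n) / (1 + df_j)))  for C_ij > 0

with rows scaled to unit l2 norm afterwards; zeros stay zero and all-zero
rows are left unnormalized. The implementation is direct sparse arithmetic
and is cross-checked in the tests against both a per-entry hand evaluation
and scikit-learn's `TfidfTransformer(sublinear_tf=True)`, which computes the
same quantity.

Truncated SVD returns scores U·S. Singular vectors are sign-ambiguous; signs
are canonicalized by making each component's largest-magnitude loading
positive, so results are deterministic across solvers (ARPACK for sparse
input, LAPACK otherwise). Optional row normalization of the scores makes
Euclidean neighbor search equivalent to cosine similarity on the raw scores.
Whitening uses the SVD of the centered matrix and drops directions whose
singular value falls below 1e-10 of the largest (rank-deficient covariance
cannot be whitened; the output then has fewer columns).

## The embedding

Affinities are uniform on the exact kNN graph: w_j|i = 1/k for the k = 10
nearest neighbors, symmetrized as p_ij = (w_j|i + w_i|j) / (2n). This
matrix sums to exactly 1, is symmetric with zero diagonal, and each row has
at least k nonzeros. (The upper bound is k + in-degree, which exceeds 2k at
hub points — kNN in-degree is unbounded — so no 2k bound is enforced.)

The optimizer minimizes KL(P‖Q) with the Student-t kernel
q_ij ∝ 1/(1 + ‖y_i − y_j‖²). Defaults: 2,250 iterations; the first 250
multiply the attractive term by an exaggeration factor annealed **linearly**
from ρ = 12 to 1 (no abrupt switch; the linear ramp is our choice where only
"annealing" is specified), followed by 2,000 plain iterations with no late
exaggeration. Learning rate n/12; momentum 0.5 during the exaggeration phase
and 0.8 after; per-coordinate gain adaptation (×0.8 on sign agreement, +0.2
otherwise, floored at 0.01); iterates recentered every step. The gradient is
implemented in the convention where the constant factor is absorbed into the
learning rate. Initialization is the first two principal components with
signs canonicalized and the first coordinate scaled to standard deviation
1e-4, the usual convention for stable early exaggeration. With exact
repulsion the whole procedure is deterministic; reruns are bit-identical.

Repulsive forces are computed exactly in O(n²) by a numba kernel (~0.03 s
per iteration at n = 5,000 on one core), which is the intended regime for
this package (n up to a few 10⁴). `tsne_embed(repulsion=...)` accepts a
callable so an approximate backend (e.g. interpolation- or tree-based) can
be plugged in; its contract is a final KL within 5 % of the exact mode,
checkable directly at n ≤ 2,000. The KL trace is logged every 50 iterations
plus at the first post-exaggeration iteration and the final one, always with
ρ = 1 (the unexaggerated objective), so the trace is comparable across
phases.

The t-SNE objective is invariant to rotations and axis flips. Orientation
alignment evaluates all four (±x, ±y) sign pairs over the ids shared with a
reference embedding and keeps the pair maximizing the summed per-axis Pearson
correlation; zero-variance axes contribute 0, and ties keep the earlier pair
in (+,+), (+,−), (−,+), (−,−) order.

## kNN statistics

All statistics use exact neighbors (chunked brute force over scipy `cdist`)
with deterministic tie handling: equidistant candidates resolve to the lower
index (stable sort), and majority-vote ties resolve to the nearest neighbor
carrying a tied label. The query point is never its own neighbor. Squared
Euclidean ordering is the default; cosine is selectable and is what
row-normalized SVD scores effectively use.

- **Label accuracy**: test papers are sampled from the labeled subset;
  neighbors are searched among labeled non-test papers; the prediction is
  the majority label of the k = 10 neighbors. Chance level = stratified
  random guessing from the empirical label distribution (→ Σ p² for label
  shares p).
- **Year RMSE**: prediction is the mean year of the k neighbors; chance mode
  draws k = 10 uniform training papers instead. For tightly clustered years
  with within-cluster noise σ the kNN predictor's RMSE approaches
  σ·√(1 + 1/k); the chance predictor approaches σ_pop·√(1 + 1/10).
- **Recall**: mean |kNN_high ∩ kNN_low|/k over a sampled subset; for a
  random layout its expectation is k/(n−1).
- **Isolatedness**: mean fraction of a corpus member's neighbors inside the
  corpus, neighbors searched over the whole dataset; the subsample (default
  5,000) is capped at the corpus size. For a uniformly mixed mask of m
  members the expectation is (m−1)/(n−1).
- **Overlap by year**: per calendar year, up to 500 source-corpus papers are
  sampled; each contributes the fraction of its k high-dimensional neighbors
  carrying the target label; the yearly mean is returned unsmoothed
  (smoothing belongs to the trends module).
- **Region fractions**: boundary-inclusive point-in-box, or point-in-polygon
  via shapely `covers`.

Default subsample sizes (5,000 high-dimensional / 10,000 2-D test points,
5,000 per corpus for isolatedness) follow common practice at corpus scale;
the packaged study uses 1,000 at its 6,000-paper size.

## Trends

Yearly fractions carry Wilson 95 % intervals. A predicate may return None to
drop a record from the denominator — gender fractions count only
gender-resolved papers. The terminal year of a snapshot is incomplete and
can be excluded. Smooth trends are penalized cubic B-spline GAMs
(statsmodels `GLMGam`) with publication year as the sole predictor: 6 basis
functions for Gaussian-identity fits, 12 for binomial-logit fits. The
smoothing weight is selected by k-fold (default 3) cross-validated grid
search over 10^−2…10^6, minimizing held-out deviance; the rows attaining the
minimum and maximum year stay in every training fold so the spline knots
span the held-out years. Intervals are pointwise 95 % on the link scale,
transformed through the inverse link (a curve-wise band is not attempted).
Note the derivative penalty's null space is linear, so the
infinite-smoothing limit is the best straight line, which coincides with the
constant fit only for trendless responses.

## The synthetic study

The generator draws abstracts as bags of words from per-topic vocabularies
mixed with 40 % shared stop-words (≈ 90 words, ≥ 250 characters, ending in a
period), journal titles containing the topic keyword, years from per-topic
Gaussians rounded and truncated to 1975–2021, author forenames from
majority-gender pools with a per-topic, year-interpolated female proportion,
and Bernoulli retraction flags. Vector mode skips text and draws
unit-variance spherical Gaussians around centers placed pairwise
`cluster_separation` standard deviations apart (a regular simplex when the
dimension allows it, approximate sphere placement otherwise). One global
seed spawns independent child streams per stage, so corpora are bit-identical
across runs.

The packaged study fixes six topics: virology, a covid-like topic (year
center 2020.5, sd 0.8 — a recent burst), neuroscience, genetics (whose
vocabulary includes the token "machine learning"), surgery, and a cancer
topic with an 8 % retraction rate against a 0.5 % background (paper-mill-like
enrichment); female authorship rises from roughly 15 % to 55 % over
1975–2021 with surgery lower throughout. Adjacent disciplines share a few
bridge terms so cross-topic neighbors are possible at all. Study sizes —
6,000 papers, SVD to 50 dimensions, k = 10, test sets of 1,000 — keep a full
run in the minutes range on one core while leaving every estimate's Monte
Carlo error far below the effects being measured.

What the generator does **not** emulate: natural language (word order,
syntax, polysemy), heavy-tailed topic sizes and vocabulary growth,
inter-topic gradation (real disciplines overlap far more than disjoint
vocabularies do), citation structure, and affiliation metadata. Consequently
the study corpus separates essentially perfectly — label accuracy near 100 %
against the ~65–70 % typical of real biomedical corpora — and passing tests
demonstrate correctness of the computations and the expected qualitative
orderings (2-D accuracy tracks high-dimensional accuracy; isolated topics
score high; enriched regions show enriched flag fractions), not quantitative
performance on real text.

## Known limitations

- Exact O(n²) repulsion bounds practical embedding size; no approximate
  repulsion backend ships, only the hook and its contract.
- The "approximate" kNN mode delegates to scikit-learn's tree-based search,
  which is exact on these metrics (it trivially satisfies the ≥ 95 % recall
  contract); a true ANN index would be needed beyond ~10⁵ points.
- The name–gender table is synthetic and binary by construction; inference
  quality on real names is entirely a property of the table supplied.
- GAM interval coverage is pointwise, not simultaneous.
- TF-IDF vocabulary handling targets desk scale; no out-of-core paths.
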