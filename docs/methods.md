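# Methods

## The overlap model

Two entities annotated with property sets of sizes `m` and `n` sharing
`d` properties, from a universe of `N` distinct properties, define an
overlap `(m, n, d; N)`.  All scoring is a function of this triple.  Two
derived coordinates drive the analysis: the average expansion ratio
`R = sqrt(m·n)/d` and the imbalance `r = max(m,n)/min(m,n)`; their valid
domain is `R ≥ 1`, `1 ≤ r ≤ R²`.  Under independent uniform draws the
expected intersection is `λ = m·n/N`.  An overlap is a *real* overlap
when `d > λ` (strictly); as a region of the d-R plane this is the area
below the boundary curve `d = N/R²`.  Cases with `d = 0` are excluded
from scoring and from the characteristic-parameter space: readers emit
them, the scorer skips them, and a `--min-d` flag can raise the floor.

## Classical scores

Jaccard, Ochiai and the overlap coefficient are the standard similarity
forms.  Mutual information is the 2×2 contingency MI (cells
`d, m−d, n−d, N−m−n+d`) in nats; it is kept for completeness but treated
as non-normative, because the reference table's printed MI column is not
reproduced by the standard 2×2 MI in any common log base (e.g. the
strongest reference case evaluates to ≈0.057 bits against a printed
0.1000), and no alternative formula consistent with all six printed
values could be identified.  Its qualitative properties (zero at
independence, symmetry, ordering of clearly different cases) are tested
instead.

Poisson, hypergeometric and binomial scores are `-log10` of *point*
probabilities (the mass at exactly `d`), not tail sums: the choice is
pinned by exact reproduction of the integer reference scores for the
asymmetric case (m=625, n=100, d=100), where tails and points differ
visibly in other conventions.  The same case pins the binomial
convention: trials = `max(m, n)`, success probability `min(m, n)/N`
(the min-trials variant misses the printed value by ~38 in log10 units).
Log base 10 throughout; natural log over-predicts the printed columns by
a factor ln 10.

The hypergeometric and binomial scores assemble log-gamma terms
directly, so every case yields a finite score; the cells that underflow
in probability-first arithmetic (reported as "Inf" by naive pipelines)
come out as large finite values (e.g. 338/389 for the strongest
reference case).  The Poisson score always uses the three-term Stirling
form — that closed form *is* the model, with error below
`1/(12·d·ln 10)` versus the exact mass (the test suite grants a 1e-9
numerical slack on this analytic bound for the double rounding of
~1e5-magnitude intermediate terms).

## OScal

`OS = Ps + M_J − M_r`, all in `-log10` units.

**Basal score.**  `Ps` is the Stirling-Poisson score evaluated at an
enlarged expectation.  The enlargement is parameterized as a geometric
pull of `λ` toward the observed count:

```
ψ  = w_coef · (R² − 1)^w_exp_r / d^w_exp_d
w  = ψ / (1 + ψ)                     ∈ [0, 1)
λ' = λ^(1−w) · d^w                   (coefficient c = λ'/λ = (d/λ)^w)
```

This form was chosen over a free multiplicative coefficient because it
saturates: `λ'` can approach but never overshoot `d`, so the basal score
decreases monotonically toward its floor `½·log10(2πd)` instead of
re-inflating deep in the small-d/large-R corner, and `Ps ≤ P` holds
everywhere within the boundary.  Beyond the boundary (`d < λ`) the same
pull shrinks `λ'` toward `d` from above, which also caps the spuriously
huge Poisson scores of far-below-expectation overlaps.  `w` grows with
`R` and decays with `d`, so the coefficient is large exactly for small,
high-expansion overlaps and tends to 1 as `d` grows.

**Correction items.**  `M_J = a·exp(−d/τ) + (8/9)·(J_sym − J)`, where
`J` is the pair's Jaccard index and `J_sym = 1/(2R−1)` its value at
`r = 1`.  The first part is a small-`d` baseline; the second is zero for
balanced pairs and grows with imbalance, so at fixed `(d, R)` a more
lopsided pair scores higher — the same direction as the hypergeometric
model.  `M_r = ((m+n)/(2N))²` penalizes hyper-large sets; it is
negligible (<5e-3) for ordinary annotation sets, reaches at most 1, and
keeps the total finite even at `m = n = N`.

**Calibration.**  The upstream description of OScal fixes the three
items' contracts (directions, limits, decomposition) and the reference
scores of six printed overlaps, but the algebraic displays of the
enlargement coefficient and the two correction items are only available
as figures in the source we derive from.  The five shape constants
(`w_coef = 4.2082270e-4`, `w_exp_r = 2.2428978`, `w_exp_d = 0.3408534`,
`a = 1.0541940`, `τ = 39.732747`; imbalance weight fixed at 8/9 by the
one printed imbalanced case) were therefore solved once, exactly, from
the six reference scores under the functional forms above.  They are
model constants, not tunables.  Reference scores reproduce to two
decimals; behavior away from the calibration points follows from the
contracts (monotonicity, saturation, finiteness), which are
property-tested, but the reconstruction is necessarily not
character-identical to the original derivation.

## Simulation space

The d-R plane machinery evaluates models on the continuous relaxation
`m = d·R·sqrt(r)`, `n = d·R/sqrt(r)` (log-gamma accepts real arguments),
with 2-D analyses fixing `r = 1` and `N = 22507` by default
(overridable).  Class-II and OScal scores are masked to the
within-boundary region: a class-II score at `d ≪ λ` is large because
*too few* shared properties are also improbable, which is meaningless
for overlap calling, and leaving those points in would make every
"positive area is inside the boundary" statement false.  Class-I models
are evaluated over the whole plane (their trap districts beyond the
boundary are precisely what the region analysis needs to expose).
Isolines are extracted by sign-change scanning with linear interpolation
along both grid directions (handles both curved and axis-parallel
isolines uniformly); reference points solve the two cutoff-line
equations with a grid-seeded root find and report absence (no unique
crossing, or identical lines) as `None`.  Default grids are 512×512 with
a 1e-6 score tolerance.  District names (I, II, III, IV/V) are derived
from the predicate combination (boundary side × per-model positivity),
not from hard-coded geometry; the two beyond-boundary similarity-trap
bands are not distinguishable from predicates alone and are reported as
one label.

## Pair scoring

Annotation input is a two-column TSV edge list or GMT.  The background
`N` defaults to the distinct-property count and should be overridden
when a domain universe is known (e.g. 22507 for human-genome-wide
annotations).  Pair enumeration goes through the inverted
property→entity map, touching only co-annotated pairs, streaming in
lexicographic pair order; self-pairs are excluded and `d = 0` pairs are
never emitted.

## Synthetic data

The generator emulates bipartite annotation data: entity set sizes are
lognormal (median 30, σ = 1.0 by default — a heavy tail comparable to
real regulatory/ontology annotation sizes), filled by uniform sampling
without replacement from `n_properties` (= N, default 5000) properties;
sizes are clamped to half the universe so planted partners can always
top up with fresh properties.  Planted pairs (disjoint; default 50 of
300 entities) copy `k = round(2mj/(1+j))` members of one set into the
partner so the realized Jaccard matches the configured boost, topping up
outside the source set so the overlap is exact; boost 1 yields exact
copies.  The planted pairs are the gold standard.

What the generator does *not* emulate: property popularity (every
property is equally likely, whereas real GO terms/targets are highly
non-uniform), ontology structure and network topology.  One consequence
is quantitative: with uniform properties, random background pairs almost
never reach high similarity scores, so on default synthetic data the
similarity models look nearly as precise as OScal at the top of the
ranking.  The class-II-over-class-I sorting advantage is therefore
demonstrated with an explicit hub stratum (entities with ~1500-property
sets, whose mutual overlaps are large in absolute terms but sit at
random expectation) — the documented beyond-boundary trap for
similarity coefficients.  In that construction Ochiai ranks hub pairs
above the weakly-similar-but-significant gold pairs and its top-k PPV
collapses, while OScal's stays near 1.  Passing tests on synthetic data
accordingly show correctness of the machinery and the direction of the
qualitative claims, not corpus-scale effect sizes.

## Evaluation

`PPV = TP/PC` with positive calls defined as `score ≥ cutoff` (closed;
ties all included, so matched-call depths may exceed `k`).  Zero calls
leave the PPV undefined (NaN), never 0 or 1.  Curves are cumulative
(score ≥ cutoff) over the distinct observed scores by default, with an
optional quantile grid for large inputs; PPV depends only on induced
rankings, which is property-tested via monotone score transforms.
ROC/AUC is out of scope for lack of a gold negative set.

## Problem sizes

The default test and acceptance runs use: full exact-oracle sweeps for
all feasible overlaps with `N ≤ 50` (~5·10⁵ cases), 10⁵-case random
property checks, a 10⁶-case vectorized scoring benchmark, and 10-seed
synthetic studies with 300 entities × 5000 properties (~10⁴ scored pairs
per seed).  These sizes were chosen to exercise every code path with
comfortable margins on a single CPU.

## Known limitations

* The OScal correction items are a calibrated reconstruction (see
  above); extrapolations far outside the calibrated region honor the
  stated contracts but are not guaranteed to match the original model's
  third decimal.
* The printed MI column is not reproduced (see Classical scores).
* Multi-background normalization (comparing scores across datasets with
  different `N`) is out of scope; `N` is per-dataset configuration.
* District sub-bands beyond the boundary are reported as a single
  label.
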