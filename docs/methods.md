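# Methods

## Problem setting and model

`pm3` targets two-group transcriptomic studies in which the interesting
signal is a *coordinated set of small shifts* across biochemically linked
genes rather than any single strongly differential gene.  The canonical
use case is a postmortem-cortex comparison of ~12 cases vs ~12 controls
over a curated panel of ~158 metabolic genes, where group-mean shifts of
2–17% are the expected effect scale.  At that scale per-gene hypothesis
tests are underpowered and noisy, so the package deliberately ranks genes
by an unsupervised divergence profile — percent difference, log2 fold
change, Euclidean divergence and an anomaly-score AUC — and pushes
interpretation to annotation strata (metabolic domain, cofactor
dependency, subcellular compartment).

## Divergence metrics

All ratio metrics are computed on the **linear** expression scale, where
group-mean ratios are meaningful:

- `%Δ = 100 (mean_case − mean_control) / mean_control`;
- `log2FC = log2(1 + %Δ/100)`, algebraically identical to
  `log2(mean_case/mean_control)`; the implementation derives it from `%Δ`
  so the two columns satisfy the identity to 1e−12 by construction;
- mean Euclidean distance, default **centroid** convention (mean absolute
  deviation of case samples from the control mean); a **pairwise**
  convention (mean over all case × control pairs) is available by flag.
  The centroid form matches the "distance from controls" reading of the
  per-compartment figures this table feeds.

A gene whose control mean is zero has no defined ratio; such genes are
flagged (`control_mean_zero`), carried with NaN metrics, placed after all
ranked rows, and excluded from threshold views — never silently dropped.
No minimum-expression or fold-change filter is applied.

An optional `log2(x+1)` transform can be applied to the anomaly and
distance stages only; `%Δ`/`log2FC` always use linear values.  The default
is no transform.

## Isolation forest

The anomaly score follows the canonical isolation-forest construction:
`t = 100` trees, subsample `ψ = min(256, n)` drawn without replacement,
depth cap `⌈log2 ψ⌉`, splits at a uniform point in the range of a
uniformly chosen non-constant dimension, and score
`s(x) = 2^(−E[h(x)]/c(ψ))` with `c(n) = 2(ln(n−1) + γ) − 2(n−1)/n`
(the `H(i) ≈ ln i + γ` approximation used uniformly; an exact-harmonic
oracle bounds the approximation error in the tests).  External nodes
contribute `c(size)`; a constant subsample terminates immediately, which
makes the degenerate all-constant gene well defined: every sample scores
exactly 0.5.  One seeded generator is consumed tree-index major, so a
fitted forest is a pure function of (data, parameters).

Per-gene scoring fits a **one-dimensional** forest per gene and scores all
samples, producing the genes × samples score matrix that K-means consumes.
Two training modes exist:

- `reference_controls` (default): train on the control samples only.
  Anomaly then means "deviates from the control distribution", which
  preserves the monotone link between |group shift| and AUC.  With equal
  groups a pooled fit marks *both* tails of the pooled distribution
  anomalous and destroys that link, which is why pooled is not the
  default; it is retained as an explicit mode.
- `pooled`: train on all samples; scores are label-independent.

Training values are sorted before fitting and the per-gene seed is
`base_seed + crc32(symbol) mod 2^31`, so results depend on neither sample
order nor gene order.

A structural limit worth knowing: in 1-D, a case cohort shifted below the
control range follows the leftmost path of every tree and therefore ties
the *minimum* control exactly, and the opposite extreme control can be
equally isolated.  Perfect directional AUC is thus capped near
`(n−1.5)/n` even in the noiseless limit; the tests assert the attainable
bound rather than an idealized 1.0.

## Discrimination AUC

`auc_rank` is the Mann–Whitney statistic computed from midranks —
exactly `(#{case > control} + ½#{ties}) / (n_case · n_control)` (an
exhaustive pair-counting oracle verifies this on all small inputs).  For
ranking, the AUC is folded to `max(a, 1−a) ∈ [0.5, 1]`: an unsigned
anomaly magnitude cannot encode direction, which is carried by `%Δ`.
Folding inflates the null expectation (median ≈ 0.58 at 12 vs 12), so
AUC thresholds must be read against that small-sample null, not against
0.5.

## Clustering

K-means on the raw anomaly-score matrix (rows already share the (0, 1]
scale, so no row standardization): k-means++ seeding, Lloyd iterations to
a 1e−6 centroid-shift tolerance, best of 10 restarts by inertia.  An
empty cluster is re-seeded at the point farthest from its assigned
centroid.  Initial draws are made against the canonical sorted-symbol row
order, so assignments are invariant to input gene order.  k defaults to
the mean-silhouette maximizer over 2..8 (ties to the smallest k) and can
be fixed by flag.  The per-iteration inertia trace is exposed and asserted
non-increasing in the tests; on 8-point instances the converged inertia
matches the exhaustive-bipartition optimum.

## Ranking and reports

The merged report sorts by folded AUC descending, ties by |%Δ| descending
then symbol, flagged genes last.  The `top_genes` view uses a strict
`AUC > 0.70` cut by default — 0.70 itself is excluded, consistent with
reading a "> 0.70" rule at printed precision.  Domain stratification is a
partition (asserted lossless and duplication-free) over the three major
domains — glycolysis/PPP; redox/sulfur/one-carbon; mitochondrial — plus
`other`; the cofactor view is long-format, one row per (gene, cofactor
tag).  Hypothesis testing (two-sided Mann–Whitney, Benjamini–Hochberg) is
opt-in annotation only, reflecting the method's explicitly non-inferential
design; it never affects ranking.

Every parameter that can affect results (seeds, modes, k, thresholds,
panel identity, alignment report) is recorded in the report metadata, and
all serialized outputs are byte-stable across reruns of one configuration.

## Synthetic cohorts

`synthetic_data.simulate` draws control values
`LogNormal(ln μ_g − σ²/2, σ)` and case values with `μ_g(1+δ_g)` in place
of `μ_g` — mean-corrected so the arithmetic group means are exact in
expectation, and exactly equal to them at `σ = 0`.  Defaults are the
study conditions the package is designed around: 12 vs 12, 158 genes,
`σ = 0.2` (chosen so that 5–15% shifts land AUCs in the 0.6–0.9 band at
this n), planted shifts for the 26 bundled panel genes equal to their
published percent-difference estimates, null fillers elsewhere, baselines
log-uniform on 5–500 normalized units.  An optional `domain_correlation`
parameter shares a per-(sample, domain) log-normal factor, splitting the
log-variance while preserving its total, to emulate coordinated
pathway-level regulation.

What the generator does **not** emulate: library-size and normalization
artifacts, count discreteness, gene–gene correlation beyond the optional
block factor, outlier samples, and any real-data dispersion structure —
σ is a free parameter, not an estimate.  Passing the simulation-based
tests therefore demonstrates statistical correctness of the machinery at
the intended effect scale, not performance on any particular real cohort.

Two quantitative properties of this regime, measured by the test suite:

- the ratio-of-means `%Δ` estimator carries a small positive
  finite-sample bias, ≈ `100·(e^{σ²}−1)/n_control ≈ 0.3` percentage
  points at σ = 0.2, n = 12 — visible when averaging hundreds of
  replicates, negligible per study;
- isolation-forest score noise at ψ = 12 widens per-gene AUC variance
  substantially relative to the direct expression-rank AUC, so
  seed-to-seed ranking power is limited by the forest ensemble, not by the
  information in the data.  The simulation problem sizes used in the test
  suite (200 replicates for recovery, 20 for ranking power, 100 for
  outlier detection) reflect these variances.

## Numerical and degenerate-input choices

- ψ is clamped to `[2, n]`; `c(n ≤ 1) = 0`; `c(ψ)` never divides by zero.
- Splits require a non-constant dimension; fully constant subsets become
  external nodes (scores 0.5).
- Study round-trips are bit-exact: full-precision (`%.17g`) serialization
  and round-trip float parsing.
- Labels accept `asd`→case and `ctrl`/`neurotypical`→control synonyms;
  cofactor tokens are normalized case-insensitively through a synonym map
  (e.g. `B1`→`thiamine_TPP`, `ADP`→`ATP`, `lipoate`→`lipoic_acid`) and
  unknown tokens are load errors naming the row.
- Empty cofactor cells mean `none` (carriers and regulatory subunits with
  no annotated small-molecule cofactor).

## Known limitations

- Per-gene 1-D forests ignore cross-gene structure by design; a
  multivariate forest would answer a different question (sample-level
  anomaly) than the per-gene screen implemented here.
- The AUC of a 12 vs 12 comparison is coarse (granularity 1/144) and its
  folded null is well above 0.5; thresholded counts should always be read
  against a null cohort of the same size.
- The bundled 26-gene panel is a fixture, not a recommendation; the
  intended use is a user-curated panel at the hundred-gene scale.
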