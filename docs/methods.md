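# Methods

## Model and procedure

The scanner treats promoters of orthologous genes as replicated
observations of the same regulatory context. For each motif × gene-cluster
pair it runs three steps:

1. **Scoring.** Every sequence gets a raw score
   RS = ln((1/M) Σ_s Π_k q(k, L_k)/p(L_k)) — the log of the average
   likelihood ratio over all length-w windows. q is the motif probability
   matrix (pseudocounted position frequencies), p the sequence's own base
   composition. RS is proportional, in a simple thermodynamic reading, to
   the factor's total equilibrium occupancy of the sequence; averaging over
   windows means multiple weaker "shadow" sites contribute, and extending a
   sequence with non-motif DNA dilutes RS downward.
2. **Testing.** The mixed Student's t-test compares the single target score
   (`one`) against the background mean, pooling variance from the ortholog
   sample (`obs`, which includes `one`) and the background sample (`bkg`):
   t' = (X̄_bkg − one) / ( sqrt(((n_obs−1)s²_obs + (n_bkg−1)s²_bkg)/(n_obs+n_bkg−2)) · sqrt(1/n_obs + 1/n_bkg) ),
   with Welch–Satterthwaite degrees of freedom built from s²_obs/n_obs and
   s²_bkg/n_bkg. p = P(T_df ≤ t') (lower tail; two-sided available).
   Limiting behaviour: with obs = bkg elementwise the statistic reduces to
   (X̄ − one)/(s·sqrt(2/n)); with one = X̄_obs it is exactly the pooled
   two-sample t statistic of bkg vs obs. Both reductions are asserted in
   the tests.
3. **Filtering.** Benjamini–Hochberg q-values are computed jointly across
   all motif × gene tests (a per-motif scope is available) and calls with
   q ≤ threshold are reported with the best-scoring site on the target
   promoter, CCV and SD.

CCV = |X̄_obs| / sqrt(Σ_i (obs_i − one)²/n_obs) measures how tightly
ortholog scores cluster around the target's score (∞ when all equal `one`);
SD = (one − X̄_bkg)/|X̄_bkg| is the relative score excess over background.
High CCV and high SD each push p down; the significance surface is
monotone in both, which the tests assert on a synthetic grid.

## Parameters

| parameter | default | meaning |
|---|---|---|
| pseudocount | 0.2/cell (0.8/position) | keeps every q(k,b) > 0, hence finite log-LRs, without washing out informative columns of typical JASPAR matrices |
| n_subsets (-n) | 10 | background subsets sampled per motif |
| subset_size (-z) | 200 | promoters per subset; pooled n_bkg = n·z |
| step (-s) | 1 | window stride (1 = every position) |
| fdr_threshold (-t) | 0.05 | BH q-value cutoff |
| tail (-p) | lower (0) | sidedness of the p-value |
| strand_mode | both | TF binding is strand-agnostic; forward-only available |
| min_orthologs | 3 | smallest cluster tested (sample variance with headroom) |
| composition floor | 1/(2l) | a base absent from a sequence keeps a positive background probability |

Interpretations of the terse scan flags: `-s` is read as the scanning
stride and `-p` as the p-value sidedness selector; both are interpretations
of an undocumented interface and are labelled as such in `--help`.

`bkg_pooling="pooled"` (default) uses all n·z background scores as one
sample; `"per_subset"` runs the test once per subset and averages t', df, p
and SD across subsets. The background is sampled once per motif per run
from a seed derived deterministically from the root seed, and background
scores are reused across clusters (the background does not depend on the
cluster), keeping the cost O(motifs × (clusters + background)).

## Coordinate and strand conventions

Coordinates are 0-based half-open internally and in BED output. In
both-strand mode the reverse-complement matrix is scanned against the
forward text with the forward-strand composition; a minus-strand site at
[s, s+w) refers to forward-strand coordinates. Best-site ties break to the
smallest start, then the forward strand. Windows containing N are excluded
from the average rather than scored as LR = 1, so masked regions do not
drag RS toward zero; sequences with no valid window are skipped with a
logged warning.

One worked-example subtlety: the composition estimator floors absent bases
at 1/(2l) and renormalises, so a sequence like "AACT" has p(A) = 4/9, not
1/2. Textbook-style examples that assume the unfloored frequencies can be
reproduced by passing an explicit composition to `raw_score`.

## Synthetic studies

`synth.make_study` emulates the structure the scanner consumes: in a
planted cluster the target always carries a site sampled column-wise from
the motif, and each reference species carries one independently with
probability c (the conservation rate). Unplanted clusters and the
background are kept motif-free by rejection sampling: any window whose LLR
exceeds the motif's 99.9th-percentile null score (on either strand) is
redrawn, so truth tables are clean at desk scale. Defaults are the
reference study: 200 clusters, 30 species, 2 kb promoters, 25% planted,
c = 0.9, one site per carrier, uniform composition, 400 background
promoters (at least twice the default subset size), and an 8-bp motif with
dominant-base probability 0.85 (~1.1 bits/column, comparable to the
informative core of curated matrices).

What the generator does **not** emulate: phylogenetic correlation between
species, substitution models, indels within sites, CpG islands or other
composition heterogeneity, and repeat structure. Passing tests therefore
demonstrate the statistical machinery under idealised i.i.d. sequences, not
performance on real promoters.

## Null calibration: a structural property

The mixed statistic is **not** calibrated under the null. `one` is a single
draw, so var(X̄_bkg − one) = σ²(1 + 1/n_bkg), while the denominator
estimates σ²(1/n_obs + 1/n_bkg); under the null t' is therefore inflated by

κ = sqrt( (1 + 1/n_bkg) / (1/n_obs + 1/n_bkg) ),

which equals 1 only at n_obs = 1 and is ≈ 5.5 at the default sample sizes
(n_obs = 31, n_bkg = 2000). The test suite measures the consequences at
those sizes: null lower-tail p-values have a Kolmogorov–Smirnov distance
≈ 0.34 from uniform (≈ 37% of null tests give p < 0.05), an unplanted
reference study yields ≈ 34% false cluster calls after BH at 0.05, and the
planted reference study is recovered with Sn ≈ 0.76 but PPV ≈ 0.38. The
corresponding acceptance tests assert uniformity, ≤ 5% false calls and
Sn/PPV ≥ 0.9, and are left failing deliberately: the statistic is
implemented exactly as defined, with no recalibration, and the red tests
document the gap between the method's nominal and actual error control.
In practice the method works as a *ranking* statistic — genuinely planted
(or biologically bound) clusters produce overwhelmingly smaller p-values
than null clusters — which is consistent with the moderate PPV the approach
attains on published ChIP-seq benchmarks.

The sensitivity ceiling at the reference conditions is a signal-to-noise
effect, not a defect: a single ~9-bit site contributes ln-average lift of
roughly e^6.4 to one of ~4000 both-strand windows of a 2 kb promoter, and
the sampled-site strength is lognormal, so a fraction of planted targets
score within the null range.

## Numerical choices

- RS is computed in log space via logsumexp; the brute-force oracle in the
  tests uses plain-Python products and agrees to 1e-10.
- Degenerate inputs: zero pooled variance (e.g. identical sequences
  throughout) raises and the cluster is skipped with a warning; a zero
  background mean makes SD undefined (raises); all-N sequences are
  rejected. Non-finite t' clamps p to 0 or 1 with a warning.
- BH-FDR is delegated to statsmodels (`fdr_bh`) behind input validation and
  is cross-checked in the tests against a hand-written step-up oracle.
- ACCg is the geometric mean sqrt(Sn·PPV). Published benchmark tables of
  this quantity are reproduced by the geometric mean and not by the plain
  product (0.51 × 0.15 → 0.28 = sqrt, not 0.08); the packaged table and a
  test document this.
- Reciprocal-best-hit ties break by minimum E-value, then maximum bitscore,
  then lexicographically smallest subject id, making pairing deterministic.
- All randomness flows from a single root seed via numpy `SeedSequence`
  spawning (per-motif background seeds are recorded in the log), so outputs
  are byte-identical across runs with the same seed.

## Known limitations

- No calibrated per-test error control (see above); q-values should be read
  as a ranking, not as frequentist FDR guarantees.
- Orthology is pairwise reciprocal best hit only; no tree-aware orthology,
  and the alignment step itself (e.g. BLASTN) is consumed as tabular input,
  not executed.
- Promoter extraction from genome annotation is upstream of this package.
- Matrix dialects other than JASPAR PFM text are not parsed.
- The desk-scale reference study (200 clusters × 31 sequences × 2 kb) is
  the intended problem size; genome-scale runs are out of scope.
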