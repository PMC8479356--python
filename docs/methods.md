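# Methods

## The procedure

A Bayesian dating run yields a posterior sample of chronograms: rooted,
ultrametric trees whose branch lengths are in time units, each a plausible
hypothesis about node ages under the chosen branch-rate model and
calibrations.  A horizontal gene transfer between two clades implies the
donor lineage existed no later than the recipient, so a curated transfer
between clades A and B asserts the relative-age statement
`age(A) > age(B)` independently of any fossil or geochemical calibration.

`hgtclock` evaluates each constraint against each sampled chronogram
(strict inequality on the resolved node ages) to form a boolean
trees x constraints **compatibility matrix**.  Everything downstream is a
function of this matrix:

* **constraint profile** — per constraint, the percentage of chronograms
  in which the donor is older;
* **model score** — the mean of the profile, used to rank branch-rate
  models (equivalently, to rounding, the fraction of compatible cells);
* **supported count** — constraints compatible with at least 20% of the
  posterior (boundary inclusive);
* **miscalibration flag** — constraints under 1.2% compatibility in
  *every* model compared; in practice these point at a node calibration
  that is misplaced in the species tree, and the intended workflow is to
  re-run the dating without the suspect calibration and compare profiles;
* **stringency sweep** — for n = 1..N, the set of trees satisfying at
  least n constraints.  These sets are nested by construction.  The
  selected stringency is the largest n whose set still holds at least
  `min_trees` trees (default 25), and node-age summaries (mean, 95%
  equal-tailed credible interval, reported older-bound first) are
  recomputed from that subset.

Reading "passing n constraints" cumulatively (at least n) is what makes
the sweep monotone; exact-n sets would not shrink with n and could not
drive a stringency choice.

## Node-age conventions

Ages are derived from branch lengths with the max-depth convention,
`age(v) = max path length from v to a descendant leaf`, which guarantees
`age(parent) >= age(child)` even for text-rounded input.  Ultrametricity
is enforced as a relative tolerance: the spread of root-to-leaf distances
divided by the root age must not exceed 1e-6 (user-overridable); leaf ages
are then forced to exactly 0.  Time units are opaque; a single scale
factor can be applied at read time.

A named clade resolves to its MRCA.  *Crown* age is the MRCA node's age;
*total-group* age is the MRCA's parent's age (the top of the stem branch),
undefined when the MRCA is the root.  Crown age of a single taxon is
undefined; its total-group age is the terminal branch's parent age.
Non-monophyletic taxon sets resolve via the MRCA anyway, with a
`monophyletic=False` flag and a logged warning — analyses are meant to run
on a fixed topology, and silently changing ages would be worse than
flagging them.  Constraints compare crown ages on both sides by default;
either side can be switched to the total group per constraint for
sensitivity analyses, since which node a transfer "dates" is a modelling
choice, not a fact of the data.

Ties count as incompatible: "older than" is strict, and exact ties have
measure zero in continuous posteriors (they arise in practice only through
the monotonicity repair of the synthetic generator or duplicated trees).

Burn-in removal uses a ceiling count (`ceil(fraction * n_trees)`), erring
toward discarding, and applies per chain before pooling.  Chains may be
pooled with `merge_chains`; whether to pool or analyse a single chain is
left to the caller.

Multiple transfer events frequently map onto one unique donor/recipient
clade pair; pairs are deduplicated before matrix construction with the
merged event ids kept in the constraint's note field, so the constraint
count reflects unique relative-age statements.

An ultrametric tree cannot be rerooted along an edge without inventing a
root age, so a basal polytomy is an error unless an outgroup taxon set is
supplied, in which case the non-outgroup root children are grouped under a
zero-length node at the root age — crown ages of all existing clades are
preserved.

## Synthetic data

The generator emulates the *shape* of a dating study, not its inference:

* **Topology and true ages** — a pure-birth (Yule) tree conditioned on the
  root age: the n-2 non-root node ages are i.i.d. truncated-exponential
  draws on [0, T] (rate = birth rate), assigned in descending order as the
  topology grows by splitting a uniformly chosen lineage.  Pure birth
  rather than birth–death: the job is plausible ultrametric shapes, and
  extinction adds parameters without adding test power.
* **Posterior spread** — each internal age is multiplied by i.i.d.
  lognormal noise with mean 1 and a configurable coefficient of variation,
  then parent >= child is repaired by propagating the maximum child age
  upward.  Leaves stay at age 0.
* **Planted constraints** — donor/recipient pairs drawn uniformly from the
  disjoint internal-clade pairs of the generating tree; a configurable
  fraction is oriented donor-older (true), the rest deliberately inverted,
  with the truth recorded per constraint id.

Defaults are fixed once as the package's study conditions: 32 taxa, root
age 3500 Ma, birth rate 8e-4 per Ma (about ln(16)/3500, a typical
pure-birth rate for a 32-taxon crown of that age), 2000 trees, age-noise
CV 0.15, 24 constraints, all true.  All randomness flows from one integer
seed through `numpy` SeedSequence spawn keys, one stream per stage, so
changing the noise level never changes the topology or the constraint set.

### What the generator does and does not show

The jitter is *centred on the truth*: every node's posterior mean equals
its true age up to the (upward) monotonicity-repair bias and Monte Carlo
error.  That makes the generator ideal for contract tests — zero-noise
exactness, tie rules, nestedness, permutation invariance, model ranking by
noise level — but it deliberately does not emulate the one feature of real
posteriors that makes HGT filtering *improve accuracy*: systematic,
tree-correlated distortion from model misspecification or bad
calibrations, which correlates with constraint violation.  Under unbiased
noise, conditioning on `donor > recipient` for a constraint that is true
in the generating tree truncates an unbiased distribution, biasing donor
nodes old and recipient nodes young; and because relative-age constraints
are scale-invariant, no per-tree stretch factor can change this.  The
consequence is visible in the test suite: the recovery property test
asserting that filtering reduces the RMSE of posterior mean ages in >= 90%
of replicates fails (measured ~4–10% of replicates improve), and is left
failing on purpose as a documented property of this noise model rather
than of the method.  Passing it would require simulating biased
posteriors, which is outside the generator's scope.  What filtering *does*
deliver under this generator — and what the tests assert — is increased
precision: credible-interval width shrinks monotonically (in trend) with
the stringency n.

## Numerical choices

* Credible intervals: equal-tailed percentiles with linear interpolation
  between order statistics, matching the usual "95% CI" of MCMC summaries;
  a shortest-interval (HPD) option is available.  Intervals are reported
  (older, younger).
* `model_score` is computed as the mean of the per-constraint profile, so
  the report invariant `overall = mean(per-constraint)` holds bit-exactly;
  its identity with the raw cell fraction holds to floating-point
  summation order (~1e-12 relative).
* Degenerate filter (no tree passes even n = 1 at the requested
  `min_trees`): the selected stringency is 0 and unfiltered summaries are
  reported with a prominent warning instead of failing the run.
* Text outputs carry 6 significant digits plus a config-echo header
  comment; tree round-trips through files preserve ages to 1e-9 relative.
* `min_trees` defaults to 25 — deliberately just under the smallest
  filtered set size (28 trees) accepted in practice for estimating an age
  distribution; always overridable.

## Problem sizes

The stochastic properties are asserted over 50 seeded replicates at the
default study conditions (2000-tree posteriors for recovery; 400-tree
posteriors per model for the model-selection comparison, which is a
two-sample contrast and needs fewer trees per sample).  Oracle-equivalence
checks run exhaustively over all ordered internal-clade pairs of random
4–10-leaf chronograms against an independent dendropy-based recomputation.

## Limitations

* The tool consumes dated trees; it neither runs MCMC dating nor infers
  HGTs from sequence data, and offers no convergence diagnostics beyond
  burn-in removal.
* Filtering is hard subsetting, not importance re-weighting; with few
  passing trees the credible intervals become noisy, which is exactly what
  `min_trees` guards against.
* Clade resolution is by exact leaf-label match on a fixed taxon sampling;
  there is no taxonomy-aware normalization.
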