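# Methods

## The envelopment model

flockbench scores each farm (decision-making unit, DMU) with the
output-oriented variable-returns-to-scale (VRS) envelopment LP: maximize
the radial output expansion θ subject to a convex combination of peer
farms producing at least θ times the farm's output with no more of any
input, intensity weights λ summing to one. Technical efficiency is
TE = 1/θ. The single output is gross revenue (EUR/year, subsidies
included); the four inputs are flock size (ewes), total labor
(hours/year), variable cost (EUR/year) and fixed capital cost
(EUR/year). Output orientation fits sheep systems that valorize
resources with little alternative use (marginal grazing land): the
question is how much more revenue the existing input bundle could earn,
not how many inputs could be shed.

Farm types (French extensive, French intensive, Spanish semi-intensive,
UK extensive) are benchmarked separately — four frontiers, no cross-type
peers — because the production technologies differ structurally.

### Two-phase solution

Phase 1 solves the radial LP per DMU (n independent LPs, no
warm-starting; the contract is value-level determinism). Phase 2 fixes
θ at its optimum and maximizes the total slack subject to the same
constraints written as equalities, so weakly efficient units (on the
frontier's vertical/horizontal extensions) are projected to the strongly
efficient subset. The efficient target reported for every farm is the
slack-adjusted projection: output θ·y + s_out, inputs x − s.

The default phase-2 objective is the raw sum of slacks across inputs and
output. The inputs are heterogeneous (head, hours, EUR), so a raw sum is
unit-sensitive; an `input-mean-scaled` normalization (each slack weighted
by the reciprocal of that input's sample mean) is provided for users who
want a commensurable objective. The choice affects only how ties among
alternative slack vectors resolve — θ, TE and the zero/nonzero slack
pattern of strongly efficient units do not depend on it.

### Numerical choices

- LPs are solved with HiGHS (scipy.optimize.linprog), feasibility
  tolerance 1e-7. A solver failure raises with the DMU index and solver
  status — a score of 1 is never silently substituted.
- θ is clamped up to 1 when it lands within feasibility tolerance below
  (self-envelopment guarantees θ ≥ 1); TE is clamped into (0, 1].
- A farm counts as efficient when TE ≥ 1 − ε with ε = 1e-6 *and* all
  phase-2 slacks are below 1e-5 of the farm's own input scale. The
  ε threshold alone defines the efficient *group* in the report tables
  (frequency table top bin, group comparisons), matching the convention
  of reporting "TE = 1.000" groups.
- Alternate optimal λ vectors are not disambiguated; only θ, TE, slacks
  and projections are contract-bearing outputs.

## Report tables

- **TE frequency table** — bins [0, .60), [.60, .70), [.70, .80),
  [.80, .90), [.90, 1−ε) and {TE ≥ 1−ε}, binned on unrounded scores;
  labels print as `<0.60`, `0.60–0.69`, …, `1.00`. Binning a score like
  0.695 therefore follows the half-open rule, not its printed rounding.
- **Projection summary** — mean existing vs mean slack-adjusted target
  output per flock-size class and overall, with the percent increase
  100·(target/existing − 1). Size classes are type-specific (France
  350/450 ewes, Spain 600/1000, UK 400/900); a flock exactly at a cut
  goes to the medium class, matching the printed interval labels.
  Empty classes are flagged rather than propagating NaN.
- **Revenue composition** — per-ewe group means of the five revenue
  components (lambs for meat, lambs for breeding, culls, subsidies,
  wool/other) and their shares of the group total. A component absent
  for a whole group (UK subsidies) is excluded from the total and listed
  in the table metadata, never imputed as zero.
- **Techno-economic indicators** — per-ewe group means with the derived
  identities: production cost = labor + feed + variable capital + fixed
  capital cost; gross margin = gross revenue − feed − variable capital
  cost (the variable-cost definition consistent with the published
  indicator arithmetic); profit = gross revenue − production cost;
  lambs/ewe; ewes per annual labor unit (ALU, 1800 h).
- Group means are unweighted means over farms of each farm's per-ewe
  ratio, not ratios of group sums. The convention is recorded in the
  table metadata; it keeps a few very large flocks from dominating the
  group profile.
- All aggregation happens on unrounded internals; printed-precision
  comparisons round only at the end.

## Synthetic populations with known truth

The generator's purpose is falsifiable testing of the whole pipeline:
it plants a known frontier and known inefficiencies, and the DEA
estimates must recover them exactly, not approximately.

Construction, per farm type:

1. **Flock sizes** are drawn uniformly within the type's three size-class
   ranges at the calibrated class counts (e.g. 80/45/116 for the French
   extensive type, n = 241). The large-class upper bounds are set so the
   population mean flock size lands near the calibrated mean.
2. **Input ray.** All farms share the type's per-ewe input profile
   (1 ewe, h labor hours, v EUR variable cost, f EUR fixed cost), so a
   farm of z ewes uses inputs z·(1, h, v, f). Inefficient farms inflate
   each non-ewe input by an independent Uniform(0, 0.25) factor — waste
   that DEA phase 2 must pick up as input slack. The ewe count is never
   inflated, so it is always the binding input and the frontier lives in
   the (ewes, revenue) plane.
3. **Frontier.** Anchor farms sit exactly on y = c0 + a·z^b with
   b = 0.9 and intercept c0 = 5 % of the frontier level at the mean
   flock size (the VRS intercept); a is solved so the frontier at the
   mean flock size equals the calibrated mean revenue per ewe divided by
   the calibrated mean TE. Twelve anchors are chosen at evenly spaced
   size quantiles including both extremes; the operative frontier is the
   piecewise-linear interpolation of the anchors — exactly the VRS hull
   the estimator constructs. Concavity of z^b makes every anchor a hull
   vertex.
4. **Efficiencies.** The calibrated number of farms (anchors included)
   gets TE_true = 1 and no input inflation. Every other farm draws
   TE_true from te_min + (1 − te_min)·Beta(α, β) with α = 2 and β set so
   the inefficient-group mean matches the calibration (type-specific
   te_min between 0.31 and 0.576). Output is TE_true times the hull
   value at the farm's flock size.
5. **Components.** Revenue components are the calibrated composition
   shares perturbed by lognormal noise (σ = 0.15), renormalized, and
   forced to sum to gross revenue exactly; per-ewe cost fields are
   derived from the farm's actual generated inputs, so the
   production-cost identities hold farm by farm. UK farms carry no
   subsidy component (marked absent, not zero).
6. **Practice flags.** For surveyed types, each efficient farm flags each
   catalog practice independently with probability p solving
   1 − (1−p)^c = r, where c is the category's practice count and r the
   calibrated category-level adoption rate — so the probability of
   flagging at least one practice in the category is exactly r.

One seeded generator stream per call; the same spec and seed give
byte-identical output files.

**Why recovery is exact.** Any convex combination of sample farms with
total ewes ≤ z has output ≤ hull(z), because all farms lie on or below a
concave increasing hull and the ewe constraint binds; the combination of
the two anchors adjacent to z attains hull(z). Hence the phase-1 optimum
is hull(z)/y exactly and TE_hat = TE_true whenever the anchors are in
the sample. Removing the anchors shrinks the estimated frontier inward,
so estimates can then only exceed the truth — the well-known upward bias
of DEA in finite samples, which the tests assert as TE_hat ≥ TE_true.

**What the generator does not emulate.** Real farms do not share one
input-profile ray (input mixes vary continuously), frontiers need not be
single-aggregate, measurement error and output noise are absent, and
flock sizes are uniform within classes rather than skewed. Passing
recovery tests therefore validates the estimator and pipeline logic, not
the behaviour of DEA under noisy multi-dimensional data; on real data
DEA scores remain finite-sample upward-biased estimates.

## Test oracles

Two independent oracles check the LP core on small instances (n ≤ 6,
m ≤ 2): the radial phase against an exhaustive simplex grid search over
intensity supports of size ≤ m+1 (step 0.005; an optimal basic solution
has at most m+1 positive intensities, so the support enumeration is
exhaustive and the error is bounded by the grid resolution); the slack
phase against exact enumeration of the basic feasible solutions of its
equality system, because at the fixed optimal θ the feasible set is a
lower-dimensional face a grid almost never touches.

## Problem sizes

Default test and acceptance runs use the calibrated sample sizes
(n = 241/61/37/119), 200 random oracle instances and one 250-farm
recovery population — a full run takes well under a minute on one core,
since each farm is two small LPs.

## Known limitations

- Single-output model only; multi-output revenue decomposition enters
  the report tables, not the frontier.
- No input orientation, no constant-returns/scale-efficiency
  decomposition, no super-efficiency, no bootstrap confidence intervals.
- Group comparisons are descriptive; no significance testing.
- The best-practice catalog maps categories to the named practices of
  the default template; user extensions are possible but selections are
  validated strictly against the active catalog.
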