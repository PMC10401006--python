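# Methods

## Experiment mechanics

A *trial* administers one case vignette to 40 clinicians over three rounds.
In the network condition the 40 clinicians occupy the nodes of a simple,
connected, 4-regular random graph; before rounds 2 and 3 each clinician is
shown the arithmetic mean of their four contacts' previous-round risk
estimates (their own estimate excluded). Control clinicians see nothing
between rounds. Every round elicits a risk estimate in [0, 100] and a
categorical treatment recommendation. A study is 7 vignettes × (8 network +
4 control) trials = 84 trials; allocation of invitations to arms is 2:1
with any remainder going to the network arm.

**Topology.** One canonical 40-node degree-4 topology (fixed internal seed)
is reused across all networked trials, matching the single realized
topology of the design this package models; per-trial node placement is
randomized. The graph sampler is `networkx.random_regular_graph` behind a
seeded rejection loop that redraws until the graph is connected.
Connectivity is not strictly implied by the design but is imposed (and
configurable) so that every node has a defined peer signal; an isolated
node raises a distinct `NoSignalError`.

## Outcome measures

- Error ε = |estimate − truth| in percentage points.
- Accuracy = min–max-normalized negated error. Default bounds are the
  *theoretical* range of negated error, [−100, 0], so accuracy = 1 − ε/100
  exactly and percent accuracy + error = 100. An observed-min/max mode
  (`norm="observed"`) normalizes by the dataset's own error range instead.
  Fixed bounds are the default because they make accuracy comparable
  across datasets and keep the percent identity exact.
- The unit of inference is the trial: clinician values are averaged within
  a trial before any between/within-condition test, which respects the
  non-independence of networked clinicians.
- Quartiles and deciles are assigned from round-1 accuracy only. Default
  scope pools clinicians across trials within a condition (`binning=
  "pooled"`); `per-trial` binning is available. Bins are equal-frequency
  with sizes differing by at most one; the remainder enlarges the
  low-accuracy bins; ties are broken by the stable key
  (accuracy, trial id, clinician id). **Bin 1 is always the least accurate
  group** — note that error-quartile labelling conventions elsewhere can
  run in the opposite direction.
- Revision magnitude = |round-3 estimate − round-1 estimate|.
- Switch rates condition on eligibility: among initially-incorrect
  clinicians the fraction ending correct, and conversely. An empty
  eligibility set yields NaN (undefined), never 0.
- Clinicians missing any round are excluded from panel-level metrics; the
  exclusion count is logged and carried in the table's `attrs`.

## Synthetic cohort

The generator is the simplest mechanism that produces the statistical
structure the analysis assumes; it makes no attempt to model clinician
demographics, attrition, or cross-vignette learning.

- **Initial estimates.** estimate = clip(truth + bias + noise, 0, 100),
  bias ~ N(0, `bias_spread`), noise ~ N(0, `noise_sd`) per round-1 draw.
  Defaults `bias_spread = 35`, `noise_sd = 5` pp: after clipping across
  the seven default truths this yields a mean absolute initial error near
  23 pp and an initial-accuracy quartile spread from the mid-90s down to
  roughly 50 — the heterogeneity the quartile analyses require.
- **Network revision (DeGroot-style).** x ← w·x + (1 − w)·peer-mean,
  clipped to [0, 100] before feeding the next round's peer signals. The
  self-weight is fixed per clinician by round-1 error:
  w = clip(`stubbornness_base` + `alpha_link`·(1 − ε₁/100), 0, 1),
  defaults 0.3 and 0.6, so w runs from 0.3 (maximally wrong) to 0.9
  (exactly right). This accuracy→stubbornness link is the minimal form
  generating a positive revision coefficient; setting `alpha_link = 0`
  switches the mechanism off, which the tests use as a null.
- **Control revision.** x ← x + `control_gain`·(truth − x) + N(0,
  `control_noise_sd`), clipped. Defaults 0.06 and 3 pp: two revision
  rounds then shrink mean error by ≈ 2–3 pp, the improvement scale
  independent reflection is expected to produce.
- **Recommendations.** A strictly increasing threshold vector maps the
  estimate to an option band; an estimate exactly at a cut-point takes the
  higher-index option (fixed convention). Each round's recommendation is
  recomputed from that round's estimate.
- **Seeding.** Trial *t* of a study uses the RNG stream
  `SeedSequence(master_seed, spawn_key=(t,))`, so datasets are bit-for-bit
  reproducible and appending trials never perturbs earlier ones. Analysis
  substreams (permutation tests, power simulation) hang off the same
  master seed under reserved spawn keys.

What passing tests on this cohort do *not* show: real clinicians are not
unbiased-on-average with normal dispersion, revision rules are not exactly
convex combinations, and vignette difficulty varies in ways the seven
default truths only sketch. The simulated network-arm improvement
(~10 pp at defaults) is larger than a human cohort should be expected to
show; the generator is calibrated to qualitative structure (heterogeneity,
revision-accuracy link, control improvement scale), not to any deposited
dataset.

## Inference

All tests default to two-sided p-values and are implemented from first
principles; scipy is used only for rank assignment and reference
distributions (normal, t).

- **Wilcoxon rank-sum.** Statistic = rank sum of the first sample with
  midranks. Exact mode enumerates the C(N, n₁) rank assignments via a
  dynamic program on doubled midranks (auto when N ≤ 12 and tie-free;
  forceable, and then valid with ties as the conditional distribution);
  otherwise a normal approximation with tie-corrected variance and 0.5
  continuity correction. Exact two-sided tails are symmetric about the
  null mean, in exact integer arithmetic.
- **Wilcoxon signed-rank.** W⁺ with zeros dropped (Wilcoxon convention;
  Pratt variant by flag). Exact sign-flip enumeration (DP over subset
  sums) when the nonzero count ≤ 15 and magnitudes are tie-free, else
  tie-corrected normal approximation with continuity correction.
- **Jonckheere–Terpstra.** Sum of Mann–Whitney counts over ordered group
  pairs (ties count ½). Modes: exact enumeration of distinct group
  assignments when their number is ≤ 50,000; seeded Monte-Carlo
  permutation with p = (1 + #extreme)/(B + 1), drawing from the sorted
  pooled multiset so p depends only on the data multiset; tie-corrected
  normal approximation (the default at analysis scale, where the clinician
  counts make permutation needlessly expensive and the approximation is
  excellent). Constant data returns the exact p = 1.
- **Spearman.** Pearson correlation of midranks; p from the t
  approximation on n − 2 degrees of freedom.
- **Hodges–Lehmann shift CI.** Point estimate = median of the n₁n₂
  pairwise differences; endpoints are order statistics of those
  differences with the cut index k = max{u : P(U ≤ u) ≤ α/2} from the
  exact Mann–Whitney distribution for small tie-free samples, else from
  the normal approximation. The interval is closed and never extends
  beyond the extreme pairwise differences.
- **t test.** Welch by default (Student's pooled variant by flag). Both
  samples constant and equal → t = 0, p = 1; constant and unequal raises
  a degenerate-input error.
- **Power.** Simulated: N(0,1) vs N(d,1) at the trial-level sizes
  (56 vs 28 by default), two-sided rank-sum at α, seeded. A simulation is
  used because no single closed-form convention for rank-sum power is
  canonical; the trial-level power of the design can be read directly off
  the grid of d values. No multiplicity adjustment is applied anywhere;
  quartile-level p-values are reported unadjusted.

## Pipeline conventions

- Response schema: `trial_id,vignette_id,condition,clinician_id,round,
  estimate,recommendation`; estimates are written at full float precision
  (`%.17g`) and parsed with round-trip precision so write→read is the
  identity. External files map onto the schema through a column-mapping
  importer hook. Malformed rows are skipped and collected with 1-based
  line numbers and named reasons; missing columns fail immediately.
- Edge lists: `trial_id,node_a,node_b`, one undirected edge per row.
- Every simulation output directory carries a manifest with the config
  hash (SHA-256 of the canonical config serialization), master seed, trial
  count and package version; the analysis bundle's `meta` table repeats
  the hash and seed, and the report prints them.
- The quartile differential contrast is computed in both modes the design
  leaves ambiguous — clinician-level changes (network vs control per
  quartile) and trial-level (per-trial mean change within quartile) — and
  both p-values are reported side by side.
- The switch analysis correlates clinician-level accuracy change with the
  switched-to-correct indicator among initially-incorrect clinicians
  (both conditions pooled), and contrasts network vs control switch rates
  per quartile with Student's t, matching the reporting conventions this
  pipeline mirrors.

## Problem sizes used by the test suite

The default study (84 trials × 40 clinicians × 3 rounds) simulates and
analyzes in well under a second, so the acceptance-style suites run the
full design: mechanism recovery uses 20 master seeds at the complete
56 + 28 trial shape; null calibration uses 5,000 replicates per test at
trial-level-like sample sizes; oracle equivalence enumerates all
arrangements for total n ≤ 10 across 220 random cases.

## Known limitations

- The normal-approximation modes are large-sample; at intermediate sizes
  (N ≈ 13–25 with heavy ties) neither exact-auto nor the approximation is
  ideal — force `mode="exact"` there.
- The generator's recommendation model is a deterministic threshold rule;
  real categorical decisions carry noise unrelated to the risk estimate,
  so simulated estimate/recommendation coupling is tighter than reality.
- Observed-bounds normalization makes accuracy dataset-relative; summary
  tables produced under it are not comparable across datasets.
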