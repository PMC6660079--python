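# Methods

## Data model and assumptions

The pipeline consumes a probe × sample matrix of normalized hybridization
intensities (arbitrary units, assumed already normalized across arrays)
with a four-arm design — vehicle (VEH), T3, CORT, T3+CORT — and at least
two replicates per arm (three in the design the defaults target). Signals
are floored at a configurable positive value (default 0.1 signal units)
before any ratio: background-subtracted intensities can be zero or
negative, and fold change is a ratio of group means. Missing cells are
rejected rather than imputed; with n = 3 there is no basis for imputation.

All group means, variances (unbiased, n−1) and fold changes are computed
on the raw floored signal scale. Hypothesis tests on expression run on
log2 signals by default, where multiplicative effects are additive and
replicate scatter is approximately homoscedastic.

## Differential expression

Per probe and hormone arm: FC = mean(arm)/mean(VEH), and a two-sided
Welch two-sample t-test of the arm's log2 signals against vehicle's.
A probe is *up* when FC ≥ 1.5 and p < 0.02, *down* when FC ≤ 1/1.5 and
p < 0.02 (symmetric on the log2 scale; log2 1.5 = 0.58496), *ns*
otherwise. No multiple-testing correction enters the calls — the joint
FC + p filter is the deliberate, conservative screen — but a
Benjamini–Hochberg column is emitted for information.

The test is configurable (`test="student"`, `test_scale="raw"`). Two
calibration facts worth knowing at n = 3 vs 3 (verified by the test
suite on null simulations):

- Student's pooled-df t is *exactly* calibrated on log-normal data
  (its df = 4 is exact under equal variances);
- Welch's test is *conservative* (≈ 0.011 observed at α = 0.02) because
  its Satterthwaite df is itself a noisy estimate. It never becomes
  anticonservative, so the default trades a little power for robustness
  to unequal variances.

Zero-variance probes (all replicates identical in both groups) get p = 1
when the means agree; otherwise a 1e-12 variance floor keeps the
statistic finite and the call obvious.

## Venn partition and pattern codes

Membership in the three DE lists partitions probes into the regions of a
three-way Venn diagram: a (T3 only), b (CORT only), c (combined only),
d (T3 ∩ combined), e (CORT ∩ combined), f (all three). The seventh
geometric region — T3 ∩ CORT without a combined response — is labelled
`g`; it is empty in data shaped like the four-arm study this pipeline
targets, but the partition must be exhaustive for arbitrary inputs, so
the identities are |T3| = a+d+f+g, |CORT| = b+e+f+g,
|combined| = c+d+e+f.

Intersection probes (d, e, f) are refined with a two-sided Welch test on
log2 signals of the combined arm against the relevant single arm at
α = 0.05 (the conventional default; the cut-off is exposed in config).
Codes follow the direction of the *combined* response:

| code | meaning |
|---|---|
| A1 | T3 response, abolished by CORT |
| B1/B2 | CORT response (induced/repressed), abolished by T3 |
| C1/C2 | combined-only response (induced/repressed) |
| D1 | T3 response enhanced by the combination (significant, larger, same sign) |
| D2 | T3 response reversed or suppressed by the combination (significant) |
| D3 | T3 response unaffected (not significant) |
| E1/E2 | CORT response unaffected by T3 |
| E3/E4 | CORT response enhanced by T3 (significant, \|log2FC_comb\| > \|log2FC_CORT\|) |
| E5/E6 | CORT response suppressed by T3 (significant, smaller) |
| F1 | responsive in all three arms (not subdivided) |

No fold-change requirement is attached to the refinement test. Probe →
gene collapsing keeps, per gene, the probe with the largest |log2 FC| in
its own section's defining arm (T3 for a, CORT for b/g, combined
otherwise), breaking ties on probe id; unannotated probes are dropped
and counted.

## Synergy

A probe is synergistic when either criterion holds:

1. **Combined-only**: DE in the combined arm with both singles ns —
   exactly Venn section c.
2. **Greater-than-additive**: evaluated on the Venn intersection probes
   (DE in the combined arm and ≥ 1 single arm). The combined mean must
   depart from the additive expectation by ≥ `sd_multiplier` × SD margin
   *on the synergistic side*, and the variance-sum Welch test must pass
   at α = 0.02. Both sub-rules are conjoined by default and can be
   relaxed individually.

The **additive expectation** defaults to x̄_T3 + x̄_CORT − x̄_VEH
(single-hormone effects above baseline add). The literal sum
x̄_T3 + x̄_CORT is retained as `literal_sum`; note that mode makes
synergistic repression undetectable, since the sum of two near-baseline
signals always exceeds a repressed combined signal.

The **SD margin** is √(var_T3 + var_CORT) in all modes — the summed
variances of the single treatments. The **Welch statistic** divides the
departure by √(Σ s²ᵢ/nᵢ) over the combined, T3 and CORT arms (plus VEH
under baseline correction), with Welch–Satterthwaite df over the same
terms and a two-sided p.

*Synergistic side*: the departure must point away from baseline in the
direction of the net single-hormone effect. Mere blunting of a
single-hormone response (combined pulled back toward baseline) is a
suppression pattern (B/E5/E6), never synergy. When the net single effect
is zero, either side counts.

*Intersection restriction*: criterion 2 is scored only on intersection
probes, matching the definition of the synergy set as
(section c) ∪ (intersections passing criterion 2);
`restrict_to_intersections=False` scores it everywhere.

### Power of the variance-sum Welch test at n = 3

A Monte-Carlo fact the benchmarks quantify and the test suite pins down
(and an independent from-scratch simulation reproduces): when the
combined arm sits k SD margins above the additive expectation under the
log-normal noise model, the combined arm's own variance grows with its
shifted mean, capping the Welch statistic near 5–6 at a Satterthwaite
df of roughly 2.5–3. At k = 6 with 0.15 log2 replicate noise the test's
power at p < 0.02 is ≈ 78%, and pushing k higher helps only marginally.
Overall synergy-caller sensitivity on the default planted mixture
(criterion-2 induced + criterion-1 repressed probes) is ≈ 90%, not the
~99% a normal-theory intuition with known variances would suggest. The
false-positive rate of the unrestricted criterion-2 rule on null probes
stays well below the nominal 2%. Users who need more power at this
design size should raise n or relax the conjunction to the margin rule.

A related geometric fact: a k-margin *repressed* departure below the
additive expectation requires the expectation to sit at least k margins
above zero signal. With repressing single effects the expectation is
already close to zero, so deeply greater-than-additive repression on
repressing singles cannot exist on the raw scale; real repressed synergy
arises through the combined-only route (singles inside the FC band),
and the generator's default repressed-synergy class is built that way.

## Regulatory mapping

Coordinates are BED: 0-based, half-open; gaps are edge-to-edge;
book-ended intervals have gap 0; different chromosomes are infinitely
far. Each gene's search window is its body ± `flank_bp` (default 50 kb),
clamped at the chromosome origin and strand-independent. A receptor
(GR/TR) peak counts for a gene when it overlaps the window at least
partially and lies within `proximity_bp` (default 1 kb) of some
enhancer-mark peak; the mark peak may sit outside the window. MED1 and
MED12 merge into one mark group. Per mark group a gene is classed
none / GR_only / TR_only / both.

The proximity search is a per-chromosome sorted sweep (binary search on
interval starts plus a running maximum of ends); the test suite checks
it for exact agreement with a brute-force all-pairs oracle on random
fixtures, including degenerate thresholds. Growing `proximity_bp` or
`flank_bp` can only promote a gene's class (none < single < both).

The control cohort is a uniform, seed-reproducible sample (default 300)
from the non-regulated gene universe, sorted by symbol before drawing so
the sample depends only on the seed and the candidate set. Inputs must
share one genome assembly; the pipeline rejects track/loci pairs with
disjoint chromosome names.

## Synthetic data

Expression: per probe a baseline log2 level ~ N(7.0, 1.5²) (≈ 128 signal
units, typical bead-array mid-range), class-specific log2 effects per
arm, i.i.d. N(0, 0.15²) log2 replicate noise, then exponentiation. The
combined arm is baseline + T3 effect + CORT effect + a planted departure
from additivity — in log2 units for pattern classes, in raw-scale SD
margins (the same quantity the caller thresholds on, via the
delta-method SD of a log-normal) for the synergy classes. Default class
fractions are small and CORT-rich, echoing the kind of four-arm
transcriptome the pipeline targets. Truth labels record class, planted
effects, expected Venn section and synergy direction.

Tracks: genes occupy disjoint slots wide enough that one gene's peaks
can never reach another gene's window; per gene and mark group, planted
receptor peaks sit inside the window with their mark partner at a
controlled gap — at least 2 bp below the proximity threshold for planted
pairs and at least 2 bp above it for decoys — so no coordinate
convention can flip a truth label. Receptor anchors for different mark
groups are spaced so cross-group contamination is impossible. The
default planted class fractions (e.g. 21/15/16% GR-only/TR-only/both for
H3K27Ac) echo the published per-class percentages for a synergy cohort,
so a 110-gene run reports 57/110 = 51.82% H3K27Ac-proximal.

What the generator does **not** emulate: probe-level microarray
artifacts (spatial effects, cross-hybridization, saturation), correlated
probes of one gene, realistic genome sequence or peak-width/score
distributions, and overlapping gene neighbourhoods. Passing recovery
tests therefore demonstrates the pipeline's statistical machinery under
its assumed noise model, not performance on any particular deposited
dataset.

## Benchmark problem sizes

The recovery benchmarks use 10,000-probe matrices across 5 seeds for the
synergy caller (≈ 5,000 planted, 45,000 null probes), 6,000 probes × 3
seeds for pattern recovery, one 20,000-probe matrix planted with the
published Venn composition for end-to-end count recovery, and a 110-gene
planted cohort for co-localization — sizes at which every reported rate
carries a few-per-mille binomial error.

## Known limitations

- No moderated-variance (empirical Bayes) testing; at n = 3 a limma-style
  shrinkage would add power but is deliberately out of scope.
- The per-probe test behind the original study's P values is unnamed
  vendor software; reproducing its exact gene lists from the deposited
  matrix may require matching that test and is expected to be
  approximate.
- Cross-assembly coordinate conversion (liftOver) is out of scope;
  inputs must share one assembly.
- Functional annotation clustering and motif scoring are external
  analyses; the pipeline only exports gene sets.
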