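# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; 1-based input tables are
converted at the reader boundary. An origin's *anchor* is the integer
midpoint of its annotated interval — the annotation gives an interval,
not a point, and the midpoint is the symmetric, reproducible choice. A
site exactly at the anchor has no defined strand role and is excluded
from tallies (a measure-zero convention, logged when it fires).

The strand-role rule follows bidirectional replication: downstream of
the anchor the plus strand is the nascent leading strand and the minus
strand the lagging strand; upstream the roles swap. The rule is
mirror-symmetric: reflecting coordinates about the anchor and flipping
strands preserves every site's role (property-tested).

## Origin classes, flanks and bins

Origins are split into early/late halves at the **median** of the known
firing times, with ties at the median classified early (T ≤ threshold).
Efficiency classes use fixed thresholds: high ≥ 0.7, low ≤ 0.5, mid in
between. Records lacking a value are labelled unknown and never force a
class.

Each origin gets 15-kb flanks on both sides (configurable), truncated at
chromosome ends and — when neighbouring anchors are closer than twice
the flank length — at the fork-collision point

x = (anchor_A + anchor_B)/2 + v·(t_B − t_A)/2,

with fork speed v = 1.6 kb/min. The point is clamped into
[anchor_A, anchor_B]: a fork that would nominally pass the neighbouring
origin truncates at that origin's anchor. When a neighbour lacks a
firing time the inter-anchor midpoint is used and the fallback flagged.
Flanks are cut into 500-nt bins numbered outward from the anchor; a
truncated flank's terminal partial bin is kept with its true size (used
as the RPB denominator), since dropping it would bias truncated flanks.

## Rate measures and the ratio model

RPB = site count / region size; PPB = RPB / library total. PPB is
conserved: Σ_bins PPB·bin_size·library_total equals the flank count
exactly.

For libraries i = 1..N of one genotype-and-technique group, leading and
lagging tallies are modelled as X_i ~ Poisson(r_i·a·L) and
Y_i ~ Poisson(r_i·b·L) with unknown capture rates r_i. Maximizing the
joint likelihood in (a, b) gives a = ΣX/(L·Σr), b = ΣY/(L·Σr), so the
ratio θ = a/b has the capture-rate-free MLE θ̂ = ΣX/ΣY. Its delta-method
standard error is θ̂·√(1/ΣX + 1/ΣY). ΣY = 0 with ΣX > 0 is reported as
an infinite-ratio signal, both zero as undefined — distinct from errors.

Per-origin log ratios use the natural logarithm (configurable base,
recorded in output metadata). Origins with a zero on either strand are
excluded from regressions rather than pseudocounted — pseudocounts would
bias exactly the small-count origins the regression is most sensitive
to; exclusion counts are reported. The regression itself is ordinary
least squares (scipy.stats.linregress) of log θ on firing time or
efficiency, with a t-based slope confidence interval.

## Changing-phase detection

Given the binned θ series θ_1..θ_K (bins with zero lagging counts are
skipped), the chord slope from the first bin,
slope_k = (θ_k − θ_1)/((k−1)·bin_size), is computed for every k ≥ 2.
The baseline is the first bin's θ because no observed value exists at
x = 0. The phase direction is the sign of the dominant extreme slope
(|min| vs max); slopes within 10⁻⁹ of zero throughout mean no phase
(end_bin 0, extent 0). The phase ends at the *largest* bin attaining the
extreme slope — slopes within the 10⁻⁹ tolerance of the extreme count as
ties — so the detected phase covers the full rise or fall; extent =
end_bin·bin_size. The implementation is checked against an independent
brute-force slope enumeration over a grid of series.

## Mann–Whitney U

One-sided tests (leading vs lagging pattern frequencies, early vs late
percentages) use the exact null distribution for tie-free samples with
n_x + n_y ≤ 12, and the tie-corrected normal approximation with
continuity correction otherwise. Samples in which every observation is
identical return p = 0.5 (the statistic is degenerate at its mean).
Exactness is property-tested against full enumeration of rank splits.

## Fork simulator

The expected incorporation rate at distance x from the anchor:

* **leading**: the Pol δ rate (1/5000 per nt) out to the visible δ-tract
  end, the Pol ϵ rate (1/1250) beyond. Only these two phases are visible
  downstream of the anchor because the Pol α primer (~10 nt, starting
  ~100 nt upstream) lies before it; `leading_start_offset` and the
  visible tract length are configurable.
* **lagging**: Okazaki-periodic — 10 nt at the Pol α rate (1/625) then
  160 nt at the Pol δ rate, repeating with period 170 nt. The period is
  taken as 10 + 160 = 170 from the stated tract lengths (a ~200-nt
  figure also circulates; the period is configurable).

Genotype multipliers act multiplicatively on exactly one polymerase:
ϵ-mutants (pol2-M644G) ×5, δ-mutants (pol3-L612M/G) ×10; the α-mutant
fold change is not established and must be supplied explicitly.

The combined-origin profile averages n = 400 (default) single-origin
profiles, each with anchor jitter ~ Normal(0, 1000 nt), a leading
δ-tract ~ Uniform(500, 4000 nt) and a uniform Okazaki phase. Positions
upstream of a jittered origin keep the δ rate (the handoff has not
happened there), which makes every per-origin leading profile a
non-decreasing step function for wild type — hence the averaged ramp is
exactly monotone, converging to the analytic mixture
δ·P(tract > x − jitter) + ϵ·P(tract ≤ x − jitter). Profiles are
deterministic given (config, seed). The ratio of a profile divides the
leading rate by the bin-averaged lagging rate to remove Okazaki
periodicity. Parameter changes rescale the axes but not the
increase/decrease trends, so tests assert trends and asymptotes rather
than curve shapes.

## Composition analysis

Windows are named offsets from the anchor (presets 0–100, 0–200, 0–500,
4000–10000 nt) measured outward along a strand role's direction; each
origin contributes a downstream and an upstream interval per role, with
the nascent orientation on the plus strand downstream/minus upstream for
leading (reverse for lagging). Termination-zone windows flank each
fork-collision point; the leading orientation flips across the point
because the approaching forks converge. Windows clamped against an
anchor are truncated and flagged.

Background mono- and dinucleotide frequencies are computed from the
reference sequence of the same windows, reverse-complemented where the
nascent orientation is the minus strand — window- and role-specific
backgrounds, not genome-wide ones, so that strand asymmetry of the
reference cannot masquerade as incorporation preference. Observed rNMP
bases (complemented for minus-strand sites) and their 5′ (NR) or 3′ (RN)
neighbours in nascent orientation are counted, divided by the matching
background frequency, and renormalized to sum to 1 over the four bases
(mono) or the four neighbours of each fixed rNMP base (dinucleotide);
0.25 everywhere means no preference. Neighbour lookup is genomic — a
neighbour just outside the window still counts; only sites whose
neighbour falls off the chromosome are skipped (tallied). Libraries
contributing fewer than 100 rNMPs to a window group are excluded from
mono tables, fewer than 400 from dinucleotide tables, both scoped per
window group.

## Synthetic data generator

The generator realizes the estimator's own model so that recovery tests
are exact in expectation: per position and strand of every origin flank,
counts are Poisson with mean r_i · rate(role) · w(5′ neighbour, base,
role). Context weights are multiplicative and not renormalized, keeping
rates interpretable as absolute probabilities; a configuration whose
per-position probability reaches 1 is rejected. Positions are sampled
independently (no site clustering).

Defaults (one 500-kb chromosome, 10 origins ≥ 40 kb apart so 15-kb
flanks never collide, firing times Uniform(10, 45) min, efficiencies
Uniform(0.3, 0.9), a = 2×10⁻³, b = 1×10⁻³ per nt, one library at capture
rate 1) give ~600 leading and ~300 lagging counts per library — enough
for θ̂ recovery within a few percent while keeping a full generate-
analyze cycle under a second. These rates are far above physiological
ones; what matters for validating the estimator is the count regime, not
the absolute rate. A manifest records the true a, b, θ, capture rates
and seed for scoring.

What the generator does *not* emulate: technique-specific capture biases
beyond a scalar r_i (the reader's `offset` handles techniques that mark
a neighbour of the rNMP), rNMP-dense clusters, chromatin context, and
real yeast sequence composition. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data features.

## Numerical and degenerate-input choices

* Collision points are rounded to the nearest integer coordinate.
* Zero-length flanks (dense origin clusters) are kept and recorded, and
  produce empty bin lists.
* Bins whose pooled lagging count is zero yield θ = ∞ and are excluded
  from phase detection.
* Composition rows with a zero background and zero count are 0; a zero
  background with a positive count raises an error rather than silently
  producing infinity.
* Mann–Whitney exactness cutoff (n ≤ 12, tie-free) trades enumeration
  cost against approximation error; at n = 12 the normal approximation
  is already accurate to ~0.01.

## Problem sizes in the test suite

The suite validates on desk-scale inputs chosen to keep every check
sharp: 10–24 origins per synthetic dataset, 10⁵–10⁶-nt genomes,
hundreds to thousands of Poisson counts per library, 100–200 Monte-Carlo
replicates for recovery statements, 10,000 origins for the combined-
profile convergence check, and exhaustive enumeration up to length-5
series (plus 2,000 random longer ones) for the phase-detection oracle.

## Known limitations

* Flank truncation treats each neighbour pair independently; the
  ordering of truncations inside dense clusters of ≥3 origins is not
  jointly optimized (each side truncates against its nearest neighbour).
* Library pooling follows the MLE derivation (counts pooled within a
  genotype-and-technique group before ratio computation); a per-library
  mode exists but no weighting scheme between groups is provided.
* The simulator's termination behaviour is limited to the collision
  geometry; the Pol ϵ→Pol δ switch zone on the approaching leading
  strand is represented only through the termination-zone windows of the
  composition analysis, not as a rate change in the profile.
* No confidence bands on θ beyond the Poisson standard error, and no
  robust/weighted regression variants.
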