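# Methods

## Study design and data model

The package analyzes population-by-sample abundance tables from a
112-hour Lagrangian sampling series anchored at 16:00 local time: surface
(SUR) samples every 4 h (29 scheduled, 2 masked as unusable, 27 analyzed)
and deep-chlorophyll-maximum (DCM) samples every 12 h (10 scheduled, 2
masked, 8 analyzed). Abundances are trimmed-mean read coverages normalized
per 10⁹ quality-trimmed reads:

    value[i, j] = coverage[i, j] / clean_reads[j] × 10⁹.

Masked samples stay in files and metadata with `included = False`; each
analysis stage decides whether to drop them (all statistical stages do).
Whether a table on disk is pre- or post-normalization cannot be detected
from the file, so the loader accepts either and `normalize_coverage` is an
explicit, optional step.

## Diel rhythm detection

**Detrending.** Each series is reduced to OLS residuals of abundance on
*elapsed hours* (not sample index — masked gaps keep their true spacing)
over included samples. Residuals have zero mean and zero empirical slope,
and detrending is idempotent.

**Time-of-day classes and alternatives.** Included samples pool into
c = period/Δt classes (SUR: c = 6, DCM: c = 2). An umbrella alternative
is an ordered (peak, trough) class pair: abundance is postulated to rise
monotonically from the trough to the peak along one arc of the circular
clock and to fall back along the other. All c(c−1) alternatives are
scanned (30 for SUR, 2 for DCM).

**Statistic.** For one alternative, each arc is walked trough → peak and
every ordered class pair (i before j) on the walk contributes the
Mann–Whitney count #{x ∈ i, y ∈ j : x < y} + ½·#ties. Both the trough and
the peak class belong to both arcs, so the direct trough/peak pair is
counted once per arc (pair weight 2); pairs between the interiors of
different arcs are never compared. Two consequences used as tests: the
statistic plus its reversal (peak and trough swapped) equals the total
weighted pair count, and the permutation null mean is half that count.

**Null distribution.** Three routes:

* *Exact, tie-free* — a dynamic program places ranks smallest-first into
  classes; adding a rank to class g raises the statistic by
  Σᵢ countᵢ·w[i, g]. States are class fill counts with exact integer
  arrangement tallies; the program handles any nonnegative pair-weight
  matrix and is refused (falling back to the normal route) only if the
  total arrangement count would overflow 64-bit integers. The tie-free
  null depends only on class sizes and weights, so one table per
  alternative serves every population of a layer, and a reversal
  alternative reuses the mirrored table.
* *Exact, with ties* — complete enumeration over all n! assignments for
  n ≤ 8; the independent oracle against which the DP is verified.
* *Normal* — Gaussian upper tail with ½ continuity correction, using the
  exact permutation mean and variance. The variance comes from the
  covariance of weighted pair counts: every pair-of-pairs slot pattern
  (shared first class, shared second class, chain overlaps, identical
  pair, reversed pair, all distinct) is counted and weighted by the
  matching moment of the pair indicator ψ(x, y) = 1{x<y} + ½·1{x=y}
  computed from the observed tie structure. The moments are verified
  against enumeration in the tests.

The scan uses the exact route for tie-free series (ties, in practice, only
arise in degenerate series such as constants, which correctly get p = 1);
the direct `jt_pvalue` API defaults to exact for tie-free n ≤ 12 and the
normal approximation otherwise. The exact route matters: at the
per-alternative Bonferroni threshold the normal tail overestimates p by
~40 %, which would make the scan needlessly conservative.

**Multiplicity.** Per population, p = min over alternatives of the
alternative's p times the *effective* number of distinct alternatives
(weight matrices deduplicated; all 30 are distinct for SUR), capped at 1.
Across populations, Benjamini–Hochberg step-up adjustment; diel means
adjusted p ≤ α (default 0.05). This per-shape Bonferroni over strongly
dependent alternatives is conservative by construction: on 1,000 simulated
pure-noise populations the raw-p rejection rate at α = 0.05 is ≈ 0.033
(reproduced by the acceptance suite), not 0.05. Populations with zero
abundance in every included sample of a layer are excluded from that
layer's scan and from "% diel" denominators.

**Host-level testing** sums abundances per predicted host genus per sample
and scans the genus × sample matrix identically. Exact antiphase pairs
cancel to a constant and are correctly non-significant.

## Peak timing and day/night labels

All included values of a series are ranked together (mid-ranks on ties),
ranks are averaged within each time-of-day class, and the peak is the
class with the highest mean — a rank heuristic invariant to monotone
transforms. Exact between-class ties resolve to the circular midpoint of
the tied clock times (20:00 with 00:00 → 22:00); antipodal ties and
all-tied (constant) series are reported as "no peak". Night is the
circular window [18:00, 06:00), closed at 18:00 — so a 04:00 peak is
night and a 12:00 peak is day; the window is configurable. Peak ranks are
computed on the raw (not detrended) series by default in the CLI-level
report; the function accepts either, and rank invariance makes the choice
immaterial for monotone drifts only, so strongly trending series should be
detrended first.

## Archetype discovery

Diel series are detrended and standardized per row (mean 0, SD 1 over
included samples) so Euclidean distances compare waveform shape, not
magnitude; zero-variance rows are excluded with a warning.

*Clusterability.* Hopkins statistic with m = ⌈0.1 n⌉ probes: h =
Σu/(Σu+Σw), where u are nearest-real-neighbor distances of uniform draws
in the data bounding box and w are nearest-other-neighbor distances of
sampled real points. h ≈ 0.5 means no structure; the acceptance suite
verifies 0.50 ± 0.05 on uniform data and > 0.9 on tight clusters.

*Methods.* (1) 1-D batch self-organizing map: k prototypes on a line,
500 epochs, Gaussian neighborhood with radius decaying linearly k → 0.5,
batch updates to the neighborhood-weighted mean; empty units are reseeded
from the worst-fit point; labels are best-matching units. (2) PAM
(BUILD + steepest-descent SWAP) on the Euclidean distance matrix.
(3) Complete-linkage agglomerative clustering cut at k. All are
deterministic given a seed. These SOM hyperparameters (grid, epochs,
schedule) are package defaults, not claims about any external analysis.

*Model selection.* Every method is fitted at every k in the range
(default 2–6). Fit quality: Calinski–Harabasz on the data vectors and
mean silhouette on the distance matrix — each metric on the input it
naturally consumes. Per method the operating k is the *elbow of the
silhouette profile*, read as the point where the decline begins: a profile
that first rises takes its maximum (ties → smaller k); a profile
decreasing from the start takes the k preceding its largest drop, unless
no drop reaches twice every other drop, in which case there is no clear
elbow and the smallest k is reported with a warning. The winning method is
the one with the highest silhouette at its chosen k (ties prefer the SOM),
and the report includes the k ± 1 fits for inspection. The "decline
begins" reading matters in practice: on planted three-archetype data the
profile rises from k = 2 to a maximum at k = 3 before decaying, and a
literal largest-drop rule would land on the decay tail rather than the
true cluster count.

## Diversity

Inverse Simpson is computed on abundance shares within a sample (the
per-sample normalization cancels in the shares). Bray–Curtis uses
log₂(x+1) by default — the pseudocount is a package choice forced by
ubiquitous zeros. PCoA double-centers −d²/2 and keeps positive-eigenvalue
axes; for Euclidean-embeddable input the retained space reproduces the
distances to numerical precision (a self-consistency oracle in the
tests). MRPP uses δ = Σ (nᵢ/N) · mean within-group distance with
lower-tail permutation p; ANOSIM uses R = (r̄_between − r̄_within)/(M/2)
on ranked distances with upper-tail permutation p. Both use the add-one
convention p = (1 + hits)/(1 + n_perm), a seeded generator, and default
n_perm = 999; sub-uniformity under the label-exchange null is verified by
simulation. Day/night contrasts default to night = {20:00, 00:00, 04:00}
versus day = {08:00, 12:00, 16:00} clock samples; the windows are
configurable since day/night boundaries are a convention.

## AMG curation

A gene survives only if every rule passes: R1 auxiliary score ∈ {1,2,3};
R2 metabolic module OR flag M/K/E; R3 inside a viral region call OR
contig virus score ≥ 0.95; R4 no mobile-genetic-element keyword
(case-insensitive substring over the contig's gene annotations — one
flagged gene taints the contig); R5 if adjacent to a phage genome end,
no tRNA or repeat overlap; R6 (toggleable) KEGG KO present. The "and/or"
inside R2 and R3 is an inclusive OR; the rules combine conjunctively, so
removing any single rule can only grow the kept set (a tested
monotonicity). The audit records every failed rule per gene. Whether the
KO requirement is part of the conservative chain or a subsequent step is
ambiguous in common usage; it is modeled as rule R6 with a toggle.
Depth exclusivity of an AMG-bearing population means nonzero abundance in
at least one included sample of one layer and zero in all included
samples of the other.

## Synthetic data

Diel rows follow value(t) = exp(b + s·t + ε_t) · w(clock(t)): log-normal
baseline b ~ N(3, 1) (natural-log scale of normalized coverage), linear
log-drift s ~ N(0, 0.005/h), iid log-noise ε ~ N(0, noise_sd = 0.3), and a
24-h periodic waveform w with max/min ratio = amplitude (default 4). The
default waveform is piecewise log-linear — rising over `rise_hours`
(default 8) to the archetype's peak, falling over the remainder — so the
simulated alternative matches the umbrella test's alternative exactly; a
log-cosine option exists for robustness checks. Default archetypes peak at
20:00, 04:00 (night, weight 0.4 each) and 12:00 (day, weight 0.2).
Non-diel rows omit w. Noise is multiplicative log-normal, not count noise,
because the pipeline consumes continuous normalized coverages. Masked
samples are simulated and then flagged, so masked and full analyses can be
compared. A single root generator drives every draw; identical seeds give
byte-identical outputs.

What the generator does *not* emulate — and hence what green tests do not
establish about field data: compositional coupling between populations,
autocorrelated (red) noise, burst-like lytic dynamics, depth migration,
read-mapping artifacts, and detection-limit zeros (zeros arise only in
hand-built fixtures). Type-I calibration on iid log-normal noise says
nothing about autocorrelated series, for which pooled-by-class rank tests
can be anticonservative.

## Problem sizes and numerics

The test and acceptance workloads use 300–1,000 populations per run, 500
replicates for permutation-calibration checks, and 100 seeds for Hopkins
references — sizes at which every stochastic band in the suite is stable
across seeds. Numerical conventions: ties get mid-ranks / ½-counts
throughout; permutation p-values are never 0 (add-one convention);
constant series give p = 1 in the rhythm scan and "no peak" in peak
timing; all-zero sample pairs get Bray–Curtis 0 with a warning; negative
PCoA eigenvalues are dropped; zero-variance rows are excluded from
scaling with a warning.

## Known limitations

* The umbrella test's per-shape Bonferroni is conservative under the
  strong dependence among alternatives (measured ≈ 0.033 raw type-I at
  α = 0.05); an exact max-statistic null would be sharper but is not part
  of the procedure modeled here.
* p-values from other umbrella-test implementations need not match
  bit-for-bit: internal multiplicity corrections differ between
  implementations, and only the construction documented here is
  guaranteed.
* The DCM design (8 included samples, c = 2) has little power; a lack of
  detected rhythms there is expected behavior, not evidence of absence.
* PAM uses steepest-descent swaps; for very large k·n the classic
  O(k(n−k)²) sweep dominates runtime before clustering quality does.
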