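# Methods

## The screening model

The expression screen treats the post-normalization (RMA-style) log2 matrix
as given; normalization and probe summarization are upstream and out of
scope. The unit of replication is the pooled array: 4 treated and 4 control
pools, each an equal-RNA pool of 3 animals. Per probe:

* ALR = mean(treated pools) − mean(control pools) (data already log2, so a
  difference of means is a log2 ratio; |ALR| = 0.585 ≈ 1.5-fold).
* Two-tailed equal-variance Student *t* with df = n_T + n_C − 2 = 6. The
  equal-variance form is the conventional choice for a balanced pooled
  design; Welch's form is available (`variant="welch"`). Degenerate probes
  (zero variance in both arms) return (t = 0, p = 1) when means are equal
  and (±∞, 0) otherwise, so constant probes never masquerade as hits.

### Permutation FDR

The null is estimated by re-labeling the 8 pools into balanced halves, each
mixing 2 treated with 2 control pools, so a true treatment effect cancels
within each side. Three fixed designs are used by default:

* Boot 1: c1-c2-e3-e4 vs c3-c4-e1-e2
* Boot 2: c1-c3-e2-e4 vs c2-c4-e1-e3
* Boot 3: c1-c4-e2-e3 vs c2-c3-e1-e4

For a stringency (|ALR| ≥ a, P < p), FDR = 100 × mean(null counts) / EXP.
The default aggregation (`fdr_boot_agg = "first_two"`) averages the first
two designs only: this is the convention under which the published
stringency grid this screen reproduces was computed (all seven printed FDR
values match it exactly, and none match the three-design mean). The
principled all-designs mean is available as `"mean_all"`. For non-4v4
designs, all 18 distinct balanced splits can be enumerated instead.

Threshold conventions are |ALR| **≥** a ("reaching" the fold change) and
P **<** p; ties have measure zero on continuous data but the convention is
fixed and tested. FDR is undefined (NaN) at zero experimental hits and may
exceed 100%.

### Stringency selection and robustness

The selected stringency minimizes FDR among rows with at least `min_exp`
(default 10) experimental hits. The guard exists because a row with a
single hit and zero null hits has a nominal 0% FDR but no usable yield;
without it the selection is dominated by noise at the extreme thresholds.
Ties break toward larger yield, then larger |ALR|.

The robustness filter forms all 16 individual treated-vs-control pool
differences per probe and keeps probes with |difference| ≥ 0.585 in at
least 9 of 16. In the full pipeline this filter is applied to the probes
passing the selected stringency (a refinement of that list); the filter
function itself is usable standalone. The reported per-probe s.d. is the
sample standard deviation of the 16 differences. The pipeline stores an
unsigned robustness count plus a direction flag; a signed convention
(−sign(ALR) × count) exists in some published tabulations and can be
emitted by report code if needed.

## Gene-locus GWAS statistic

Lookup regions span all of a gene's transcripts padded 20 kb per side,
floored at position 1; coordinates are 1-based inclusive everywhere in the
package, with BED's 0-based half-open intervals converted on ingest.
Locus-wide significance is min(1, p* × n): a per-gene Bonferroni bound
using the raw marker count, not an effective number of tests — fidelity to
the modeled lookup procedure is preferred over LD-aware power. Under
independent uniform nulls the bound is nearly exact for small α
(P ≈ 1 − e^(−α) ≈ 0.0488 at α = 0.05), which the calibration tests assert;
under LD it is conservative. Ties for best marker resolve to the smallest
position for determinism. The experiment-wide correction multiplies each
locus's best P by the total marker count over all tested loci.

The packaged `candidate_loci.tsv` carries the 20 candidate schizophrenia
loci (hg19 region, marker count, best marker and its P) that the lookup
analyses and the acceptance script consume as inputs.

## CNV refinement

Order: outlier-sample exclusion → minimum-marker filter → joining. The
outlier rule (call count > median + 3×MAD; IQR substitutes when MAD = 0,
and when both are 0 any count above the median is flagged) is a documented
stand-in — the modeled procedure never defines "sample outliers" — and an
explicit exclusion list is honored verbatim for fidelity. Calls with fewer
than 10 markers are dropped (≥10 kept).

Joining is greedy over adjacent calls within one (sample, chromosome,
copy-state) group, iterated to a fixed point; deletions never join
duplications. The criterion — total gap length < 50% of the joined span —
is evaluated on the union of the original member intervals, not on
bounding boxes, so chained fragments merge exactly when the original rule
allows. For ≥3 fragments the pairwise rule is ambiguous; the greedy
fixed-point result is verified in tests against a brute-force enumeration
of all reachable merge orders on groups of ≤5. Whenever the full set of
fragments satisfies the criterion jointly, at least one adjacent pair does
too, so the greedy iteration provably restores fully mergeable events.
Merged marker counts are the sum over members: markers inside gaps are
unknowable from a call list (documented limitation). Overlap annotation
requires ≥1 bp intersection with the locus (exon-disrupting: with any
exon) and tolerates `chr`-prefix differences.

## Synthetic data

The generator simulates animals, then pools: each animal value is
baseline + signed effect (treated, DE probes only) + N(0, animal_sd); each
pool is the mean of its 3 animals plus N(0, tech_sd) array noise. Pool
variance is therefore animal_sd²/3 + tech_sd², the variance reduction that
makes the 4v4 pooled design workable, and is Monte-Carlo-checked against
that closed form.

Defaults: 31 000 probes (the array scale of the emulated design), 20 DE
probes at |effect| = 0.8 log2 units with random sign (the magnitude range
of a strongly selected hit list), baseline 7.0. The noise scales —
animal_sd = 0.35, tech_sd = 0.12, giving pool-level s.d. ≈ 0.23 — are the
package's own calibration: no per-probe noise scale is available for the
modeled data, so values were chosen within the range typical of
post-normalization log2 replicate data, large enough that the null matters
(the robustness filter's per-pair null exceedance is ≈ 8%) and small
enough that the tests retain power. Synthetic results therefore
demonstrate correctness of the machinery, not the magnitudes of any real
experiment: real probe-level noise is heteroskedastic and correlated
across probes, neither of which is modeled.

GWAS markers are placed uniformly without replacement; null P-values are
Uniform(0,1) with no LD, the simplest null under which the min-P × n
statistic is calibrated. A spiked locus receives one marker at exactly the
requested P; null draws below the spike are redrawn above it so the spike
is provably the locus minimum (at genome-wide-significant spike levels the
redraw is almost never triggered and the null is essentially undistorted).
True CNV events are fragmented into 2-3 pieces with total gap ≤ 40% of the
span — strictly inside the 50% joining criterion — with marker counts
apportioned over fragments (each ≥ 10 so the fragments survive the marker
filter); events too short or too marker-poor to split cleanly are emitted
intact.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical config + seed gives byte-identical outputs
  (hash-compared in tests). The provenance digest excludes the output
  directory, which locates results but does not influence them.
* Problem sizes in the test-suite simulations (2 000-10 000 probes,
  hundreds of loci, ≤ 700 CNV events) are chosen so the whole suite runs
  in a few seconds while keeping Monte-Carlo error well inside the
  asserted tolerances; the analysis drivers run the full 31k-probe scale.
* The expression screen's P-values rely on `scipy.stats.t`; the t statistic
  itself is computed directly so an independent library implementation
  remains available as a cross-check in the tests.
* Fragmented-event restoration in the end-to-end test is assessed on
  samples not flagged by the outlier rule: fragmentation inflates
  per-sample call counts, and a sample excluded for that reason loses its
  events by design, not by error.

## Known limitations

* The FDR estimator divides mean null counts by the experimental count;
  it is an estimate of the false-discovery fraction at a threshold, not an
  FDR-controlling procedure, and can exceed 100%.
* No LD, no marker-density variation, and no genotyping noise in the GWAS
  simulation; locus-wide calibration under dependence is conservative.
* Merged CNV marker counts undercount markers spanning former gaps.
* The outlier-sample rule is heuristic; use the explicit-list mode to
  reproduce a specific published exclusion.
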