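# Methods

This note records the models behind `tetramap`, the defaults and why they
were chosen, what the bundled simulator does and does not emulate, and
the numerical choices a maintainer would want to know.

## Inheritance model

All analysis assumes an autotetraploid with polysomic (tetrasomic)
inheritance: at meiosis the four homologs pair at random. Under bivalent
pairing the three possible pairings are equiprobable and a gamete
receives one chromatid per bivalent, so at a single locus a parent of
dosage *d* transmits *k* allele copies with hypergeometric probability
C(d,k)·C(4−d,2−k)/6. Disomic inheritance (strict preferential pairing
over two fixed subgenome pairs, each segregating like a diploid locus) is
implemented only for segregation-pattern enumeration and QC candidate
fitting; linkage analysis is polysomic throughout. Enumerating all
parental dosage pairs over both modes and deduplicating by offspring
distribution yields exactly 20 distinct expected segregation patterns.

## Two-point model

For a marker pair, each parent is described by the homolog sets carrying
the two markers' allele copies; under random pairing only the overlap
matters (overlap = min(d₁,d₂) is coupling, 0 is repulsion). Per bivalent
the transmitted chromatid takes either member with probability 1/2 at
marker 1 and switches with probability *r* at marker 2; no interference
is modelled within a pair, and double reduction is excluded from the
likelihood (it is rare, and robustness to small quadrivalent rates is a
simulator test, not a model feature). Averaging over pairings and
convolving the two parents gives the exact 5×5 offspring law. The
multinomial log-likelihood is profiled on a 201-point grid over
r ∈ [0, 0.5] per admissible phase and refined by bounded scalar
minimisation (tolerance 10⁻⁶); batch scans use parabolic interpolation on
the same grid instead. Model probabilities are floored at 10⁻⁹ so that
occasional miscalls outside a phase's support penalise rather than
annihilate the likelihood. Pairs whose profile is flat (grid curvature
< 10⁻⁶) or whose table is degenerate are flagged `low_information`.
Offspring missing at either marker are dropped pairwise, matching the
multinomial likelihood.

Two estimation modes exist. `phases="all"` maximises over every
admissible overlap pair — full phase inference. `phases="coupling"`
evaluates only the maximal-overlap configuration, on the original marker
coding and on the mirrored (x → 4−x) recoding of the second marker. For
simplex markers the mirrored coupling model is algebraically identical to
the repulsion model (the complement of a simplex subset is a triplex
subset sharing one homolog), so the orientation flag cleanly labels
same-homolog (non-mirrored) versus different-homolog (mirrored) linkage
while keeping the JoinMap-style coupling workflow. Mapping scans use this
mode; `.pwd` files report its estimates.

## Marker quality control

Filters run in order: (a) markers with > 10 % missing offspring calls on
either probe are dropped (the criterion is standard; the fraction is this
package's default, configurable); (b) the SNP's two array probes must
disagree at < 4 % of jointly scored offspring and (c) both probes'
best-fitting segregation patterns must be identical, after which the
higher-confidence call per sample is kept (missing only if both are);
(d) the χ² best fit (classes with expected count < 1 pooled into a
neighbour; observed counts in zero-probability classes reject a candidate
outright) must reach P ≥ 0.05 and admit a generating parental dosage pair
consistent with the scored parents — the father unconstrained when
unknown. P values are unadjusted for multiple testing, deliberately.

## Disentanglement

Pairwise genetic distance is the mean absolute dosage difference over
jointly scored markers, scaled to [0, 1]; it uses the full dosage
information and reduces to simple matching on {0,4} data. Restricted to
markers monomorphic (dosage 0 or 4) in the mother, it reflects only the
paternal contribution. Classical metric scaling (double-centring,
eigendecomposition) embeds the distances; k-means (k ≤ 3, 50 restarts,
fixed seed) on the first two coordinates is accepted only if the best
silhouette reaches 0.5 — the usual "reasonable structure" rule of thumb,
needed because k-means on a featureless cloud still scores ≈ 0.35 while
genuine father-structure scores > 0.9 on simulated data.

A candidate father is rejected when more than 5 % of markers are
incompatible: an offspring dosage class with ≥ 2 observations that is
impossible under every inheritance mode for the scored parental dosages,
or a best fit below P = 0.001 (counts under the 2-observation tolerance
in impossible classes are presumed miscalls in both routes). These
thresholds tolerate the simulator's default genotyping-error rate. The
unknown parent's dosage per marker is the maximiser of the multinomial
likelihood over father dosages 0–4 (polysomic only), with the log₁₀
best/second-best ratio as confidence. The selfing test combines (i) the
fraction of reference S×N markers whose best-fitting distribution in the
test population is 1:2:1 — compared as distributions, since several
parental configurations share one distribution — with (ii) mean offspring
heterozygosity (dosage ∈ {1,2,3}) versus the parent's, tested by a
two-sided bootstrap over markers (10⁴ resamples, fixed seed; no
distributional assumptions). The verdict requires consistency ≥ 0.95
(when a reference exists) and significantly lower offspring
heterozygosity.

## Map construction

Markers informative for the focal parent (S×N; S×S in a selfed
population, where no S×N can exist) are grouped at LOD > 4 by connected
components. Homolog separation then proceeds in two steps. First, by
assigned phase: components of the subgraph restricted to non-mirrored
(same-homolog) coupling edges at LOD > 4. This step is necessary because
the classical gap rule alone cannot resolve more than two merged
homologs — every cross-homolog pair sits at an apparent ≈ 40 cM, so 1-D
seriation interleaves three or more homologs instead of separating
them — and in a selfed population repulsion linkage genuinely exceeds
LOD 4 at n ≈ 100 (both parental meioses are informative). A single
coupling edge whose removal separates two sides of ≥ 4 markers each is
pruned as spurious (a genuine homolog chain is locally dense; with ~10⁵
scanned pairs one chance LOD > 4 edge would otherwise fuse two
chromosomes). Second, the gap rule as backstop: each ordered fragment is
split at inter-marker gaps above 35 cM — the expectation for co-mapped
homologs is kosambi(1/3) = 40.2 cM, and 35 leaves margin for estimation
noise. Homolog groups are connected into chromosomes by bridge markers
(D×N, S×S) with non-mirrored LOD > 4 links into two groups, and by shared
array contigs (marker name up to the final underscore token); a cluster
implying more than four homologs per parent is flagged, never silently
merged.

Within a homolog, markers are seriated by the first principal coordinate
of the Kosambi-transformed r̂ matrix (missing entries completed by
shortest paths) and, alternatively, by the Fiedler vector of the LOD²
weight graph — both starts are polished by segment reversals and
single-marker reinsertions minimising the weighted stress, and the lower
stress wins. Positions are weighted least squares over all pairs with
r̂ < 0.49 (Kosambi diverges at 0.5), weights LOD² (a standard
inverse-variance proxy for regression mapping), first marker at 0,
markers re-sorted by fitted position. The reported `fit_stress` is the
weighted RMS residual relative to the weighted distance scale.

## The simulator

`simcross` emulates a tetraploid F1 experiment end to end: phased
parents, meiosis, crosses (including selfing and admixed multi-father
batches), and array-style observation. Crossovers follow a per-interval
Markov rule calibrated so the chromatid recombination fraction across one
marker interval equals the inverse-Kosambi transform of its cM width —
simulator distances and the mapping function are therefore mutually
consistent interval by interval. Across several intervals the chain
composes recombination Haldane-fashion, slightly below the Kosambi value
at long range; fitted maps are consequently a few percent short of the
nominal span (≈ 10 % at the default marker density), well inside the 20 %
recovery tolerance asserted in the tests. Quadrivalents form with
probability q (default 0, so the bivalent laws hold exactly); given one,
the gamete's second chromatid is replaced by a sister copy of the first
with probability rising linearly from 0 at the proximal end to
`double_reduction_max` distally — the simplest monotone gradient
consistent with double reduction increasing towards telomeres. At the
proximal end the two draws still coincide on one homolog 1/4 of the time
(they are then sisters), so the dosage-2 rate of a simplex parent runs
from 1/16 proximally to 1/4 distally at maximal settings.

Observation noise emulates mixture-model dosage calling: a shared ±1
miscall layer (clipped to 0–4), per-probe missingness with confidence
below the 0.95 assignment threshold, and a second probe that duplicates
the first except at a configurable fraction of disagreeing calls plus its
own missing pattern.

The default experiment mirrors the study design the package targets:
7 chromosomes × 100 cM, 152 markers per chromosome on contigs of 1–3
co-located SNPs (the per-class counts put ~47 % of markers monomorphic in
the mother, 48 S×S and 24 S×N per chromosome), 103 selfed plus 74
outcrossed offspring in one admixed batch, 2 % missing calls, 0.5 %
miscalls, 1 % probe disagreement. What the simulator does **not**
emulate: raw array intensities and real dosage-calling error structure
(errors here are independent ±1 miscalls, not cluster-boundary
confusions), segregation distortion, preferential pairing, linkage
disequilibrium between parents, or population structure beyond the
father mixture. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under the stated model,
not their performance on any particular array dataset.

## Pipeline determinism and sizes

Every stochastic step draws from a named substream derived from the
single config seed via SHA-256, so identical config + seed reproduce all
output files byte for byte (asserted in the tests). The default
end-to-end run (1064 markers × 177 offspring) completes in under a
minute on one CPU; the clean-data map-recovery test (700 S×N markers,
n = 200) is the largest computation in the suite at about two minutes.

## Known limitations

* Two-point only: no multi-point/HMM refinement, no integrated consensus
  maps across populations, no QTL analysis.
* Polysomic likelihoods only for linkage; intermediate/mixed pairing
  behaviours are out of scope.
* Marker types beyond S×N, D×N, S×S and their allele-swap mirrors are
  excluded from scans (triplex/quadruplex-involved pairs carry little
  two-point information at these sample sizes).
* Homolog maps with 4–6 sparse markers can order imperfectly at n ≈ 100;
  where the true order's stress equals the fitted one this is a data
  limit, not a search failure.
* The Kosambi distance of the 1/3 repulsion fraction is reported as
  40.24 cM from the formula; quoting it as "≈ 39.5 cM" corresponds to
  rounding r ≈ 0.33 before transforming.
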