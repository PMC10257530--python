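# Methods

## Coordinate conventions

Per-cytosine call files use 1-based positions (the convention of
cytosine-report and coverage dialects); all interval tracks are half-open
0-based (BED). Conversions are explicit: a CpG at 1-based position *p* is the
point *p*−1 in interval space. CpG methylation is symmetric across strands,
so the − strand cytosine of a dinucleotide sits at *p*+1 and strand merging
sums it into the + strand record at *p*; orphan − records are re-keyed to
*p*−1. Merging conserves total methylated and unmethylated counts exactly.

## Filtering and uniting

Coverage filtering (default ≥5×) is applied per sample before uniting, and a
CpG enters a group's united matrix when it survives that filter in at least
`min_per_group` replicates (default 2 of 3). Both an all-sample overlap
(`min_per_group = n`) and the 2-of-3 rule are expressible; 2-of-3 is the
default because it defines the CpG universe used by every downstream
enrichment. The united matrix keeps per-sample counts with a presence mask,
so pooled group counts only include samples that captured the site at
threshold coverage. Output ordering is (chrom, pos)-sorted and invariant to
sample input order.

## Per-CpG test

The default `logistic_lrt` test compares binomial-logit models with and
without a group term on the per-replicate (methylated, unmethylated) counts.
Because the group indicator is the only covariate, the MLE of the full model
is attained at the pooled per-group proportions and the null at the overall
pooled proportion; the likelihood-ratio statistic therefore reduces exactly
to the pooled G-test with 1 df, which is how it is computed (vectorised over
all CpGs at once). The effect size is the difference of coverage-pooled
group proportions in percentage points; CpGs with zero pooled coverage in
either group are skipped with a log notice. `fisher_pooled` (two-sided exact
test on the pooled 2×2 table) is offered for unreplicated designs.

Multiple testing uses Benjamini–Hochberg over all tested CpGs. The DMC gate
is |Δ| ≥ 35 percentage points — read as inclusive, so a CpG at exactly
35.000 is called — and q < 0.01 (strict).

Calibration: on a zero-effect cohort drawn from the default bimodal
baseline, the fraction of CpGs with p < 0.05 is ≈0.042–0.043 (the suite
checks the [0.04, 0.06] band at 2×10⁵ CpGs). The mild conservatism comes
from the discreteness of near-0/near-1 sites, where the χ² approximation
under-rejects; at intermediate methylation the test is essentially nominal.

## DMR tiling

Chaining is single linkage on inter-DMC gaps: consecutive DMCs ≤500 bp apart
(inclusive, per neighbour distance — not tile diameter) join one tile. A raw
tile spans its member cytosines inclusively (width = max − min + 1 bp).
Tiles below 100 bp are padded symmetrically; an odd remainder goes to the
right, and the left edge clips at the chromosome start without compensating
on the right. Tiles with members of both signs are ambiguous and removed
(the removed fraction is reported); each remaining DMR's effect is the
unweighted mean of member differences. Tiling the members of a tile
reproduces its raw span (idempotence), every DMC lands in exactly one tile,
and output is input-order invariant.

Venn intersection of 2–3 same-direction DMR sets pools all tiles and forms
connected components under ≥1 bp overlap (single linkage); each component
counts once under the pattern of sets contributing to it. Components give
symmetric, order-free counts where per-set region counting would not.

## Odds-ratio enrichment

The background universe is the united, coverage-filtered CpG set
(configurable). Each universe CpG is classified by DMR membership × feature
membership; OR = ad/bc with the natural log reported. Zero cells are
flagged (OR = ∞ when ad > 0, undefined when both products vanish) rather
than continuity-corrected, so impossible ratios stay visible. The two-sided
Fisher p is computed by direct hypergeometric enumeration over the support,
summing probabilities not exceeding the observed table's (relative tie
tolerance 1 + 1e−7, the conventional guard for float ties); the test suite
verifies exact agreement with integer-arithmetic enumeration on all
135,751 tables of total ≤ 40. Counts are invariant to feature interval
fragmentation because tracks are flattened before membership testing.

Distance-to-TSS enrichment uses unsigned, strand-blind distances to the
nearest TSS, with default bins [0,1k), [1k,5k), [5k,10k), [10k,50k),
[50k,100k), ≥100k — edges chosen to bracket the near-promoter and distal
ranges of interest. Empty bins are reported counts-only.

## Profiles

The global summary is 100·Σm/Σn over all retained CpGs and present samples.
Histograms report the fractions strictly below 5% and above 95% methylation;
their sum is the bimodality proxy. Feature-centered profiles use the
interval midpoint (floored) as anchor — wide features need a defined center
and the midpoint is the only symmetric choice — with a 5-kb window in 50
bins of 100 bp; − strand features are flipped so negative offsets are
upstream. Bin values are coverage-weighted means; the smoothed curve is a
cubic smoothing spline (smoothing level by generalized cross-validation) on
the defined bins, a presentation-layer device — assertions are made on raw
bin means only. With fewer than 4 defined bins the curve falls back to
linear interpolation.

## Gene association

Regulatory domains follow the basal-plus-extension rule at its documented
defaults: basal = 5 kb upstream / 1 kb downstream of the TSS (strand-aware),
extended each way to the nearest other gene's basal domain or 1 Mb,
whichever is closer, never shrinking the gene's own basal domain. Two
neighbouring genes' extensions may both cover the gap between them, so a DMR
there associates with both genes; what the rule guarantees is that no
gene's domain encroaches on a neighbour's *basal* domain beyond whatever the
basal domains themselves share. Promoter partition labels an associated
gene "within" when ≥1 of its DMRs overlaps that gene's own promoter by
≥1 bp (genes are counted, not DMRs; the alternative DMR-counting convention
would weight multi-DMR genes differently). Top-*n* hypomethylated selection
sorts ascending by mean difference with (chrom, start) tie-breaks, making it
deterministic and idempotent. Cancer-role labels follow citation majority;
a gene with zero citations on both sides is "Neither" rather than the dual
label, which presupposes evidence exists.

## Bliss synergy

Expected combination viability is V_A·V_B on control-normalised fractions;
δ = V_expected − V_observed per replicate set, and the verdict is
mean δ > 0 over retained replicates. The 3-SD control outlier rule uses the
leave-one-out sample SD: with the candidate left in, |x − mean|/SD is
bounded by (n−1)/√n, which is below 3 for any plate with fewer than 11
replicate sets — the rule would be unsatisfiable at realistic plate sizes.
Leave-one-out restores the intended behaviour (a control at 1.80 among
{1.00, 1.01, 0.99} sits 80 SDs out and is excluded). A zero leave-one-out
SD with nonzero deviation counts as infinitely many SDs (excluded); with
only 2 replicates the leave-one-out SD is undefined and nothing is excluded.
Scoring is scale-consistent: percentages renormalised to fractions give
identical mean δ.

## Synthetic data

The generator emulates the structure of a four-arm (control + three
treatments) × three-replicate RRBS cohort:

- **CpG placement** — uniform over odd 1-based positions (so the − strand
  partner never collides with the next site), plus a guaranteed ≥8 CpGs per
  planted region, reflecting that differential regions arise in CpG-dense
  context; default 50,000 CpGs over 2 × 5 Mb.
- **Baseline** — two-component beta mixture, weights 0.45/0.55 with modes
  Beta(0.5, 10) near 0 and Beta(10, 0.5) near 1; ≈68% of sites fall below
  5% or above 95% methylation, the bimodal shape of somatic methylomes.
- **Planted regions** — non-overlapping 1-kb intervals whose treatment-group
  methylation is shifted by a signed effect (percentage points, clamped to
  [0, 1] as a fraction). Hypomethylated regions draw their baseline from the
  high mode and hypermethylated regions from the low mode, since a −40
  shift from a near-zero baseline (or +40 from a near-one one) is not
  expressible; biologically, demethylation presupposes methylation.
- **Coverage** — negative binomial with mean 30 and dispersion 5 per sample
  (typical RRBS per-CpG depth), with 5% site dropout; when stranded output
  is requested the site depth is split binomially between strands so strand
  merging restores site totals exactly.
- **Viability plates** — observed combination viability
  V_A·V_B − ε + N(0, σ²) floored at 0, singles and controls noised the same
  way (defaults V_A = 0.6, V_B = 0.5, σ = 0.05); optional planted control
  outliers displaced by a chosen number of noise SDs.

All generators are pure functions of (seed, parameters) through independent
named substreams, so annotation, methylome and plate randomness do not
interact and outputs are byte-identical across runs.

What the generator does *not* emulate: restriction-site-driven CpG
clustering and fragment-length bias, PCR duplicates and conversion errors,
coverage correlation along fragments, batch effects, and spatially
structured baselines. Passing tests therefore demonstrate the correctness
and calibration of the analysis machinery under a clean generative model,
not robustness to those real-data artifacts.

## Problem sizes and numerical choices

The default test suite and the acceptance script run cohorts of 2×10⁴–2×10⁵
CpGs over 2–20 Mb genomes with 100 planted regions — large enough for
stable rate estimates (Monte-Carlo error on the null calibration fraction is
≈0.0005 at 2×10⁵ CpGs) while keeping a full run in seconds. Degenerate
inputs are defined behaviours, not crashes: empty call files parse to empty
sets, an empty DMC stage propagates empty-but-valid artifacts downstream,
empty enrichment bins are flagged, and zero-coverage CpGs are skipped with
notices. Ties are fixed deterministically throughout (tile padding to the
right, top-*n* by coordinate, mergesort everywhere ordering matters).

## Known limitations

- The per-CpG test ignores overdispersion between replicates beyond the
  binomial; replicate-aware shrinkage or beta-binomial models are out of
  scope, and exact DMC counts from other callers will differ with their
  test and q-value method.
- The Fisher p enumeration is exact but O(support) per table; for very
  large universes the normal-approximation alternatives would be faster but
  are not implemented.
- Gene association assumes TSS-defined regulatory domains; enhancer-capture
  or contact-map-based assignment is not modelled.
- The smoothing spline is a display device; no inference is attached to the
  smoothed curves.
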