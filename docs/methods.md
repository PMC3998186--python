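# Methods

## Band matrices and reproducibility filtering

A RAPD profile is a binary vector over bands identified by
`(primer, approximate size in bp)`; band identity across samples follows the
gel-scoring convention exactly, with no tolerance matching of sizes.  The
reproducibility rule keeps a band for a sample only when it appears in at
least `min_count` (default 2) replicate amplifications; raising `min_count`
is monotone (it can only remove bands), and `min_count = 1` gives the union
of replicates.

Per-primer summaries follow the conventions of marker screens: a band
column counts toward a primer's **total** when amplified in at least one
sample (a column absent everywhere was never observed and is excluded); it
is **polymorphic** when present in some but not all samples; the
polymorphism percentage is `100 · polymorphic / total`, reported as missing
for a primer with no amplified bands.  Note integer band counts quantize the
attainable percentages — e.g. a 7-band primer can show 85.7% (6/7) but not
98% — so summaries of real screens should be read at that granularity.

## Similarity, distance, UPGMA

`Ssm` is the fraction of band positions at which two samples agree, both
presences and both absences (computed as 1 − Hamming fraction); the genetic
distance is `d = 1 − Ssm`, chosen because it maps the similarity extremes
onto the distance extremes a marker study reports on a [0, 1] scale.

UPGMA repeatedly merges the two clusters at minimal distance, placing the
merge node at **half** that distance; the distance from the merged cluster
to any other is the size-weighted arithmetic mean
`(|A|·d(A,C) + |B|·d(B,C)) / (|A| + |B|)`, which equals the unweighted mean
over all member pairs of the original matrix — the defining property of the
method.  Ties at the minimal distance are broken toward the smallest
(row, column) index pair in the current cluster order, making output
deterministic; when a merge happens, the child whose subtree contains the
earlier input sample is written first, fixing the Newick string too.
Merge heights are non-decreasing, so the result is always ultrametric, and
ultrametric inputs are fixed points: `cophenetic(upgma(d)) = d`.

Distance matrices are exchanged as PHYLIP square matrices, trees as Newick
with branch length = parent height − child height.  `read_newick` rejects
non-ultrametric input (tolerance 1e-6 relative to tree height).

## Densitometric calibration

The standard curve is ordinary least squares **of concentration on peak
area**.  For a calibration used exclusively for inverse prediction this
direction estimates the predictor of interest directly and avoids the bias
of inverting an area-on-concentration fit at the observed areas; it is also
the direction under which the packaged standard series reproduces the
published per-species table.  Reported concentrations are rounded to one
decimal, the table convention; replicate SDs use ddof = 1 and are defined as
0 for a single replicate.  A predicted concentration below zero (area below
the calibrated range) is returned with a warning rather than clamped.

Identity of the quantified spot is checked by Rf agreement with the
verbascoside standard (Rf 0.65 in ethylacetate:water:formic acid 10:3:2);
the default tolerance of 0.02 reflects typical plate-to-plate Rf
repeatability, since exact equality of measured Rf values is not a workable
criterion.  Linearity diagnostics back-predict each standard through the
fitted curve; on the packaged four-point series the 9.0 mg/mL standard
back-predicts at 8.63 mg/mL, a visible scatter (residual SD 0.37 mg/mL)
that propagates into one-decimal disagreements of the same order in the
sample table.

Units: the packaged tables use the printed table units (standards at
3.0–12.0), which differ from the named solution concentrations
(0.3–1.2 mg/mL) by a constant factor; the calibration is invariant to that
rescaling and no unit conversion is applied.

## Mantel concordance

Metabolite levels are turned into a distance by `|mean_i − mean_j|`,
rescaled by the maximum difference to [0, 1].  The Mantel statistic r is the
Pearson correlation of the strict upper triangles; the test is one-sided
for positive association (the scientific claim is directional).  For n ≤ 7
samples all n! relabelings are enumerated and p is the exact fraction with
`r_perm ≥ r_obs`; otherwise p = `(1 + #{r_perm ≥ r_obs}) / (n_perm + 1)`
over seeded random permutations (default 999), which is a valid p-value by
construction.  A constant upper triangle leaves r undefined and is an
error, not a silent NaN.

## Synthetic data generator

Bands evolve independently on a known tree: root presence Bernoulli(`p0`),
loss along a branch of length t with probability `1 − e^{−μt}` (a mutation
at the primer site abolishes the product), gain with per-branch probability
`g`.  A truly present band is detected in each of `r` replicate gels with
probability `q`; the analysed matrix applies the ≥2-replicate rule.
Defaults: 30 primers × 10 candidate bands (the scale of a full RAPD screen
reporting 4–16 scored bands per primer), `p0 = 0.6`, `μ = 0.5` per unit
branch length (a moderate loss rate giving mixed shared/variable bands on
trees with branch lengths of order 0.1–1), `g = 0.01` (homoplasy exists but
is rare), `r = 3`, `q = 0.95` (visual scoring misses an occasional faint
band).  No quantitative mutation model exists for the real assay, so μ, g
and q are modelling choices, fixed here once.

What the generator does *not* emulate: linkage between bands (all bands are
independent), comigration of non-homologous fragments of similar size,
intensity variation, or partial amplification — so tests passing on
synthetic data demonstrate the correctness of the analysis chain, not the
fidelity of RAPD scoring on real gels.

The densitometry generator inverts the calibration
(`area = (conc − intercept)/slope`) and adds Gaussian noise (default SD
2000 area units, ≈0.05 mg/mL through the default slope) to every
measurement; each standard level and each sample receives `n` (default 5)
replicate tracks, mirroring the five-fold analysis protocol.  Noiseless
simulation followed by fitting and quantification is an exact round trip.

## Problem sizes and numerical checks

The validation suite runs UPGMA against a brute-force average-linkage
oracle on 500 random matrices of up to 6 taxa, recovers a generating
quartet topology from 100 simulated 120-band screens, calibrates the Mantel
test's type-I error over 1000 null simulations at n = 9 with 999
permutations each, and checks noisy slope recovery over 200 generator
seeds against the slope's true sampling SD (`slope · σ_area / √Sxx`).
These sizes give stable Monte-Carlo estimates while keeping the whole suite
fast.  All simulations are seeded; fixed seeds reproduce bit-for-bit.

## Known limitations

* The study's real band matrix was never published, so its specific
  similarity values and dendrogram cannot be regenerated; the synthetic tree
  in `data/` is a labelled stand-in mirroring the sampled accessions.
* Replicate-level densitometer readings behind the published per-sample SDs
  are likewise unavailable; the packaged tracks carry one printed mean area
  per sample, so refitted SDs are 0.
* One published sample concentration (9.1 mg/mL) differs from the value the
  four-point calibration yields from its printed area (9.0); it most likely
  reflects replicate data we lack, and is treated as a documented
  discrepancy rather than a target.
* UPGMA assumes a clock-like divergence; on strongly rate-heterogeneous
  data its topology can be wrong even with perfect distances.
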