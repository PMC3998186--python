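# chemotax

Chemotaxonomy links molecular-marker variation to secondary-metabolite
chemistry.  `chemotax` implements both measurement arms of a RAPD + HPTLC
study of *Phlomis* (Lamiaceae) species and the statistic that joins them:

* **RAPD marker analysis** — binary band matrices (samples × bands grouped
  by primer), reproducibility filtering (a band counts only when seen in at
  least two replicate gels), per-primer polymorphism percentages and
  unique-band counts.
* **Genetic distances and clustering** — simple matching coefficient
  `Ssm(i,j) = (#1–1 matches + #0–0 matches) / #bands`, genetic distance
  `d = 1 − Ssm`, and UPGMA agglomeration (merge height = half the
  size-weighted mean inter-cluster distance), giving an ultrametric
  dendrogram exported as Newick.
* **HPTLC densitometry** — ordinary least squares of concentration on peak
  area over a four-level verbascoside standard series, inverse prediction of
  sample concentrations with replicate mean ± SD, Rf specificity checks and
  linearity diagnostics.
* **Concordance** — a one-sided Mantel permutation test between the genetic
  distance matrix and the matrix of absolute verbascoside-level differences
  (exact enumeration of all n! relabelings for n ≤ 7).
* **Synthetic data** — band matrices simulated as independent binary
  characters on a known tree (root presence `p0`; loss `1 − e^{−μt}` along a
  branch of length `t`, modelling primer-site mutation; small gain
  probability `g`; per-replicate detection `q`), and densitometry tables
  with Gaussian area noise — so every downstream stage is testable without
  gel photographs or chromatograms.

The library lives in `src/chemotax/`; the numbered scripts in `analysis/`
run the study's analyses in order and write their tables under `results/`.

## Worked example

Quantify verbascoside from the packaged densitometric tables (the published
standard series and per-species peak areas):

```sh
python analysis/04_quantify_verbascoside.py
```

```
calibration: conc = 2.2846e-05 * area + -1.9405 (R^2 = 0.9939, residual SD = 0.370 mg/mL)
largest back-prediction residual: +0.37 mg/mL at the 9.0 mg/mL standard
olivieri_azerbayjan     3.9
olivieri_tabriz         8.6
olivieri_mazandaran     9.0
...
anisodonta             11.3
highest verbascoside level: anisodonta (11.3 mg/mL)
```

The slope converts densitometer area units to mg/mL; the per-sample numbers
are inverse-predicted concentrations at one-decimal rounding.  *P.
anisodonta* carries the highest verbascoside level and *P. olivieri*
(Azerbayjan) the lowest, with the three *P. olivieri* accessions spanning
3.9–9.0 mg/mL.

The marker arm runs the same way:

```sh
python analysis/01_simulate_bands.py   # replicate gels on a synthetic 15-sample tree
python analysis/02_band_summary.py     # polymorphism % per primer, unique bands
python analysis/03_distances_tree.py   # Ssm, d, UPGMA -> results/upgma.nwk
python analysis/05_concordance.py      # Mantel r, p between the two arms
```

or through the console script, stage by stage:

```sh
chemotax simulate-bands --tree data/synthetic_study_tree.nwk --seed 0 --out-dir results
chemotax distances results/bands.tsv --out-dir results
chemotax tree results/distances.phylip --out-dir results
```

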