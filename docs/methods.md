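# Methods

This note records the models, parameter choices and numerical conventions
behind `nucint`, and what the synthetic-data validation does and does not
establish about real data.

## AP-MS composite score

Each candidate protein in a bait immunoprecipitation is scored as
`S = FC × v × E`: peptide-count fold change over the no-antibody control
(NAC), sequence coverage %, and IP efficiency (the bait's own IP/NAC
enrichment — a per-sample quality factor that is identical for every
protein in that sample). The design is two epitope tags × three biological
replicates = six samples; dual tagging suppresses tag-specific non-specific
binders.

Choices that the verbal description of such a score leaves open, and how
this implementation resolves them:

- **Zero denominators.** `FC = c_IP / max(c_NAC, 1)`. A protein absent from
  the control keeps a finite, strongly enriched ratio with plain-ratio
  semantics for detected controls. A symmetric `(c+1)/(c+1)` pseudocount
  policy is available via `policy="pseudocount"`.
- **Replicate aggregation.** Per-sample FC and coverage are averaged over
  all six samples, with samples where the protein was undetected imputed as
  zero. This rewards reproducible detection across both tags; a
  `pooled=True` alternative sums counts across samples before forming one
  ratio. Efficiency `E` is the mean of the per-sample bait efficiencies.
- **Ranking.** Descending score; ties broken by higher aggregated FC, then
  lexicographic protein id, so output order is deterministic. The bait is
  excluded from the candidate list by default (`include_bait=True` restores
  it). Fractions (nuclear/cytoplasmic) are scored independently; nuclear is
  the default.
- **Arithmetic.** Component means use plain sequential summation, so an
  independent naive-loop recomputation reproduces the scores bit for bit;
  the stored score always equals the product of the three stored components.

## BiFC image classification

Nuclei are segmented from DAPI by Otsu thresholding + connected components,
discarding objects under 50 px (parameter-free stand-in for the
proprietary software used on the original instrument). Each cell's
cytoplasmic region is a 5 px ring obtained by nearest-label expansion of
the nuclei, so pixels contested between adjacent cells go to the nearer
nucleus and rings never overlap nuclei. Local background is the median of
pixels outside all expanded cell regions, per field.

Per cell, over nucleus ∪ ring: the positivity statistic is the
**90th percentile of background-corrected Venus** (robust to single hot
pixels while still catching punctate signal — the per-cell statistic
compared against the published grey-level threshold is a documented
assumption of this implementation, as is computing the Venus–DAPI Pearson
correlation over nucleus ∪ ring). Decision sequence, with defaults on the
16-bit grey scale:

1. level < 1000 above local background (detectability floor) or
   ≤ 2500 (positivity) → `negative`;
2. Venus–DAPI correlation ≥ 0.8 → `nuclear`;
3. cytoplasm/nucleus Venus median quotient ≥ 1.2 → `cytoplasmic`;
4. otherwise `mixed`.

Both thresholds are inclusive ("equal or above"). Nuclear precedence over
cytoplasmic is a design choice; the rules themselves do not order the two.
A constant Venus region has no defined correlation: it is recorded as r = 0
with `corr_defined=False`, which the decision sequence then treats as
non-nuclear. The live-cell counting mode instead calls a nucleus positive
on any detectable signal — operationalized as nuclear Venus median more
than three background MADs above background unless an explicit threshold is
given.

Line profiles sample channels by bilinear interpolation at unit-pixel steps
along a polyline (`ceil(length)+1` samples including both endpoints),
averaged across the requested line width using perpendicular offsets;
off-field control points are an error, while width offsets at the border
clamp to the nearest pixel.

## Group statistics

Student's t is the classic pooled-variance two-sided test (Welch behind
`equal_var=False`); the Shapiro–Wilk gate uses α = 0.05 and reports
zero-variance samples as degenerate failures rather than raising.
Significance bands: \*\*\* p < 0.0001, \*\* p < 0.001, \* p < 0.05, else ns
(strict inequalities). qPCR quantification is the comparative-Ct method:
technical repetitions are averaged on the Ct scale, then
`fold = 2^−(ΔCt_sample − ΔCt_control)` with ΔCt = Ct_target − Ct_reference
(Rp49 as the conventional fly reference); the control sample's fold is
exactly 1 by construction. ChIP-qPCR enrichment is percent input with the
saved input fraction defaulting to 5%. No multiple-testing correction is
applied, matching the pairwise-comparison workflow the package supports.

## Synthetic-data generators

The generators define the validation conditions; their defaults are fixed
and the tests run against them.

- **AP-MS** (`ApmsSimConfig`): spectral counts are Poisson around per-class
  means — background proteins bind non-specifically, so IP and NAC share a
  mean of 5 counts; planted interactors are enriched 10-fold in the IP with
  5% of that signal leaking into the NAC; the bait draws around 60 (IP) and
  3 (NAC). Coverage is truncated-normal, mean 25% ± 8 on (0, 100]. Dropout
  (default 10%) independently zeroes a protein's IP count and coverage per
  sample; the bait is exempt, since per-sample efficiency requires it.
  Default design: 20 planted interactors, 200 background proteins, 2 tags ×
  3 replicates, nuclear fraction. `deterministic=True` replaces draws with
  rounded means — the noiseless limit in which exact top-20 recovery is
  asserted.
- **BiFC fields** (`ImageSimConfig`): 512×512 single-plane 16-bit images,
  50 cells, nucleus radius 8 px inside a 14 px cell radius, placed by
  rejection sampling with a 2×cell-radius minimum centre distance (failure
  past an attempt budget raises with a suggestion to request fewer cells).
  Grey levels: DAPI 20 000, Venus signal 12 000 (nuclear disk or
  cytoplasmic annulus by label), background 300, Gaussian noise σ = 50 by
  default (σ = 100 in the robustness checks). 60% of cells are positive,
  half of those nuclear. Labels are drawn per cell, so the truth sidecar
  records the realized — not the expected — composition.
- **qPCR** (`generate_qpcr_table`): a fold f shifts the target Ct by
  −log₂ f cycles from a base of 24 (reference fixed at 18), with per-well
  Gaussian Ct noise and two technical repetitions per (sample, gene).

What these emulate — and what they do not: count overdispersion beyond
Poisson, correlated dropout, tag-specific binders, uneven illumination,
overlapping or irregular nuclei, autofluorescence, and amplification-
efficiency drift are all absent. Passing the synthetic checks therefore
demonstrates the correctness of the arithmetic, rules and ranking logic
under the stated generative model, not segmentation or scoring performance
on real instrument data.

## Validation design

Score arithmetic is checked against an independent brute-force naive-loop
recomputation on random mini-datasets (exact equality); Shapiro–Wilk and
Student's t are checked to 1e-6 against values computed once with an
independent reference implementation (R 4.3 `shapiro.test` / `t.test`) on
frozen seeded samples; classifier accuracy is measured against generator
truth by matching detected nucleus centroids to planted centres. Problem
sizes (100 mini-datasets, 10 fields of 50 cells per noise level, 20 + 10
frozen statistical samples) were chosen to keep the full validation suite
in the tens of seconds while leaving each check statistically meaningful.

## Known limitations

- The per-cell positivity statistic and correlation region are assumptions
  (see above); real high-content software may differ in both.
- Otsu segmentation presumes well-separated, roughly uniform nuclei.
- The score is the plain three-factor product — no probabilistic
  interaction model (SAINT-style) is provided.
- qPCR assumes perfect (2-fold per cycle) amplification efficiency.
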