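# nucint — nuclear interactome quantification

`nucint` is a Python toolkit for the quantitative analyses that accompany a
nuclear interactome study built around a tagged bait protein: scoring
candidate interactors from affinity-purification mass spectrometry (AP-MS)
hit tables, classifying bimolecular fluorescence complementation (BiFC /
split-Venus) images per cell, and the small-sample statistics used for
qPCR and ChIP-qPCR readouts. It is aimed at bench scientists and analysts
who have replicate hit tables or high-content image fields and want the
published scoring and classification rules as tested, scriptable code.

Every stage has a seeded synthetic-data generator that emits ground truth
alongside the data, so the whole pipeline can be exercised and validated
without any raw instrument output.

## The core quantities

**AP-MS composite score.** For each candidate protein detected in a bait IP
against a no-antibody control (NAC), aggregated over the six biological
replicate samples (three per epitope tag, GFP and HA):

    S = FC × v × E

where `FC` is the peptide-count fold change IP/NAC, `v` the sequence
coverage % and `E` the IP efficiency — the bait protein's own IP/NAC
enrichment, a per-sample quality factor. Ratios floor the denominator at
one count (configurable), per-sample values are averaged over all six
samples with missing detections imputed as zero, and candidates are ranked
by descending score. Membership of an annotated complex (e.g. Mediator)
among the top N is summarized from the ranked list.

**BiFC per-cell classifier.** Nuclei are segmented from DAPI (Otsu +
connected components), each cell gets a cytoplasmic ring, and the Venus
channel is classified per cell: *negative* unless the background-corrected
Venus level exceeds 2500 grey levels (with a 1000 grey-level detectability
floor), *nuclear* if the Venus–DAPI Pearson correlation is ≥ 0.8,
*cytoplasmic* if the cytoplasm/nucleus median quotient is ≥ 1.2, *mixed*
otherwise. Percent positive is reported relative to the total cell count.
A separate live-cell mode counts any detectable nuclear signal as positive,
and a line-profile utility samples channel intensities along hand-fitted
polylines.

**Group statistics.** Shapiro–Wilk normality gate, pairwise Student's
t-tests with the usual significance bands (\*\*\* p < 0.0001, \*\* p < 0.001,
\* p < 0.05), mean ± s.d. summaries, qPCR relative expression by 2^−ΔΔCt
against a reference transcript (Rp49 by default), and ChIP-qPCR enrichment
as percent input.

## Worked example

```python
import nucint as ni

config = ni.ApmsSimConfig(seed=1)          # 20 planted interactors, 200 background
table, truth = ni.generate_apms_counts(config)
ranked = ni.score_proteins(table, bait_id=config.bait_id, fraction="nuclear")
print(ranked.head(3).to_string(index=False))
```

```
protein_id  fold_change  coverage_pct  ip_efficiency        score  rank  n_replicates_detected
    INT010    35.263889     32.830667      35.222222 40778.069237     1                      6
    INT006    34.616667     30.045000      35.222222 36633.145194     2                      6
    INT007    35.750000     28.932167      35.222222 36431.223532     3                      6
```

Each row shows the three aggregated score components and their product:
`INT010` was seen with a mean 35.3-fold peptide-count enrichment over the
control at 32.8 % mean coverage, in all six replicate samples. Summarizing
the planted truth set against the ranking
(`ni.complex_membership_summary(ranked, annotation, top_n=40)`) reports

```
20 of 20 planted interactors rank in the top 40 (worst planted rank: 20)
```

i.e. the score separates every true interactor from the non-specific
background. The scripts in `examples/` walk through each capability the
same way (image classification, line profiles, qPCR/ChIP statistics); a
thin CLI mirrors them (`nucint simulate|score|classify|profile|stats`).
Real hit tables with foreign column names can be ingested via
`ni.read_hit_table(path, column_map={...})`.

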