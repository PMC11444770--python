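"""Score and rank candidate interactors from replicate AP-MS hit tables.

Simulates the full six-sample design (GFP and HA tags, three biological
replicates each) with 20 planted true interactors among 200 non-specific
background proteins, runs the composite score S = fold change x coverage %
x IP efficiency, and summarizes membership of an annotated complex among
the top hits.

To score a real hit table instead, load it with
``nucint.read_hit_table(path, column_map=...)`` — the column map lets a
supplementary table with foreign column names be ingested unchanged — and
pass the result to ``score_proteins`` exactly as below.
"""

import nucint as ni

config = ni.ApmsSimConfig(seed=1)
table, truth = ni.generate_apms_counts(config)
ranked = ni.score_proteins(table, bait_id=config.bait_id, fraction="nuclear")

print(ranked.head(10).to_string(index=False))
# Each row: aggregated fold change (IP vs no-antibody control), mean coverage %,
# mean bait IP efficiency, their product (the score) and the resulting rank.

annotation = ni.ComplexAnnotation("planted interactors", truth.true_interactors)
summary = ni.complex_membership_summary(ranked, annotation, top_n=40)
print(f"\n{summary['n_in_top_n']} of {len(truth.true_interactors)} planted "
      f"interactors rank in the top {summary['top_n']} "
      f"(worst planted rank: {summary['member_ranks'][-1][1]})")
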