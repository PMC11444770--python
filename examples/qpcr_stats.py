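"""Relative expression, group comparison and ChIP enrichment.

Simulates a qPCR experiment where the treatment halves target expression
(true fold 0.5 vs control, Rp49 as reference gene), quantifies it by
2^-ddCt, compares the groups with the Shapiro-Wilk-gated Student's t-test,
and converts a ChIP-qPCR quantity pair to percent input.
"""

import nucint as ni

table = ni.generate_qpcr_table([1.0, 0.5], n_reps=3, ct_noise_sd=0.15, seed=2)
folds = ni.relative_expression(table, control_sample="control_r1",
                               reference_gene="Rp49")
print(folds.to_string(index=False))

control = ni.GroupSample("control", tuple(
    folds[folds["sample"].str.startswith("control")]["fold_change"]))
treated = ni.GroupSample("treated", tuple(
    folds[folds["sample"].str.startswith("group1")]["fold_change"]))
res = ni.pairwise_t_test(control, treated)
mean_t, sd_t = ni.summarize(treated)
print(f"\ntreated fold: {mean_t:.3f} +/- {sd_t:.3f} (mean +/- s.d., n=3)")
print(f"Student's t = {res.statistic:.3f}, df = {res.df:.0f}, "
      f"p = {res.p_value:.4f} [{res.significance_band}], "
      f"normality pass = {res.normality_pass}")

pct = ni.chip_enrichment(ip_quantity=0.8, input_quantity=1.6,
                         input_fraction_saved=0.05)
print(f"\nChIP recovery: {pct:.2f}% of input chromatin")
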