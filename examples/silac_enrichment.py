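"""Quantify UV-dependent protein enrichment from a simulated SILAC table.

Simulates a peptide evidence table with 10% planted RNA binders (4-fold
enrichment in the irradiated channel) and intensity-dependent missingness,
then runs the full pipeline: filtering, left-censored imputation, +UV/-UV
ratios, median-of-peptides aggregation, and the moderated t-test.
"""

from trappkit import ImputationParams, SilacSimConfig, run_enrichment, simulate_silac_table

config = SilacSimConfig(n_proteins=300, binder_fraction=0.1, binder_log2_effect=2.0, seed=5)
table, truth = simulate_silac_table(config)
design = {"exp1": "forward", "exp2": "forward", "exp3": "reverse"}

result = run_enrichment(table, design, ImputationParams(q=0.1, tune_sigma=0.01, seed=5))
truth = truth.set_index("protein")

called = result[result["enriched"]]
binders = set(truth.index[truth["is_binder"]])
tp = len(set(called.index) & binders)
print(f"{len(result)} proteins tested, {len(called)} called enriched "
      f"(adjusted p < 0.05), {tp} of them true binders")
print(f"planted binders quantified: {len(binders & set(result.index))}")

print("\ntop enriched proteins:")
cols = ["mean_log2_ratio", "t", "p_adjusted"]
print(called.sort_values("p_adjusted")[cols].head(8).to_string(float_format="%.3g"))
print("\nmean_log2_ratio ~ 2 recovers the planted 4-fold UV enrichment.")
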