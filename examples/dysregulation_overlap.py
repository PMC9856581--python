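"""Tumor- and age-associated pathway dysregulation and their overlap.

Per cancer type: a pooled t-test of tumor vs normal scores (BH-adjusted) and
an OLS age trend on tumor samples, followed by Fisher's exact test of the
overlap between the two significant pathway sets.
"""

import immunoaging as ia

cohort = ia.generate_cohort(ia.SimulationConfig(seed=2))
scores = ia.minmax_normalize_per_group(
    ia.score_all(cohort.expression, cohort.gene_sets),
    cohort.metadata["cancer"])

for cancer, meta in cohort.metadata.groupby("cancer"):
    block = scores.scores[meta.index]
    tumor = ia.tumor_differential(block, meta["is_tumor"].to_numpy(), cancer=cancer)
    ages = ia.model_ages(meta)
    age = ia.age_trend(block[ages.index], ages.to_numpy(), cancer=cancer)

    tumor_sig = set(tumor.index[tumor["significant"]])
    age_sig = set(age.index[age["significant"]])
    overlap = ia.overlap_test(tumor_sig, age_sig, universe=scores.scores.index,
                              tumor_direction=tumor["direction"].to_dict(),
                              age_direction=age["direction"].to_dict(),
                              cancer=cancer)
    print(f"{cancer}: tumor-dysregulated={len(tumor_sig)} "
          f"age-dysregulated={len(age_sig)} both={overlap.a} "
          f"Fisher p={overlap.p_value:.3g} "
          f"concordant={overlap.concordant_count} "
          f"discordant={overlap.discordant_count}")

print()
print("'both' counts pathways significant in the tumor and the age analysis;")
print("concordant means the two effects point the same way, the pattern the")
print("Fisher test asks about when its p-value is small.")
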