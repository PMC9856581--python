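"""Discriminating immunotherapy responders with pathway scores.

Simulates a responder / non-responder cohort where one pathway's genes are
shifted upward in responders, scores all pathways with ssGSEA, and reports
per-pathway AUC and Wilcoxon rank-sum p-values.
"""

import immunoaging as ia

cohort = ia.generate_response_cohort(n_resp=50, n_nonresp=50, shift=3.0, seed=5)
report = ia.evaluate_cohort(cohort, alpha=0.25)

print(report.round(4).sort_values("auc", ascending=False).head(6))
print()
print(f"planted pathway: {cohort.shifted_pathway} "
      f"(AUC {report.loc[cohort.shifted_pathway, 'auc']:.3f})")
print("AUC is the probability a random responder outscores a random")
print("non-responder; pathways with AUC > 0.7 are flagged as discriminative,")
print("and only the planted pathway should clear that bar here.")
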