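"""Recover planted driver genes from a synthetic cohort.

Simulates a 40-gene cohort (a quarter TSG-like, a quarter
oncogene-like, half neutral), runs both gene-level analyses, and scores
how well each analysis recognises its target class: TSG-like genes by
the signed damage-enrichment score, oncogene-like genes by the EDC of
recurrent mutations. AUC 1.0 is perfect ranking, 0.5 is chance.
"""

from oncostruct import generate_mutation_cohort
from oncostruct.pipeline import recovery_scores

cohort = generate_mutation_cohort(n_genes=40, seed=7)
scores = recovery_scores(cohort)

print(f"genes simulated                : {scores['n_genes']}")
print(f"genes with a recurrent EDC     : {scores['n_edc_reported']}")
print(f"TSG-like recovery by damage    : AUC = {scores['tsg_damage_auc']:.3f}")
print(f"oncogene-like recovery by EDC  : AUC = {scores['oncogene_edc_auc']:.3f}")
print("both well above 0.5: damage enrichment finds the loss-of-function genes,")
print("spatial clustering of recurrent mutations finds the gain-of-function ones")
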