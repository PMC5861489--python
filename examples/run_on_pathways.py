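"""Score pathway ego-subnetworks on a cohort with a hidden subtype.

Builds a synthetic two-phenotype cohort in which only half of the "disease"
samples carry a 3-fold perturbation of one pathway's genes, generates
ego-network candidates from a small pathway collection, and runs both the
subpopulation-sensitive (SPSNet) and whole-phenotype (PFSNet) scorings.
"""

import numpy as np

from spsnet import (
    ExpressionMatrix,
    PhenotypeAssignment,
    generate_base_cohort,
    generate_ego_subnetworks,
    results_to_frame,
    run_spsnet,
)
from spsnet.containers import PathwayCollection

rng = np.random.default_rng(0)

# 500 genes x 40 samples; samples s0001..s0020 are controls
base = generate_base_cohort(500, 40, seed=0)
control = base.samples[:20]
disease = base.samples[20:]

# hidden subtype: only 10 of the 20 disease samples are perturbed,
# on the 12 genes of pathway PW1
values = base.values.copy()
perturbed_genes = list(range(12))
hidden_subtype = disease[:10]
cols = [base.sample_index(s) for s in hidden_subtype]
values[np.ix_(perturbed_genes, cols)] *= 3.0
expr = ExpressionMatrix(base.genes, base.samples, values)

# two pathways: the perturbed one and an untouched control pathway
def chain_with_hub(genes):
    edges = {frozenset({genes[0], g}) for g in genes[1:]}
    edges |= {frozenset({a, b}) for a, b in zip(genes[1:], genes[2:])}
    return edges

pathways = PathwayCollection({
    "PW1": chain_with_hub(base.genes[:12]),
    "PW2": chain_with_hub(base.genes[100:112]),
})
subnetworks = generate_ego_subnetworks(pathways, min_size=5)
phen = PhenotypeAssignment(frozenset(control), frozenset(disease))

for mode in ("spsnet", "pfsnet"):
    results = run_spsnet(expr, phen, subnetworks, mode=mode, x=10,
                         theta1=0.05, theta2=0.15)
    frame = results_to_frame(results)
    sig = frame[frame["significant"]]
    print(f"\n{mode}: {len(sig)}/{len(frame)} subnetworks significant")
    cols_to_show = ["subnetwork_id", "direction", "mean_sps_score", "p_value",
                    "passed_filter", "significant"]
    print(frame[cols_to_show].to_string(index=False))

print(
    "\nThe perturbed pathway's subnetwork (PW1::*) is reported significant"
    "\neven though only half the disease samples carry the signal. The"
    "\nuntouched pathway PW2 can show a small t-test p-value (selection"
    "\nnoise in the representative sets), but it fails the beta >= 0.5"
    "\nrelevance filter and is therefore not reported — the filter is what"
    "\nkeeps the false-positive rate controlled."
)
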